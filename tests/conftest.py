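"""Shared fixtures: compact builders for peak-groups and a reusable
simulated training set (expensive fixtures are session-scoped)."""

from __future__ import annotations

import pytest

from peakdecoder.config import RunConfig
from peakdecoder.core_model import (DECOY, TARGET, PeakGroupXIC,
                                    TransitionRecord, XICMetrics)
from peakdecoder.synthetic_data import SimulationConfig, simulate_peakgroups


def make_metrics(area=1000.0, height=500.0, fwhm=0.15, rt=5.0,
                 mass_error_ppm=2.0, run_id="run1") -> XICMetrics:
    return XICMetrics(area=area, height=height, fwhm=fwhm, rt=rt,
                      mass_error_ppm=mass_error_ppm, run_id=run_id)


def make_group(group_id="G1", run_id="run1", label=TARGET, precursor=None,
               precursor_sn=50.0, fragments=None, expected_rt=None,
               expected_ccs=None, observed_ccs=None,
               paired_group_id=None) -> PeakGroupXIC:
    """A peak-group whose fragments are given as (mz, expected_intensity,
    XICMetrics) triples."""
    precursor = precursor or make_metrics(area=5e4, height=1e4, run_id=run_id)
    frag_list = []
    for mz, expected, metrics in (fragments or []):
        rec = TransitionRecord(group_id=group_id, label=label,
                               is_precursor=False, mz=mz,
                               expected_intensity=expected,
                               precursor_mz=300.0,
                               paired_group_id=paired_group_id)
        frag_list.append((rec, metrics))
    return PeakGroupXIC(group_id=group_id, run_id=run_id, label=label,
                        precursor=precursor, precursor_sn=precursor_sn,
                        fragments=frag_list, expected_rt=expected_rt,
                        expected_ccs=expected_ccs, observed_ccs=observed_ccs,
                        paired_group_id=paired_group_id)


def good_fragment(mz=150.0, expected=5000.0, prec=None, **overrides):
    """A fragment whose metrics sit comfortably inside every quality band
    relative to the given precursor metrics."""
    prec = prec or make_metrics(area=5e4, height=1e4)
    kwargs = dict(area=expected * prec.fwhm, height=expected,
                  fwhm=prec.fwhm, rt=prec.rt, mass_error_ppm=1.0,
                  run_id=prec.run_id)
    kwargs.update(overrides)
    return (mz, expected, XICMetrics(**kwargs))


@pytest.fixture(scope="session")
def sim_default() -> "SimulatedData":
    """Default-condition simulation reused by classifier-level tests."""
    cfg = SimulationConfig(n_true_groups=400, n_false_groups=400, n_runs=1,
                           seed=11)
    return simulate_peakgroups(cfg)


@pytest.fixture(scope="session")
def trained_default(sim_default):
    """Model + FDR table trained on the default simulation."""
    from peakdecoder.cli import run_training

    model, table, vectors, audit = run_training(sim_default.groups,
                                                RunConfig(seed=11))
    return {"model": model, "table": table, "vectors": vectors,
            "audit": audit, "sim": sim_default}
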