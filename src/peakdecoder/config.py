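"""Workflow defaults and run configuration.

Every numeric default used by the pipeline lives in one place so that a run
is fully described by a :class:`RunConfig`.  The values are the published
operating points of the method:

========================  =======  ==========================================
parameter                 default  meaning
========================  =======  ==========================================
target_min_sn             15       min precursor S/N for a feature to become
                                   a training target
target_min_fragments      3        min in-band fragments per target
rel_intensity_range       1%-130%  fragment intensity relative to precursor
                                   height that counts as in-band
target_top_n_fragments    16       most intense fragments kept per target
pair_mz_window            50 Th    max precursor m/z difference for pairing
pair_min_rt_gap           3 min    min RT separation of paired targets
swap_fraction_range       0.4-0.6  fraction of fragments whose m/z is swapped
                                   between a pair of decoys
filter_min_precursor_sn   20       training filter: precursor S/N floor
frag_max_mass_error_ppm   15 ppm   fragment mass-error quality bound
frag_max_rt_diff          0.1 min  fragment-to-precursor RT co-elution bound
frag_fwhm_diff_factor     2        fragment FWHM may differ from the
                                   precursor's by at most this multiple of it
frag_min_rel_height       0.01     fragment height floor, relative to
                                   precursor height
min_good_fragments        2        targets need this many zero-flag fragments
min_total_fragments       3        and this many fragments overall
id_max_mass_error_ppm     18 ppm   identification cutoffs (query scoring)
id_max_rt_error           0.4 min
id_max_ccs_error_pct      0.8 %
id_min_score              0.8      replaced by the FDR-table threshold when a
                                   target FDR is requested
match_mass_tol            0.01 Th  selectivity matching tolerances
match_rt_tol              0.2 min
match_ccs_tol_pct         0.8 %
svm_cost                  1.0      RBF-SVM hyperparameters (gamma defaults to
svm_gamma                 1/7      one over the number of descriptors)
fdr_target                0.01
========================  =======  ==========================================
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("peakdecoder")

N_DESCRIPTORS = 7


@dataclass
class RunConfig:
    """All tunable parameters of one workflow run."""

    dataset_tag: str = "run"
    seed: int = 0

    # step 2: target selection and decoy generation
    target_min_sn: float = 15.0
    target_min_fragments: int = 3
    rel_intensity_range: tuple[float, float] = (0.01, 1.30)
    target_top_n_fragments: int = 16
    pair_mz_window: float = 50.0
    pair_min_rt_gap: float = 3.0
    swap_fraction_range: tuple[float, float] = (0.4, 0.6)
    representative_run: str | None = None  # default: run with most targets

    # step 4: training-set filtering
    filter_min_precursor_sn: float = 20.0
    frag_max_mass_error_ppm: float = 15.0
    frag_max_rt_diff: float = 0.1
    frag_fwhm_diff_factor: float = 2.0
    frag_min_rel_height: float = 0.01
    min_good_fragments: int = 2
    min_total_fragments: int = 3

    # classifier
    svm_cost: float = 1.0
    svm_gamma: float = 1.0 / N_DESCRIPTORS
    cv_folds: int = 10
    fdr_target: float = 0.01
    fdr_on_cv_predictions: bool = False  # full-training-set FDR by default

    # step 5/6: identification cutoffs
    id_max_mass_error_ppm: float = 18.0
    id_max_rt_error: float = 0.4
    id_max_ccs_error_pct: float = 0.8
    id_min_score: float = 0.8

    # selectivity matching
    match_mass_tol: float = 0.01
    match_rt_tol: float = 0.2
    match_ccs_tol_pct: float = 0.8

    # library expected-intensity source for query scoring: "raw" | "normalized"
    expected_intensity: str = "raw"

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config file; unknown keys raise, missing keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("rel_intensity_range", "swap_fraction_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["rel_intensity_range"] = list(d["rel_intensity_range"])
        d["swap_fraction_range"] = list(d["swap_fraction_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def setup_logging(level: str = "INFO") -> None:
    """Structured per-stage logging used by the CLI."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        datefmt="%H:%M:%S",
    )
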