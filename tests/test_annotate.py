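"""Query scoring, identification cutoffs and annotation-selectivity
matching."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import good_fragment, make_group, make_metrics
from peakdecoder.annotate import (Annotation, MatchTypeCounts,
                                  apply_id_cutoffs, best_replicate_summary,
                                  match_features, score_queries)
from peakdecoder.core_model import (QUERY, DeconvolutedFeature, FragmentIon,
                                    LibraryEntry, rank_fragments)
from peakdecoder.classifier_fdr import FDRTableRow


def annotation(**overrides) -> Annotation:
    base = dict(metabolite="m", run_id="run1", score=0.95,
                mass_error_ppm=12.0, rt_error=0.1, ccs_error_pct=0.3,
                n_fragments=4, level="RT-CCS-DIA")
    base.update(overrides)
    return Annotation(**base)


class TestApplyIdCutoffs:
    def test_all_within_cutoffs_identified(self):
        assert apply_id_cutoffs([annotation()]) == ["m"]

    @pytest.mark.parametrize("field,value", [
        ("mass_error_ppm", 18.5), ("mass_error_ppm", -18.5),
        ("rt_error", 0.45), ("rt_error", -0.45),
        ("ccs_error_pct", 0.9), ("ccs_error_pct", -0.9),
        ("score", 0.75),
    ])
    def test_single_cutoff_violation_blocks(self, field, value):
        assert apply_id_cutoffs([annotation(**{field: value})]) == []

    def test_missing_dimension_cannot_pass(self):
        assert apply_id_cutoffs([annotation(ccs_error_pct=None)]) == []
        assert apply_id_cutoffs([annotation(score=None)]) == []

    def test_identified_if_passing_in_one_of_many_runs(self):
        failing = [annotation(run_id=f"r{i}", score=0.2) for i in range(5)]
        passing = [annotation(run_id="r6")]
        assert apply_id_cutoffs(failing + passing) == ["m"]

    def test_fdr_table_replaces_score_cutoff(self):
        table = [FDRTableRow(0.95, 0.0), FDRTableRow(0.6, 0.01),
                 FDRTableRow(0.3, 0.2)]
        ann = annotation(score=0.65)  # below 0.8 but above the 1% threshold
        assert apply_id_cutoffs([ann], fdr_table=table, fdr_target=0.01) == ["m"]
        assert ann.q_value == pytest.approx(0.01)

    def test_loosening_cutoffs_never_removes_identifications(self):
        rng = np.random.default_rng(8)
        anns = [annotation(metabolite=f"m{i}",
                           mass_error_ppm=float(rng.uniform(0, 30)),
                           rt_error=float(rng.uniform(-0.8, 0.8)),
                           ccs_error_pct=float(rng.uniform(-1.5, 1.5)),
                           score=float(rng.uniform(0, 1))) for i in range(80)]
        tight = set(apply_id_cutoffs(anns, max_mass_ppm=10, max_rt_error=0.2,
                                     max_ccs_pct=0.4, min_score=0.9))
        loose = set(apply_id_cutoffs(anns))
        assert tight <= loose


class TestScoreQueries:
    def _library_entry(self):
        return LibraryEntry(
            name="Q1", formula="", adduct="[M-H]-", precursor_mz=300.0,
            rt=5.0, ccs=150.0,
            fragments=rank_fragments([FragmentIon(mz=100.0, intensity=900.0),
                                      FragmentIon(mz=110.0, intensity=300.0),
                                      FragmentIon(mz=120.0, intensity=100.0)]))

    def test_errors_computed_against_expected(self, trained_default):
        prec = make_metrics(rt=5.1, mass_error_ppm=3.0)
        group = make_group(group_id="Q1", label=QUERY, precursor=prec,
                           fragments=[good_fragment(mz=100.0, prec=prec, area=900.0),
                                      good_fragment(mz=110.0, prec=prec, area=300.0),
                                      good_fragment(mz=120.0, prec=prec, area=100.0)],
                           expected_rt=5.0, expected_ccs=113.0,
                           observed_ccs=113.8)
        (ann,) = score_queries(trained_default["model"], [group],
                               [self._library_entry()])
        assert ann.rt_error == pytest.approx(0.1, abs=1e-9)
        assert ann.ccs_error_pct == pytest.approx(100 * 0.8 / 113.0)
        assert ann.level == "RT-CCS-DIA"
        assert 0.0 <= ann.score <= 1.0

    def test_group_without_fragments_is_ms1_level(self, trained_default):
        group = make_group(group_id="Q1", label=QUERY, fragments=[],
                           expected_rt=5.0, expected_ccs=150.0,
                           observed_ccs=150.4)
        (ann,) = score_queries(trained_default["model"], [group],
                               [self._library_entry()])
        assert ann.level == "RT-CCS"
        assert ann.score is None

    def test_metabolite_absent_from_library_skipped(self, trained_default):
        group = make_group(group_id="unknown", label=QUERY,
                           fragments=[good_fragment()])
        assert score_queries(trained_default["model"], [group],
                             [self._library_entry()]) == []

    def test_well_matching_query_scores_high(self, trained_default):
        """A query whose areas mirror the library spectrum and whose
        fragments co-elute tightly should be scored near 1."""
        entry = self._library_entry()
        prec = make_metrics(rt=5.01, mass_error_ppm=2.0)
        frags = [good_fragment(mz=f.mz, prec=prec, area=f.intensity * 3.0,
                               rt=prec.rt + 0.002 * (i - 1),
                               mass_error_ppm=1.5)
                 for i, f in enumerate(entry.fragments)]
        group = make_group(group_id="Q1", label=QUERY, precursor=prec,
                           fragments=frags, expected_rt=5.0,
                           expected_ccs=150.0, observed_ccs=150.2)
        (ann,) = score_queries(trained_default["model"], [group], [entry])
        assert ann.score > 0.9


class TestBestReplicate:
    def test_max_score_across_runs(self):
        anns = [annotation(run_id="r1", score=0.5),
                annotation(run_id="r2", score=0.9),
                annotation(metabolite="other", run_id="r1", score=0.2)]
        best = best_replicate_summary(anns)
        assert {(a.metabolite, a.score) for a in best} == {("m", 0.9), ("other", 0.2)}


def brute_force_match(features, entry, mass_tol, rt_tol, ccs_tol_pct):
    m = mrt = mccs = mboth = 0
    for f in features:
        if abs(f.precursor_mz - entry.precursor_mz) > mass_tol:
            continue
        m += 1
        rt_ok = entry.rt is not None and abs(f.rt - entry.rt) <= rt_tol
        ccs_ok = (entry.ccs is not None and f.ccs is not None and
                  abs(f.ccs - entry.ccs) / entry.ccs * 100.0 <= ccs_tol_pct)
        mrt += rt_ok
        mccs += ccs_ok
        mboth += rt_ok and ccs_ok
    return MatchTypeCounts(m, mrt, mccs, mboth)


def toy_feature(fid, mz, rt, ccs):
    return DeconvolutedFeature(feature_id=fid, run_id="r", precursor_mz=mz,
                               rt=rt, ccs=ccs, sn=10.0, height=1e4, fragments=[])


class TestMatchFeatures:
    ENTRY = LibraryEntry(name="E", formula="", adduct="[M-H]-",
                         precursor_mz=300.0, rt=5.0, ccs=150.0)

    def test_toy_counts_by_enumeration(self):
        feats = [
            toy_feature("a", 300.005, 5.1, 150.5),   # mass+rt+ccs
            toy_feature("b", 300.009, 5.15, 160.0),  # mass+rt
            toy_feature("c", 299.995, 7.0, 150.9),   # mass+ccs
            toy_feature("d", 300.002, 9.0, 200.0),   # mass only
            toy_feature("e", 301.0, 5.0, 150.0),     # outside mass tol
        ]
        counts = match_features(feats, [self.ENTRY])["E"]
        assert counts == MatchTypeCounts(mass_only=4, mass_rt=2,
                                         mass_ccs=2, mass_rt_ccs=1)

    def test_empty_library_empty_counts(self):
        assert match_features([toy_feature("a", 300.0, 5.0, 150.0)], []) == {}

    def test_feature_missing_ccs_matches_mass_and_rt_only(self):
        feats = [toy_feature("a", 300.0, 5.0, None)]
        counts = match_features(feats, [self.ENTRY])["E"]
        assert counts == MatchTypeCounts(1, 1, 0, 0)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(21)
        feats = [toy_feature(f"f{i}", float(rng.uniform(299.9, 300.1)),
                             float(rng.uniform(4.0, 6.0)),
                             None if rng.random() < 0.1
                             else float(rng.uniform(147.0, 153.0)))
                 for i in range(200)]
        entries = [LibraryEntry(name=f"E{j}", formula="", adduct="[M-H]-",
                                precursor_mz=float(rng.uniform(299.95, 300.05)),
                                rt=float(rng.uniform(4.5, 5.5)),
                                ccs=float(rng.uniform(148.0, 152.0)))
                   for j in range(10)]
        got = match_features(feats, entries)
        for e in entries:
            assert got[e.name] == brute_force_match(feats, e, 0.01, 0.2, 0.8)

    def test_nesting_invariant_random(self):
        rng = np.random.default_rng(22)
        feats = [toy_feature(f"f{i}", float(rng.uniform(299.9, 300.1)),
                             float(rng.uniform(0, 12)),
                             float(rng.uniform(140, 160)))
                 for i in range(150)]
        for c in match_features(feats, [self.ENTRY]).values():
            assert c.mass_rt_ccs <= min(c.mass_rt, c.mass_ccs) <= c.mass_only
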