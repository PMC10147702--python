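"""Readers, writers and the missing-value / ranking contracts."""

from __future__ import annotations

import numpy as np
import pytest

from peakdecoder.core_model import (DECOY, TARGET, DeconvolutedFeature,
                                    FormatError, FragmentIon, LibraryEntry,
                                    StructuralError, TransitionRecord,
                                    parse_float, rank_fragments,
                                    read_feature_alignment, read_library_msp,
                                    read_transition_list, read_xic_report,
                                    write_feature_alignment,
                                    write_library_msp, write_results,
                                    write_transition_list, write_xic_report)
from peakdecoder.classifier_fdr import FDRTableRow
from peakdecoder.annotate import Annotation

ALIGNMENT_3ROW = """\
feature_id\trun_id\tprecursor_mz\trt\tccs\tsn\theight\tms2
F1\trunA\t300.1\t2.5\t180.2\t25\t10000\t100.1:50 200.2:500 90.0:40 80.0:30 70.0:20 60.0:10
F2\trunA\t400.2\t5.0\t210.0\t30\t20000\t150.0:900 250.0:400 120.0:100 110.0:50
F3\trunA\t500.3\t8.0\t\t12\t5000\t
"""


class TestFeatureAlignment:
    def test_three_row_fixture_fragment_counts(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(ALIGNMENT_3ROW)
        feats = read_feature_alignment(p)
        assert [f.feature_id for f in feats] == ["F1", "F2", "F3"]
        assert [len(f.fragments) for f in feats] == [6, 4, 0]
        assert feats[2].ccs is None  # empty cell is missing, not 0

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("feature_id\trun_id\tprecursor_mz\trt\tccs\tsn\theight\tms2\n")
        assert read_feature_alignment(p) == []

    def test_fragment_ranks_sorted_by_intensity(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("feature_id\tprecursor_mz\trt\tms2\n"
                     "F1\t300\t2.0\t100.1:50 200.2:500\n")
        (f,) = read_feature_alignment(p)
        by_rank = {frag.rank: frag.mz for frag in f.fragments}
        assert by_rank == {1: 200.2, 2: 100.1}

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("feature_id\trt\tms2\nF1\t2.0\t\n")
        with pytest.raises(FormatError, match="precursor_mz"):
            read_feature_alignment(p)

    def test_bad_fragment_token_skipped_not_fatal(self, tmp_path, caplog):
        p = tmp_path / "a.tsv"
        p.write_text("feature_id\tprecursor_mz\trt\tms2\n"
                     "F1\t300\t2.0\t100.1:50 garbage 200.2:7\n")
        with caplog.at_level("WARNING"):
            (f,) = read_feature_alignment(p)
        assert len(f.fragments) == 2
        assert "garbage" in caplog.text

    def test_msdial_style_headers_accepted(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("Alignment ID\tAverage Mz\tAverage Rt(min)\tCCS\t"
                     "S/N average\tHeight\tMS/MS spectrum\n"
                     "17\t300.5\t3.3\t175.0\t22\t9000\t120.0:80 90.0:10\n")
        (f,) = read_feature_alignment(p, dialect="msdial_alignment")
        assert f.feature_id == "17" and f.sn == 22 and len(f.fragments) == 2


class TestXICReport:
    def _write(self, tmp_path, groups):
        p = tmp_path / "r.csv"
        write_xic_report(groups, p)
        return p

    def test_two_groups_six_transitions(self, tmp_path):
        from conftest import good_fragment, make_group, make_metrics

        groups = []
        for gid in ("G1", "G2"):
            prec = make_metrics(area=5e4, height=1e4)
            frags = [good_fragment(mz=100.0 + i, prec=prec) for i in range(5)]
            groups.append(make_group(group_id=gid, precursor=prec, fragments=frags))
        back = read_xic_report(self._write(tmp_path, groups))
        assert len(back) == 2
        assert all(g.n_fragments == 5 for g in back)

    def test_missing_cell_flagged_not_zero(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "group_id,run_id,label,is_precursor,mz,expected_intensity,area,"
            "height,fwhm,rt,mass_error_ppm,expected_rt,expected_ccs,"
            "observed_ccs,precursor_sn,paired_group_id\n"
            "G1,run1,target,1,300.0,,50000,#N/A,0.15,5.0,1.0,,,,40,\n"
            "G1,run1,target,0,150.0,5000,700,NA,0.15,5.0,1.5,,,,,\n")
        (g,) = read_xic_report(p)
        assert g.precursor.height is None
        assert g.fragments[0][1].height is None

    def test_same_group_in_three_runs(self, tmp_path):
        from conftest import good_fragment, make_group

        groups = [make_group(group_id="G1", run_id=f"run{i}",
                             fragments=[good_fragment()]) for i in range(3)]
        back = read_xic_report(self._write(tmp_path, groups))
        assert len(back) == 3
        assert {g.run_id for g in back} == {"run0", "run1", "run2"}
        assert {g.group_id for g in back} == {"G1"}

    def test_group_without_precursor_row_is_structural_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "group_id,run_id,label,is_precursor,mz,area,height,fwhm,rt,"
            "mass_error_ppm\n"
            "GX,run1,target,0,150.0,700,600,0.15,5.0,1.5\n")
        with pytest.raises(StructuralError, match="GX"):
            read_xic_report(p)


class TestLibraryMSP:
    def test_packaged_synthetic_library_has_64_entries(self):
        from peakdecoder.synthetic_data import default_library_path

        entries = read_library_msp(default_library_path())
        assert len(entries) == 64

    def test_anchored_entry_coordinates(self):
        from peakdecoder.synthetic_data import default_library_path

        entries = read_library_msp(default_library_path())
        f16dp = next(e for e in entries if e.name == "fructose 1,6-diphosphate")
        assert f16dp.precursor_mz == pytest.approx(338.98877)
        assert f16dp.rt == pytest.approx(4.95)
        assert f16dp.ccs == pytest.approx(155.00)
        assert len(f16dp.fragments) == 6

    def test_empty_msp_gives_empty_list(self, tmp_path):
        p = tmp_path / "e.msp"
        p.write_text("")
        assert read_library_msp(p) == []

    def test_record_without_precursor_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "l.msp"
        p.write_text("Name: no-precursor\nNum Peaks: 1\n100.0 50\n\n"
                     "Name: ok\nPrecursorMZ: 200.0\nNum Peaks: 0\n\n")
        with caplog.at_level("WARNING"):
            entries = read_library_msp(p)
        assert [e.name for e in entries] == ["ok"]
        assert "no-precursor" in caplog.text

    def test_agrees_with_independent_msp_reader(self):
        """Cross-check against matchms (which skips peak-less records)."""
        from matchms.importing import load_from_msp
        from peakdecoder.synthetic_data import default_library_path

        ours = read_library_msp(default_library_path())
        theirs = list(load_from_msp(str(default_library_path())))
        with_peaks = [e for e in ours if e.fragments]
        assert len(theirs) == len(with_peaks)
        by_name = {s.get("compound_name"): s for s in theirs}
        for e in with_peaks:
            s = by_name[e.name]
            assert float(s.get("precursor_mz")) == pytest.approx(e.precursor_mz)
            assert len(s.peaks.mz) == len(e.fragments)
            assert sorted(s.peaks.mz) == pytest.approx(
                sorted(f.mz for f in e.fragments))

    def test_normalized_intensities_max_100_alongside_raw(self, tmp_path):
        entry = LibraryEntry(name="x", formula="", adduct="[M-H]-",
                             precursor_mz=300.0, rt=1.0, ccs=150.0,
                             fragments=rank_fragments([
                                 FragmentIon(mz=100.0, intensity=400.0),
                                 FragmentIon(mz=120.0, intensity=100.0)]))
        assert entry.fragment_intensities("raw") == [400.0, 100.0]
        assert entry.fragment_intensities("normalized") == [100.0, 25.0]


class TestTransitionList:
    def _records(self):
        recs = []
        for gid, label, paired in (("T1", TARGET, None), ("D1", DECOY, "T1")):
            recs.append(TransitionRecord(group_id=gid, label=label,
                                         is_precursor=True, mz=300.0,
                                         precursor_mz=300.0, explicit_rt=5.0,
                                         explicit_ccs=180.0,
                                         expected_intensity=1e4,
                                         paired_group_id=paired))
            for i in range(6):
                recs.append(TransitionRecord(group_id=gid, label=label,
                                             is_precursor=False, mz=100.0 + i,
                                             precursor_mz=300.0,
                                             explicit_rt=5.0,
                                             explicit_ccs=180.0,
                                             expected_intensity=1000.0 - i,
                                             paired_group_id=paired))
        return recs

    def test_target_plus_decoy_row_count(self, tmp_path):
        p = tmp_path / "t.csv"
        write_transition_list(self._records(), p)
        lines = [ln for ln in p.read_text().splitlines() if not ln.startswith("#")]
        assert len(lines) == 1 + 14  # header + 2 precursors + 12 products

    def test_empty_input_header_only(self, tmp_path):
        p = tmp_path / "t.csv"
        write_transition_list([], p)
        assert len(p.read_text().splitlines()) == 1

    def test_round_trip_identity(self, tmp_path):
        p = tmp_path / "t.csv"
        recs = self._records()
        write_transition_list(recs, p, metadata={"seed": "7"})
        assert read_transition_list(p) == recs


class TestRoundTripProperties:
    """Randomised round-trip property for every writer/reader pair."""

    def test_alignment_round_trip_random(self, tmp_path):
        rng = np.random.default_rng(3)
        feats = []
        for i in range(30):
            n = int(rng.integers(0, 10))
            frags = rank_fragments(
                FragmentIon(mz=float(rng.uniform(50, 800)),
                            intensity=float(rng.uniform(1, 1e6)))
                for _ in range(n))
            feats.append(DeconvolutedFeature(
                feature_id=f"F{i}", run_id="runZ",
                precursor_mz=float(rng.uniform(100, 900)),
                rt=float(rng.uniform(0, 15)),
                ccs=None if rng.random() < 0.2 else float(rng.uniform(100, 300)),
                sn=float(rng.uniform(1, 100)),
                height=float(rng.uniform(1e3, 1e6)), fragments=frags))
        p = tmp_path / "rt.tsv"
        write_feature_alignment(feats, p)
        assert read_feature_alignment(p) == feats

    def test_xic_round_trip_random(self, tmp_path):
        from conftest import make_group, make_metrics

        rng = np.random.default_rng(4)
        groups = []
        for i in range(20):
            prec = make_metrics(area=float(rng.uniform(1e3, 1e6)),
                                height=float(rng.uniform(1e3, 1e5)),
                                rt=float(rng.uniform(0, 14)))
            frags = []
            for j in range(int(rng.integers(1, 8))):
                m = make_metrics(
                    area=None if rng.random() < 0.15 else float(rng.uniform(10, 1e5)),
                    height=float(rng.uniform(10, 1e5)),
                    rt=float(rng.uniform(0, 14)))
                frags.append((float(rng.uniform(50, 700)),
                              float(rng.uniform(1, 1e5)), m))
            groups.append(make_group(group_id=f"G{i}", fragments=frags,
                                     expected_rt=float(rng.uniform(0, 14)),
                                     observed_ccs=float(rng.uniform(100, 300))))
        p = tmp_path / "rt.csv"
        write_xic_report(groups, p)
        back = read_xic_report(p)
        assert len(back) == len(groups)
        for a, b in zip(back, groups):
            assert a.group_id == b.group_id
            assert a.precursor == b.precursor
            assert [f[1] for f in a.fragments] == [f[1] for f in b.fragments]
            assert [f[0].mz for f in a.fragments] == [f[0].mz for f in b.fragments]

    def test_msp_round_trip_random(self, tmp_path):
        from peakdecoder.synthetic_data import build_synthetic_library

        lib = build_synthetic_library()
        p = tmp_path / "lib.msp"
        write_library_msp(lib, p)
        assert read_library_msp(p) == lib


class TestWriteResults:
    def test_threshold_csv_and_dataset_tag(self, tmp_path):
        table = [FDRTableRow(0.9, 0.0), FDRTableRow(0.5, 0.01),
                 FDRTableRow(0.1, 0.2)]
        ann = [Annotation(metabolite="m1", run_id="run1", score=0.3,
                          mass_error_ppm=5.0, rt_error=0.1,
                          ccs_error_pct=0.2, n_fragments=4,
                          level="RT-CCS-DIA", passed=False)]
        paths = write_results(ann, table, tmp_path, dataset_tag="demo")
        assert paths["thresholds"].name == "PeakDecoder-FDR-thresholds_demo.csv"
        lines = paths["thresholds"].read_text().splitlines()
        assert len(lines) == 4  # header + 3 rows
        body = paths["annotations"].read_text()
        assert "m1" in body and "false" in body  # non-passing row still present


def test_parse_float_missing_tokens():
    for token in ("", "NA", "#N/A", "NaN", "n/a"):
        assert parse_float(token) is None
    assert parse_float("1.5") == 1.5


def test_rank_ties_broken_by_ascending_mz():
    frags = rank_fragments([FragmentIon(mz=200.0, intensity=50.0),
                            FragmentIon(mz=100.0, intensity=50.0)])
    assert [(f.rank, f.mz) for f in frags] == [(1, 100.0), (2, 200.0)]
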