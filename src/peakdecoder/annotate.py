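"""Query scoring, identification cutoffs and annotation selectivity.

At inference time the query metabolites of the library are extracted from
every run and scored with the trained model, using the library fragment
intensities as the expected vector.  A metabolite is identified when, in at
least one run, it passes all of: precursor mass error < 18 ppm, precursor
RT error < 0.4 min, CCS error < 0.8%, and score above 0.8 (or above the
score corresponding to the requested FDR).  Error cutoffs compare absolute
values.

Independently, :func:`match_features` quantifies how much each added
separation dimension (RT, CCS) narrows down the untargeted features that
could be confused with each library metabolite.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

from .classifier_fdr import (FDRTableRow, TrainedModel, score_many,
                             threshold_for_fdr)
from .core_model import DeconvolutedFeature, LibraryEntry, PeakGroupXIC
from .descriptors import compute_descriptors

log = logging.getLogger("peakdecoder.annotate")

LEVEL_DIA = "RT-CCS-DIA"
LEVEL_MS1 = "RT-CCS"


@dataclass
class Annotation:
    """One metabolite's evidence in one run."""

    metabolite: str
    run_id: str
    score: float | None          # missing when no scorable fragments
    mass_error_ppm: float | None
    rt_error: float | None       # run RT - expected RT, minutes
    ccs_error_pct: float | None  # 100 * (run CCS - expected CCS) / expected
    n_fragments: int
    level: str                   # RT-CCS-DIA | RT-CCS
    passed: bool = False
    q_value: float | None = None


@dataclass(frozen=True)
class MatchTypeCounts:
    """Feature counts per library entry by match dimensionality."""

    mass_only: int
    mass_rt: int
    mass_ccs: int
    mass_rt_ccs: int

    def __post_init__(self) -> None:
        if not (self.mass_rt_ccs <= min(self.mass_rt, self.mass_ccs)
                <= max(self.mass_rt, self.mass_ccs) <= self.mass_only):
            raise ValueError("match counts must nest: mass_rt_ccs <= "
                             "mass_rt, mass_ccs <= mass_only")


def _library_expected(entry: LibraryEntry, group: PeakGroupXIC,
                      kind: str, mz_tol: float = 0.01) -> list[float] | None:
    """Expected-intensity vector aligned with the group's fragments, from
    the library spectrum (matched by fragment m/z)."""
    if not entry.fragments:
        return None
    frags = entry.fragments if kind == "raw" else entry.normalized_fragments()
    out = []
    for rec, _m in group.fragments:
        match = min(frags, key=lambda f: abs(f.mz - rec.mz))
        out.append(match.intensity if abs(match.mz - rec.mz) <= mz_tol else None)
    return out


def score_queries(model: TrainedModel, groups: list[PeakGroupXIC],
                  library: list[LibraryEntry],
                  expected_intensity: str = "raw") -> list[Annotation]:
    """Score query peak-groups against the library, one annotation per
    (metabolite, run).

    Query groups are matched to library entries by group_id == entry name.
    Groups with fewer than two scorable fragments are annotated at the
    MS1-only level (RT and CCS evidence) with a missing score.
    """
    by_name = {e.name: e for e in library}
    annotations: list[Annotation] = []
    to_score: list[tuple[int, object]] = []
    for g in groups:
        entry = by_name.get(g.group_id)
        if entry is None:
            log.info("score_queries: group %r not in library, skipped", g.group_id)
            continue
        expected_rt = g.expected_rt if g.expected_rt is not None else entry.rt
        expected_ccs = g.expected_ccs if g.expected_ccs is not None else entry.ccs
        rt_error = (g.precursor.rt - expected_rt
                    if g.precursor.rt is not None and expected_rt is not None else None)
        ccs_error = (100.0 * (g.observed_ccs - expected_ccs) / expected_ccs
                     if g.observed_ccs is not None and expected_ccs not in (None, 0)
                     else None)
        override = _library_expected(entry, g, expected_intensity)
        vector = compute_descriptors(g, expected_override=override) if override else None
        n_scorable = sum(1 for (rec, m) in g.fragments if m.area is not None)
        ann = Annotation(
            metabolite=g.group_id, run_id=g.run_id, score=None,
            mass_error_ppm=g.precursor.mass_error_ppm,
            rt_error=rt_error, ccs_error_pct=ccs_error,
            n_fragments=n_scorable,
            level=LEVEL_DIA if vector is not None else LEVEL_MS1)
        annotations.append(ann)
        if vector is not None:
            to_score.append((len(annotations) - 1, vector))
    if to_score:
        scores = score_many(model, [v for _, v in to_score])
        for (idx, _v), s in zip(to_score, scores):
            annotations[idx].score = float(s)
    return annotations


def apply_id_cutoffs(annotations: list[Annotation],
                     max_mass_ppm: float = 18.0,
                     max_rt_error: float = 0.4,
                     max_ccs_pct: float = 0.8,
                     min_score: float = 0.8,
                     fdr_table: list[FDRTableRow] | None = None,
                     fdr_target: float = 0.01) -> list[str]:
    """Mark passing annotations and return the identified metabolites.

    A metabolite is identified when at least one of its runs passes every
    cutoff; all error comparisons use absolute values.  When an FDR table
    is supplied, the score cutoff is the table's threshold at
    ``fdr_target`` (falling back to ``min_score`` if unreachable).  Each
    scored annotation also receives a q-value: the enveloped FDR of the
    table at its score.
    """
    if fdr_table is not None:
        thr = threshold_for_fdr(fdr_table, fdr_target)
        if thr is not None:
            min_score = thr
        for a in annotations:
            if a.score is not None:
                at_or_below = [r.fdr for r in fdr_table if r.score_threshold <= a.score]
                a.q_value = min(at_or_below) if at_or_below else (
                    fdr_table[0].fdr if fdr_table else None)
    identified: list[str] = []
    for a in annotations:
        a.passed = (
            a.mass_error_ppm is not None and abs(a.mass_error_ppm) < max_mass_ppm
            and a.rt_error is not None and abs(a.rt_error) < max_rt_error
            and a.ccs_error_pct is not None and abs(a.ccs_error_pct) < max_ccs_pct
            and a.score is not None and a.score > min_score)
        if a.passed and a.metabolite not in identified:
            identified.append(a.metabolite)
    log.info("apply_id_cutoffs: %d metabolites identified (score cutoff %.4g)",
             len(identified), min_score)
    return identified


def best_replicate_summary(annotations: list[Annotation]) -> list[Annotation]:
    """One row per metabolite: the best-scoring replicate (highest score;
    ties and scoreless metabolites fall back to smallest |RT error|)."""

    def sort_key(a: Annotation):
        return (-(a.score if a.score is not None else -1.0),
                abs(a.rt_error) if a.rt_error is not None else float("inf"))

    best: dict[str, Annotation] = {}
    for a in annotations:
        if a.metabolite not in best or sort_key(a) < sort_key(best[a.metabolite]):
            best[a.metabolite] = a
    return [best[name] for name in sorted(best)]


def match_features(features: list[DeconvolutedFeature],
                   library: list[LibraryEntry],
                   mass_tol: float = 0.01,
                   rt_tol: float = 0.2,
                   ccs_tol_pct: float = 0.8) -> dict[str, MatchTypeCounts]:
    """Count, per library entry, the untargeted features matching by mass
    alone, mass+RT, mass+CCS, and mass+RT+CCS.

    Mass tolerance is absolute (Th), RT absolute (min), CCS relative
    (percent of the library value).  A feature with missing CCS can match
    in the mass and mass+RT classes only.
    """
    out: dict[str, MatchTypeCounts] = {}
    for entry in library:
        n_mass = n_rt = n_ccs = n_both = 0
        for f in features:
            if abs(f.precursor_mz - entry.precursor_mz) > mass_tol:
                continue
            n_mass += 1
            rt_ok = (entry.rt is not None and abs(f.rt - entry.rt) <= rt_tol)
            ccs_ok = (entry.ccs is not None and f.ccs is not None
                      and abs(100.0 * (f.ccs - entry.ccs) / entry.ccs) <= ccs_tol_pct)
            n_rt += rt_ok
            n_ccs += ccs_ok
            n_both += rt_ok and ccs_ok
        out[entry.name] = MatchTypeCounts(
            mass_only=n_mass, mass_rt=n_rt, mass_ccs=n_ccs, mass_rt_ccs=n_both)
    return out


def write_selectivity_counts(counts: dict[str, MatchTypeCounts],
                             path: str | Path) -> None:
    """Selectivity table: one TSV row per library entry."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metabolite", "mass", "mass_rt", "mass_ccs", "mass_rt_ccs"])
        for name in sorted(counts):
            c = counts[name]
            writer.writerow([name, c.mass_only, c.mass_rt, c.mass_ccs, c.mass_rt_ccs])
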