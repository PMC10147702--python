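"""Preliminary training-set construction: target selection, pairing, and
decoy generation by fragment m/z swapping.

Decoys are built from real deconvoluted peak-groups rather than from an
annotated library.  Two targets of similar precursor mass but well-separated
retention time are paired; each decoy keeps its target's precursor
properties and fragment intensity profile, but 40-60% of its fragment m/z
values are exchanged with the partner at matching intensity rank.  Because
the construction is paired and m/z values are only permuted between the two
members, the decoy set has exactly the same precursor m/z, RT, CCS and
fragment-count distributions as the target set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .core_model import (DECOY, TARGET, DeconvolutedFeature, FragmentIon,
                         TransitionRecord, rank_fragments)

log = logging.getLogger("peakdecoder.decoys")


@dataclass
class TargetPair:
    """Two targets from the same run eligible for decoy generation."""

    a: DeconvolutedFeature
    b: DeconvolutedFeature
    n_swap: int = 0
    swap_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.a.run_id != self.b.run_id:
            raise ValueError("paired targets must come from the same run")
        if len(self.a.fragments) != len(self.b.fragments):
            raise ValueError("paired targets must have the same fragment count")


def select_targets(features: list[DeconvolutedFeature],
                   min_sn: float = 15.0,
                   min_fragments: int = 3,
                   rel_intensity_range: tuple[float, float] = (0.01, 1.30),
                   top_n: int = 16) -> list[DeconvolutedFeature]:
    """Keep high-quality features as training targets.

    A feature is kept when its S/N is at least ``min_sn`` and it has at
    least ``min_fragments`` fragments whose intensity lies within
    ``rel_intensity_range`` of the precursor height (1-130% by default).
    Out-of-band fragments are removed and at most ``top_n`` of the most
    intense in-band fragments are retained.
    """
    lo, hi = rel_intensity_range
    kept: list[DeconvolutedFeature] = []
    for f in features:
        if f.sn is None or f.sn < min_sn:
            continue
        if f.height is None or f.height <= 0:
            continue
        in_band = [frag for frag in f.fragments
                   if lo <= frag.intensity / f.height <= hi]
        if len(in_band) < min_fragments:
            continue
        trimmed = rank_fragments(in_band)[:top_n]
        kept.append(replace(f, fragments=trimmed))
    log.info("select_targets: %d/%d features kept", len(kept), len(features))
    return kept


def select_representative_run(targets: list[DeconvolutedFeature]) -> str:
    """The run contributing the most selected targets (ties: lexicographic)."""
    counts: dict[str, int] = {}
    for t in targets:
        counts[t.run_id] = counts.get(t.run_id, 0) + 1
    if not counts:
        raise ValueError("no targets, cannot choose a representative run")
    return min(counts, key=lambda r: (-counts[r], r))


def pair_targets(targets: list[DeconvolutedFeature],
                 mz_window: float = 50.0,
                 min_rt_gap: float = 3.0,
                 representative_run: str | None = None) -> list[TargetPair]:
    """Associate targets by pairs for decoy generation.

    Pairing is restricted to one representative run.  For each target (taken
    greedily in descending precursor height, each target used at most once)
    the partner is the not-yet-paired target with the same fragment count
    and precursor m/z within ``mz_window`` that maximises the RT difference,
    subject to that difference being at least ``min_rt_gap`` minutes —
    a floor that avoids pairing a repeated feature from a long tailing peak.
    Targets with no eligible partner are left unpaired.
    """
    if representative_run is None:
        representative_run = select_representative_run(targets)
    pool = [t for t in targets if t.run_id == representative_run]
    pool.sort(key=lambda t: (-(t.height or 0.0), t.feature_id))

    paired: set[str] = set()
    pairs: list[TargetPair] = []
    for t in pool:
        if t.feature_id in paired:
            continue
        best = None
        best_gap = -1.0
        for cand in pool:
            if cand.feature_id == t.feature_id or cand.feature_id in paired:
                continue
            if len(cand.fragments) != len(t.fragments):
                continue
            if abs(cand.precursor_mz - t.precursor_mz) > mz_window:
                continue
            gap = abs(cand.rt - t.rt)
            if gap < min_rt_gap:
                continue
            if gap > best_gap:
                best, best_gap = cand, gap
        if best is not None:
            paired.add(t.feature_id)
            paired.add(best.feature_id)
            pairs.append(TargetPair(a=t, b=best))
    unpaired = len(pool) - 2 * len(pairs)
    log.info("pair_targets: %d pairs formed in run %r, %d targets unpaired",
             len(pairs), representative_run, unpaired)
    return pairs


def swap_count_range(n_fragments: int,
                     swap_fraction_range: tuple[float, float] = (0.4, 0.6)
                     ) -> tuple[int, int] | None:
    """Integer swap counts k with k/n inside the fraction range, or None
    when no integer satisfies it (e.g. n = 3: 1.2 <= k <= 1.8)."""
    lo = math.ceil(swap_fraction_range[0] * n_fragments)
    hi = math.floor(swap_fraction_range[1] * n_fragments)
    return (lo, hi) if lo <= hi and lo >= 1 else None


def generate_decoys(pairs: list[TargetPair],
                    swap_fraction_range: tuple[float, float] = (0.4, 0.6),
                    seed: int = 0,
                    top_pool: int = 16,
                    ) -> list[tuple[DeconvolutedFeature, DeconvolutedFeature]]:
    """Generate a pair of decoys from each target pair.

    Each decoy keeps its target's precursor m/z, RT, CCS, S/N, height,
    fragment count and fragment intensities.  A swap count k is drawn
    uniformly from the integers with k/n in ``swap_fraction_range``; k
    positions are then sampled without replacement among the
    top-most-intense ranks (1..min(n, top_pool)) and the fragment m/z
    values at those ranks are exchanged between the two members.  The same
    positions are used for both decoys of a pair, so the swap is a pure
    m/z permutation within the pair.  Pairs whose fragment count admits no
    valid k are rejected.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[DeconvolutedFeature, DeconvolutedFeature]] = []
    rejected = 0
    for pair in pairs:
        n = len(pair.a.fragments)
        bounds = swap_count_range(n, swap_fraction_range)
        if bounds is None:
            rejected += 1
            continue
        k = int(rng.integers(bounds[0], bounds[1] + 1))
        pool = min(n, top_pool)
        positions = frozenset(int(p) for p in rng.choice(pool, size=k, replace=False))
        pair.n_swap = k
        pair.swap_positions = positions

        frags_a = rank_fragments(pair.a.fragments)
        frags_b = rank_fragments(pair.b.fragments)
        decoy_a_frags: list[FragmentIon] = []
        decoy_b_frags: list[FragmentIon] = []
        for i, (fa, fb) in enumerate(zip(frags_a, frags_b)):
            if i in positions:  # exchange m/z at matching intensity rank
                decoy_a_frags.append(replace(fa, mz=fb.mz))
                decoy_b_frags.append(replace(fb, mz=fa.mz))
            else:
                decoy_a_frags.append(fa)
                decoy_b_frags.append(fb)
        decoy_a = replace(pair.a, feature_id=f"DECOY_{pair.a.feature_id}",
                          fragments=decoy_a_frags)
        decoy_b = replace(pair.b, feature_id=f"DECOY_{pair.b.feature_id}",
                          fragments=decoy_b_frags)
        out.append((decoy_a, decoy_b))
    if rejected:
        log.info("generate_decoys: %d pairs rejected (no valid swap count)", rejected)
    return out


def build_transition_records(pairs: list[TargetPair],
                             decoys: list[tuple[DeconvolutedFeature, DeconvolutedFeature]]
                             ) -> list[TransitionRecord]:
    """Flatten targets and decoys into transition-list rows."""

    def records_for(feature: DeconvolutedFeature, label: str,
                    paired: str | None) -> list[TransitionRecord]:
        rows = [TransitionRecord(
            group_id=feature.feature_id, label=label, is_precursor=True,
            mz=feature.precursor_mz, precursor_mz=feature.precursor_mz,
            explicit_rt=feature.rt, explicit_ccs=feature.ccs,
            expected_intensity=feature.height, paired_group_id=paired)]
        for frag in feature.fragments:
            rows.append(TransitionRecord(
                group_id=feature.feature_id, label=label, is_precursor=False,
                mz=frag.mz, precursor_mz=feature.precursor_mz,
                explicit_rt=feature.rt, explicit_ccs=feature.ccs,
                expected_intensity=frag.intensity, paired_group_id=paired))
        return rows

    by_id = {d.feature_id: d for pair in decoys for d in pair}
    records: list[TransitionRecord] = []
    for pair in pairs:
        da = by_id.get(f"DECOY_{pair.a.feature_id}")
        db = by_id.get(f"DECOY_{pair.b.feature_id}")
        if da is None or db is None:  # pair was rejected at decoy generation
            continue
        records += records_for(pair.a, TARGET, None)
        records += records_for(pair.b, TARGET, None)
        records += records_for(da, DECOY, pair.a.feature_id)
        records += records_for(db, DECOY, pair.b.feature_id)
    return records
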