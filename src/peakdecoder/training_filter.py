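"""Final training-set filtering of extracted peak-groups.

After targeted data extraction, targets are filtered to keep only
high-quality peak-groups while deliberately retaining a bounded number of
low-quality fragments to simulate real interference.  Decoys survive only
in tandem with their paired target and inherit the target's fragment subset
and expected intensities, which keeps the target and decoy populations
matched in fragment count and m/z.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .core_model import DECOY, TARGET, PeakGroupXIC, TransitionRecord, XICMetrics

log = logging.getLogger("peakdecoder.filter")


@dataclass
class FragmentQualityFlags:
    """Low-quality-metric flags for one fragment of a peak-group.

    A fragment is flagged when: its area is non-positive; its height is
    below 1% of the precursor height; its mass error exceeds 15 ppm; its
    apex RT differs from the precursor's by more than 0.1 min; or its LC
    FWHM differs from the precursor's by more than twice the precursor
    FWHM.  A metric that is missing counts as low quality.
    """

    bad_area: bool
    bad_height: bool
    bad_mass: bool
    bad_rt: bool
    bad_fwhm: bool

    @property
    def n_bad(self) -> int:
        return sum((self.bad_area, self.bad_height, self.bad_mass,
                    self.bad_rt, self.bad_fwhm))


def _has_height(metrics: XICMetrics) -> bool:
    return metrics.height is not None and metrics.height > 0


def flag_fragment_quality(group: PeakGroupXIC,
                          max_mass_error_ppm: float = 15.0,
                          max_rt_diff: float = 0.1,
                          fwhm_diff_factor: float = 2.0,
                          min_rel_height: float = 0.01,
                          ) -> list[tuple[tuple[TransitionRecord, XICMetrics], FragmentQualityFlags]]:
    """Evaluate every fragment of a group against the quality thresholds.

    Fragments with unassigned height (missing or zero) are removed before
    flagging; each remaining fragment gets one flag record.
    """
    prec = group.precursor
    flagged = []
    for rec, m in group.fragments:
        if not _has_height(m):
            continue
        bad_area = m.area is None or m.area <= 0
        bad_height = (prec.height is None or
                      m.height < min_rel_height * prec.height)
        bad_mass = (m.mass_error_ppm is None or
                    abs(m.mass_error_ppm) > max_mass_error_ppm)
        bad_rt = (m.rt is None or prec.rt is None or
                  abs(m.rt - prec.rt) > max_rt_diff)
        bad_fwhm = (m.fwhm is None or prec.fwhm is None or
                    abs(m.fwhm - prec.fwhm) > fwhm_diff_factor * prec.fwhm)
        flagged.append(((rec, m), FragmentQualityFlags(
            bad_area=bad_area, bad_height=bad_height, bad_mass=bad_mass,
            bad_rt=bad_rt, bad_fwhm=bad_fwhm)))
    return flagged


def filter_training_set(groups: list[PeakGroupXIC],
                        min_precursor_sn: float = 20.0,
                        min_good_fragments: int = 2,
                        min_total_fragments: int = 3,
                        max_mass_error_ppm: float = 15.0,
                        max_rt_diff: float = 0.1,
                        fwhm_diff_factor: float = 2.0,
                        min_rel_height: float = 0.01,
                        audit: list[tuple[str, str, str]] | None = None,
                        ) -> list[PeakGroupXIC]:
    """Produce the final training set from target/decoy peak-groups.

    Per run: (i) targets with precursor S/N below ``min_precursor_sn`` are
    dropped; (ii) targets with fewer than ``min_good_fragments`` zero-flag
    fragments are dropped; (iii) within a kept target, fragments are ordered
    by (number of flags ascending, height descending) and those ranked past
    2x the zero-flag count are removed — some flagged fragments are
    intentionally retained to simulate interference; (iv) targets left with
    fewer than ``min_total_fragments`` fragments are dropped; (v) a decoy
    survives only if its paired target survived in the same run, restricted
    to the same fragment subset (matched by position in the transition
    list); (vi) each surviving decoy fragment's expected intensity is set to
    the paired target fragment's measured height, which decouples training
    from integration differences between the detection and extraction tools.

    ``audit`` (optional) collects ``(group_id, run_id, reason)`` rows for
    every group that was removed.
    """

    def note(g: PeakGroupXIC, reason: str) -> None:
        if audit is not None:
            audit.append((g.group_id, g.run_id, reason))

    # pass 1: filter targets, remembering surviving fragment positions
    surviving_targets: dict[tuple[str, str], PeakGroupXIC] = {}
    kept_positions: dict[tuple[str, str], list[int]] = {}
    for g in groups:
        if g.label != TARGET:
            continue
        if g.precursor_sn is None or g.precursor_sn < min_precursor_sn:
            note(g, f"precursor S/N below {min_precursor_sn}")
            continue
        indexed = [(i, rec, m) for i, (rec, m) in enumerate(g.fragments)]
        flags_by_pos: dict[int, FragmentQualityFlags] = {}
        flagged = flag_fragment_quality(
            g, max_mass_error_ppm=max_mass_error_ppm, max_rt_diff=max_rt_diff,
            fwhm_diff_factor=fwhm_diff_factor, min_rel_height=min_rel_height)
        # align flags back to positions (flag_fragment_quality preserves order
        # of fragments that have height)
        with_height = [i for i, rec, m in indexed if _has_height(m)]
        for pos, (_frag, fl) in zip(with_height, flagged):
            flags_by_pos[pos] = fl

        n_good = sum(1 for fl in flags_by_pos.values() if fl.n_bad == 0)
        if n_good < min_good_fragments:
            note(g, f"fewer than {min_good_fragments} zero-flag fragments")
            continue
        # order by (n_bad asc, height desc); keep up to 2x the good count
        ordered = sorted(flags_by_pos,
                         key=lambda p: (flags_by_pos[p].n_bad,
                                        -(g.fragments[p][1].height or 0.0)))
        keep = sorted(ordered[:2 * n_good])
        if len(keep) < min_total_fragments:
            note(g, f"fewer than {min_total_fragments} fragments after trimming")
            continue
        key = (g.group_id, g.run_id)
        surviving_targets[key] = PeakGroupXIC(
            group_id=g.group_id, run_id=g.run_id, label=g.label,
            precursor=g.precursor, precursor_sn=g.precursor_sn,
            fragments=[g.fragments[p] for p in keep],
            expected_rt=g.expected_rt, expected_ccs=g.expected_ccs,
            observed_ccs=g.observed_ccs, paired_group_id=g.paired_group_id)
        kept_positions[key] = keep

    # pass 2: decoys survive with their paired target, same fragment subset
    out: list[PeakGroupXIC] = []
    for g in groups:
        if g.label == TARGET:
            key = (g.group_id, g.run_id)
            if key in surviving_targets:
                out.append(surviving_targets[key])
            continue
        if g.label != DECOY:
            out.append(g)
            continue
        if g.paired_group_id is None:
            note(g, "decoy without paired target link")
            continue
        key = (g.paired_group_id, g.run_id)
        target = surviving_targets.get(key)
        if target is None:
            note(g, "paired target did not survive")
            continue
        keep = kept_positions[key]
        if any(p >= len(g.fragments) for p in keep):
            note(g, "decoy fragment list shorter than its target's")
            continue
        new_fragments = []
        for p, (t_rec, t_metrics) in zip(keep, target.fragments):
            d_rec, d_metrics = g.fragments[p]
            d_rec = TransitionRecord(
                group_id=d_rec.group_id, label=d_rec.label,
                is_precursor=False, mz=d_rec.mz,
                expected_intensity=t_metrics.height,  # rule (vi)
                precursor_mz=d_rec.precursor_mz,
                explicit_rt=d_rec.explicit_rt, explicit_ccs=d_rec.explicit_ccs,
                paired_group_id=d_rec.paired_group_id)
            new_fragments.append((d_rec, d_metrics))
        out.append(PeakGroupXIC(
            group_id=g.group_id, run_id=g.run_id, label=g.label,
            precursor=g.precursor, precursor_sn=g.precursor_sn,
            fragments=new_fragments, expected_rt=g.expected_rt,
            expected_ccs=g.expected_ccs, observed_ccs=g.observed_ccs,
            paired_group_id=g.paired_group_id))

    n_t = sum(1 for g in out if g.label == TARGET)
    n_d = sum(1 for g in out if g.label == DECOY)
    log.info("filter_training_set: %d targets and %d decoys survive "
             "(of %d input groups)", n_t, n_d, len(groups))
    return out


def write_filter_audit(audit: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write the removal audit as a TSV (group_id, run_id, reason)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group_id", "run_id", "reason"])
        writer.writerows(audit)
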