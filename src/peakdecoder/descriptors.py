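"""Per-peak-group scoring descriptors and the fragment mobility offset.

Seven descriptors summarise how well a peak-group's fragment signals
co-elute with, and resemble, their precursor:

* ``cos_sim`` — cosine similarity between the fragments' integrated areas
  and their expected (reference) intensities;
* ``rtdiff_mean`` / ``rtdiff_sd`` — mean and sample standard deviation of
  the signed differences (precursor RT - fragment RT), in minutes;
* ``fwhmdiff_mean`` / ``fwhmdiff_sd`` — same for LC peak FWHM;
* ``masserror_mean`` / ``masserror_sd`` — mean and sd of the fragment mass
  errors, in ppm.

Differences are signed; standard deviations use the n-1 (sample) form.
Fragments with a missing area are excluded pairwise from every vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np

from .core_model import PeakGroupXIC

log = logging.getLogger("peakdecoder.descriptors")

DESCRIPTOR_NAMES = ("cos_sim", "rtdiff_sd", "rtdiff_mean", "fwhmdiff_sd",
                    "fwhmdiff_mean", "masserror_sd", "masserror_mean")


@dataclass(frozen=True)
class ScoreVector:
    """The seven ML descriptors of one peak-group."""

    cos_sim: float
    rtdiff_sd: float
    rtdiff_mean: float
    fwhmdiff_sd: float
    fwhmdiff_mean: float
    masserror_sd: float
    masserror_mean: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)


def cosine_similarity(observed, expected) -> float:
    """Cosine of the angle between two equal-length non-negative vectors.

    A zero-norm vector yields 0 (degenerate group) with a warning rather
    than an error.
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(expected, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("vectors must be equal-length and one-dimensional")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        log.warning("cosine_similarity: zero-norm vector, returning 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def compute_descriptors(group: PeakGroupXIC,
                        expected_override: list[float] | None = None,
                        ) -> ScoreVector | None:
    """Compute the :class:`ScoreVector` of one peak-group.

    ``expected_override`` replaces the per-transition expected intensities
    (used at query time, where the library spectrum supplies them; it must
    align with ``group.fragments``).  Returns ``None`` when fewer than two
    fragments have a usable area — the standard deviations are then
    undefined and the group is unscorable.
    """
    prec = group.precursor
    areas, expected, rtdiffs, fwhmdiffs, masserrors = [], [], [], [], []
    for i, (rec, m) in enumerate(group.fragments):
        if m.area is None:
            continue  # missing area excludes the fragment from all vectors
        exp = (expected_override[i] if expected_override is not None
               else rec.expected_intensity)
        if exp is None:
            continue
        areas.append(m.area)
        expected.append(exp)
        rtdiffs.append((prec.rt - m.rt) if (prec.rt is not None and m.rt is not None)
                       else math.nan)
        fwhmdiffs.append((prec.fwhm - m.fwhm) if (prec.fwhm is not None and m.fwhm is not None)
                         else math.nan)
        masserrors.append(m.mass_error_ppm if m.mass_error_ppm is not None else math.nan)
    if len(areas) < 2:
        return None

    def mean_sd(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            return (float(arr.mean()) if arr.size else 0.0, 0.0)
        return float(arr.mean()), float(arr.std(ddof=1))

    rt_mean, rt_sd = mean_sd(rtdiffs)
    fwhm_mean, fwhm_sd = mean_sd(fwhmdiffs)
    mass_mean, mass_sd = mean_sd(masserrors)
    return ScoreVector(
        cos_sim=cosine_similarity(areas, expected),
        rtdiff_sd=rt_sd, rtdiff_mean=rt_mean,
        fwhmdiff_sd=fwhm_sd, fwhmdiff_mean=fwhm_mean,
        masserror_sd=mass_sd, masserror_mean=mass_mean)


def descriptor_matrix(groups: list[PeakGroupXIC]):
    """Descriptor table for a list of groups (unscorable groups skipped).

    Returns ``(frame, kept_groups)`` where ``frame`` is a pandas DataFrame
    with one row per scorable group, exportable as TSV for inspection.
    """
    import pandas as pd

    rows, kept = [], []
    for g in groups:
        v = compute_descriptors(g)
        if v is None:
            continue
        rows.append({"group_id": g.group_id, "run_id": g.run_id,
                     "label": g.label,
                     **{n: getattr(v, n) for n in DESCRIPTOR_NAMES}})
        kept.append(g)
    return pd.DataFrame(rows, columns=["group_id", "run_id", "label",
                                       *DESCRIPTOR_NAMES]), kept


def mobility_offset(precursor_mz: float, fragment_mz: float) -> float:
    """Drift-time offset (ms) at which a fragment is sought relative to its
    precursor's drift time.

    Fragments of a precursor arrive slightly earlier than the precursor in
    the high-energy frames because lighter ions traverse the post-drift-cell
    optics faster; the offset grows as the fragment gets lighter than its
    precursor.  Empirical form::

        ((fragment_mz - precursor_mz) / precursor_mz) * 0.7 - precursor_mz * 1e-4

    Typical values fall between -0.1 and -0.3 ms.
    """
    if precursor_mz <= 0 or fragment_mz <= 0:
        raise ValueError("m/z values must be positive")
    return ((fragment_mz - precursor_mz) / precursor_mz) * 0.7 - precursor_mz * 1e-4
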