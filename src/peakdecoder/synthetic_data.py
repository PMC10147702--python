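"""Synthetic LC-IM-MS DIA fixtures with ground-truth labels.

The algorithm never consumes raw spectra — only feature-alignment rows and
XIC summary metrics — so the simulator models exactly that surface:

* *true* peak-groups have fragment apexes jittered tightly around the
  precursor RT, integrated areas proportional to the expected intensities
  (with multiplicative lognormal noise), and small mass errors;
* *false* peak-groups keep realistic precursor properties but their
  fragment signals are decorrelated from the expected intensities (the
  expected vector is permuted and the noise is wide), their RT jitter is an
  order of magnitude larger, and their mass errors are drawn from a much
  wider distribution — emulating the broken co-elution that decoys are
  designed to model, rather than pure noise;
* a configurable fraction of fragments in true groups is corrupted (area
  zeroed or apex shifted) to exercise the interference rules of the
  training filter.

All outputs are written in the canonical ``simple_tsv``/CSV dialects that
the readers accept, and generation is byte-reproducible from the seed.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .core_model import (DECOY, QUERY, TARGET, DeconvolutedFeature,
                         FragmentIon, LibraryEntry, PeakGroupXIC,
                         TransitionRecord, XICMetrics, rank_fragments,
                         write_feature_alignment, write_xic_report)


@dataclass
class SimulationConfig:
    """Parameters of one simulated experiment.

    RT jitter is the standard deviation of fragment-apex offsets from the
    precursor apex (minutes); the *false* values describe broken
    co-elution.  ``intensity_decay`` sets the geometric fall-off of the
    fragment intensity profile; ``interference_rate`` is the fraction of
    true-group fragments corrupted to emulate co-fragmentation
    interference.
    """

    n_true_groups: int = 500
    n_false_groups: int = 500
    n_runs: int = 3
    rt_jitter_sd_true: float = 0.01   # min
    rt_jitter_sd_false: float = 0.15  # min
    fwhm_mean: float = 0.15           # min
    fwhm_sd: float = 0.03
    mass_error_sd_true: float = 3.0   # ppm
    mass_error_sd_false: float = 12.0
    intensity_decay: float = 0.6
    interference_rate: float = 0.1
    # class-overlap realism: a small fraction of true groups suffers
    # degraded chromatography, and a small fraction of false groups
    # partially co-elutes by chance — without this overlap the classes
    # separate perfectly and the smallest non-zero estimable FDR becomes
    # degenerate
    quality_outlier_rate: float = 0.05
    chance_coelution_rate: float = 0.05
    area_noise_sd_true: float = 0.15   # lognormal sigma on areas
    area_noise_sd_false: float = 0.8
    sn_lognormal_params: tuple[float, float] = (math.log(60.0), 0.8)
    fragment_count_range: tuple[int, int] = (4, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rt_jitter_sd_true", "rt_jitter_sd_false", "fwhm_sd",
                     "mass_error_sd_true", "mass_error_sd_false",
                     "area_noise_sd_true", "area_noise_sd_false"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("interference_rate", "quality_outlier_rate",
                     "chance_coelution_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.intensity_decay <= 1.0:
            raise ValueError("intensity_decay must be in (0, 1]")
        lo, hi = self.fragment_count_range
        if not (2 <= lo <= hi <= 16):
            raise ValueError("fragment_count_range must lie within [2, 16]")
        if min(self.n_true_groups, self.n_false_groups, self.n_runs) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a TOML-style plain-text key=value file."""
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("sn_lognormal_params", "fragment_count_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedData:
    """In-memory simulation result plus the files written (if any)."""

    features: list[DeconvolutedFeature]
    groups: list[PeakGroupXIC]
    truth: dict[str, str]  # group_id -> "true" | "false"
    paths: dict[str, Path] = field(default_factory=dict)


def _write_truth(truth: dict[str, str], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("group_id\ttruth\n")
        for gid in truth:
            fh.write(f"{gid}\t{truth[gid]}\n")


def _simulate_feature(rng: np.random.Generator, gid: str, run_id: str,
                      cfg: SimulationConfig) -> DeconvolutedFeature:
    mz = float(rng.uniform(150.0, 850.0))
    rt = float(rng.uniform(0.5, 13.0))
    ccs = 120.0 + 0.35 * (mz - 150.0) + float(rng.normal(0.0, 5.0))
    sn = float(rng.lognormal(*cfg.sn_lognormal_params))
    height = float(rng.lognormal(math.log(1e5), 1.0))
    lo, hi = cfg.fragment_count_range
    n_frag = int(rng.integers(lo, hi + 1))
    frag_mzs = np.sort(rng.uniform(50.0, mz, size=n_frag))[::-1]
    intensities = height * cfg.intensity_decay ** np.arange(1, n_frag + 1) \
        * rng.lognormal(0.0, 0.3, size=n_frag)
    fragments = rank_fragments(
        FragmentIon(mz=float(m), intensity=float(i))
        for m, i in zip(frag_mzs, intensities))
    return DeconvolutedFeature(feature_id=gid, run_id=run_id, precursor_mz=mz,
                               rt=rt, ccs=ccs, sn=sn, height=height,
                               fragments=fragments)


def _group_from_feature(rng: np.random.Generator, feat: DeconvolutedFeature,
                        run_id: str, cfg: SimulationConfig, is_true: bool,
                        gid: str, label: str, paired: str | None,
                        ) -> PeakGroupXIC:
    """Extracted XIC metrics for one (group, run)."""
    # per-group chromatographic quality varies continuously (lognormal
    # scale factors); without this within-class spread the two classes
    # separate perfectly and the smallest estimable non-zero FDR degenerates
    mix = 0.0  # fraction of decorrelated (permuted) intensity profile
    if is_true:
        degraded = rng.random() < cfg.quality_outlier_rate
        rt_sd = cfg.rt_jitter_sd_true * float(rng.lognormal(0.0, 0.6)) \
            * (3.0 if degraded else 1.0)
        area_sd = cfg.area_noise_sd_true * (3.0 if degraded else 1.0)
        mass_sd = cfg.mass_error_sd_true * float(rng.lognormal(0.0, 0.3))
        fwhm_jit = 0.01 * float(rng.lognormal(0.0, 0.5)) * (2.0 if degraded else 1.0)
        mix = 0.3 if degraded else 0.0
    else:
        coelutes = rng.random() < cfg.chance_coelution_rate
        if coelutes:
            # an interfering real molecule whose signals partially line up
            # in RT and partially mimic the expected intensity profile
            rt_sd = cfg.rt_jitter_sd_true * float(rng.lognormal(0.3, 0.6))
            mass_sd = cfg.mass_error_sd_true * float(rng.lognormal(0.3, 0.3))
            area_sd = cfg.area_noise_sd_true * 1.5
            fwhm_jit = 0.015 * float(rng.lognormal(0.0, 0.5))
            mix = float(rng.uniform(0.1, 0.6))
        else:
            rt_sd = cfg.rt_jitter_sd_false * float(rng.lognormal(0.0, 0.4))
            mass_sd = cfg.mass_error_sd_false
            area_sd = cfg.area_noise_sd_false
            fwhm_jit = 0.08 * float(rng.lognormal(0.0, 0.4))
            mix = 1.0

    prec_rt = feat.rt + float(rng.normal(0.0, 0.005))
    prec_fwhm = max(0.02, cfg.fwhm_mean + float(rng.normal(0.0, cfg.fwhm_sd)))
    prec_area = feat.height * prec_fwhm * float(rng.lognormal(0.0, 0.1))
    precursor = XICMetrics(area=prec_area, height=feat.height, fwhm=prec_fwhm,
                           rt=prec_rt,
                           mass_error_ppm=float(rng.normal(0.0, 2.0)),
                           run_id=run_id)

    expected = np.array([f.intensity for f in feat.fragments])
    profile = (1.0 - mix) * expected + mix * rng.permutation(expected)
    fragments: list[tuple[TransitionRecord, XICMetrics]] = []
    for i, frag in enumerate(feat.fragments):
        area = float(profile[i] * prec_fwhm * rng.lognormal(0.0, area_sd))
        frt = prec_rt + float(rng.normal(0.0, rt_sd))
        ffwhm = max(0.02, prec_fwhm + float(rng.normal(0.0, fwhm_jit)))
        merr = float(rng.normal(0.0, mass_sd))
        if is_true and rng.random() < cfg.interference_rate:
            if rng.random() < 0.5:
                area = 0.0
            else:
                frt += float(rng.choice([-1.0, 1.0])) * (0.1 + float(rng.uniform(0.02, 0.3)))
        metrics = XICMetrics(area=area, height=area / max(ffwhm, 1e-6),
                             fwhm=ffwhm, rt=frt, mass_error_ppm=merr,
                             run_id=run_id)
        rec = TransitionRecord(group_id=gid, label=label, is_precursor=False,
                               mz=frag.mz, expected_intensity=frag.intensity,
                               precursor_mz=feat.precursor_mz,
                               paired_group_id=paired)
        fragments.append((rec, metrics))
    return PeakGroupXIC(
        group_id=gid, run_id=run_id, label=label, precursor=precursor,
        precursor_sn=feat.sn, fragments=fragments,
        expected_rt=feat.rt, expected_ccs=feat.ccs,
        observed_ccs=feat.ccs + float(rng.normal(0.0, 0.3)),
        paired_group_id=paired)


def simulate_peakgroups(cfg: SimulationConfig,
                        out_dir: str | Path | None = None) -> SimulatedData:
    """Generate a labelled training fixture.

    Produces a feature-alignment table (the true groups, as deconvoluted
    features in one representative run), a long XIC report with the true
    groups labelled ``target`` and their paired false groups labelled
    ``decoy``, and a truth-label map.  With ``out_dir`` set, the three
    files (``alignment.tsv``, ``xic_report.csv``, ``truth.tsv``) are
    written in the canonical dialects.
    """
    rng = np.random.default_rng(cfg.seed)
    runs = [f"run{i + 1}" for i in range(cfg.n_runs)]

    features = [_simulate_feature(rng, f"T{i:05d}", "run1", cfg)
                for i in range(cfg.n_true_groups)]
    truth: dict[str, str] = {}
    groups: list[PeakGroupXIC] = []
    for i, feat in enumerate(features):
        truth[feat.feature_id] = "true"
        for run in runs:
            groups.append(_group_from_feature(rng, feat, run, cfg, True,
                                              feat.feature_id, TARGET, None))
    for j in range(cfg.n_false_groups):
        partner = features[j % max(1, cfg.n_true_groups)]
        gid = f"F{j:05d}"
        truth[gid] = "false"
        for run in runs:
            groups.append(_group_from_feature(rng, partner, run, cfg, False,
                                              gid, DECOY, partner.feature_id))

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"alignment": out / "alignment.tsv",
                 "xic_report": out / "xic_report.csv",
                 "truth": out / "truth.tsv"}
        write_feature_alignment(features, paths["alignment"])
        write_xic_report(groups, paths["xic_report"])
        _write_truth(truth, paths["truth"])
    return SimulatedData(features=features, groups=groups, truth=truth,
                         paths=paths)


# 64 metabolites typical of a microbial central-carbon panel, as (name,
# formula, [M-H]- m/z).  Used to build the synthetic stand-in reference
# library shipped with the package.
_LIBRARY_PANEL: list[tuple[str, str, float]] = [
    ("fructose 1,6-diphosphate", "C6H14O12P2", 338.98877),
    ("3-hydroxypropanoic acid", "C3H6O3", 89.02442),
    ("lactic acid", "C3H6O3", 89.02442),
    ("pyruvic acid", "C3H4O3", 87.00877),
    ("citric acid", "C6H8O7", 191.01973),
    ("isocitric acid", "C6H8O7", 191.01973),
    ("cis-aconitic acid", "C6H6O6", 173.00916),
    ("itaconic acid", "C5H6O4", 129.01933),
    ("succinic acid", "C4H6O4", 117.01933),
    ("fumaric acid", "C4H4O4", 115.00368),
    ("malic acid", "C4H6O5", 133.01425),
    ("oxaloacetic acid", "C4H4O5", 130.99859),
    ("2-oxoglutaric acid", "C5H6O5", 145.01425),
    ("glutamic acid", "C5H9NO4", 146.04588),
    ("aspartic acid", "C4H7NO4", 132.03023),
    ("alanine", "C3H7NO2", 88.04040),
    ("glycine", "C2H5NO2", 74.02475),
    ("serine", "C3H7NO3", 104.03532),
    ("threonine", "C4H9NO3", 118.05097),
    ("valine", "C5H11NO2", 116.07170),
    ("leucine", "C6H13NO2", 130.08735),
    ("isoleucine", "C6H13NO2", 130.08735),
    ("proline", "C5H9NO2", 114.05605),
    ("phenylalanine", "C9H11NO2", 164.07170),
    ("tyrosine", "C9H11NO3", 180.06662),
    ("tryptophan", "C11H12N2O2", 203.08260),
    ("histidine", "C6H9N3O2", 154.06220),
    ("lysine", "C6H14N2O2", 145.09825),
    ("arginine", "C6H14N4O2", 173.10440),
    ("methionine", "C5H11NO2S", 148.04378),
    ("cysteine", "C3H7NO2S", 120.01247),
    ("asparagine", "C4H8N2O3", 131.04622),
    ("glutamine", "C5H10N2O3", 145.06187),
    ("beta-alanine", "C3H7NO2", 88.04040),
    ("2,4-diaminobutanoic acid", "C4H10N2O2", 117.06695),
    ("glucose", "C6H12O6", 179.05611),
    ("fructose", "C6H12O6", 179.05611),
    ("sucrose", "C12H22O11", 341.10894),
    ("trehalose", "C12H22O11", 341.10894),
    ("glucose 6-phosphate", "C6H13O9P", 259.02244),
    ("fructose 6-phosphate", "C6H13O9P", 259.02244),
    ("glycerol 3-phosphate", "C3H9O6P", 171.00627),
    ("phosphoenolpyruvic acid", "C3H5O6P", 166.97508),
    ("3-phosphoglyceric acid", "C3H7O7P", 184.98565),
    ("dihydroxyacetone phosphate", "C3H7O6P", 168.99062),
    ("ribose 5-phosphate", "C5H11O8P", 229.01187),
    ("sedoheptulose 7-phosphate", "C7H15O10P", 289.03300),
    ("6-phosphogluconic acid", "C6H13O10P", 275.01735),
    ("AMP", "C10H14N5O7P", 346.05580),
    ("ADP", "C10H15N5O10P2", 426.02213),
    ("ATP", "C10H16N5O13P3", 505.98846),
    ("NAD", "C21H27N7O14P2", 662.10237),
    ("GMP", "C10H14N5O8P", 362.05072),
    ("UMP", "C9H13N2O9P", 323.02846),
    ("inosine", "C10H12N4O5", 267.07346),
    ("adenosine", "C10H13N5O4", 266.08945),
    ("uridine", "C9H12N2O6", 243.06226),
    ("guanosine", "C10H13N5O5", 282.08436),
    ("shikimic acid", "C7H10O5", 173.04555),
    ("quinic acid", "C7H12O6", 191.05611),
    ("gluconic acid", "C6H12O7", 195.05103),
    ("pantothenic acid", "C9H17NO5", 218.10340),
    ("glycerol", "C3H8O3", 91.04007),
    ("citramalic acid", "C5H8O5", 147.02990),
]

_MS1_ONLY = {"glycerol", "glycine", "alanine", "beta-alanine"}


def build_synthetic_library(seed: int = 2024) -> list[LibraryEntry]:
    """A synthetic 64-standard RT-CCS-MS/MS reference library.

    Stand-in for a library measured from pure standards: 64 metabolites of
    a microbial central-carbon panel as [M-H]- ions, with deterministic
    synthetic RT, CCS and fragment spectra.  A few small metabolites carry
    no fragments (MS1-only entries).  Anchored instances: fructose
    1,6-diphosphate at m/z 338.98877 / RT 4.95 min / CCS 155.00 with six
    fragments, and the 3-hydroxypropanoic vs lactic acid isomer pair at
    CCS 113.8 vs 113.0.
    """
    rng = np.random.default_rng(seed)
    anchors = {
        "fructose 1,6-diphosphate": (4.95, 155.00),
        "3-hydroxypropanoic acid": (1.21, 113.8),
        "lactic acid": (1.55, 113.0),
    }
    f16dp_fragments = [  # phosphate-series fragments of the anchored entry
        (96.96961, 999.0), (78.95905, 620.0), (241.01193, 310.0),
        (168.99078, 180.0), (138.98023, 95.0), (259.02249, 60.0)]
    entries: list[LibraryEntry] = []
    for name, formula, mz in _LIBRARY_PANEL:
        if name in anchors:
            rt, ccs = anchors[name]
        else:
            rt = round(float(rng.uniform(0.8, 11.5)), 2)
            ccs = round(115.0 + 0.32 * (mz - 80.0) + float(rng.normal(0.0, 4.0)), 2)
        if name == "fructose 1,6-diphosphate":
            peaks = f16dp_fragments
        elif name in _MS1_ONLY:
            peaks = []
        else:
            n = int(rng.integers(3, 9))
            frag_mz = np.sort(rng.uniform(50.0, max(55.0, mz - 10.0), size=n))[::-1]
            inten = np.round(999.0 * 0.55 ** np.arange(n)
                             * rng.lognormal(0.0, 0.25, size=n), 1)
            peaks = [(round(float(m), 5), max(float(i), 1.0))
                     for m, i in zip(frag_mz, inten)]
        entries.append(LibraryEntry(
            name=name, formula=formula, adduct="[M-H]-", precursor_mz=mz,
            rt=rt, ccs=ccs,
            fragments=rank_fragments(FragmentIon(mz=m, intensity=i)
                                     for m, i in peaks)))
    return entries


def default_library_path() -> Path:
    """Path of the packaged synthetic stand-in library MSP."""
    return Path(__file__).parent / "data" / "synthetic_library_64.msp"


def simulate_query(library: list[LibraryEntry], present: set[str],
                   cfg: SimulationConfig,
                   out_dir: str | Path | None = None,
                   absent_mode: str = "noise") -> SimulatedData:
    """Generate a query-extraction fixture from a library.

    Metabolites in ``present`` behave as genuinely detected: signals at the
    library RT/CCS with areas proportional to the library fragment
    intensities.  Absent metabolites are either omitted or emitted as
    blank-extraction noise (sparse, weak, decorrelated signals at a random
    RT inside the window), per ``absent_mode`` ("omit" | "noise").
    """
    unknown = present - {e.name for e in library}
    if unknown:
        raise ValueError(f"present metabolites not in library: {sorted(unknown)}")
    if absent_mode not in ("noise", "omit"):
        raise ValueError(f"absent_mode must be 'noise' or 'omit', got {absent_mode!r}")
    rng = np.random.default_rng(cfg.seed)
    runs = [f"run{i + 1}" for i in range(cfg.n_runs)]
    groups: list[PeakGroupXIC] = []
    truth: dict[str, str] = {}

    for entry in library:
        is_present = entry.name in present
        if not is_present and absent_mode == "omit":
            continue
        truth[entry.name] = "true" if is_present else "false"
        lib_rt = entry.rt if entry.rt is not None else float(rng.uniform(1.0, 12.0))
        lib_ccs = entry.ccs
        expected = np.array([f.intensity for f in entry.fragments]) \
            if entry.fragments else np.empty(0)
        base_height = float(rng.lognormal(math.log(5e4), 0.5))
        for run in runs:
            prec_fwhm = max(0.02, cfg.fwhm_mean + float(rng.normal(0.0, cfg.fwhm_sd)))
            if is_present:
                prec_rt = lib_rt + float(rng.normal(0.0, 0.02))
                prec_err = float(rng.normal(0.0, 3.0))
                obs_ccs = (lib_ccs * (1.0 + float(rng.normal(0.0, 0.15)) / 100.0)
                           if lib_ccs is not None else None)
                prec_area = base_height * prec_fwhm * float(rng.lognormal(0.0, 0.1))
            else:
                prec_rt = lib_rt + float(rng.uniform(-1.0, 1.0))
                prec_err = float(rng.normal(0.0, 8.0))
                obs_ccs = (lib_ccs * (1.0 + float(rng.uniform(-2.0, 2.0)) / 100.0)
                           if lib_ccs is not None and rng.random() < 0.5 else None)
                prec_area = base_height * prec_fwhm * 0.01 * float(rng.lognormal(0.0, 1.0))
            precursor = XICMetrics(area=prec_area, height=prec_area / prec_fwhm,
                                   fwhm=prec_fwhm, rt=prec_rt,
                                   mass_error_ppm=prec_err, run_id=run)
            fragments = []
            for i, frag in enumerate(entry.fragments):
                if is_present:
                    scale = base_height / max(expected.max(), 1.0)
                    area = float(expected[i] * scale * prec_fwhm
                                 * rng.lognormal(0.0, cfg.area_noise_sd_true))
                    frt = prec_rt + float(rng.normal(0.0, cfg.rt_jitter_sd_true))
                    merr = float(rng.normal(0.0, cfg.mass_error_sd_true))
                else:
                    if rng.random() < 0.6:  # transition found nothing
                        area, frt, merr = None, None, None
                    else:
                        area = float(rng.lognormal(math.log(50.0), 1.0)) * prec_fwhm
                        frt = prec_rt + float(rng.normal(0.0, cfg.rt_jitter_sd_false))
                        merr = float(rng.normal(0.0, cfg.mass_error_sd_false))
                ffwhm = max(0.02, prec_fwhm + float(
                    rng.normal(0.0, 0.01 if is_present else 0.08)))
                metrics = XICMetrics(
                    area=area,
                    height=None if area is None else area / ffwhm,
                    fwhm=None if area is None else ffwhm,
                    rt=frt, mass_error_ppm=merr, run_id=run)
                rec = TransitionRecord(group_id=entry.name, label=QUERY,
                                       is_precursor=False, mz=frag.mz,
                                       expected_intensity=frag.intensity,
                                       precursor_mz=entry.precursor_mz)
                fragments.append((rec, metrics))
            groups.append(PeakGroupXIC(
                group_id=entry.name, run_id=run, label=QUERY,
                precursor=precursor, precursor_sn=None, fragments=fragments,
                expected_rt=lib_rt, expected_ccs=lib_ccs,
                observed_ccs=obs_ccs))

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"xic_report": out / "query_report.csv",
                 "truth": out / "query_truth.tsv"}
        write_xic_report(groups, paths["xic_report"])
        _write_truth(truth, paths["truth"])
    return SimulatedData(features=[], groups=groups, truth=truth, paths=paths)
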