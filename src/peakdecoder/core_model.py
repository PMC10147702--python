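"""Domain types and tabular/text readers and writers.

The workflow touches three text dialects:

* a feature-alignment export from untargeted feature detection (one row per
  deconvoluted precursor feature, pseudo-MS2 fragments inlined as
  ``mz:intensity`` pairs),
* a long-format XIC report from targeted data extraction (one row per
  transition per run),
* a metabolite library in NIST MSP text format plus a transition-list CSV.

Column vocabularies of the vendor exports drift between versions, so the
readers match headers case-insensitively against a small alias table and also
accept a canonical ``simple_tsv`` dialect that the synthetic-data module
emits.  Missing numeric cells are carried as ``None`` — never silently
coerced to zero.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger("peakdecoder.io")

MISSING_TOKENS = {"", "na", "#n/a", "nan", "n/a", "none", "null"}

TARGET, DECOY, QUERY = "target", "decoy", "query"


class FormatError(ValueError):
    """A file does not match the expected dialect (bad/missing header)."""


class StructuralError(ValueError):
    """A file parses but violates a structural contract (e.g. a peak-group
    without exactly one precursor row)."""


def parse_float(cell: str | float | None) -> float | None:
    """Parse a numeric cell; missing-value tokens map to ``None``."""
    if cell is None:
        return None
    if isinstance(cell, float):
        return None if math.isnan(cell) else cell
    if str(cell).strip().lower() in MISSING_TOKENS:
        return None
    return float(cell)


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentIon:
    """One fragment of a deconvoluted feature or library entry.

    ``rank`` is the 1-based intensity rank within the owning feature
    (rank 1 = most intense; ties broken by ascending m/z).
    """

    mz: float
    intensity: float
    rank: int = 0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"fragment mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("fragment intensity must be non-negative")


def rank_fragments(fragments: Iterable[FragmentIon]) -> list[FragmentIon]:
    """Sort by descending intensity (ties: ascending m/z) and assign ranks."""
    ordered = sorted(fragments, key=lambda f: (-f.intensity, f.mz))
    return [replace(f, rank=i + 1) for i, f in enumerate(ordered)]


@dataclass
class DeconvolutedFeature:
    """One precursor feature with its pseudo-MS2 fragment list."""

    feature_id: str
    run_id: str
    precursor_mz: float
    rt: float
    ccs: float | None
    sn: float | None
    height: float | None
    fragments: list[FragmentIon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError("rt must be non-negative")
        if self.ccs is not None and self.ccs <= 0:
            raise ValueError("ccs must be positive when present")


@dataclass
class TransitionRecord:
    """One row of a transition list (a precursor or product ion to extract)."""

    group_id: str
    label: str  # target | decoy | query
    is_precursor: bool
    mz: float
    expected_intensity: float | None = None
    precursor_mz: float | None = None
    explicit_rt: float | None = None
    explicit_ccs: float | None = None
    paired_group_id: str | None = None  # decoys reference their target

    def __post_init__(self) -> None:
        if self.label not in (TARGET, DECOY, QUERY):
            raise ValueError(f"label must be target/decoy/query, got {self.label!r}")


@dataclass
class XICMetrics:
    """Summary metrics of one extracted ion chromatogram in one run.

    A metric that the extraction tool could not assign is ``None``.
    """

    area: float | None
    height: float | None
    fwhm: float | None
    rt: float | None
    mass_error_ppm: float | None
    run_id: str = ""


@dataclass
class PeakGroupXIC:
    """One precursor plus its fragment transitions, extracted in one run."""

    group_id: str
    run_id: str
    label: str
    precursor: XICMetrics
    precursor_sn: float | None
    fragments: list[tuple[TransitionRecord, XICMetrics]]
    expected_rt: float | None = None
    expected_ccs: float | None = None
    observed_ccs: float | None = None
    paired_group_id: str | None = None

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class LibraryEntry:
    """One metabolite's reference coordinates and fragment spectrum.

    ``fragments`` hold the raw reference intensities; intensities normalised
    to max = 100 are kept alongside via :meth:`normalized_fragments`.
    """

    name: str
    formula: str
    adduct: str
    precursor_mz: float
    rt: float | None
    ccs: float | None
    fragments: list[FragmentIon] = field(default_factory=list)

    def normalized_fragments(self) -> list[FragmentIon]:
        if not self.fragments:
            return []
        top = max(f.intensity for f in self.fragments)
        if top <= 0:
            return list(self.fragments)
        return [replace(f, intensity=100.0 * f.intensity / top) for f in self.fragments]

    def fragment_intensities(self, kind: str = "raw") -> list[float]:
        frags = self.fragments if kind == "raw" else self.normalized_fragments()
        return [f.intensity for f in frags]


# ---------------------------------------------------------------------------
# Feature-alignment reader
# ---------------------------------------------------------------------------

# canonical column -> accepted aliases (lower-cased, stripped)
_ALIGNMENT_ALIASES: dict[str, tuple[str, ...]] = {
    "feature_id": ("feature_id", "alignment id", "peak id"),
    "run_id": ("run_id", "representative file", "file name", "spectrum reference file name"),
    "precursor_mz": ("precursor_mz", "average mz", "precursor m/z", "precursor mz"),
    "rt": ("rt", "average rt(min)", "rt (min)", "retention time"),
    "ccs": ("ccs", "average ccs", "collision cross section"),
    "sn": ("sn", "s/n average", "s/n", "signal/noise"),
    "height": ("height", "average height", "precursor height"),
    "ms2": ("ms2", "ms/ms spectrum", "msms spectrum", "fragments"),
}

_REQUIRED_ALIGNMENT = ("feature_id", "precursor_mz", "rt", "ms2")


def _map_header(header: Sequence[str], aliases: dict[str, tuple[str, ...]],
                required: Sequence[str], what: str) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    mapping: dict[str, int] = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lowered:
                mapping[canon] = lowered.index(name)
                break
    missing = [c for c in required if c not in mapping]
    if missing:
        raise FormatError(f"{what}: header is missing required column(s) {missing}; got {list(header)}")
    return mapping


def parse_fragment_string(text: str, context: str = "") -> list[FragmentIon]:
    """Parse space-separated ``mz:intensity`` pairs; bad tokens are skipped
    with a warning."""
    fragments: list[FragmentIon] = []
    for token in text.split():
        try:
            mz_s, int_s = token.split(":")
            fragments.append(FragmentIon(mz=float(mz_s), intensity=float(int_s)))
        except (ValueError, TypeError):
            log.warning("skipping unparsable fragment token %r %s", token, context)
    return rank_fragments(fragments)


def read_feature_alignment(path: str | Path, dialect: str = "simple_tsv") -> list[DeconvolutedFeature]:
    """Read a feature-alignment export into :class:`DeconvolutedFeature` rows.

    ``dialect`` is ``simple_tsv`` (canonical, tab-separated) or
    ``msdial_alignment`` (vendor-style headers, also tab-separated); both are
    resolved through the same alias table, the dialect mainly documents intent.
    """
    if dialect not in ("simple_tsv", "msdial_alignment"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    features: list[DeconvolutedFeature] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        cols = _map_header(header, _ALIGNMENT_ALIASES, _REQUIRED_ALIGNMENT, str(path))

        def cell(row: list[str], name: str) -> str | None:
            idx = cols.get(name)
            return row[idx] if idx is not None and idx < len(row) else None

        for row in reader:
            if not any(c.strip() for c in row):
                continue
            fid = cell(row, "feature_id")
            ms2 = cell(row, "ms2") or ""
            features.append(DeconvolutedFeature(
                feature_id=str(fid),
                run_id=str(cell(row, "run_id") or ""),
                precursor_mz=float(cell(row, "precursor_mz")),
                rt=float(cell(row, "rt")),
                ccs=parse_float(cell(row, "ccs")),
                sn=parse_float(cell(row, "sn")),
                height=parse_float(cell(row, "height")),
                fragments=parse_fragment_string(ms2, context=f"(feature {fid})"),
            ))
    return features


def write_feature_alignment(features: Iterable[DeconvolutedFeature], path: str | Path) -> None:
    """Write features in the canonical simple_tsv dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature_id", "run_id", "precursor_mz", "rt", "ccs",
                         "sn", "height", "ms2"])
        for f in features:
            ms2 = " ".join(f"{frag.mz!r}:{frag.intensity!r}" for frag in f.fragments)
            writer.writerow([f.feature_id, f.run_id, repr(f.precursor_mz), repr(f.rt),
                             _fmt(f.ccs), _fmt(f.sn), _fmt(f.height), ms2])


# ---------------------------------------------------------------------------
# XIC report reader/writer (long format, one row per transition per run)
# ---------------------------------------------------------------------------

_XIC_ALIASES: dict[str, tuple[str, ...]] = {
    "group_id": ("group_id", "molecule name", "molecule"),
    "run_id": ("run_id", "replicate name", "replicate", "file name"),
    "label": ("label", "molecule list name", "molecule list"),
    "is_precursor": ("is_precursor", "fragment ion type", "ion type"),
    "mz": ("mz", "product mz", "product m/z"),
    "expected_intensity": ("expected_intensity", "library intensity"),
    "area": ("area", "total area"),
    "height": ("height", "max height"),
    "fwhm": ("fwhm", "max fwhm"),
    "rt": ("rt", "retention time", "best retention time"),
    "mass_error_ppm": ("mass_error_ppm", "average mass error ppm", "mass error ppm"),
    "expected_rt": ("expected_rt", "explicit retention time"),
    "expected_ccs": ("expected_ccs", "explicit collision cross section"),
    "observed_ccs": ("observed_ccs", "run ccs"),
    "precursor_sn": ("precursor_sn", "s/n", "sn"),
    "paired_group_id": ("paired_group_id", "paired target"),
}

_REQUIRED_XIC = ("group_id", "run_id", "label", "is_precursor", "mz", "area",
                 "height", "fwhm", "rt", "mass_error_ppm")

_XIC_COLUMNS = ["group_id", "run_id", "label", "is_precursor", "mz",
                "expected_intensity", "area", "height", "fwhm", "rt",
                "mass_error_ppm", "expected_rt", "expected_ccs",
                "observed_ccs", "precursor_sn", "paired_group_id"]


def _truthy(cell: str) -> bool:
    return str(cell).strip().lower() in {"1", "true", "yes", "precursor", "p"}


def read_xic_report(path: str | Path) -> list[PeakGroupXIC]:
    """Read a long-format XIC report; rows are grouped by (group_id, run_id).

    Each group must contain exactly one precursor row; a group with zero or
    more than one raises :class:`StructuralError` naming the group.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        cols = _map_header(header, _XIC_ALIASES, _REQUIRED_XIC, str(path))

        def cell(row: list[str], name: str) -> str | None:
            idx = cols.get(name)
            return row[idx] if idx is not None and idx < len(row) else None

        by_group: dict[tuple[str, str], list[list[str]]] = {}
        order: list[tuple[str, str]] = []
        for row in reader:
            if not any(c.strip() for c in row):
                continue
            key = (str(cell(row, "group_id")), str(cell(row, "run_id")))
            if key not in by_group:
                by_group[key] = []
                order.append(key)
            by_group[key].append(row)

    groups: list[PeakGroupXIC] = []
    for key in order:
        rows = by_group[key]
        gid, run = key
        prec_rows = [r for r in rows if _truthy(cell(r, "is_precursor") or "")]
        if len(prec_rows) != 1:
            raise StructuralError(
                f"{path}: group {gid!r} in run {run!r} has {len(prec_rows)} precursor rows, expected 1")
        prec = prec_rows[0]

        def metrics(row: list[str]) -> XICMetrics:
            return XICMetrics(
                area=parse_float(cell(row, "area")),
                height=parse_float(cell(row, "height")),
                fwhm=parse_float(cell(row, "fwhm")),
                rt=parse_float(cell(row, "rt")),
                mass_error_ppm=parse_float(cell(row, "mass_error_ppm")),
                run_id=run,
            )

        label = str(cell(prec, "label") or "").strip().lower()
        fragments = []
        for r in rows:
            if r is prec:
                continue
            rec = TransitionRecord(
                group_id=gid, label=label, is_precursor=False,
                mz=float(cell(r, "mz")),
                expected_intensity=parse_float(cell(r, "expected_intensity")),
                precursor_mz=parse_float(cell(prec, "mz")),
            )
            fragments.append((rec, metrics(r)))
        paired = cell(prec, "paired_group_id")
        groups.append(PeakGroupXIC(
            group_id=gid, run_id=run, label=label,
            precursor=metrics(prec),
            precursor_sn=parse_float(cell(prec, "precursor_sn")),
            fragments=fragments,
            expected_rt=parse_float(cell(prec, "expected_rt")),
            expected_ccs=parse_float(cell(prec, "expected_ccs")),
            observed_ccs=parse_float(cell(prec, "observed_ccs")),
            paired_group_id=str(paired) if paired and str(paired).strip() else None,
        ))
    return groups


def write_xic_report(groups: Iterable[PeakGroupXIC], path: str | Path) -> None:
    """Write peak-groups back out in the canonical long CSV format."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_XIC_COLUMNS)

        def row(g: PeakGroupXIC, is_prec: bool, mz: float,
                m: XICMetrics, expected_intensity: float | None) -> list[str]:
            return [g.group_id, g.run_id, g.label, "1" if is_prec else "0",
                    repr(float(mz)), _fmt(expected_intensity), _fmt(m.area),
                    _fmt(m.height), _fmt(m.fwhm), _fmt(m.rt),
                    _fmt(m.mass_error_ppm), _fmt(g.expected_rt),
                    _fmt(g.expected_ccs), _fmt(g.observed_ccs),
                    _fmt(g.precursor_sn), g.paired_group_id or ""]

        for g in groups:
            prec_mz = g.fragments[0][0].precursor_mz if g.fragments else None
            writer.writerow(row(g, True, prec_mz if prec_mz is not None else 0.0,
                                g.precursor, None))
            for rec, m in g.fragments:
                writer.writerow(row(g, False, rec.mz, m, rec.expected_intensity))


# ---------------------------------------------------------------------------
# MSP library reader
# ---------------------------------------------------------------------------

def read_library_msp(path: str | Path) -> list[LibraryEntry]:
    """Read a NIST MSP text library.

    One entry per record; records lacking a precursor m/z are skipped with a
    warning.  Fragment intensities are stored raw; max-100 normalisation is
    available from the returned entries.
    """
    path = Path(path)
    entries: list[LibraryEntry] = []
    record: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_peaks_expected = 0

    def flush() -> None:
        nonlocal record, peaks, n_peaks_expected
        if not record:
            return
        name = record.get("name", "<unnamed>")
        pmz = record.get("precursormz") or record.get("precursor_mz")
        if pmz is None:
            log.warning("skipping MSP record %r: no PrecursorMZ field", name)
        else:
            fragments = rank_fragments(
                FragmentIon(mz=mz, intensity=inten) for mz, inten in peaks)
            entries.append(LibraryEntry(
                name=name,
                formula=record.get("formula", ""),
                adduct=record.get("precursortype") or record.get("adduct", ""),
                precursor_mz=float(pmz),
                rt=parse_float(record.get("retentiontime") or record.get("rt")),
                ccs=parse_float(record.get("ccs") or record.get("collisioncrosssection")),
                fragments=fragments,
            ))
        record, peaks, n_peaks_expected = {}, [], 0

    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().lower().replace(" ", "")
                value = value.strip()
                if key == "numpeaks":
                    n_peaks_expected = int(value)
                else:
                    record[key] = value
            else:
                parts = line.replace("\t", " ").split()
                if len(parts) >= 2:
                    try:
                        peaks.append((float(parts[0]), float(parts[1])))
                    except ValueError:
                        log.warning("skipping unparsable MSP peak line %r", line)
    flush()
    return entries


def write_library_msp(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for e in entries:
            fh.write(f"Name: {e.name}\n")
            if e.formula:
                fh.write(f"Formula: {e.formula}\n")
            if e.adduct:
                fh.write(f"PrecursorType: {e.adduct}\n")
            fh.write(f"PrecursorMZ: {e.precursor_mz!r}\n")
            if e.rt is not None:
                fh.write(f"RetentionTime: {e.rt!r}\n")
            if e.ccs is not None:
                fh.write(f"CCS: {e.ccs!r}\n")
            fh.write(f"Num Peaks: {len(e.fragments)}\n")
            for f in e.fragments:
                fh.write(f"{f.mz!r} {f.intensity!r}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Transition-list writer/reader
# ---------------------------------------------------------------------------

_TRANSITION_COLUMNS = ["Molecule List Name", "Molecule Name", "Precursor m/z",
                       "Product m/z", "Explicit Retention Time",
                       "Explicit Collision Cross Section",
                       "Expected Intensity", "Paired Target"]


def write_transition_list(records: Iterable[TransitionRecord], path: str | Path,
                          metadata: dict[str, str] | None = None) -> None:
    """Write a transition-list CSV (one row per precursor or product ion).

    Optional ``metadata`` key/value pairs are written as ``# key=value``
    comment lines before the header (e.g. the decoy-generation seed).
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_TRANSITION_COLUMNS)
        for r in records:
            list_name = r.label.capitalize()
            writer.writerow([
                list_name, r.group_id,
                _fmt(r.precursor_mz if r.precursor_mz is not None else
                     (r.mz if r.is_precursor else None)),
                repr(float(r.mz)),
                _fmt(r.explicit_rt), _fmt(r.explicit_ccs),
                _fmt(r.expected_intensity), r.paired_group_id or ""])


def read_transition_list(path: str | Path) -> list[TransitionRecord]:
    path = Path(path)
    records: list[TransitionRecord] = []
    with path.open(newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.reader(lines)
    header = next(reader)
    lowered = [h.strip().lower() for h in header]
    idx = {name.lower(): i for i, name in enumerate(_TRANSITION_COLUMNS)}
    for want in idx:
        if want not in lowered:
            raise FormatError(f"{path}: transition list missing column {want!r}")
    col = {name: lowered.index(name.lower()) for name in _TRANSITION_COLUMNS}
    for row in reader:
        if not any(c.strip() for c in row):
            continue
        pmz = parse_float(row[col["Precursor m/z"]])
        prod = float(row[col["Product m/z"]])
        paired = row[col["Paired Target"]].strip()
        records.append(TransitionRecord(
            group_id=row[col["Molecule Name"]],
            label=row[col["Molecule List Name"]].strip().lower(),
            is_precursor=(pmz is not None and prod == pmz),
            mz=prod,
            expected_intensity=parse_float(row[col["Expected Intensity"]]),
            precursor_mz=pmz,
            explicit_rt=parse_float(row[col["Explicit Retention Time"]]),
            explicit_ccs=parse_float(row[col["Explicit Collision Cross Section"]]),
            paired_group_id=paired or None,
        ))
    return records


# ---------------------------------------------------------------------------
# Results writers
# ---------------------------------------------------------------------------

def write_results(annotations, fdr_table, path_prefix: str | Path,
                  dataset_tag: str = "run") -> dict[str, Path]:
    """Write the FDR-threshold table and the annotation report.

    Emits ``PeakDecoder-FDR-thresholds_<dataset>.csv`` and
    ``PeakDecoder-annotations_<dataset>.csv`` under the directory
    ``path_prefix`` (created if needed).  Returns the paths written.
    """
    base = Path(path_prefix)
    base.mkdir(parents=True, exist_ok=True)
    thresholds_path = base / f"PeakDecoder-FDR-thresholds_{dataset_tag}.csv"
    annotations_path = base / f"PeakDecoder-annotations_{dataset_tag}.csv"

    with thresholds_path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["PeakDecoderScore", "FDR"])
        for row in fdr_table:
            writer.writerow([repr(float(row.score_threshold)), repr(float(row.fdr))])

    with annotations_path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["Metabolite", "Run", "Score", "MassErrorPPM",
                         "RTError", "CCSErrorPct", "NFragments", "Level", "Passed"])
        for a in annotations:
            writer.writerow([a.metabolite, a.run_id, _fmt(a.score),
                             _fmt(a.mass_error_ppm), _fmt(a.rt_error),
                             _fmt(a.ccs_error_pct), a.n_fragments, a.level,
                             "true" if a.passed else "false"])
    return {"thresholds": thresholds_path, "annotations": annotations_path}
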