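"""Reading, validating and merging SmartRoot-style CSV exports.

A tracing session exports one CSV per photographed plate (days 0 and 1) or
per seedling (day 2).  Each row names one traced structure — ``seed7rt2`` is
root 2 of seedling 7, ``seed7sht`` its coleoptile (shoot) — and carries its
length in millimetres.  Filenames follow the
``"20160413 Zak wt WW1 day0.csv"`` scheme: a capture date, the cultivar name
after the first space, a condition+plate token (``WW1``–``WS3``), a day token
(``day0``–``day2``) and, on day-2 per-seedling photographs, an ``s1``–``s24``
token.

This module parses both grammars, reads exports into :class:`TracingTable`
objects and merges the per-folder file sets into single combined tables, the
first step of the analysis pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import ExportError, FilenameParseError, LabelParseError, MergeError

#: canonical anatomical structure names, in stable reporting order
STRUCTURE_ORDER = ("shoot", "root1", "root2", "root3", "root4", "root5", "root6")

#: roots that emerge after transplant; missing records mean "absent", value 0
LATE_ROOTS = frozenset({"root4", "root5", "root6"})

#: structures present from day 0; missing records mean "occluded"
CORE_STRUCTURES = frozenset({"shoot", "root1", "root2", "root3"})

_LABEL_RE = re.compile(
    r"^seed(?P<idx>\d+)"
    r"(?:(?P<shoot>sht|st)|(?P<roottok>rt|r)(?P<num>\d+))"
    r"(?P<na>_na)?$",
    re.IGNORECASE,
)

_COND_RE = re.compile(r"^(WW|WS)([1-3])$", re.IGNORECASE)
_DAY_RE = re.compile(r"^day([0-2])$", re.IGNORECASE)
_SEEDLING_RE = re.compile(r"^s([0-9]+)$", re.IGNORECASE)


@dataclass(frozen=True)
class StructureLabel:
    """Parsed identity of one traced object.

    ``measurable=False`` corresponds to the ``_NA`` suffix used on day-1
    tracings of a late root (4–6) that is present but partly hidden; such
    records are excluded from analysis rather than scored as zero.
    """

    seedling_index: int
    kind: str  # "root" | "shoot"
    root_number: Optional[int] = None
    measurable: bool = True

    def __post_init__(self) -> None:
        if self.seedling_index < 1:
            raise LabelParseError(
                f"seedling index must be >= 1, got {self.seedling_index}"
            )
        if self.kind not in ("root", "shoot"):
            raise LabelParseError(f"unknown structure kind {self.kind!r}")
        if self.kind == "root":
            if self.root_number is None or not 1 <= self.root_number <= 6:
                raise LabelParseError(
                    f"root number must be in 1..6, got {self.root_number}"
                )
        elif self.root_number is not None:
            raise LabelParseError("shoot labels carry no root number")
        if not self.measurable:
            if self.kind != "root" or self.root_number not in (4, 5, 6):
                raise LabelParseError(
                    "'_NA' (non-measurable) is only valid on roots 4-6; "
                    "roots 1-3 and the shoot are simply skipped when occluded"
                )

    @property
    def structure(self) -> str:
        """Canonical structure name: ``"shoot"`` or ``"root1"``–``"root6"``."""
        return "shoot" if self.kind == "shoot" else f"root{self.root_number}"

    def canonical(self) -> str:
        """Canonical label text, e.g. ``"seed7rt2"`` or ``"seed7r4_NA"``."""
        if self.kind == "shoot":
            return f"seed{self.seedling_index}sht"
        suffix = "" if self.measurable else "_NA"
        tok = "r" if not self.measurable else "rt"
        return f"seed{self.seedling_index}{tok}{self.root_number}{suffix}"


def parse_structure_label(text: str) -> StructureLabel:
    """Parse a structure label such as ``seed1rt1``, ``seed24sht`` or ``seed1r4_NA``.

    Both root spellings (``rt``/``r``) and shoot spellings (``sht``/``st``)
    are accepted, case-insensitively.  A trailing ``_NA`` marks a
    non-measurable (occluded) late root.

    Raises
    ------
    LabelParseError
        If the text does not follow the grammar, the seedling index is 0,
        the root number is outside 1–6, or ``_NA`` is attached to a
        structure where it is not allowed.
    """
    if not isinstance(text, str) or not text.strip():
        raise LabelParseError(f"empty or non-string label: {text!r}")
    token = text.strip()
    m = _LABEL_RE.match(token)
    if m is None:
        raise LabelParseError(f"malformed structure label {token!r}")
    idx = int(m.group("idx"))
    measurable = m.group("na") is None
    if m.group("shoot") is not None:
        return StructureLabel(idx, "shoot", None, measurable)
    return StructureLabel(idx, "root", int(m.group("num")), measurable)


@dataclass(frozen=True)
class FileMeta:
    """Experimental metadata carried by an export filename."""

    condition: str  # "WW" | "WS"
    plate_index: int  # 1..3
    day: int  # 0..2
    genotype: Optional[str] = None
    capture_date: Optional[date] = None
    seedling_image: Optional[int] = None  # day-2 per-seedling photographs only
    filename: Optional[str] = None

    def __post_init__(self) -> None:
        if self.condition not in ("WW", "WS"):
            raise FilenameParseError(f"condition must be WW or WS, got {self.condition!r}")
        if not 1 <= self.plate_index <= 3:
            raise FilenameParseError(f"plate index must be 1..3, got {self.plate_index}")
        if self.day not in (0, 1, 2):
            raise FilenameParseError(f"day must be 0..2, got {self.day}")
        if self.seedling_image is not None:
            if self.day != 2:
                raise FilenameParseError(
                    "a per-seedling token (s1-s24) is only valid on day-2 files"
                )
            if not 1 <= self.seedling_image <= 24:
                raise FilenameParseError(
                    f"seedling image number must be 1..24, got {self.seedling_image}"
                )


def parse_filename(name: Union[str, Path]) -> FileMeta:
    """Extract :class:`FileMeta` from an export filename.

    The condition and plate come from a space-delimited ``WW1``-style token,
    the day from a ``day0``/``day1``/``day2`` token, the genotype is the
    token immediately after the first space, and an optional leading
    ``YYYYMMDD`` token gives the capture date.  Day-2 filenames may carry an
    ``s<n>`` per-seedling token.
    """
    name = Path(name).name
    if not name.lower().endswith(".csv"):
        raise FilenameParseError(f"{name!r}: expected a .csv filename")
    stem = name[:-4]
    tokens = stem.split()
    if not tokens:
        raise FilenameParseError(f"{name!r}: empty filename")

    cond_matches = [(i, _COND_RE.match(t)) for i, t in enumerate(tokens)]
    cond_matches = [(i, m) for i, m in cond_matches if m]
    if not cond_matches:
        raise FilenameParseError(
            f"{name!r}: missing condition token (e.g. 'WW1' surrounded by spaces)"
        )
    if len(cond_matches) > 1:
        raise FilenameParseError(f"{name!r}: multiple condition tokens")
    _, cm = cond_matches[0]
    condition = cm.group(1).upper()
    plate = int(cm.group(2))

    day_matches = [m for t in tokens if (m := _DAY_RE.match(t))]
    if len(day_matches) != 1:
        raise FilenameParseError(f"{name!r}: expected exactly one day0/day1/day2 token")
    day = int(day_matches[0].group(1))

    seedling: Optional[int] = None
    for t in tokens:
        sm = _SEEDLING_RE.match(t)
        if sm:
            seedling = int(sm.group(1))
            break

    capture: Optional[date] = None
    try:
        capture = datetime.strptime(tokens[0], "%Y%m%d").date()
    except ValueError:
        capture = None

    # genotype = the single token after the first space, unless it is itself
    # a condition/day token (anything after it, e.g. "wt", is free text)
    genotype: Optional[str] = None
    if len(tokens) > 1 and not _COND_RE.match(tokens[1]) and not _DAY_RE.match(tokens[1]):
        genotype = tokens[1]

    return FileMeta(
        condition=condition,
        plate_index=plate,
        day=day,
        genotype=genotype,
        capture_date=capture,
        seedling_image=seedling,
        filename=name,
    )


@dataclass(frozen=True)
class TracingRecord:
    """One traced structure: label + length (mm) + file metadata."""

    label: StructureLabel
    length_mm: float
    meta: FileMeta
    extra_measurements: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = float(self.length_mm)
        if not (v >= 0.0) or v != v or v in (float("inf"),):
            raise ExportError(f"length must be finite and >= 0, got {self.length_mm!r}")

    def key(self) -> tuple:
        """Uniqueness key within an experiment: (condition, image unit, day, seedling, structure)."""
        unit = (
            self.meta.seedling_image
            if self.meta.day == 2 and self.meta.seedling_image is not None
            else self.meta.plate_index
        )
        return (
            self.meta.condition,
            unit,
            self.meta.day,
            self.label.seedling_index,
            self.label.structure,
        )


@dataclass
class TracingTable:
    """Ordered collection of :class:`TracingRecord` with source provenance."""

    records: list[TracingRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple, str] = {}
        for rec in self.records:
            k = rec.key()
            if k in seen:
                raise ExportError(
                    f"duplicate structure key {k} (files {seen[k]!r} and "
                    f"{rec.meta.filename!r})"
                )
            seen[k] = rec.meta.filename or "<memory>"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TracingRecord]:
        return iter(self.records)

    @property
    def n_files(self) -> int:
        return len(self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Long DataFrame view: one row per traced structure."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "condition": r.meta.condition,
                    "plate_index": r.meta.plate_index,
                    "day": r.meta.day,
                    "seedling_index": r.label.seedling_index,
                    "structure": r.label.structure,
                    "measurable": r.label.measurable,
                    "length_mm": float(r.length_mm),
                    "genotype": r.meta.genotype,
                    "seedling_image": r.meta.seedling_image,
                    "source_file": r.meta.filename,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "condition",
                "plate_index",
                "day",
                "seedling_index",
                "structure",
                "measurable",
                "length_mm",
                "genotype",
                "seedling_image",
                "source_file",
            ],
        )


@dataclass(frozen=True)
class ColumnMap:
    """Names of the required columns in an export; overridable per tracing-software version."""

    label: str = "root"
    length: str = "length"


DEFAULT_COLUMNS = ColumnMap()


def _find_column(columns: Sequence[str], wanted: str, path: Path) -> str:
    lowered = {c.strip().lower(): c for c in columns}
    key = wanted.strip().lower()
    if key not in lowered:
        raise ExportError(
            f"{path.name}: required column {wanted!r} not found "
            f"(have: {', '.join(columns)})"
        )
    return lowered[key]


def read_export(
    path: Union[str, Path],
    columns: ColumnMap = DEFAULT_COLUMNS,
    meta: Optional[FileMeta] = None,
) -> TracingTable:
    """Read one tracing export, stamping every row with filename metadata.

    The file must be comma-separated with a header row containing a
    structure-label column and a length column (default names ``root`` and
    ``length``; see :class:`ColumnMap`).  All other columns are retained on
    each record as ``extra_measurements``.
    """
    path = Path(path)
    if meta is None:
        meta = parse_filename(path.name)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExportError(f"{path.name}: unreadable CSV ({exc})") from exc
    label_col = _find_column(list(df.columns), columns.label, path)
    length_col = _find_column(list(df.columns), columns.length, path)
    extra_cols = [c for c in df.columns if c not in (label_col, length_col)]

    records: list[TracingRecord] = []
    seen_labels: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        raw = getattr(row, "_asdict", None)
        vals = row._asdict() if raw else dict(zip(df.columns, row))
        try:
            label = parse_structure_label(str(vals[label_col]))
        except LabelParseError as exc:
            raise ExportError(f"{path.name}, line {i}: {exc}") from exc
        lkey = f"seed{label.seedling_index}:{label.structure}"
        if lkey in seen_labels:
            raise ExportError(
                f"{path.name}, line {i}: duplicate structure label for "
                f"seedling {label.seedling_index} {label.structure} "
                f"(first seen at line {seen_labels[lkey]})"
            )
        seen_labels[lkey] = i
        try:
            length = float(vals[length_col])
        except (TypeError, ValueError) as exc:
            raise ExportError(
                f"{path.name}, line {i}: non-numeric length {vals[length_col]!r}"
            ) from exc
        if not (length >= 0.0) or length != length:
            raise ExportError(f"{path.name}, line {i}: negative or NaN length {length!r}")
        extras = {c: vals[c] for c in extra_cols}
        records.append(TracingRecord(label, length, meta, extras))
    return TracingTable(records, provenance=[path.name])


def merge_exports(
    source: Union[str, Path, Iterable[Union[str, Path]]],
    out: Optional[Union[str, Path]] = None,
    columns: ColumnMap = DEFAULT_COLUMNS,
) -> TracingTable:
    """Merge all exports of one (condition, day) folder into a single table.

    ``source`` is either a folder (all ``*.csv`` files in it, sorted by name)
    or an explicit list of paths.  All files must agree on condition and day.
    When ``out`` is given, the combined table is also written there as CSV;
    passing a directory writes ``"<folder name> (combined).csv"`` inside it.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        folder = Path(source)
        paths = sorted(
            (p for p in folder.iterdir() if p.suffix.lower() == ".csv"),
            key=lambda p: p.name,
        )
        default_name = combined_name(folder)
    else:
        paths = [Path(p) for p in source]  # type: ignore[union-attr]
        folder = paths[0].parent if paths else None
        default_name = combined_name(folder) if folder else "merged (combined).csv"
    if not paths:
        raise MergeError(f"no CSV files to merge in {source!r}")

    tables = [read_export(p, columns=columns) for p in paths]
    pairs = {(t.records[0].meta.condition, t.records[0].meta.day) for t in tables if t.records}
    if len(pairs) > 1:
        raise MergeError(
            f"refusing to merge mixed (condition, day) file sets: {sorted(pairs)}"
        )
    merged = TracingTable(
        records=[r for t in tables for r in t.records],
        provenance=[p.name for p in paths],
    )
    if out is not None:
        out_path = Path(out)
        if out_path.is_dir():
            out_path = out_path / default_name
        write_combined(merged, out_path)
    return merged


def combined_name(folder: Union[str, Path]) -> str:
    """Output filename for a merged folder: ``"<folder name> (combined).csv"``."""
    return f"{Path(folder).name} (combined).csv"


def write_combined(table: TracingTable, path: Union[str, Path]) -> Path:
    """Write a merged table as a combined CSV (label, length, metadata, extras)."""
    path = Path(path)
    df = table.to_frame()
    df.insert(0, "root", [r.label.canonical() for r in table.records])
    df.insert(1, "length", df.pop("length_mm"))
    extra_keys = sorted({k for r in table.records for k in r.extra_measurements})
    for k in extra_keys:
        df[k] = [r.extra_measurements.get(k) for r in table.records]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_combined(path: Union[str, Path], columns: ColumnMap = DEFAULT_COLUMNS) -> TracingTable:
    """Read back a combined CSV written by :func:`write_combined`."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"root", "length", "condition", "plate_index", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ExportError(f"{path.name}: combined CSV missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        label = parse_structure_label(str(row["root"]))
        seedling_image = row.get("seedling_image")
        seedling_image = (
            int(seedling_image) if pd.notna(seedling_image) else None
        )
        capture = None
        meta = FileMeta(
            condition=str(row["condition"]),
            plate_index=int(row["plate_index"]),
            day=int(row["day"]),
            genotype=None if pd.isna(row.get("genotype")) else str(row.get("genotype")),
            capture_date=capture,
            seedling_image=seedling_image,
            filename=None if pd.isna(row.get("source_file")) else str(row.get("source_file")),
        )
        records.append(TracingRecord(label, float(row["length"]), meta))
    return TracingTable(records, provenance=[path.name])
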