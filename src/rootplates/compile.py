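"""Seedling × structure × day time-course compilation for one condition.

The three merged day tables (0, 1, 2) are turned into a complete long table
with one row per seedling × structure × day and an explicit status:

``measured``
    a usable traced length exists;
``occluded``
    the structure exists but was not measurable in that photograph (grew
    away from the transparent wall, around the plate edge, was traced with
    an ``_NA`` label, or the whole seedling is missing from the image) —
    excluded from means and from n without touching any other structure;
``absent``
    a late root (4–6) that has not emerged yet — scored as length 0 and
    counted toward n, because "not there yet" is a real biological zero.

Roots 1–3 and the shoot exist from transplant, so a missing record for them
can only mean occlusion.  The per-condition root-6 inclusion rule (more than
`threshold` of the seedlings ever show a sixth root) and the per-interval
growth increments used by the root plots live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DataQualityWarning
from .smartroot_io import (
    CORE_STRUCTURES,
    LATE_ROOTS,
    STRUCTURE_ORDER,
    TracingTable,
)

STATUS_MEASURED = "measured"
STATUS_OCCLUDED = "occluded"
STATUS_ABSENT = "absent"

#: default root-6 rule: include only when MORE THAN this many seedlings show one
ROOT6_THRESHOLD = 3

_COMPILED_COLUMNS = [
    "plate_index",
    "seedling_index",
    "structure",
    "day",
    "length_mm",
    "status",
    "reason",
]


@dataclass
class CompiledCondition:
    """Complete per-seedling time course for one condition.

    ``data`` has exactly one row per (seedling, structure, day); occluded
    rows carry NaN length, absent rows carry 0.  ``events`` records every
    rule application (occlusions, zeros) for the run log.
    """

    genotype: Optional[str]
    condition: str
    data: pd.DataFrame
    events: list[dict] = field(default_factory=list)

    @property
    def seedlings(self) -> list[int]:
        return sorted(self.data["seedling_index"].unique().tolist())

    @property
    def structures(self) -> list[str]:
        present = set(self.data["structure"].unique())
        return [s for s in STRUCTURE_ORDER if s in present]

    def event_counts(self) -> dict[str, int]:
        """Tally of rule applications by kind (for run-log reconciliation)."""
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev["rule"]] = out.get(ev["rule"], 0) + 1
        return out

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = self.data.copy()
        df.insert(0, "condition", self.condition)
        df.insert(0, "genotype", self.genotype if self.genotype is not None else "")
        df.to_csv(path, index=False)
        return path


def read_compiled(path: Union[str, Path]) -> CompiledCondition:
    """Read back a compiled long table written by :meth:`CompiledCondition.to_csv`."""
    df = pd.read_csv(path)
    genotype = None
    if "genotype" in df.columns and len(df) and str(df["genotype"].iloc[0]):
        g = df["genotype"].iloc[0]
        genotype = None if pd.isna(g) else str(g)
    condition = str(df["condition"].iloc[0]) if len(df) else "WW"
    body = df[_COMPILED_COLUMNS[:-1] + (["reason"] if "reason" in df.columns else [])].copy()
    if "reason" not in body.columns:
        body["reason"] = ""
    body["reason"] = body["reason"].fillna("")
    return CompiledCondition(genotype=genotype, condition=condition, data=body)


def _records_by_key(table: TracingTable) -> dict[tuple[int, str], object]:
    out: dict[tuple[int, str], object] = {}
    for rec in table.records:
        out[(rec.label.seedling_index, rec.label.structure)] = rec
    return out


def compile_condition(
    day0: TracingTable,
    day1: TracingTable,
    day2: TracingTable,
) -> CompiledCondition:
    """Build the complete status-annotated time course for one condition.

    Missing-record semantics follow the field rules: roots 1–3/shoot missing
    on any day are occluded (photo problem, not biology); late roots missing
    are absent with length 0 unless they were already measured at a nonzero
    length on an earlier day, which is a consistency error.  A seedling with
    no records at all in a day-1 image has every structure occluded that day
    (the photograph, not the plant, is the missing unit).
    """
    tables = {0: day0, 1: day1, 2: day2}
    conditions = set()
    genotypes = set()
    for t in tables.values():
        for rec in t.records:
            conditions.add(rec.meta.condition)
            if rec.meta.genotype:
                genotypes.add(rec.meta.genotype)
    if len(conditions) != 1:
        raise ConsistencyError(
            f"compile_condition needs a single condition, got {sorted(conditions)}"
        )
    condition = conditions.pop()
    if len(genotypes) > 1:
        raise ConsistencyError(f"mixed genotypes in one condition: {sorted(genotypes)}")
    genotype = genotypes.pop() if genotypes else None

    by_day = {d: _records_by_key(t) for d, t in tables.items()}

    # seedling universe + plate mapping (day 0 first, later days fill gaps)
    plate_of: dict[int, Optional[int]] = {}
    for d in (0, 1, 2):
        for rec in tables[d].records:
            plate_of.setdefault(rec.label.seedling_index, rec.meta.plate_index)
    if not plate_of:
        raise ConsistencyError("no records in any day table")
    seedlings = sorted(plate_of)

    day0_seedlings = {rec.label.seedling_index for rec in day0.records}
    unknown = [s for s in seedlings if s not in day0_seedlings]
    if unknown:
        raise ConsistencyError(
            f"seedling indices {unknown} appear after day 0 but never on day 0"
        )

    structures = [s for s in STRUCTURE_ORDER if s != "root6"]
    if any(rec.label.structure == "root6" for t in tables.values() for rec in t.records):
        structures = list(STRUCTURE_ORDER)

    seedlings_present_by_day = {
        d: {rec.label.seedling_index for rec in t.records} for d, t in tables.items()
    }

    rows: list[dict] = []
    events: list[dict] = []

    def log(rule: str, seedling: int, structure: str, day: int) -> None:
        events.append(
            {"rule": rule, "seedling": seedling, "structure": structure, "day": day}
        )

    for s in seedlings:
        for struct in structures:
            measured_nonzero_day: Optional[int] = None
            for d in (0, 1, 2):
                rec = by_day[d].get((s, struct))
                if rec is not None and rec.label.measurable:
                    status, length, reason = STATUS_MEASURED, float(rec.length_mm), ""
                elif rec is not None:  # traced with an _NA label
                    status, length, reason = STATUS_OCCLUDED, np.nan, "na_label"
                    log("occluded_na", s, struct, d)
                elif s not in seedlings_present_by_day[d]:
                    status, length, reason = STATUS_OCCLUDED, np.nan, "seedling_missing"
                    log("occluded_seedling_missing", s, struct, d)
                elif struct in CORE_STRUCTURES:
                    status, length, reason = STATUS_OCCLUDED, np.nan, "missing_record"
                    log("occluded_missing", s, struct, d)
                else:  # late root absent: biological zero
                    if measured_nonzero_day is not None:
                        raise ConsistencyError(
                            f"{struct} of seedling {s} was measured on day "
                            f"{measured_nonzero_day} but has no record on day {d}: "
                            "an emerged root cannot become absent"
                        )
                    status, length, reason = STATUS_ABSENT, 0.0, "not_emerged"
                    log("absent_zero", s, struct, d)
                if (
                    status == STATUS_MEASURED
                    and struct in LATE_ROOTS
                    and length > 0.0
                    and measured_nonzero_day is None
                ):
                    measured_nonzero_day = d
                rows.append(
                    {
                        "plate_index": plate_of[s],
                        "seedling_index": s,
                        "structure": struct,
                        "day": d,
                        "length_mm": length,
                        "status": status,
                        "reason": reason,
                    }
                )

    data = pd.DataFrame(rows, columns=_COMPILED_COLUMNS)

    # real tracings can shrink between days (tracing error); flag, never reject
    wide = data[data["status"] == STATUS_MEASURED].pivot_table(
        index=["seedling_index", "structure"], columns="day", values="length_mm"
    )
    for (s, struct), row in wide.iterrows():
        vals = row.dropna()
        if len(vals) >= 2 and (np.diff(vals.values) < -1e-9).any():
            warnings.warn(
                f"{condition}: measured length of {struct} (seedling {s}) "
                "decreased between days — possible tracing error",
                DataQualityWarning,
                stacklevel=2,
            )
            log("length_decrease", s, struct, -1)

    return CompiledCondition(genotype=genotype, condition=condition, data=data, events=events)


def structure_mean(
    compiled: CompiledCondition, structure: str, day: int
) -> tuple[float, int]:
    """Mean length (mm) and n for one structure on one day.

    Measured and absent rows count (absent as 0); occluded rows count toward
    neither the mean nor n.  With n = 0 the mean is reported as NaN.
    """
    d = compiled.data
    sel = d[
        (d["structure"] == structure)
        & (d["day"] == day)
        & (d["status"].isin([STATUS_MEASURED, STATUS_ABSENT]))
    ]
    n = int(len(sel))
    if n == 0:
        return (float("nan"), 0)
    return (float(sel["length_mm"].mean()), n)


def root6_count(compiled: CompiledCondition) -> int:
    """Number of seedlings that ever show a sixth root.

    Presence means a measured nonzero length or an ``_NA`` tracing (present
    but not measurable) on any day; occlusions caused by a wholly missing
    seedling photograph do not count.
    """
    d = compiled.data
    r6 = d[d["structure"] == "root6"]
    if r6.empty:
        return 0
    present = r6[
        ((r6["status"] == STATUS_MEASURED) & (r6["length_mm"] > 0))
        | ((r6["status"] == STATUS_OCCLUDED) & (r6["reason"] == "na_label"))
    ]
    return int(present["seedling_index"].nunique())


def root6_included(compiled: CompiledCondition, threshold: int = ROOT6_THRESHOLD) -> bool:
    """Whether root 6 enters plots and summaries for this condition.

    True iff strictly more than ``threshold`` seedlings ever show a sixth
    root (see :func:`root6_count`); the decision is applied uniformly to
    plots, summaries and statistics.
    """
    return root6_count(compiled) > threshold


@dataclass
class GrowthSegments:
    """Mean per-interval length change per structure (day0→1 and day1→2)."""

    data: pd.DataFrame  # columns: structure, interval, mean_change_mm, n


def growth_increments(compiled: CompiledCondition) -> GrowthSegments:
    """Mean growth per structure over each 24 h interval.

    Each interval mean uses only seedlings with usable values at both
    endpoints (measured, or absent counted as 0).  Negative increments are
    kept — they flag tracing problems — with a warning.
    """
    d = compiled.data
    usable = d[d["status"].isin([STATUS_MEASURED, STATUS_ABSENT])].copy()
    wide = usable.pivot_table(
        index=["seedling_index", "structure"], columns="day", values="length_mm"
    )
    rows = []
    for struct in compiled.structures:
        try:
            sub = wide.xs(struct, level="structure")
        except KeyError:
            sub = pd.DataFrame()
        for start, end, name in ((0, 1, "day0-1"), (1, 2, "day1-2")):
            if sub.empty or start not in sub.columns or end not in sub.columns:
                rows.append(
                    {"structure": struct, "interval": name, "mean_change_mm": np.nan, "n": 0}
                )
                continue
            pair = sub[[start, end]].dropna()
            n = int(len(pair))
            change = float((pair[end] - pair[start]).mean()) if n else np.nan
            if n and change < -1e-9:
                warnings.warn(
                    f"{compiled.condition}: mean {name} increment of {struct} is "
                    f"negative ({change:.3g} mm) — check tracings",
                    DataQualityWarning,
                    stacklevel=2,
                )
            rows.append(
                {"structure": struct, "interval": name, "mean_change_mm": change, "n": n}
            )
    return GrowthSegments(pd.DataFrame(rows, columns=["structure", "interval", "mean_change_mm", "n"]))


def day_means(compiled: CompiledCondition) -> pd.DataFrame:
    """Per structure × day mean/n table (plot-spec building block)."""
    rows = []
    for struct in compiled.structures:
        for day in (0, 1, 2):
            mean, n = structure_mean(compiled, struct, day)
            rows.append({"structure": struct, "day": day, "mean_mm": mean, "n": n})
    return pd.DataFrame(rows, columns=["structure", "day", "mean_mm", "n"])
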