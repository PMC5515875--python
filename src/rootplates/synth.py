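"""Synthetic soil-plate experiment generator.

Emulates the full wet-lab design so the pipeline can be exercised without
photographs: 2 conditions (WW, WS) × 3 plates × 8 seedlings, photographed
on days 0/1/2 after transplant.  At transplant the coleoptile (shoot) and
roots 1–3 are present, root 1 near 10 mm; roots 4–5 emerge after day 1.
Growth is piecewise linear with a higher early rate for roots 1–3; water
stress multiplies growth rates, hitting the shoot harder than the roots.
Gaussian plate- and seedling-level intercepts plus truncated measurement
noise sit on top.  Day-1 occlusion (a structure hidden from the camera) is
random, with doubled odds for the outward-facing roots of the edge
seedlings, and is emitted per field convention: roots 1–3/shoot are simply
missing from the file, emerged late roots are written with an ``_NA`` label.

Outputs are SmartRoot-style CSV file sets in six folders (``"WW day0"`` …
``"WS day2"``), byte-deterministic for a given seed, plus in-memory tables
for tests; :func:`emit_tracings` additionally produces node-coordinate
polylines with a 16 mm reference strip per plate to exercise the geometry
stage end-to-end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SimParamError
from .geometry import Polyline
from .smartroot_io import (
    CORE_STRUCTURES,
    FileMeta,
    StructureLabel,
    TracingRecord,
    TracingTable,
    parse_structure_label,
)

_ALL_STRUCTURES = ("shoot", "root1", "root2", "root3", "root4", "root5", "root6")


def _default_baseline() -> dict:
    # day-0 (transplant) means, mm; root 1 ≈ 10 mm at the selected stage
    return {"shoot": 9.0, "root1": 10.0, "root2": 8.5, "root3": 7.5}


def _default_rate01() -> dict:
    # mm/day over day 0→1; early rate is the higher one for roots 1–3
    return {"shoot": 7.0, "root1": 15.0, "root2": 13.0, "root3": 12.0,
            "root4": 8.0, "root5": 6.0, "root6": 4.0}


def _default_rate12() -> dict:
    # mm/day over day 1→2
    return {"shoot": 7.0, "root1": 12.0, "root2": 10.5, "root3": 9.5,
            "root4": 8.0, "root5": 6.0, "root6": 4.0}


def _default_emergence() -> dict:
    # days after transplant; later than day 1 for this cultivar
    return {"root4": 1.25, "root5": 1.5, "root6": 1.5}


@dataclass
class SimParams:
    """Growth, noise and occlusion parameters of the simulated experiment.

    Defaults encode the study design: 3 plates × 8 seedlings per condition
    (24 replicates), days 0/1/2 at 24 h spacing, Zak cultivar, water
    potentials −0.02 MPa (WW) vs −0.65 MPa (WS, 20 % PEG) carried as
    metadata only.  ``ws_shoot_mult < ws_root_mult`` reflects the stronger
    inhibition of shoot growth under stress.
    """

    n_plates: int = 3
    seedlings_per_plate: int = 8
    genotype: str = "Zak"
    capture_date: str = "20160413"  # day-0 date; later days advance by 24 h

    baseline_mm: dict = field(default_factory=_default_baseline)
    rate_day01: dict = field(default_factory=_default_rate01)
    rate_day12: dict = field(default_factory=_default_rate12)
    emergence_day: dict = field(default_factory=_default_emergence)

    ws_root_mult: float = 0.6
    ws_shoot_mult: float = 0.4

    root6_prob: float = 0.0
    occlusion_prob: float = 0.05
    edge_occlusion_factor: float = 2.0

    noise_sd: float = 0.5
    plate_sd: float = 0.3
    seedling_sd: float = 0.5

    psi_w_ww_mpa: float = -0.02  # metadata only
    psi_w_ws_mpa: float = -0.65  # metadata only

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_seedlings(self) -> int:
        return self.n_plates * self.seedlings_per_plate

    def validate(self) -> None:
        """Raise :class:`SimParamError` listing every invalid field."""
        bad: list[tuple[str, str]] = []
        if self.n_plates < 1:
            bad.append(("n_plates", "must be >= 1"))
        if self.seedlings_per_plate < 1:
            bad.append(("seedlings_per_plate", "must be >= 1"))
        for name in ("root6_prob", "occlusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append((name, f"probability must be in [0, 1], got {v}"))
        for name in ("ws_root_mult", "ws_shoot_mult"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                bad.append((name, f"multiplier must be in (0, 1], got {v}"))
        for name in ("noise_sd", "plate_sd", "seedling_sd"):
            if getattr(self, name) < 0:
                bad.append((name, "standard deviation must be >= 0"))
        if self.edge_occlusion_factor < 1.0:
            bad.append(("edge_occlusion_factor", "must be >= 1"))
        for table_name in ("rate_day01", "rate_day12"):
            for s, r in getattr(self, table_name).items():
                if r < 0:
                    bad.append((table_name, f"rate for {s} must be >= 0"))
        for s in ("root1", "root2", "root3"):
            if self.rate_day01.get(s, 0.0) < self.rate_day12.get(s, 0.0):
                bad.append(
                    (f"rate_day01[{s}]", "early rate must be >= late rate for roots 1-3")
                )
        for s, e in self.emergence_day.items():
            if e <= 0:
                bad.append((f"emergence_day[{s}]", "must be > 0"))
        if bad:
            raise SimParamError(bad)

    def to_dict(self) -> dict:
        return asdict(self)


def _ws_mult(params: SimParams, structure: str, condition: str) -> float:
    if condition == "WW":
        return 1.0
    return params.ws_shoot_mult if structure == "shoot" else params.ws_root_mult


def expected_length(
    structure: str, condition: str, day: float, params: Optional[SimParams] = None
) -> float:
    """Noise-free mean trajectory of one structure, in mm.

    Piecewise linear: baseline + interval rate × elapsed time, the WS
    multiplier scaling growth (never the transplant baseline).  Late roots
    are 0 until their emergence day, then grow at the rate of the interval
    they are in.
    """
    params = params or SimParams()
    if structure not in _ALL_STRUCTURES:
        raise SimParamError([("structure", f"unknown structure {structure!r}")])
    m = _ws_mult(params, structure, condition)
    r01 = params.rate_day01.get(structure, 0.0) * m
    r12 = params.rate_day12.get(structure, 0.0) * m
    t = float(day)
    if structure in CORE_STRUCTURES:
        base = params.baseline_mm.get(structure, 0.0)
        return base + r01 * min(t, 1.0) + r12 * max(t - 1.0, 0.0)
    e = params.emergence_day.get(structure, 1.5)
    if t <= e:
        return 0.0
    grow01 = max(0.0, min(t, 1.0) - e)  # overlap of (e, t) with day 0→1
    grow12 = max(0.0, t - max(e, 1.0))  # overlap with day 1→2
    return r01 * grow01 + r12 * grow12


# -- truth table --------------------------------------------------------------

def _edge_factor(params: SimParams, position: int, structure: str) -> float:
    """Outward-facing roots of edge seedlings are the likeliest to be obscured."""
    left = position == 1 and structure in ("root2", "root4")
    right = position == params.seedlings_per_plate and structure in ("root3", "root5")
    return params.edge_occlusion_factor if (left or right) else 1.0


def simulate_truth(params: SimParams, seed: int) -> pd.DataFrame:
    """Per-observation ground truth for both conditions.

    Columns: condition, plate, position, seedling, structure, day, emerged,
    occluded (day 1 only), true_mm (pre-noise), obs_mm (measured value).
    Deterministic for a given seed.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for condition in ("WW", "WS"):
        plate_int = rng.normal(0.0, params.plate_sd, size=params.n_plates)
        seed_int = rng.normal(0.0, params.seedling_sd, size=params.n_seedlings)
        has_root6 = rng.random(params.n_seedlings) < params.root6_prob
        for plate in range(1, params.n_plates + 1):
            for pos in range(1, params.seedlings_per_plate + 1):
                s_idx = (plate - 1) * params.seedlings_per_plate + pos
                intercept = plate_int[plate - 1] + seed_int[s_idx - 1]
                structures = [
                    s
                    for s in _ALL_STRUCTURES
                    if s != "root6" or bool(has_root6[s_idx - 1])
                ]
                for structure in structures:
                    occl_roll = rng.random()
                    p_occl = min(
                        1.0,
                        params.occlusion_prob * _edge_factor(params, pos, structure),
                    )
                    occluded_d1 = occl_roll < p_occl
                    noise = rng.normal(0.0, params.noise_sd, size=3)
                    for d in (0, 1, 2):
                        mu = expected_length(structure, condition, d, params)
                        emerged = (
                            structure in CORE_STRUCTURES
                            or d > params.emergence_day.get(structure, 1.5)
                        )
                        true = max(0.0, mu + intercept) if emerged else 0.0
                        obs = max(0.0, true + noise[d]) if emerged else 0.0
                        rows.append(
                            {
                                "condition": condition,
                                "plate": plate,
                                "position": pos,
                                "seedling": s_idx,
                                "structure": structure,
                                "day": d,
                                "emerged": emerged,
                                "occluded": bool(occluded_d1 and d == 1 and emerged),
                                "true_mm": true,
                                "obs_mm": obs,
                            }
                        )
    return pd.DataFrame(rows)


# -- emission: in-memory tables and CSV file sets ------------------------------

def _day_date(params: SimParams, day: int) -> str:
    d0 = datetime.strptime(params.capture_date, "%Y%m%d")
    return (d0 + timedelta(days=day)).strftime("%Y%m%d")


def _filename(params: SimParams, condition: str, plate: int, day: int,
              seedling: Optional[int] = None) -> str:
    stem = f"{_day_date(params, day)} {params.genotype} wt {condition}{plate} day{day}"
    if seedling is not None:
        stem += f" s{seedling}"
    return stem + ".csv"


def _file_rows(truth: pd.DataFrame, params: SimParams) -> dict[tuple, list[tuple[str, float]]]:
    """Group truth into per-file (label, length) rows, applying occlusion rules."""
    files: dict[tuple, list[tuple[str, float]]] = {}
    for row in truth.itertuples(index=False):
        if not row.emerged:
            continue  # absent late root: omitted, compile scores it 0
        day, cond, plate = int(row.day), str(row.condition), int(row.plate)
        if day == 2:
            key = (cond, day, plate, int(row.seedling))
        else:
            key = (cond, day, plate, None)
        label = StructureLabel(
            seedling_index=int(row.seedling),
            kind="shoot" if row.structure == "shoot" else "root",
            root_number=None if row.structure == "shoot" else int(row.structure[-1]),
            measurable=True,
        )
        if row.occluded and day == 1:
            if row.structure in CORE_STRUCTURES:
                continue  # skipped during root calling
            # emerged late root, partly hidden: traced with an _NA label
            label = StructureLabel(
                label.seedling_index, label.kind, label.root_number, measurable=False
            )
        files.setdefault(key, []).append((label.canonical(), float(row.obs_mm)))
    # every plate/seedling image exists even if (pathologically) empty
    for cond in ("WW", "WS"):
        for plate in range(1, params.n_plates + 1):
            for day in (0, 1):
                files.setdefault((cond, day, plate, None), [])
            for pos in range(1, params.seedlings_per_plate + 1):
                s_idx = (plate - 1) * params.seedlings_per_plate + pos
                files.setdefault((cond, 2, plate, s_idx), [])
    return files


def tables_from_truth(truth: pd.DataFrame, params: SimParams) -> dict[str, tuple]:
    """In-memory (day0, day1, day2) :class:`TracingTable` triples per condition."""
    files = _file_rows(truth, params)
    tables: dict[str, dict[int, list[TracingRecord]]] = {
        "WW": {0: [], 1: [], 2: []},
        "WS": {0: [], 1: [], 2: []},
    }
    prov: dict[tuple[str, int], list[str]] = {}
    for (cond, day, plate, seedling), rows in sorted(
        files.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3] or 0)
    ):
        fname = _filename(params, cond, plate, day, seedling)
        meta = FileMeta(
            condition=cond,
            plate_index=plate,
            day=day,
            genotype=params.genotype,
            capture_date=datetime.strptime(_day_date(params, day), "%Y%m%d").date(),
            seedling_image=seedling,
            filename=fname,
        )
        prov.setdefault((cond, day), []).append(fname)
        for text, length in rows:
            tables[cond][day].append(
                TracingRecord(parse_structure_label(text), length, meta)
            )
    out = {}
    for cond in ("WW", "WS"):
        out[cond] = tuple(
            TracingTable(tables[cond][d], provenance=prov.get((cond, d), []))
            for d in (0, 1, 2)
        )
    return out


def simulate_tables(params: Optional[SimParams] = None, seed: int = 0):
    """Simulate and return ({condition: (day0, day1, day2) tables}, truth)."""
    params = params or SimParams()
    truth = simulate_truth(params, seed)
    return tables_from_truth(truth, params), truth


def simulate_experiment(
    params: Optional[SimParams] = None,
    seed: int = 0,
    out_dir: Union[str, Path] = ".",
) -> dict:
    """Write the six-folder SmartRoot-style CSV file sets plus a params manifest.

    Layout: ``<out_dir>/"WW day0"/…`` with one file per plate on days 0/1
    and one per seedling on day 2.  Byte-deterministic for a given seed.
    Returns a manifest dict (also written as ``params.yaml``).
    """
    params = params or SimParams()
    out_dir = Path(out_dir)
    truth = simulate_truth(params, seed)
    files = _file_rows(truth, params)
    written: list[str] = []
    for (cond, day, plate, seedling), rows in sorted(
        files.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3] or 0)
    ):
        folder = out_dir / f"{cond} day{day}"
        folder.mkdir(parents=True, exist_ok=True)
        fname = _filename(params, cond, plate, day, seedling)
        lines = ["root,length"]
        for text, length in rows:
            lines.append(f"{text},{length:.6f}")
        (folder / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(str(Path(f"{cond} day{day}") / fname))
    manifest = {
        "seed": int(seed),
        "params": params.to_dict(),
        "files": written,
        "layout": "six folders: {WW,WS} x {day0,day1,day2}",
    }
    (out_dir / "params.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
    )
    return manifest


# -- traced-polyline emission (exercises the geometry stage) -------------------

def emit_tracings(
    params: Optional[SimParams] = None,
    seed: int = 0,
    condition: str = "WW",
    day: int = 2,
    out: Optional[Union[str, Path]] = None,
) -> Tuple[dict, pd.DataFrame]:
    """Emit node-coordinate polylines consistent with the simulated lengths.

    For every measurable structure of one condition/day a polyline is built
    whose pixel segment sum, scaled by that plate's mm-per-pixel, equals the
    simulated length to 1e-6 mm; each plate also gets a 16 mm reference
    strip polyline.  Returns (polylines keyed by (image, label), lengths
    table).  Zero-length (pre-emergence) structures get no polyline.
    """
    params = params or SimParams()
    truth = simulate_truth(params, seed)
    sub = truth[(truth["condition"] == condition) & (truth["day"] == day)]
    rng = np.random.default_rng(seed + 10_000)
    # per-plate scale near 0.1 mm/px, as if each photo were framed slightly differently
    scales = {
        p: 0.1 * (1.0 + 0.1 * rng.uniform(-1.0, 1.0))
        for p in range(1, params.n_plates + 1)
    }
    polylines: dict[tuple[str, str], Polyline] = {}
    rows = []
    for p, scale in scales.items():
        image = f"{condition} plate{p} day{day}"
        strip_px = 16.0 / scale
        polylines[(image, "strip")] = Polyline(((0.0, 0.0), (strip_px, 0.0)))
        rows.append(
            {"image": image, "label": "strip", "length_mm": 16.0, "mm_per_pixel": scale}
        )
    for row in sub.itertuples(index=False):
        if not row.emerged or row.obs_mm <= 0.0:
            continue
        scale = scales[int(row.plate)]
        image = f"{condition} plate{int(row.plate)} day{day}"
        label = StructureLabel(
            seedling_index=int(row.seedling),
            kind="shoot" if row.structure == "shoot" else "root",
            root_number=None if row.structure == "shoot" else int(row.structure[-1]),
        ).canonical()
        total_px = float(row.obs_mm) / scale
        # 3-4-5 first segment (40 % of length), vertical remainder: exact sum
        u = 0.4 * total_px
        x0 = 5.0 * int(row.seedling)
        nodes = (
            (x0, 0.0),
            (x0 + 0.6 * u, 0.8 * u),
            (x0 + 0.6 * u, 0.8 * u + 0.6 * total_px),
        )
        polylines[(image, label)] = Polyline(nodes)
        rows.append(
            {
                "image": image,
                "label": label,
                "length_mm": float(row.obs_mm),
                "mm_per_pixel": scale,
            }
        )
    lengths = pd.DataFrame(rows, columns=["image", "label", "length_mm", "mm_per_pixel"])
    if out is not None:
        from .geometry import write_polylines

        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_polylines(polylines, out / "nodes.csv")
        lengths.to_csv(out / "lengths.csv", index=False)
    return polylines, lengths
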