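"""Physical lengths from traced polylines via the in-image 16 mm reference strip.

Root tracing yields a polyline of node coordinates per structure (image
convention: y grows downward).  A white plastic strip of known length
(16 mm by default) is photographed in every plate; tracing it once gives the
mm-per-pixel scale for the whole image.  Lengths are segment sums — no
smoothing between nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import RootPlatesError

#: default physical length of the reference strip, millimetres
REFERENCE_STRIP_MM = 16.0


@dataclass(frozen=True)
class Polyline:
    """Ordered node coordinates of one traced structure, in pixels (sub-pixel reals)."""

    nodes: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise RootPlatesError("a polyline needs at least one node")
        arr = np.asarray(self.nodes, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
            raise RootPlatesError("polyline nodes must be finite (x, y) pairs")

    @classmethod
    def from_array(cls, arr: Union[np.ndarray, Sequence[Sequence[float]]]) -> "Polyline":
        a = np.asarray(arr, dtype=float)
        return cls(tuple((float(x), float(y)) for x, y in a))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.nodes, dtype=float)


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale derived from the reference strip."""

    mm_per_pixel: float
    reference_length_mm: float = REFERENCE_STRIP_MM

    def __post_init__(self) -> None:
        if not (self.mm_per_pixel > 0) or not math.isfinite(self.mm_per_pixel):
            raise RootPlatesError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        if not (self.reference_length_mm > 0):
            raise RootPlatesError("reference length must be > 0")


def polyline_pixel_length(p: Polyline) -> float:
    """Sum of Euclidean segment lengths, in pixels; 0.0 for a single node."""
    arr = p.as_array()
    if len(arr) == 1:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(arr, axis=0).T)))


def calibrate(strip: Polyline, known_mm: float = REFERENCE_STRIP_MM) -> Calibration:
    """Derive the mm-per-pixel scale from a traced reference strip.

    Raises :class:`RootPlatesError` on a zero-pixel-length strip.
    """
    px = polyline_pixel_length(strip)
    if px <= 0.0:
        raise RootPlatesError("reference strip has zero pixel length; cannot calibrate")
    if not (known_mm > 0):
        raise RootPlatesError("known strip length must be > 0 mm")
    return Calibration(mm_per_pixel=known_mm / px, reference_length_mm=known_mm)


def measure_mm(p: Polyline, c: Calibration) -> float:
    """Physical length of a polyline: pixel length × mm_per_pixel.

    Measuring the calibration strip under its own calibration returns the
    reference length up to floating round-off.
    """
    return polyline_pixel_length(p) * c.mm_per_pixel


# -- node-coordinate CSV interchange (used by the simulator and tests) --------

_NODE_COLUMNS = ("image", "label", "node_index", "x", "y")


def write_polylines(polylines: Mapping[Tuple[str, str], Polyline], path: Union[str, Path]) -> Path:
    """Write polylines keyed by (image, label) as a long node CSV."""
    rows = []
    for (image, label), poly in polylines.items():
        for i, (x, y) in enumerate(poly.nodes):
            rows.append({"image": image, "label": label, "node_index": i, "x": x, "y": y})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=list(_NODE_COLUMNS)).to_csv(path, index=False)
    return path


def read_polylines(path: Union[str, Path]) -> dict[Tuple[str, str], Polyline]:
    """Read a node CSV back into polylines keyed by (image, label)."""
    df = pd.read_csv(path)
    missing = set(_NODE_COLUMNS) - set(df.columns)
    if missing:
        raise RootPlatesError(f"node CSV missing columns {sorted(missing)}")
    out: dict[Tuple[str, str], Polyline] = {}
    for (image, label), grp in df.groupby(["image", "label"], sort=False):
        grp = grp.sort_values("node_index")
        out[(str(image), str(label))] = Polyline(
            tuple((float(x), float(y)) for x, y in zip(grp["x"], grp["y"]))
        )
    return out
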