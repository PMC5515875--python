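"""Root plots and difference plots: declarative specs, then rendering.

A *root plot* is a stacked bar chart laid out like the seedling itself:
one upward bar for the shoot, downward bars for the roots, each bar stacked
as day-0 baseline + day0→1 growth + day1→2 growth, so the full stack is the
day-2 mean length.  A *difference plot* facets per structure and shows the
WS − WW contrast at each day with its standard error; significant points
(p < alpha) are black, the rest gray.

Specs are pure, hashable data structures built from compiled tables;
rendering is a separate step, so tests can assert geometry without touching
image files.  PDFs are written without a creation timestamp so identical
specs render byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .compile import CompiledCondition, day_means, root6_included
from .errors import PlotSpecError

#: anatomical bar order, root 1 centered, later roots outermost
ANATOMICAL_ORDER = ("root4", "root2", "root1", "root3", "root5", "root6")

SEGMENT_COLORS = {"day0": "#9e9e9e", "day0-1": "#4c72b0", "day1-2": "#55a868"}
POINT_COLORS = {True: "black", False: "#9e9e9e"}


@dataclass(frozen=True)
class RootBar:
    """One structure's stacked segments: baseline and the two growth increments (mm)."""

    structure: str
    baseline: float  # day-0 mean
    inc01: float  # day-1 mean − day-0 mean
    inc12: float  # day-2 mean − day-1 mean
    direction: int  # +1 shoot (upward), −1 root (downward)

    @property
    def total(self) -> float:
        return self.baseline + self.inc01 + self.inc12


@dataclass(frozen=True)
class RootPlotSpec:
    """Declarative root plot: ordered bars for one condition."""

    condition: str
    genotype: Optional[str]
    bars: Tuple[RootBar, ...]

    def __post_init__(self) -> None:
        if not self.bars:
            raise PlotSpecError("root plot spec has no bars")
        ups = [b for b in self.bars if b.direction == +1]
        if len(ups) != 1 or ups[0].structure != "shoot":
            raise PlotSpecError("exactly one upward bar (the shoot) is required")


@dataclass(frozen=True)
class DiffPoint:
    day: int
    estimate: float
    se: float
    significant: bool


@dataclass(frozen=True)
class DiffFacet:
    structure: str
    points: Tuple[DiffPoint, ...]


@dataclass(frozen=True)
class DiffPlotSpec:
    """Declarative difference plot: one facet per structure."""

    facets: Tuple[DiffFacet, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.facets:
            raise PlotSpecError("difference plot spec has no facets")


def build_root_plot_spec(
    compiled: CompiledCondition,
    order: Sequence[str] = ANATOMICAL_ORDER,
    root6_threshold: int = 3,
) -> RootPlotSpec:
    """Build the stacked-bar spec from a compiled condition.

    Segments are differences of per-day structure means, so the stack always
    sums to the day-2 mean.  The sixth root gets a bar only when the
    inclusion rule passes.  Negative increments stay in the spec (the
    renderer marks them) — they are informative, not errors.
    """
    means = day_means(compiled).pivot(index="structure", columns="day", values="mean_mm")
    include6 = root6_included(compiled, root6_threshold)
    bars = []
    layout = [s for s in order if s != "root6" or include6]
    for struct in layout:
        if struct not in means.index or struct not in compiled.structures:
            continue
        m0, m1, m2 = (float(means.loc[struct, d]) for d in (0, 1, 2))
        bars.append(RootBar(struct, m0, m1 - m0, m2 - m1, direction=-1))
    if "shoot" in means.index:
        m0, m1, m2 = (float(means.loc["shoot", d]) for d in (0, 1, 2))
        bars.append(RootBar("shoot", m0, m1 - m0, m2 - m1, direction=+1))
    return RootPlotSpec(condition=compiled.condition, genotype=compiled.genotype, bars=tuple(bars))


def build_difference_plot_spec(diffs, alpha: float = 0.05) -> DiffPlotSpec:
    """Build the faceted difference spec from a difference table.

    ``diffs`` is the DataFrame produced by ``stats.summary_ws_vs_ww`` with
    columns structure, day, estimate_mm, se_mm, p_value, significant.
    """
    if diffs is None or len(diffs) == 0:
        raise PlotSpecError("empty difference table")
    facets = []
    for struct in dict.fromkeys(diffs["structure"]):  # preserve order
        sub = diffs[diffs["structure"] == struct].sort_values("day")
        pts = tuple(
            DiffPoint(
                day=int(r["day"]),
                estimate=float(r["estimate_mm"]),
                se=float(r["se_mm"]),
                significant=bool(r["significant"]),
            )
            for _, r in sub.iterrows()
        )
        facets.append(DiffFacet(structure=struct, points=pts))
    return DiffPlotSpec(facets=tuple(facets), alpha=alpha)


# -- rendering ----------------------------------------------------------------

_PDF_METADATA = {"CreationDate": None}


def _draw_root_plot(ax, spec: RootPlotSpec) -> None:
    xs = np.arange(len(spec.bars))
    width = 0.7
    for x, bar in zip(xs, spec.bars):
        sgn = bar.direction
        bottom = 0.0
        for seg_name, seg in (
            ("day0", bar.baseline),
            ("day0-1", bar.inc01),
            ("day1-2", bar.inc12),
        ):
            height = sgn * seg
            face = SEGMENT_COLORS[seg_name]
            hatch = "///" if seg < 0 else None  # negative increment: marked overlay
            ax.bar(
                x,
                height,
                width,
                bottom=bottom,
                color=face,
                edgecolor="white" if hatch is None else "#c44e52",
                hatch=hatch,
                linewidth=0.5,
            )
            bottom += height
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xticks(xs)
    ax.set_xticklabels([b.structure for b in spec.bars], rotation=45, ha="right")
    ax.set_ylabel("length (mm)  roots ↓ / shoot ↑")
    title = spec.condition if not spec.genotype else f"{spec.genotype} {spec.condition}"
    ax.set_title(title)


def _draw_diff_facets(axes, spec: DiffPlotSpec) -> None:
    for ax, facet in zip(axes, spec.facets):
        days = [p.day for p in facet.points]
        ests = [p.estimate for p in facet.points]
        ses = [p.se for p in facet.points]
        ax.axhline(0.0, color="#cccccc", linewidth=0.8)
        ax.errorbar(days, ests, yerr=ses, fmt="none", ecolor="#777777", capsize=2, linewidth=1)
        for p in facet.points:
            ax.plot(
                [p.day],
                [p.estimate],
                marker="o",
                markersize=5,
                color=POINT_COLORS[p.significant],
                linestyle="none",
            )
        ax.set_title(facet.structure, fontsize=9)
        ax.set_xticks([0, 1, 2])
        ax.set_xlim(-0.4, 2.4)
    if len(spec.facets):
        axes[0].set_ylabel("WS − WW (mm)")


def render(
    spec: Union[RootPlotSpec, DiffPlotSpec],
    path: Union[str, Path],
    format: str = "pdf",
) -> Path:
    """Render one spec to a vector PDF (or PNG) file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(spec, RootPlotSpec):
        fig, ax = plt.subplots(figsize=(5.2, 4.0))
        _draw_root_plot(ax, spec)
    elif isinstance(spec, DiffPlotSpec):
        n = len(spec.facets)
        fig, axes = plt.subplots(1, n, figsize=(1.9 * n, 2.6), sharey=True, squeeze=False)
        _draw_diff_facets(axes[0], spec)
    else:
        raise PlotSpecError(f"cannot render object of type {type(spec).__name__}")
    fig.tight_layout()
    metadata = _PDF_METADATA if format == "pdf" else None
    fig.savefig(path, format=format, metadata=metadata)
    plt.close(fig)
    return path


def render_report(
    ww_spec: RootPlotSpec,
    ws_spec: RootPlotSpec,
    diff_spec: DiffPlotSpec,
    path: Union[str, Path],
    format: str = "pdf",
) -> Path:
    """Single labeled multi-panel page: (A) WW root plot, (B) WS root plot, (C) difference plot."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_facets = len(diff_spec.facets)
    fig = plt.figure(figsize=(10.0, 7.6))
    gs = fig.add_gridspec(2, 2, height_ratios=[1.4, 1.0], hspace=0.55, wspace=0.3)
    ax_a = fig.add_subplot(gs[0, 0])
    ax_b = fig.add_subplot(gs[0, 1])
    _draw_root_plot(ax_a, ww_spec)
    _draw_root_plot(ax_b, ws_spec)
    sub = gs[1, :].subgridspec(1, n_facets, wspace=0.15)
    diff_axes = [fig.add_subplot(sub[0, i]) for i in range(n_facets)]
    for ax in diff_axes[1:]:
        ax.sharey(diff_axes[0])
    _draw_diff_facets(diff_axes, diff_spec)
    for ax, letter in ((ax_a, "A"), (ax_b, "B"), (diff_axes[0], "C")):
        ax.annotate(
            letter,
            xy=(0, 1),
            xycoords="axes fraction",
            xytext=(-28, 12),
            textcoords="offset points",
            fontsize=14,
            fontweight="bold",
        )
    metadata = _PDF_METADATA if format == "pdf" else None
    fig.savefig(path, format=format, metadata=metadata)
    plt.close(fig)
    return path
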