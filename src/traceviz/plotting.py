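"""Rendering of trace data: line plots, small multiples and heatmaps.

All figures are built with matplotlib and are testable by introspection:
data polylines carry ``gid="trace"``, mean lines ``gid="mean"``, CI
ribbons ``gid="ci"``, annotation marks ``gid="annot_bar"`` /
``"annot_box"`` / ``"annot_text"`` and direct labels ``gid="direct_label"``.

The heatmap (lasagna plot) draws one row per object, time along x and
value as false color on a single shared viridis scale, so responses of
hundreds of objects can be compared at a glance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Rectangle
from matplotlib.transforms import blended_transform_factory

from .dataio import TraceSet
from .palettes import (
    DEFAULT_PALETTE,
    HEATMAP_CMAP,
    Palette,
    assign_colors,
    builtin_palette,
    resolve_color,
)
from .summarize import SummaryCurve

__all__ = [
    "PlotSpec",
    "AnnotationTrack",
    "Interval",
    "sort_objects",
    "render_lines",
    "render_small_multiples",
    "render_heatmap",
    "render_annotations",
    "place_direct_labels",
    "save_figure",
]

SORT_CRITERIA = ("original", "alphabetical", "max", "integrated")
MODES = ("lines", "small_multiples", "heatmap")

#: raster resolution; pixel sizes in PlotSpec are exact multiples of this
DPI = 100


@dataclass
class PlotSpec:
    """User-facing display settings for one figure."""

    mode: str = "lines"
    show_data: bool = True
    show_mean: bool = False
    show_ci: bool = False
    data_alpha: float = 1.0
    stat_alpha: float = 0.3
    data_linewidth: float = 1.0
    stat_linewidth: float = 2.5
    palette: Palette | list[str] | None = dc_field(
        default_factory=lambda: builtin_palette(DEFAULT_PALETTE)
    )
    direct_labels: bool = False
    sort: str = "original"
    x_label: str = "Time"
    y_label: str = "Value"
    width: int = 800
    height: int = 600
    grid: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose one of {MODES}")
        if self.sort not in SORT_CRITERIA:
            raise ValueError(
                f"unknown sort criterion {self.sort!r}; choose one of {SORT_CRITERIA}"
            )
        for name in ("data_alpha", "stat_alpha"):
            a = getattr(self, name)
            if not 0 <= a <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.mode == "lines" and not (
            self.show_data or self.show_mean or self.show_ci
        ):
            raise ValueError(
                "lines mode needs at least one of show_data/show_mean/show_ci"
            )

    def figsize(self) -> tuple[float, float]:
        return self.width / DPI, self.height / DPI


@dataclass(frozen=True)
class Interval:
    t_start: float
    t_end: float
    label: str = ""
    color: str = "#808080"

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError("interval must satisfy t_start <= t_end")


@dataclass
class AnnotationTrack:
    """Labeled treatment/perturbation windows drawn with the plot.

    ``style``: ``bar`` (strip above the plot), ``box`` (translucent
    rectangle spanning the y-range) or ``bar_and_box``.
    """

    style: str = "bar"
    intervals: list[Interval] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.style not in ("bar", "box", "bar_and_box"):
            raise ValueError(f"unknown annotation style {self.style!r}")


# ---------------------------------------------------------------------------
# ordering


def _object_stats(ts: TraceSet) -> pd.DataFrame:
    return ts.data.sort_values("time").groupby("object_id", sort=False)


def sort_objects(ts: TraceSet, criterion: str = "original") -> list[str]:
    """Order object ids by the chosen criterion.

    ``max``: descending per-object maximum; ``integrated``: descending
    trapezoidal area under the trace; ``alphabetical``: ascending;
    ``original``: order of first appearance.  Ties break lexicographically.
    """
    if criterion not in SORT_CRITERIA:
        raise ValueError(f"unknown sort criterion {criterion!r}")
    objects = ts.objects()
    if criterion == "original":
        return objects
    if criterion == "alphabetical":
        return sorted(objects)

    scores: dict[str, float] = {}
    for obj in objects:
        g = ts.data[ts.data["object_id"] == obj].sort_values("time")
        g = g.dropna(subset=["value"])
        if g.empty:
            scores[obj] = -math.inf
        elif criterion == "max":
            scores[obj] = float(g["value"].max())
        else:  # integrated
            scores[obj] = float(
                np.trapezoid(g["value"].to_numpy(), g["time"].to_numpy())
            )
    return sorted(objects, key=lambda o: (-scores[o], o))


# ---------------------------------------------------------------------------
# color assignment


def _colors_for(ids: list[str], spec: PlotSpec, fallback: str = "#404040") -> dict[str, str]:
    pal = spec.palette
    if pal is None:
        return {i: fallback for i in ids}
    if isinstance(pal, Palette):
        cols = assign_colors(len(ids), pal)
    else:
        cols = [pal[i % len(pal)] for i in range(len(ids))]
    return dict(zip(ids, cols))


# ---------------------------------------------------------------------------
# direct labels


def place_direct_labels(
    last_points: list[tuple[str, float]],
    bounds: tuple[float, float],
    label_height: float,
) -> list[tuple[str, float]]:
    """Resolve vertical overlaps between right-margin labels.

    Labels want to sit at their trace's final y.  Any two closer than one
    label height are displaced (later input entries pushed down, the whole
    run shifted back inside ``bounds`` if needed) until all pairwise gaps
    are at least ``label_height``.  For coincident desired positions the
    input order is preserved top-to-bottom.  Returns (id, y) in input order.
    """
    if not last_points:
        raise ValueError("at least one label is required")
    lo, hi = bounds
    n = len(last_points)
    desired = [float(y) for _, y in last_points]
    # stable sort: ties keep input order, which then reads top-to-bottom
    order = sorted(range(n), key=lambda i: -desired[i])
    placed = [0.0] * n
    prev = math.inf
    for i in order:
        y = min(desired[i], prev - label_height)
        placed[i] = y
        prev = y
    # push the chain back inside the bounds
    low = min(placed)
    if low < lo:
        shift = lo - low
        for i in range(n):
            placed[i] += shift
    top = max(placed)
    if top > hi:
        prev = hi + label_height
        for i in order:
            y = min(placed[i], prev - label_height)
            placed[i] = y
            prev = y
    return [(last_points[i][0], placed[i]) for i in range(n)]


def _draw_direct_labels(ax, entries: list[tuple[str, float, str]]) -> None:
    """entries: (text, desired y, color)."""
    if not entries:
        return
    ylo, yhi = ax.get_ylim()
    label_h = 0.05 * (yhi - ylo)
    placed = place_direct_labels([(t, y) for t, y, _ in entries], (ylo, yhi), label_h)
    colors = {t: c for t, _, c in entries}
    xlo, xhi = ax.get_xlim()
    x = xhi + 0.01 * (xhi - xlo)
    for text, y in placed:
        ax.text(
            x,
            y,
            text,
            color=colors[text],
            fontsize=9,
            va="center",
            ha="left",
            clip_on=False,
            gid="direct_label",
        )


# ---------------------------------------------------------------------------
# annotations


def render_annotations(track: AnnotationTrack | None, ax) -> list:
    """Draw treatment windows on an axes; returns the created artists."""
    if track is None or not track.intervals:
        return []
    artists: list = []
    xlo, xhi = ax.get_xlim()
    trans = blended_transform_factory(ax.transData, ax.transAxes)
    for iv in track.intervals:
        t0, t1 = iv.t_start, iv.t_end
        if t1 < xlo or t0 > xhi:
            warnings.warn(
                f"annotation interval ({iv.t_start}, {iv.t_end}) lies outside "
                "the plotted time range and was skipped",
                stacklevel=2,
            )
            continue
        if t0 < xlo or t1 > xhi:
            warnings.warn(
                f"annotation interval ({iv.t_start}, {iv.t_end}) clipped to "
                "the plotted time range",
                stacklevel=2,
            )
            t0, t1 = max(t0, xlo), min(t1, xhi)
        try:
            color = resolve_color(iv.color)
        except ValueError:
            warnings.warn(f"unknown annotation color {iv.color!r}; using grey")
            color = "#808080"
        if track.style in ("bar", "bar_and_box"):
            rect = Rectangle(
                (t0, 1.02),
                t1 - t0,
                0.04,
                transform=trans,
                facecolor=color,
                edgecolor="none",
                clip_on=False,
                gid="annot_bar",
            )
            ax.add_patch(rect)
            artists.append(rect)
            if iv.label:
                txt = ax.text(
                    (t0 + t1) / 2,
                    1.075,
                    iv.label,
                    transform=trans,
                    ha="center",
                    va="bottom",
                    fontsize=9,
                    clip_on=False,
                    gid="annot_text",
                )
                artists.append(txt)
        if track.style in ("box", "bar_and_box"):
            box = ax.axvspan(
                t0, t1, facecolor=color, alpha=0.2, edgecolor="none", gid="annot_box"
            )
            artists.append(box)
            if iv.label and track.style == "box":
                txt = ax.text(
                    (t0 + t1) / 2,
                    0.97,
                    iv.label,
                    transform=trans,
                    ha="center",
                    va="top",
                    fontsize=9,
                    gid="annot_text",
                )
                artists.append(txt)
    return artists


# ---------------------------------------------------------------------------
# renderers


def _finish_axes(ax, spec: PlotSpec) -> None:
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    if spec.grid:
        ax.grid(True, alpha=0.3)
    else:
        ax.grid(False)


def render_lines(
    ts: TraceSet,
    summaries: list[SummaryCurve] | None = None,
    spec: PlotSpec | None = None,
    annotations: AnnotationTrack | None = None,
):
    """Line plot: one polyline per object, optional mean/CI per condition."""
    if len(ts) == 0:
        raise ValueError("cannot render an empty TraceSet")
    spec = spec or PlotSpec()
    fig, ax = plt.subplots(figsize=spec.figsize(), dpi=DPI)

    order = sort_objects(ts, spec.sort)
    obj_colors = _colors_for(order, spec)
    conditions = ts.conditions()
    cond_colors = _colors_for(conditions, spec, fallback="#000000")

    if spec.show_data:
        for obj in order:
            g = ts.data[ts.data["object_id"] == obj].sort_values("time")
            ax.plot(
                g["time"],
                g["value"],
                color=obj_colors[obj],
                alpha=spec.data_alpha,
                linewidth=spec.data_linewidth,
                gid="trace",
            )

    if summaries is None and (spec.show_mean or spec.show_ci):
        from .summarize import summarize

        summaries = summarize(ts)

    if summaries is not None and (spec.show_mean or spec.show_ci):
        for curve in summaries:
            col = cond_colors.get(curve.condition_id, "#000000")
            pts = curve.points
            if spec.show_mean:
                ax.plot(
                    pts["time"],
                    pts["mean"],
                    color=col,
                    linewidth=spec.stat_linewidth,
                    gid="mean",
                )
            if spec.show_ci:
                ok = pts["ci_lo"].notna() & pts["ci_hi"].notna()
                if ok.any():
                    p = pts[ok]
                    ax.fill_between(
                        p["time"],
                        p["ci_lo"],
                        p["ci_hi"],
                        color=col,
                        alpha=spec.stat_alpha,
                        gid="ci",
                    )
                else:
                    warnings.warn(
                        f"condition {curve.condition_id!r}: CI undefined "
                        "everywhere (single object); no ribbon drawn",
                        stacklevel=2,
                    )

    _finish_axes(ax, spec)
    ax.autoscale_view()
    render_annotations(annotations, ax)

    if spec.direct_labels:
        entries: list[tuple[str, float, str]] = []
        if spec.show_mean or spec.show_ci:
            for curve in summaries or []:
                pts = curve.points
                if len(pts):
                    last = pts.iloc[-1]
                    entries.append(
                        (
                            curve.condition_id,
                            float(last["mean"]),
                            cond_colors.get(curve.condition_id, "#000000"),
                        )
                    )
        else:
            for obj in order:
                g = ts.data[ts.data["object_id"] == obj].dropna(subset=["value"])
                if len(g):
                    last = g.sort_values("time").iloc[-1]
                    entries.append((obj, float(last["value"]), obj_colors[obj]))
        _draw_direct_labels(ax, entries)
        fig.subplots_adjust(right=0.85)

    return fig


def small_multiples_grid(m: int) -> tuple[int, int]:
    """(rows, cols) for m panels: ceil(sqrt(m)) columns, approximately square."""
    cols = math.ceil(math.sqrt(m))
    rows = math.ceil(m / cols)
    return rows, cols


def render_small_multiples(
    ts: TraceSet,
    spec: PlotSpec | None = None,
    annotations: AnnotationTrack | None = None,
):
    """One panel per object with shared x/y limits, titled by object id."""
    if len(ts) == 0:
        raise ValueError("cannot render an empty TraceSet")
    spec = spec or PlotSpec(mode="small_multiples")
    order = sort_objects(ts, spec.sort)
    m = len(order)
    rows, cols = small_multiples_grid(m)
    fig, axes = plt.subplots(
        rows,
        cols,
        figsize=spec.figsize(),
        dpi=DPI,
        sharex=True,
        sharey=True,
        squeeze=False,
    )
    flat = axes.ravel()
    obj_colors = _colors_for(order, spec)
    for ax, obj in zip(flat, order):
        g = ts.data[ts.data["object_id"] == obj].sort_values("time")
        ax.plot(
            g["time"],
            g["value"],
            color=obj_colors[obj],
            alpha=spec.data_alpha,
            linewidth=spec.data_linewidth,
            gid="trace",
        )
        ax.set_title(obj, fontsize=8)
        if not spec.grid:
            ax.grid(False)
        if annotations is not None:
            render_annotations(annotations, ax)
    for ax in flat[m:]:
        fig.delaxes(ax)
    fig.supxlabel(spec.x_label)
    fig.supylabel(spec.y_label)
    return fig


def render_heatmap(
    ts: TraceSet,
    spec: PlotSpec | None = None,
    annotations: AnnotationTrack | None = None,
):
    """Lasagna plot: rows = objects (sorted), columns = times, viridis scale.

    A single color scale is shared across all objects so rows are directly
    comparable; missing cells render as gaps.
    """
    if len(ts) == 0:
        raise ValueError("cannot render an empty TraceSet")
    spec = spec or PlotSpec(mode="heatmap")
    order = sort_objects(ts, spec.sort)
    wide = ts.data.pivot_table(
        index="object_id", columns="time", values="value", aggfunc="first",
        dropna=False,
    )
    wide = wide.reindex(order)
    times = wide.columns.to_numpy(dtype=float)
    mat = np.ma.masked_invalid(wide.to_numpy(dtype=float))

    fig, ax = plt.subplots(figsize=spec.figsize(), dpi=DPI)
    m, T = mat.shape
    # row 0 (first in sort order) at the top
    im = ax.imshow(
        mat,
        aspect="auto",
        interpolation="nearest",
        cmap=HEATMAP_CMAP,
        origin="upper",
        extent=(times.min(), times.max(), m - 0.5, -0.5),
        gid="heatmap",
    )
    ax.set_yticks(np.arange(m))
    ax.set_yticklabels(order, fontsize=7)
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel("Object")
    fig.colorbar(im, ax=ax, label=spec.y_label)
    render_annotations(annotations, ax)
    return fig


def save_figure(fig, path, format: str | None = None) -> None:
    """Write a figure as PNG (pixel-exact size), PDF or SVG."""
    if format is None:
        format = str(path).rsplit(".", 1)[-1].lower()
    if format not in ("png", "pdf", "svg"):
        raise ValueError(f"unsupported format {format!r}; use png, pdf or svg")
    fig.savefig(path, format=format, dpi=fig.dpi)
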