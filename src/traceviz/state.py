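"""Serialization of plot settings to/from a URL query-string scheme.

A complete set of user-facing settings can be "cloned" into a compact
query string and later restored, so a figure is reproducible from its
URL alone.  The string groups settings as ``group=f1;f2;...`` joined by
``&``; groups are ``data``, ``vis``, ``layout``, ``color``, ``label``
and ``stim``; fields are positional, may themselves be comma-separated
lists, and spaces travel percent-encoded.

Positional schema (positions are 0-based; unmapped positions are carried
opaquely so encode(decode(q)) is lossless):

* ``data``:   [3] normalization method, [4] baseline window "t_lo,t_hi"
* ``vis``:    [0] display mode, [1] data alpha, [2] show mean flag,
              [3] show CI flag, [4] stat alpha
* ``layout``: [1] hide-grid flag, [9] width px, [10] height px
* ``color``:  [0] palette name, "none", or user color list
* ``label``:  [3] x-axis title, [4] y-axis title
* ``stim``:   [0] enabled flag, [1] style, [2] interval boundaries
              (flat, paired in order), [3] labels, [4] colors

Booleans encode as ``TRUE`` (or ``T``); an empty field means false.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field as dc_field
from urllib.parse import unquote

from .normalize import METHODS, NormalizationSpec
from .plotting import AnnotationTrack, Interval, PlotSpec

__all__ = [
    "StateDescriptor",
    "decode_state",
    "encode_state",
    "stim_from_state",
    "apply_state",
    "GROUP_ORDER",
]

GROUP_ORDER = ("data", "vis", "layout", "color", "label", "stim")

_BAD_ESCAPE = re.compile(r"%(?![0-9A-Fa-f]{2})")

DEFAULT_ANNOTATION_COLOR = "#808080"


@dataclass
class StateDescriptor:
    """Grouped positional plot state; values are lists of text fields."""

    groups: dict[str, list[str]] = dc_field(default_factory=dict)

    def field(self, group: str, pos: int, default: str = "") -> str:
        fields = self.groups.get(group, [])
        return fields[pos] if pos < len(fields) else default


def _truthy(tok: str) -> bool:
    return tok.strip().upper() in ("TRUE", "T")


def decode_state(query: str) -> StateDescriptor:
    """Parse a query string (the part after "?") into a StateDescriptor.

    A leading "?" and a trailing "&.", "&" or "." (sentence punctuation in
    printed URLs) are tolerated.  Unknown group names are preserved with a
    warning; empty fields keep their positions.
    """
    q = query.strip()
    if "?" in q and "://" in q:
        q = q.split("?", 1)[1]
    q = q.lstrip("?")
    if q.endswith("&."):
        q = q[:-2]
    elif q.endswith(("&", ".")):
        q = q[:-1]
    if q == "":
        return StateDescriptor()
    m = _BAD_ESCAPE.search(q)
    if m:
        raise ValueError(f"malformed percent-escape at offset {m.start()}")
    groups: dict[str, list[str]] = {}
    for part in q.split("&"):
        if part == "":
            continue
        if "=" not in part:
            raise ValueError(f"malformed group (missing '='): {part!r}")
        name, _, rest = part.partition("=")
        if name not in GROUP_ORDER:
            warnings.warn(f"unknown state group {name!r} preserved verbatim")
        groups[name] = [unquote(f) for f in rest.split(";")]
    return StateDescriptor(groups)


def _quote(field: str) -> str:
    return field.replace("%", "%25").replace(" ", "%20")


def encode_state(s: StateDescriptor) -> str:
    """Canonical query string: fixed group order, ';'-joined fields."""
    names = [g for g in GROUP_ORDER if g in s.groups]
    names += [g for g in s.groups if g not in GROUP_ORDER]
    return "&".join(
        f"{name}=" + ";".join(_quote(f) for f in s.groups[name]) for name in names
    )


def stim_from_state(s: StateDescriptor) -> AnnotationTrack:
    """Build the treatment-annotation track from the ``stim`` group.

    Boundaries are paired in order into intervals; the i-th label/color
    attaches to the i-th interval (missing labels -> empty, missing colors
    -> grey).  An unpaired trailing boundary is dropped with a warning.
    A disabled group (first field not TRUE) yields an empty track.
    """
    fields = s.groups.get("stim", [])
    if len(fields) < 3:
        raise ValueError("stim group needs at least enabled, style and boundaries")
    style = fields[1].strip().lower() or "bar"
    if style not in ("bar", "box", "bar_and_box"):
        warnings.warn(f"unknown stim style {fields[1]!r}; using 'bar'")
        style = "bar"
    if not _truthy(fields[0]):
        return AnnotationTrack(style=style, intervals=[])
    tokens = [t for t in fields[2].split(",") if t.strip() != ""]
    try:
        bounds = [float(t) for t in tokens]
    except ValueError as e:
        raise ValueError(f"non-numeric stim boundary in {fields[2]!r}") from e
    if len(bounds) % 2 == 1:
        warnings.warn(
            f"odd number of stim boundaries ({len(bounds)}); dropping the "
            f"trailing value {bounds[-1]}"
        )
        bounds = bounds[:-1]
    labels = fields[3].split(",") if len(fields) > 3 and fields[3] != "" else []
    colors = fields[4].split(",") if len(fields) > 4 and fields[4] != "" else []
    intervals = []
    for i in range(len(bounds) // 2):
        intervals.append(
            Interval(
                t_start=bounds[2 * i],
                t_end=bounds[2 * i + 1],
                label=labels[i].strip() if i < len(labels) else "",
                color=colors[i].strip() if i < len(colors) else DEFAULT_ANNOTATION_COLOR,
            )
        )
    return AnnotationTrack(style=style, intervals=intervals)


def _float_or(tok: str, default: float) -> float:
    try:
        return float(tok)
    except (TypeError, ValueError):
        return default


def apply_state(s: StateDescriptor) -> tuple[NormalizationSpec, PlotSpec, AnnotationTrack]:
    """Map a descriptor's documented positions onto concrete settings.

    Unknown enum tokens in mapped positions warn and fall back to the
    default; unmapped positions are simply left in the descriptor, so the
    encode/decode round-trip is unaffected by applying the state.
    """
    # -- normalization -------------------------------------------------
    method = s.field("data", 3).strip() or "none"
    if method not in METHODS:
        warnings.warn(f"unknown normalization method {method!r}; using 'none'")
        method = "none"
    window = None
    win_tok = s.field("data", 4).strip()
    if win_tok:
        parts = win_tok.split(",")
        if len(parts) == 2:
            try:
                window = (float(parts[0]), float(parts[1]))
            except ValueError:
                warnings.warn(f"bad baseline window {win_tok!r}; ignored")
    if method in ("fold", "delta_fold") and window is None:
        warnings.warn(f"method {method!r} without baseline window; using 'none'")
        method = "none"
    norm = NormalizationSpec(method=method, baseline_window=window)

    # -- display -------------------------------------------------------
    mode_tok = s.field("vis", 0).strip().lower()
    mode_map = {
        "": "lines",
        "dataasline": "lines",
        "lines": "lines",
        "dataassmallmultiples": "small_multiples",
        "small_multiples": "small_multiples",
        "dataasheatmap": "heatmap",
        "heatmap": "heatmap",
    }
    if mode_tok in mode_map:
        mode = mode_map[mode_tok]
    else:
        warnings.warn(f"unknown display mode {mode_tok!r}; using 'lines'")
        mode = "lines"
    data_alpha = min(1.0, max(0.0, _float_or(s.field("vis", 1), 1.0)))
    show_mean = _truthy(s.field("vis", 2))
    show_ci = _truthy(s.field("vis", 3))
    stat_alpha = min(1.0, max(0.0, _float_or(s.field("vis", 4), 0.3)))
    show_data = data_alpha > 0

    width = int(_float_or(s.field("layout", 9), 800))
    height = int(_float_or(s.field("layout", 10), 600))
    grid = not _truthy(s.field("layout", 1))

    x_label = s.field("label", 3).strip() or "Time"
    y_label = s.field("label", 4).strip() or "Value"

    from .palettes import PALETTES, builtin_palette, parse_user_colors

    color_tok = s.field("color", 0).strip()
    palette: object
    if color_tok in ("", "none"):
        palette = None
    elif color_tok.lower() in PALETTES:
        palette = builtin_palette(color_tok.lower())
    else:
        try:
            palette = parse_user_colors(color_tok)
        except ValueError:
            warnings.warn(f"unresolvable color setting {color_tok!r}; using default")
            palette = builtin_palette("okabe_ito")

    if mode == "lines" and not (show_data or show_mean or show_ci):
        show_data = True  # never an empty lines plot

    plot = PlotSpec(
        mode=mode,
        show_data=show_data,
        show_mean=show_mean,
        show_ci=show_ci,
        data_alpha=data_alpha if data_alpha > 0 else 1.0,
        stat_alpha=stat_alpha,
        palette=palette,
        x_label=x_label,
        y_label=y_label,
        width=width,
        height=height,
        grid=grid,
    )

    # -- annotations ---------------------------------------------------
    if "stim" in s.groups and len(s.groups["stim"]) >= 3:
        track = stim_from_state(s)
    else:
        track = AnnotationTrack(style="bar", intervals=[])
    return norm, plot, track
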