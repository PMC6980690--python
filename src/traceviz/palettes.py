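"""Colorblind-safe qualitative palettes and user color parsing.

The qualitative palettes are the Okabe & Ito palette (the default) and
three of Paul Tol's schemes, each 7-10 colors designed to remain
distinguishable under common color-vision deficiencies.  When more
objects than colors are drawn, the scheme is recycled.

Heatmaps use the perceptually uniform viridis sequential map; the
qualitative palettes are refused there.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from matplotlib import colors as mcolors

__all__ = [
    "Palette",
    "builtin_palette",
    "assign_colors",
    "parse_user_colors",
    "PALETTES",
    "HEATMAP_CMAP",
]

#: the sequential colormap used for heatmap-style displays
HEATMAP_CMAP = "viridis"

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


@dataclass(frozen=True)
class Palette:
    name: str
    colors: tuple[str, ...]

    def __post_init__(self) -> None:
        for c in self.colors:
            if not _HEX_RE.match(c):
                raise ValueError(f"invalid hex color {c!r} in palette {self.name!r}")

    def __len__(self) -> int:
        return len(self.colors)


PALETTES: dict[str, Palette] = {
    # Okabe & Ito (2008), 8 colors, the default
    "okabe_ito": Palette(
        "okabe_ito",
        (
            "#000000",
            "#E69F00",
            "#56B4E9",
            "#009E73",
            "#F0E442",
            "#0072B2",
            "#D55E00",
            "#CC79A7",
        ),
    ),
    # Paul Tol's bright qualitative scheme, 7 colors
    "tol_bright": Palette(
        "tol_bright",
        (
            "#4477AA",
            "#EE6677",
            "#228833",
            "#CCBB44",
            "#66CCEE",
            "#AA3377",
            "#BBBBBB",
        ),
    ),
    # Paul Tol's muted qualitative scheme, 10 colors
    "tol_muted": Palette(
        "tol_muted",
        (
            "#332288",
            "#88CCEE",
            "#44AA99",
            "#117733",
            "#999933",
            "#DDCC77",
            "#CC6677",
            "#882255",
            "#AA4499",
            "#DDDDDD",
        ),
    ),
    # Paul Tol's light qualitative scheme, 9 colors
    "tol_light": Palette(
        "tol_light",
        (
            "#77AADD",
            "#99DDFF",
            "#44BB99",
            "#BBCC33",
            "#AAAA00",
            "#EEDD88",
            "#EE8866",
            "#FFAABB",
            "#DDDDDD",
        ),
    ),
}

DEFAULT_PALETTE = "okabe_ito"

# R/X11 numbered color variants absent from the CSS table (values from the
# X11 rgb.txt used by R's colors()); greyN/grayN are handled programmatically.
_R_COMPAT: dict[str, str] = {
    "turquoise1": "#00F5FF",
    "turquoise2": "#00E5EE",
    "turquoise3": "#00C5CD",
    "turquoise4": "#00868B",
    "red1": "#FF0000",
    "red2": "#EE0000",
    "red3": "#CD0000",
    "red4": "#8B0000",
    "blue1": "#0000FF",
    "blue2": "#0000EE",
    "blue3": "#0000CD",
    "blue4": "#00008B",
    "green1": "#00FF00",
    "green2": "#00EE00",
    "green3": "#00CD00",
    "green4": "#008B00",
    "orange1": "#FFA500",
    "orange2": "#EE9A00",
    "orange3": "#CD8500",
    "orange4": "#8B5A00",
    "purple1": "#9B30FF",
    "purple2": "#912CEE",
    "purple3": "#7D26CD",
    "purple4": "#551A8B",
    "magenta1": "#FF00FF",
    "magenta2": "#EE00EE",
    "magenta3": "#CD00CD",
    "magenta4": "#8B008B",
    "yellow1": "#FFFF00",
    "yellow2": "#EEEE00",
    "yellow3": "#CDCD00",
    "yellow4": "#8B8B00",
    "cyan1": "#00FFFF",
    "cyan2": "#00EEEE",
    "cyan3": "#00CDCD",
    "cyan4": "#008B8B",
    "firebrick1": "#FF3030",
    "firebrick2": "#EE2C2C",
    "firebrick3": "#CD2626",
    "firebrick4": "#8B1A1A",
    "steelblue1": "#63B8FF",
    "steelblue2": "#5CACEE",
    "steelblue3": "#4F94CD",
    "steelblue4": "#36648B",
    "springgreen1": "#00FF7F",
    "springgreen2": "#00EE76",
    "springgreen3": "#00CD66",
    "springgreen4": "#008B45",
}

_GREY_RE = re.compile(r"^(grey|gray)(\d{1,3})$")


def builtin_palette(name: str) -> Palette:
    """Look up a registered qualitative palette by name."""
    try:
        return PALETTES[name]
    except KeyError:
        raise ValueError(
            f"unknown palette {name!r}; available: {sorted(PALETTES)}"
        ) from None


def assign_colors(n: int, palette: Palette) -> list[str]:
    """Colors for ``n`` objects; the palette is recycled when n exceeds it."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if len(palette.colors) == 0:
        raise ValueError("palette has no colors")
    return [palette.colors[i % len(palette.colors)] for i in range(n)]


def resolve_color(token: str) -> str:
    """Resolve one color token (name or ``#RRGGBB``) to uppercase hex."""
    tok = token.strip()
    if not tok:
        raise ValueError("empty color token")
    if tok.startswith("#"):
        if not _HEX_RE.match(tok):
            raise ValueError(f"invalid hex color code {tok!r}")
        return tok.upper()
    low = tok.lower()
    if low in _R_COMPAT:
        return _R_COMPAT[low]
    m = _GREY_RE.match(low)
    if m:
        level = int(m.group(2))
        if level <= 100:
            v = round(level * 255 / 100)
            return f"#{v:02X}{v:02X}{v:02X}"
    named = mcolors.get_named_colors_mapping()
    if low in named:
        return mcolors.to_hex(named[low]).upper()
    raise ValueError(f"unknown color name {token.strip()!r}")


def parse_user_colors(spec: str) -> list[str]:
    """Parse a comma-separated list of color names / hex codes.

    Names are case-insensitive (CSS/X11 extended table plus an R-name
    compatibility table); hex codes are validated and uppercased.
    """
    tokens = [t for t in (s.strip() for s in spec.split(",")) if t != ""]
    return [resolve_color(t) for t in tokens]
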