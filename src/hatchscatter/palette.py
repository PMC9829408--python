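"""CVD-friendly default colors and the group -> (color, pattern) assignment.

The default palette embeds 40 high-contrast colorblind-friendly hex values
(an Okabe-Ito-derived family: 8 base hues plus progressively darker and
lighter variants).  Redundant coding assigns every group a (fill color,
hatch pattern) pair; with the 40 default colors and 7 default patterns the
assignment stays injective for up to 280 groups.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CapacityError, ParameterError
from .patterns import (
    HatchSpec,
    PatternSpec,
    StyleDefaults,
    default_patterns,
    resolve_pattern,
)

__all__ = ["default_palette", "assign_aesthetics", "AestheticMap", "load_palette"]

# 8 colorblind-safe base hues followed by darker/lighter variants (40 total)
_DEFAULT_40 = (
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#666666",
    "#AD7700", "#1C91D4", "#007756", "#D5C711",
    "#005685", "#A04700", "#B14380", "#4D4D4D",
    "#FFBE2D", "#80C7EF", "#00F6B3", "#F4EB71",
    "#06A5FF", "#FF8320", "#D99BBD", "#8C8C8C",
    "#FFCB57", "#9AD2F2", "#2CFFC6", "#F6EF8E",
    "#38B7FF", "#FF9B4D", "#E0AFCA", "#A3A3A3",
    "#8A5F00", "#1674A9", "#005F45", "#AA9F0D",
    "#00446B", "#803800", "#8D3666", "#3D3D3D",
)


def _check_hex(c: str) -> str:
    c = c.strip()
    if not (len(c) == 7 and c.startswith("#")):
        raise ParameterError(f"palette entry {c!r} is not a #RRGGBB color")
    int(c[1:], 16)  # raises ValueError on bad digits
    return c.upper()


def default_palette() -> list:
    """The embedded 40-color CVD-friendly palette (stable across runs)."""
    return list(_DEFAULT_40)


def load_palette(path) -> list:
    """Read a custom palette file: one #RRGGBB value per line."""
    colors = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if tok and not tok.startswith("//"):
                colors.append(_check_hex(tok))
    if not colors:
        raise ParameterError(f"palette file {path} contains no colors")
    if len(set(colors)) != len(colors):
        raise ParameterError("palette entries must be pairwise distinct")
    return colors


@dataclass(frozen=True)
class AestheticMap:
    """Deterministic group -> (fill color, pattern) assignment.

    ``specs`` keeps the un-resolved PatternSpec per group so renderers can
    re-resolve style defaults against context (e.g. glyph line color on dark
    fills); ``hatches`` holds the fill-aware resolved HatchSpec.
    """

    order: tuple  # group labels in assignment order
    fills: dict  # group -> "#RRGGBB"
    specs: dict  # group -> PatternSpec
    hatches: dict  # group -> HatchSpec (resolved against the fill)

    def __contains__(self, group) -> bool:
        return group in self.fills

    def __len__(self) -> int:
        return len(self.order)

    def pair(self, group) -> tuple:
        """(fill color, resolved HatchSpec) for a group."""
        return self.fills[group], self.hatches[group]


def assign_aesthetics(
    groups,
    palette: list | None = None,
    patterns: list | None = None,
    marker_diameter: float = 3.0,
) -> AestheticMap:
    """Assign each group a distinct (color, pattern) combination.

    Color-major cycling: group n receives palette color ``n mod P`` and
    pattern ``(n // P) mod K`` (P colors, K patterns), so up to P groups get
    distinct colors under the shared first pattern, and combinations remain
    pairwise distinct up to the P*K capacity.
    """
    groups = list(groups)
    if len(set(groups)) != len(groups):
        raise ParameterError("group labels must be distinct")
    if palette is None:
        palette = default_palette()
    if patterns is None:
        patterns = default_patterns()
    if not palette or not patterns:
        raise ParameterError("palette and pattern list must be non-empty")
    capacity = len(palette) * len(patterns)
    if len(groups) > capacity:
        raise CapacityError(
            f"{len(groups)} groups exceed the {capacity} distinct "
            f"(color, pattern) combinations available "
            f"({len(palette)} colors x {len(patterns)} patterns; "
            "the default configuration supports 280)"
        )
    fills, specs, hatches = {}, {}, {}
    for n, g in enumerate(groups):
        fill = palette[n % len(palette)]
        spec = patterns[(n // len(palette)) % len(patterns)]
        fills[g] = fill
        specs[g] = spec
        hatches[g] = resolve_pattern(
            spec,
            StyleDefaults(marker_diameter=marker_diameter, fill_color=fill),
        )
    return AestheticMap(order=tuple(groups), fills=fills, specs=specs, hatches=hatches)
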