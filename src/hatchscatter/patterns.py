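"""The hatch-pattern grammar: named defaults, custom angle lists, aesthetics.

Seven named patterns ship by default — six drawn from line families plus a
``blank`` (color-only) pattern:

====================  ============
name                  line angles
====================  ============
horizontal            0
vertical              90
positiveDiagonal      45
negativeDiagonal      135
cross                 0, 90
checkers              45, 135
blank                 (none)
====================  ============

Users create new patterns by supplying a list of line angles in [0, 180]
degrees; per-line aesthetics (width, color, dash type, alpha) can be set on
the spec or fall back to context defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError, PatternNameError

__all__ = [
    "LINE_TYPES",
    "PATTERN_NAMES",
    "PatternSpec",
    "LineFamily",
    "HatchSpec",
    "StyleDefaults",
    "resolve_pattern",
    "default_patterns",
    "darken",
    "relative_luminance",
]

#: dash styles, mirroring the conventional named line types
LINE_TYPES = {
    "solid": "solid",
    "dashed": (0, (4.0, 2.0)),
    "dotted": (0, (1.0, 2.0)),
    "dotdash": (0, (1.0, 2.0, 4.0, 2.0)),
    "longdash": (0, (7.0, 2.0)),
    "twodash": (0, (4.0, 2.0, 1.0, 2.0)),
}

NAMED_ANGLES = {
    "horizontal": (0.0,),
    "vertical": (90.0,),
    "positiveDiagonal": (45.0,),
    "negativeDiagonal": (135.0,),
    "cross": (0.0, 90.0),
    "checkers": (45.0, 135.0),
    "blank": (),
}

#: fixed cycling order of the named defaults
PATTERN_NAMES = (
    "horizontal",
    "vertical",
    "positiveDiagonal",
    "negativeDiagonal",
    "cross",
    "checkers",
    "blank",
)


def _normalize_angle(a: float) -> float:
    """Angles are directions of undirected lines: 180 wraps to 0."""
    a = float(a)
    if not (0.0 <= a <= 180.0):
        raise ParameterError(f"pattern angle {a} outside [0, 180] degrees")
    return 0.0 if a == 180.0 else a


@dataclass(frozen=True)
class PatternSpec:
    """User-facing pattern description (named type or custom angle list).

    A non-None ``angle`` list overrides the named pattern.  Style fields set
    to None are filled from :class:`StyleDefaults` at resolution time.
    """

    pattern: str = "horizontal"
    angle: tuple | None = None
    line_width: float | None = None
    line_color: str | None = None
    line_type: str = "solid"
    line_alpha: float = 1.0

    def __post_init__(self):
        if self.angle is not None:
            object.__setattr__(self, "angle", tuple(float(a) for a in self.angle))
        if self.line_type not in LINE_TYPES:
            raise PatternNameError(
                f"unknown line type {self.line_type!r}; valid: {sorted(LINE_TYPES)}"
            )
        if not (0.0 <= self.line_alpha <= 1.0):
            raise ParameterError("line_alpha must lie in [0, 1]")
        if self.line_width is not None and not self.line_width > 0:
            raise ParameterError("line_width must be > 0")


@dataclass(frozen=True)
class LineFamily:
    """One family of parallel lines with complete style."""

    angle: float  # degrees in [0, 180)
    width: float  # pt
    color: str
    line_type: str
    alpha: float


@dataclass(frozen=True)
class HatchSpec:
    """Resolved pattern: ordered tuple of line families (empty = blank)."""

    families: tuple = ()

    @property
    def is_blank(self) -> bool:
        return len(self.families) == 0

    def __len__(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class StyleDefaults:
    """Context defaults used to complete a PatternSpec.

    ``line_width`` defaults to 0.15x the rendered marker diameter so pattern
    weight tracks point size.  When ``fill_color`` is given, the default line
    color is that fill darkened 40% toward black (contrast against both the
    fill and the page); otherwise plain black.
    """

    marker_diameter: float = 3.0
    fill_color: str | None = None
    line_color: str | None = None

    @property
    def width(self) -> float:
        return 0.15 * self.marker_diameter

    @property
    def color(self) -> str:
        if self.line_color is not None:
            return self.line_color
        if self.fill_color is not None:
            return darken(self.fill_color, 0.4)
        return "#000000"


def _hex_to_rgb(color: str) -> tuple:
    c = color.lstrip("#")
    if len(c) != 6:
        raise ParameterError(f"expected #RRGGBB color, got {color!r}")
    return tuple(int(c[k : k + 2], 16) for k in (0, 2, 4))


def _rgb_to_hex(rgb) -> str:
    return "#%02X%02X%02X" % tuple(int(round(v)) for v in rgb)


def darken(color: str, fraction: float) -> str:
    """Move a hex color ``fraction`` of the way toward black."""
    r, g, b = _hex_to_rgb(color)
    f = 1.0 - fraction
    return _rgb_to_hex((r * f, g * f, b * f))


def relative_luminance(color: str) -> float:
    """WCAG relative luminance of an sRGB hex color (0 = black, 1 = white)."""
    out = []
    for v in _hex_to_rgb(color):
        s = v / 255.0
        out.append(s / 12.92 if s <= 0.04045 else ((s + 0.055) / 1.055) ** 2.4)
    r, g, b = out
    return 0.2126 * r + 0.7152 * g + 0.0722 * b


def resolve_pattern(
    spec: PatternSpec, defaults: StyleDefaults | None = None
) -> HatchSpec:
    """Resolve a PatternSpec into a concrete HatchSpec.

    Named patterns map to their angle sets; an explicit angle list overrides
    the name.  Families are emitted in ascending-angle order and each carries
    the complete style (spec overrides, else defaults).
    """
    if defaults is None:
        defaults = StyleDefaults()
    if spec.angle is not None:
        angles = [_normalize_angle(a) for a in spec.angle]
    else:
        if spec.pattern not in NAMED_ANGLES:
            raise PatternNameError(
                f"unknown pattern {spec.pattern!r}; valid names: "
                f"{list(PATTERN_NAMES)}"
            )
        angles = [_normalize_angle(a) for a in NAMED_ANGLES[spec.pattern]]
    width = spec.line_width if spec.line_width is not None else defaults.width
    color = spec.line_color if spec.line_color is not None else defaults.color
    fams = tuple(
        LineFamily(
            angle=a,
            width=float(width),
            color=color,
            line_type=spec.line_type,
            alpha=float(spec.line_alpha),
        )
        for a in sorted(dict.fromkeys(angles))
    )
    return HatchSpec(families=fams)


def default_patterns() -> list:
    """The 7 named default PatternSpecs in their fixed cycling order."""
    return [PatternSpec(pattern=name) for name in PATTERN_NAMES]
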