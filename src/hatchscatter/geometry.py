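"""Hatch geometry: clipping line families to region masks and marker disks.

Dense clusters are hatched coarsely: a family of parallel lines at a given
angle and perpendicular spacing is clipped to the union of the cluster's
occupied grid cells.  Sparse points are hatched individually: each marker
disk receives chords of the same line family, so the pattern survives at
single-point scale.

All geometry is computed in display coordinates (typographic points after
the axes transform), so a 45-degree pattern is visually 45 degrees
regardless of the data-unit aspect ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from .errors import ParameterError
from .patterns import HatchSpec, LineFamily

__all__ = [
    "LineStyle",
    "RegionMask",
    "Segment",
    "connected_components",
    "hatch_segments",
    "hatch_mask",
    "glyph_segments",
]


@dataclass(frozen=True)
class LineStyle:
    """Stroke style attached to a segment."""

    width: float = 1.0
    color: str = "#000000"
    line_type: str = "solid"
    alpha: float = 1.0

    def __post_init__(self):
        if not self.width > 0:
            raise ParameterError("line width must be > 0")


@dataclass(frozen=True)
class Segment:
    """One straight stroke with endpoints in display units."""

    x1: float
    y1: float
    x2: float
    y2: float
    style: LineStyle = LineStyle()

    def __post_init__(self):
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v):
                raise ParameterError("segment endpoints must be finite")

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    @property
    def angle_deg(self) -> float:
        """Direction as an undirected-line angle in [0, 180)."""
        a = math.degrees(math.atan2(self.y2 - self.y1, self.x2 - self.x1)) % 180.0
        return a


@dataclass(frozen=True)
class RegionMask:
    """One 8-connected dense component: a set of occupied square cells.

    The mask boundary is the raw union of cells — deliberately blocky, which
    keeps concave clusters robust and reads as the intended coarse texture.
    """

    group: str
    cells: frozenset  # {(i, j)}
    origin: tuple  # (x0, y0) display units
    bin_size: float
    component_id: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cells", frozenset(self.cells))
        if not self.bin_size > 0:
            raise ParameterError("bin_size must be > 0")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def area(self) -> float:
        return len(self.cells) * self.bin_size**2

    def cell_box(self, cell) -> tuple:
        """(xmin, ymin, xmax, ymax) of one cell in display units."""
        i, j = cell
        x0, y0 = self.origin
        b = self.bin_size
        return (x0 + i * b, y0 + j * b, x0 + (i + 1) * b, y0 + (j + 1) * b)

    def polygon(self):
        """Shapely union of the occupied cells."""
        return unary_union([box(*self.cell_box(c)) for c in self.cells])

    def contains(self, x, y) -> bool:
        """Membership in the half-open cell union (exact, no epsilon)."""
        i = math.floor((x - self.origin[0]) / self.bin_size)
        j = math.floor((y - self.origin[1]) / self.bin_size)
        return (i, j) in self.cells


def connected_components(
    cells,
    origin,
    bin_size,
    group="",
    min_cells: int = 1,
) -> list:
    """Split a cell set into 8-connected RegionMasks.

    Ordering is deterministic: row-major by each component's minimal (j, i)
    cell.  Components smaller than ``min_cells`` are dropped.
    """
    remaining = set(map(tuple, cells))
    comps = []
    while remaining:
        seed = min(remaining, key=lambda c: (c[1], c[0]))
        stack, members = [seed], set()
        remaining.discard(seed)
        while stack:
            i, j = stack.pop()
            members.add((i, j))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (i + di, j + dj)
                    if nb in remaining:
                        remaining.discard(nb)
                        stack.append(nb)
        comps.append(members)
    comps = [m for m in comps if len(m) >= min_cells]
    comps.sort(key=lambda m: min((j, i) for i, j in m))
    return [
        RegionMask(
            group=group,
            cells=frozenset(m),
            origin=tuple(origin),
            bin_size=float(bin_size),
            component_id=k,
        )
        for k, m in enumerate(comps)
    ]


def _family_frame(angle_deg: float) -> tuple:
    """Unit direction and unit normal of a line family."""
    a = math.radians(angle_deg % 180.0)
    d = (math.cos(a), math.sin(a))
    n = (-d[1], d[0])
    return d, n


def hatch_segments(
    mask: RegionMask,
    angle_deg: float,
    spacing: float,
    phase: float | None = None,
    style: LineStyle | None = None,
) -> list:
    """Clip one parallel-line family to a region mask.

    Lines run at ``angle_deg`` with perpendicular offsets ``phase + n *
    spacing``; each maximal run inside the occupied-cell union becomes one
    Segment.  ``phase`` defaults to spacing/2 so even a single-cell mask
    receives at least one line.
    """
    if not spacing > 0:
        raise ParameterError("hatch spacing must be > 0")
    defaulted_phase = phase is None
    if phase is None:
        phase = spacing / 2.0
    if style is None:
        style = LineStyle()
    if not mask.cells:
        return []
    d, nrm = _family_frame(angle_deg)
    poly = mask.polygon()
    xmin, ymin, xmax, ymax = poly.bounds
    corners = [(xmin, ymin), (xmin, ymax), (xmax, ymin), (xmax, ymax)]
    offs = [cx * nrm[0] + cy * nrm[1] for cx, cy in corners]
    ts = [cx * d[0] + cy * d[1] for cx, cy in corners]
    o_lo, o_hi = min(offs), max(offs)
    t_lo, t_hi = min(ts) - 1.0, max(ts) + 1.0
    n_lo = math.ceil((o_lo - phase) / spacing - 1e-12)
    n_hi = math.floor((o_hi - phase) / spacing + 1e-12)
    offsets = [phase + n * spacing for n in range(n_lo, n_hi + 1)]
    if not offsets and defaulted_phase:
        # guarantee at least one line even when spacing exceeds the mask:
        # a single line through the middle of the mask's offset range
        offsets = [(o_lo + o_hi) / 2.0]
    segments = []
    for off in offsets:
        p1 = (off * nrm[0] + t_lo * d[0], off * nrm[1] + t_lo * d[1])
        p2 = (off * nrm[0] + t_hi * d[0], off * nrm[1] + t_hi * d[1])
        inter = LineString([p1, p2]).intersection(poly)
        if inter.is_empty:
            continue
        geoms = getattr(inter, "geoms", [inter])
        pieces = []
        for g in geoms:
            if g.geom_type == "LineString" and g.length > 1e-9:
                coords = list(g.coords)
                pieces.append((coords[0], coords[-1]))
        # deterministic order along the line direction
        pieces.sort(key=lambda pc: pc[0][0] * d[0] + pc[0][1] * d[1])
        for (ax, ay), (bx, by) in pieces:
            segments.append(Segment(ax, ay, bx, by, style=style))
    return segments


def hatch_mask(
    mask: RegionMask, hatch: HatchSpec, spacing_factor: float = 4.0
) -> list:
    """Hatch a mask with every family of a HatchSpec.

    Per-family spacing defaults to ``spacing_factor`` x the family's line
    width (coarse but legible region texture).
    """
    out = []
    for fam in hatch.families:
        out.extend(
            hatch_segments(
                mask,
                fam.angle,
                spacing=spacing_factor * fam.width,
                style=LineStyle(
                    width=fam.width,
                    color=fam.color,
                    line_type=fam.line_type,
                    alpha=fam.alpha,
                ),
            )
        )
    return out


def glyph_segments(
    center,
    marker_radius: float,
    hatch: HatchSpec,
    glyph_spacing: float | None = None,
) -> list:
    """Per-marker pattern glyph: chords of the marker disk.

    For each line family, chords at the family's angle are spaced
    ``glyph_spacing`` apart (default: the marker radius), centered so one
    chord passes through the marker center; every chord endpoint lies on the
    marker circle.  A blank HatchSpec yields no segments.
    """
    if not marker_radius > 0:
        raise ParameterError("marker_radius must be > 0")
    gs = glyph_spacing if glyph_spacing is not None else marker_radius
    if not gs > 0:
        raise ParameterError("glyph_spacing must be > 0")
    cx, cy = center
    out = []
    for fam in hatch.families:
        d, nrm = _family_frame(fam.angle)
        style = LineStyle(
            width=fam.width, color=fam.color, line_type=fam.line_type, alpha=fam.alpha
        )
        m_max = math.ceil(marker_radius / gs) + 1
        for m in range(-m_max, m_max + 1):
            off = m * gs
            if abs(off) >= marker_radius - 1e-12:
                continue
            half = math.sqrt(marker_radius**2 - off**2)
            ax = cx + off * nrm[0] - half * d[0]
            ay = cy + off * nrm[1] - half * d[1]
            bx = cx + off * nrm[0] + half * d[0]
            by = cy + off * nrm[1] + half * d[1]
            out.append(Segment(ax, ay, bx, by, style=style))
    return out
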