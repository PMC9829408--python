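"""Figure composition and output.

Builds a backend-independent :class:`FigureArtifact` — colored base markers,
coarse region hatching over dense clusters, per-point pattern glyphs over
sparse points, and a patterned legend — then writes it as SVG (internal
deterministic writer, one drawable element per segment), or PNG/PDF via
matplotlib.

All layer geometry lives in display coordinates (typographic points, origin
bottom-left), fixed at composition time, so rendering is a pure function of
its inputs and the SVG byte stream is stable across runs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np

from .classify import GridConfig, SparsityLabels, classify_sparse_dense, cell_indices
from .errors import FormatError, MappingError
from .geometry import (
    LineStyle,
    RegionMask,
    Segment,
    connected_components,
    glyph_segments,
    hatch_mask,
)
from .io import PointTable
from .palette import AestheticMap, assign_aesthetics
from .patterns import StyleDefaults, darken, relative_luminance, resolve_pattern

__all__ = ["FigureArtifact", "render_plot", "save_figure"]

LINE_TYPE_DASHES = {
    "solid": None,
    "dashed": (4.0, 2.0),
    "dotted": (1.0, 2.0),
    "dotdash": (1.0, 2.0, 4.0, 2.0),
    "longdash": (7.0, 2.0),
    "twodash": (4.0, 2.0, 1.0, 2.0),
}

_MARGIN = 10.0  # pt, around the plot panel
_SWATCH = 12.0  # pt, legend swatch side
_ROW = 18.0  # pt, legend row pitch


@dataclass(frozen=True)
class GroupMarkers:
    """Base scatter layer for one group (display coordinates)."""

    group: str
    x: tuple
    y: tuple
    fill: str
    diameter: float  # pt


@dataclass(frozen=True)
class LegendEntry:
    """One legend key: fill swatch + pattern sample + label."""

    group: str
    fill: str
    rect: tuple  # (x, y, w, h) display pt
    segments: tuple  # pattern sample clipped to the swatch
    label_pos: tuple


@dataclass(frozen=True)
class FigureArtifact:
    """Fully laid-out figure: fixed layer stack with countable geometry.

    Layer order (bottom to top): base markers, region hatching, sparse
    glyphs, legend.  Blank-pattern groups contribute zero segments.
    """

    canvas: tuple  # (width, height) pt
    equal_aspect: bool
    markers: tuple  # of GroupMarkers, in draw order
    region_segments: tuple  # of Segment
    glyph_segs: tuple  # of Segment
    legend: tuple  # of LegendEntry

    @property
    def n_region_segments(self) -> int:
        return len(self.region_segments)

    @property
    def n_glyph_segments(self) -> int:
        return len(self.glyph_segs)

    @property
    def n_segments(self) -> int:
        return self.n_region_segments + self.n_glyph_segments

    def recolor(self, mapper) -> "FigureArtifact":
        """Apply ``mapper(hex) -> hex`` to every color; geometry untouched."""

        def seg(s: Segment) -> Segment:
            return replace(s, style=replace(s.style, color=mapper(s.style.color)))

        return FigureArtifact(
            canvas=self.canvas,
            equal_aspect=self.equal_aspect,
            markers=tuple(replace(m, fill=mapper(m.fill)) for m in self.markers),
            region_segments=tuple(seg(s) for s in self.region_segments),
            glyph_segs=tuple(seg(s) for s in self.glyph_segs),
            legend=tuple(
                replace(
                    e,
                    fill=mapper(e.fill),
                    segments=tuple(seg(s) for s in e.segments),
                )
                for e in self.legend
            ),
        )


def _glyph_line_color(fill: str) -> str:
    """White chords on dark fills, darkened fill on light ones."""
    return "#FFFFFF" if relative_luminance(fill) < 0.45 else darken(fill, 0.4)


def _legend_layout(groups, canvas):
    """Column-major legend grid on the right margin; returns geometry."""
    w, h = canvas
    usable = h - 2 * _MARGIN
    per_col = max(1, int(usable // _ROW))
    ncols = int(math.ceil(len(groups) / per_col))
    col_w = _SWATCH + 4.0 + 42.0  # swatch + gap + label allowance
    legend_w = ncols * col_w + _MARGIN
    positions = []
    for n in range(len(groups)):
        col, row = divmod(n, per_col)
        x = w - legend_w + col * col_w
        y = h - _MARGIN - _SWATCH - row * _ROW
        positions.append((x, y))
    return legend_w, positions


def render_plot(
    points: PointTable,
    labels: SparsityLabels | None = None,
    aesthetics: AestheticMap | None = None,
    *,
    config: GridConfig | None = None,
    canvas: tuple = (460.8, 345.6),
    point_size: float = 3.0,
    equal_aspect: bool = False,
    legend: bool = True,
    spacing_factor: float = 4.0,
    glyph_spacing: float | None = None,
) -> FigureArtifact:
    """Compose the hatched scatter figure.

    ``point_size`` is the rendered marker diameter in pt.  Classification is
    run with ``config`` when ``labels`` is None.  Group draw order follows
    the aesthetic assignment order; overlapping groups overdraw.
    """
    if config is None:
        config = GridConfig(point_diameter=point_size, canvas=canvas)
    if labels is None:
        labels = classify_sparse_dense(points, config)
    if aesthetics is None:
        aesthetics = assign_aesthetics(points.groups(), marker_diameter=point_size)
    for g in points.groups():
        if g not in aesthetics:
            raise MappingError(f"group {g!r} has no aesthetic assignment")

    w, h = canvas
    legend_groups = [g for g in aesthetics.order if g in set(points.groups())]
    legend_w = 0.0
    legend_pos = []
    if legend and legend_groups:
        legend_w, legend_pos = _legend_layout(legend_groups, canvas)

    # data -> display transform for the plot panel
    xmin, ymin, xmax, ymax = points.bounds()
    pw = max(w - legend_w - 2 * _MARGIN, 10.0)
    ph = max(h - 2 * _MARGIN, 10.0)
    xspan = (xmax - xmin) or 1.0
    yspan = (ymax - ymin) or 1.0
    sx, sy = pw / xspan, ph / yspan
    if equal_aspect:
        sx = sy = min(sx, sy)

    def to_disp(x, y):
        return (
            _MARGIN + (np.asarray(x) - xmin) * sx,
            _MARGIN + (np.asarray(y) - ymin) * sy,
        )

    bin_pt = config.bin_factor * point_size
    radius = point_size / 2.0
    markers, region, glyphs = [], [], []
    for group in legend_groups:
        idx = points.group_indices(group)
        dx, dy = to_disp(points.x[idx], points.y[idx])
        fill, hatch = aesthetics.pair(group)
        markers.append(
            GroupMarkers(
                group=group,
                x=tuple(float(v) for v in dx),
                y=tuple(float(v) for v in dy),
                fill=fill,
                diameter=point_size,
            )
        )
        spec = aesthetics.specs[group]
        region_hatch = resolve_pattern(
            spec, StyleDefaults(marker_diameter=point_size, fill_color=fill)
        )
        glyph_hatch = resolve_pattern(
            spec,
            StyleDefaults(
                marker_diameter=point_size, line_color=_glyph_line_color(fill)
            ),
        )
        sparse_mask = labels.sparse[idx]
        dense_x, dense_y = dx[~sparse_mask], dy[~sparse_mask]
        if dense_x.size:
            cells = cell_indices(dense_x, dense_y, (0.0, 0.0), bin_pt)
            for mask in connected_components(
                map(tuple, cells), (0.0, 0.0), bin_pt, group=group
            ):
                region.extend(hatch_mask(mask, region_hatch, spacing_factor))
        for px, py in zip(dx[sparse_mask], dy[sparse_mask]):
            glyphs.extend(
                glyph_segments(
                    (float(px), float(py)), radius, glyph_hatch, glyph_spacing
                )
            )

    legend_entries = []
    for (lx, ly), group in zip(legend_pos, legend_groups):
        fill, _ = aesthetics.pair(group)
        sample_hatch = resolve_pattern(
            aesthetics.specs[group],
            StyleDefaults(marker_diameter=point_size, fill_color=fill),
        )
        swatch = RegionMask(
            group=group, cells={(0, 0)}, origin=(lx, ly), bin_size=_SWATCH
        )
        # scaled-down sample: 2 lines per family inside the swatch
        sample = []
        for fam in sample_hatch.families:
            sample.extend(_swatch_lines(swatch, fam.angle, fam, n_lines=2))
        legend_entries.append(
            LegendEntry(
                group=group,
                fill=fill,
                rect=(lx, ly, _SWATCH, _SWATCH),
                segments=tuple(sample),
                label_pos=(lx + _SWATCH + 4.0, ly + _SWATCH / 2.0),
            )
        )

    return FigureArtifact(
        canvas=canvas,
        equal_aspect=equal_aspect,
        markers=tuple(markers),
        region_segments=tuple(region),
        glyph_segs=tuple(glyphs),
        legend=tuple(legend_entries),
    )


def _swatch_lines(swatch: RegionMask, angle: float, fam, n_lines: int = 2):
    """Scaled-down pattern sample for a legend swatch."""
    from .geometry import hatch_segments

    spacing = _SWATCH / (n_lines + 1)
    return hatch_segments(
        swatch,
        angle,
        spacing=spacing,
        phase=spacing,
        style=LineStyle(
            width=fam.width, color=fam.color, line_type=fam.line_type, alpha=fam.alpha
        ),
    )


# ---------------------------------------------------------------------------
# output backends


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def _svg_line(seg: Segment, h: float) -> str:
    s = seg.style
    dash = LINE_TYPE_DASHES[s.line_type]
    attrs = (
        f'x1="{_fmt(seg.x1)}" y1="{_fmt(h - seg.y1)}" '
        f'x2="{_fmt(seg.x2)}" y2="{_fmt(h - seg.y2)}" '
        f'stroke="{s.color}" stroke-width="{_fmt(s.width)}"'
    )
    if s.alpha < 1.0:
        attrs += f' stroke-opacity="{_fmt(s.alpha)}"'
    if dash is not None:
        attrs += f' stroke-dasharray="{",".join(_fmt(d) for d in dash)}"'
    return f"    <line {attrs} />"


def _write_svg(fig: FigureArtifact, path) -> None:
    w, h = fig.canvas
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(w)}pt" '
        f'height="{_fmt(h)}pt" viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
        f'  <rect width="{_fmt(w)}" height="{_fmt(h)}" fill="#FFFFFF" />',
        '  <g id="markers">',
    ]
    for m in fig.markers:
        r = _fmt(m.diameter / 2.0)
        for x, y in zip(m.x, m.y):
            out.append(
                f'    <circle cx="{_fmt(x)}" cy="{_fmt(h - y)}" r="{r}" '
                f'fill="{m.fill}" />'
            )
    out.append("  </g>")
    out.append('  <g id="region-hatch">')
    out.extend(_svg_line(s, h) for s in fig.region_segments)
    out.append("  </g>")
    out.append('  <g id="sparse-glyphs">')
    out.extend(_svg_line(s, h) for s in fig.glyph_segs)
    out.append("  </g>")
    out.append('  <g id="legend">')
    for e in fig.legend:
        x, y, sw, sh = e.rect
        out.append(
            f'    <rect x="{_fmt(x)}" y="{_fmt(h - y - sh)}" width="{_fmt(sw)}" '
            f'height="{_fmt(sh)}" fill="{e.fill}" stroke="#000000" '
            'stroke-width="0.300" />'
        )
        out.extend(_svg_line(s, h) for s in e.segments)
        tx, ty = e.label_pos
        out.append(
            f'    <text x="{_fmt(tx)}" y="{_fmt(h - ty + 2.5)}" '
            f'font-family="sans-serif" font-size="7">{_escape(e.group)}</text>'
        )
    out.append("  </g>")
    out.append("</svg>")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(out) + "\n")


def _escape(text: str) -> str:
    return (
        str(text).replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _to_matplotlib(fig: FigureArtifact):
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.collections import LineCollection
    from matplotlib.figure import Figure
    from matplotlib.patches import Rectangle

    w, h = fig.canvas
    mfig = Figure(figsize=(w / 72.0, h / 72.0))
    FigureCanvasAgg(mfig)
    ax = mfig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, w)
    ax.set_ylim(0, h)
    ax.set_axis_off()

    for m in fig.markers:
        ax.scatter(
            m.x, m.y, s=m.diameter**2, c=m.fill, linewidths=0, zorder=1
        )

    def draw_segments(segments, zorder):
        if not segments:
            return
        lines = [[(s.x1, s.y1), (s.x2, s.y2)] for s in segments]
        styles = [
            "solid"
            if s.style.line_type == "solid"
            else (0, LINE_TYPE_DASHES[s.style.line_type])
            for s in segments
        ]
        lc = LineCollection(
            lines,
            colors=[s.style.color for s in segments],
            linewidths=[s.style.width for s in segments],
            linestyles=styles,
            alpha=None,
            zorder=zorder,
        )
        lc.set_alpha(None)
        ax.add_collection(lc)

    draw_segments(fig.region_segments, zorder=2)
    draw_segments(fig.glyph_segs, zorder=3)
    for e in fig.legend:
        x, y, sw, sh = e.rect
        ax.add_patch(
            Rectangle(
                (x, y), sw, sh, facecolor=e.fill, edgecolor="#000000",
                linewidth=0.3, zorder=4,
            )
        )
        draw_segments(e.segments, zorder=5)
        ax.text(
            e.label_pos[0], e.label_pos[1], str(e.group),
            fontsize=6, va="center", zorder=6,
        )
    return mfig


FORMATS = ("svg", "png", "pdf")


def save_figure(fig: FigureArtifact, path, format: str | None = None, dpi: int = 300):
    """Write a FigureArtifact to disk.

    SVG goes through the internal writer (byte-stable, one ``<line>`` per
    segment); PNG and PDF are rendered with matplotlib (PDF creation
    timestamp suppressed).
    """
    if format is None:
        format = os.path.splitext(str(path))[1].lstrip(".").lower()
    if format not in FORMATS:
        raise FormatError(
            f"unsupported output format {format!r}; supported: {FORMATS}"
        )
    if format == "svg":
        _write_svg(fig, path)
        return path
    mfig = _to_matplotlib(fig)
    if format == "pdf":
        mfig.savefig(path, format="pdf", metadata={"CreationDate": None})
    else:
        mfig.savefig(path, format="png", dpi=dpi)
    return path
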