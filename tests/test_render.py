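import xml.etree.ElementTree as ET

import numpy as np
import pytest

from hatchscatter.classify import GridConfig, apply_sparse_override
from hatchscatter.cvd import simulate_figure
from hatchscatter.errors import FormatError, MappingError
from hatchscatter.io import PointTable, SparseOverride
from hatchscatter.palette import assign_aesthetics
from hatchscatter.patterns import PatternSpec
from hatchscatter.render import render_plot, save_figure

SVG_NS = "{http://www.w3.org/2000/svg}"


def svg_layer_counts(path, tag="line"):
    root = ET.parse(path).getroot()
    out = {}
    for g in root.iter(f"{SVG_NS}g"):
        out[g.get("id")] = len(list(g.iter(f"{SVG_NS}{tag}")))
    return out


@pytest.fixture
def small_table():
    rng = np.random.default_rng(4)
    xs = np.concatenate([rng.normal(0, 0.3, 60), [6.0, 7.5]])
    ys = np.concatenate([rng.normal(0, 0.3, 60), [6.0, 1.0]])
    groups = ("a",) * 30 + ("b",) * 30 + ("a", "b")
    return PointTable(ids=tuple(range(62)), x=xs, y=ys, group=groups)


class TestCompose:
    def test_blank_patterns_degenerate_to_plain_scatter(self, small_table):
        aes = assign_aesthetics(
            small_table.groups(), patterns=[PatternSpec(pattern="blank")]
        )
        fig = render_plot(small_table, aesthetics=aes)
        assert fig.n_segments == 0
        assert len(fig.markers) == 2

    def test_all_sparse_glyph_count_closed_form(self, small_table):
        labels = apply_sparse_override(
            small_table, SparseOverride(ids=set(small_table.ids))
        )
        aes = assign_aesthetics(
            small_table.groups(), patterns=[PatternSpec(pattern="cross")]
        )
        fig = render_plot(small_table, labels, aes)
        assert fig.n_region_segments == 0
        # default glyph spacing = marker radius: 1 diameter chord per family
        assert fig.n_glyph_segments == len(small_table) * 2

    def test_rendering_is_deterministic(self, small_table):
        a = render_plot(small_table)
        b = render_plot(small_table)
        assert a == b

    def test_missing_aesthetic_raises(self, small_table):
        aes = assign_aesthetics(["a"])
        with pytest.raises(MappingError, match="b"):
            render_plot(small_table, aesthetics=aes)

    def test_legend_covers_every_group(self, small_table):
        fig = render_plot(small_table)
        assert [e.group for e in fig.legend] == small_table.groups()

    def test_dense_cluster_gets_region_hatching(self, small_table):
        fig = render_plot(
            small_table, config=GridConfig(bin_size=0.5, min_cluster_cells=1)
        )
        assert fig.n_region_segments > 0

    def test_canvas_scale_changes_regions_not_glyphs(self):
        from hatchscatter.classify import classify_sparse_dense

        # one well-filled cluster plus two isolated points, so the region
        # mask stays solid at both canvas scales
        rng = np.random.default_rng(17)
        xs = np.concatenate([rng.normal(0, 0.3, 2000), [6.0, -6.0]])
        ys = np.concatenate([rng.normal(0, 0.3, 2000), [6.0, -6.0]])
        t = PointTable(
            ids=tuple(range(2002)), x=xs, y=ys, group=("a",) * 2002
        )
        labels = classify_sparse_dense(t, GridConfig(bin_size=0.5))
        base = render_plot(t, labels, canvas=(460.8, 345.6))
        double = render_plot(t, labels, canvas=(921.6, 691.2))
        assert double.n_glyph_segments == base.n_glyph_segments
        # the core cross-section doubles; total hatched length ~ area x4
        longest = lambda f: max(s.length for s in f.region_segments)
        total = lambda f: sum(s.length for s in f.region_segments)
        assert longest(double) > 1.6 * longest(base)
        assert total(double) > 2.5 * total(base)


class TestRecolor:
    def test_monochromacy_preserves_geometry_bitwise(self, small_table):
        fig = render_plot(small_table)
        mono = simulate_figure(fig, "monochromacy")
        for a, b in zip(
            fig.region_segments + fig.glyph_segs,
            mono.region_segments + mono.glyph_segs,
        ):
            assert (a.x1, a.y1, a.x2, a.y2) == (b.x1, b.y1, b.x2, b.y2)
            assert a.style.width == b.style.width
        assert [m.x for m in mono.markers] == [m.x for m in fig.markers]
        assert any(
            m.fill != f.fill for m, f in zip(mono.markers, fig.markers)
        )


class TestSave:
    def test_svg_line_count_matches_figure(self, small_table, tmp_path):
        fig = render_plot(small_table)
        p = tmp_path / "fig.svg"
        save_figure(fig, p)
        counts = svg_layer_counts(p)
        assert counts["region-hatch"] == fig.n_region_segments
        assert counts["sparse-glyphs"] == fig.n_glyph_segments
        rects = svg_layer_counts(p, tag="rect")
        assert rects["legend"] == len(fig.legend)

    def test_svg_byte_identical_across_saves(self, small_table, tmp_path):
        fig = render_plot(small_table)
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        save_figure(fig, p1)
        save_figure(fig, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_png_and_pdf_written(self, small_table, tmp_path):
        fig = render_plot(small_table)
        assert save_figure(fig, tmp_path / "f.png", dpi=72)
        assert (tmp_path / "f.png").stat().st_size > 0
        save_figure(fig, tmp_path / "f.pdf")
        assert (tmp_path / "f.pdf").stat().st_size > 0

    def test_unsupported_format_rejected(self, small_table, tmp_path):
        fig = render_plot(small_table)
        with pytest.raises(FormatError, match="tiff"):
            save_figure(fig, tmp_path / "f.tiff")
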