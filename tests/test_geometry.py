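import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import Point

from hatchscatter.errors import ParameterError
from hatchscatter.geometry import (
    LineStyle,
    RegionMask,
    Segment,
    connected_components,
    glyph_segments,
    hatch_segments,
)
from hatchscatter.patterns import PatternSpec, resolve_pattern

from tests.oracles import oracle_hatch_length, pixel_hatch_length


def mask_of(cells, bin_size=1.0, origin=(0.0, 0.0)):
    return RegionMask(group="g", cells=cells, origin=origin, bin_size=bin_size)


def random_mask(rng, max_side=8):
    side = int(rng.integers(2, max_side + 1))
    density = rng.uniform(0.3, 0.9)
    cells = {
        (i, j)
        for i in range(side)
        for j in range(side)
        if rng.uniform() < density
    }
    cells.add((0, 0))
    return mask_of(cells, bin_size=float(rng.uniform(0.5, 3.0)))


class TestComponents:
    def test_disjoint_blobs_two_components(self):
        comps = connected_components(
            [(0, 0), (1, 0), (5, 5), (6, 5)], (0, 0), 1.0
        )
        assert len(comps) == 2

    def test_empty_cells_empty_list(self):
        assert connected_components([], (0, 0), 1.0) == []

    def test_diagonal_join_single_component_8conn(self):
        # L-shape whose arms meet only diagonally
        cells = [(0, 0), (0, 1), (0, 2), (1, 3), (2, 3)]
        comps = connected_components(cells, (0, 0), 1.0)
        assert len(comps) == 1
        assert comps[0].cells == frozenset(cells)

    def test_min_cells_filter_and_ordering(self):
        comps = connected_components(
            [(9, 0), (0, 5), (1, 5), (3, 3)], (0, 0), 1.0, min_cells=2
        )
        assert [len(c) for c in comps] == [2]
        assert comps[0].component_id == 0


class TestHatchSegments:
    def test_empty_mask_no_segments(self):
        assert hatch_segments(mask_of(set()), 45.0, spacing=1.0) == []

    def test_unit_cell_horizontal_two_lines(self):
        # offsets 0.25 and 0.75 cross the unit square: two length-1 runs
        segs = hatch_segments(mask_of({(0, 0)}), 0.0, spacing=0.5, phase=0.25)
        assert len(segs) == 2
        assert all(abs(s.length - 1.0) < 1e-9 for s in segs)

    def test_square_symmetry_0_vs_90(self):
        cells = {(i, j) for i in range(4) for j in range(4)}
        h = hatch_segments(mask_of(cells), 0.0, spacing=0.7, phase=0.35)
        v = hatch_segments(mask_of(cells), 90.0, spacing=0.7, phase=0.35)
        assert len(h) == len(v)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ParameterError):
            hatch_segments(mask_of({(0, 0)}), 0.0, spacing=0.0)

    def test_single_cell_mask_gets_a_line_by_default_phase(self):
        segs = hatch_segments(mask_of({(0, 0)}, bin_size=2.0), 30.0, spacing=8.0)
        assert len(segs) >= 1

    def test_segment_midpoints_inside_mask(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = random_mask(rng)
            poly = m.polygon()
            segs = hatch_segments(
                m, float(rng.uniform(0, 180)), spacing=m.bin_size / 2
            )
            for s in segs:
                mid = Point((s.x1 + s.x2) / 2, (s.y1 + s.y2) / 2)
                assert poly.distance(mid) < 1e-9

    @given(angle=st.floats(min_value=0.0, max_value=179.99))
    def test_angle_fidelity(self, angle):
        cells = {(i, j) for i in range(5) for j in range(5)}
        segs = hatch_segments(mask_of(cells, bin_size=2.0), angle, spacing=1.3)
        for s in segs:
            if s.length > 1e-6:
                diff = abs(s.angle_deg - (angle % 180.0))
                assert min(diff, 180.0 - diff) < 1e-6

    def test_length_matches_per_cell_clipping_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(8):
            m = random_mask(rng)
            angle = float(rng.uniform(0, 180))
            spacing = float(rng.uniform(0.3, 1.2)) * m.bin_size
            phase = spacing / 2
            segs = hatch_segments(m, angle, spacing, phase)
            got = sum(s.length for s in segs)
            want = oracle_hatch_length(m, angle, spacing, phase)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_length_matches_pixel_sampling_oracle(self):
        m = mask_of({(0, 0), (1, 0), (1, 1), (2, 1)}, bin_size=1.5)
        angle, spacing = 37.0, 0.8
        segs = hatch_segments(m, angle, spacing)
        got = sum(s.length for s in segs)
        want = pixel_hatch_length(m, angle, spacing, spacing / 2, step=5e-4)
        assert got == pytest.approx(want, rel=0.01)

    def test_convex_mask_coverage_density(self):
        # total length x spacing ~ area: spacing is perpendicular distance
        cells = {(i, j) for i in range(10) for j in range(10)}
        m = mask_of(cells, bin_size=1.0)
        for angle in (0.0, 30.0, 45.0, 120.0):
            segs = hatch_segments(m, angle, spacing=0.25)
            covered = sum(s.length for s in segs) * 0.25
            assert covered == pytest.approx(m.area, rel=0.10)


class TestGlyphSegments:
    def hatch(self, name="horizontal", **kw):
        return resolve_pattern(PatternSpec(pattern=name, **kw))

    def test_blank_pattern_no_chords(self):
        assert glyph_segments((0, 0), 2.0, self.hatch("blank")) == []

    def test_wide_spacing_single_diameter_chord(self):
        segs = glyph_segments((3.0, 4.0), 2.0, self.hatch(), glyph_spacing=10.0)
        assert len(segs) == 1
        assert segs[0].length == pytest.approx(4.0)
        mid = ((segs[0].x1 + segs[0].x2) / 2, (segs[0].y1 + segs[0].y2) / 2)
        assert mid == pytest.approx((3.0, 4.0))

    def test_two_family_pattern_doubles_count(self):
        one = glyph_segments((0, 0), 2.0, self.hatch("horizontal"), 0.9)
        two = glyph_segments((0, 0), 2.0, self.hatch("cross"), 0.9)
        assert len(two) == 2 * len(one)

    def test_chord_endpoints_on_marker_circle(self):
        segs = glyph_segments((1.0, -2.0), 1.7, self.hatch("checkers"), 0.6)
        for s in segs:
            for x, y in ((s.x1, s.y1), (s.x2, s.y2)):
                assert math.hypot(x - 1.0, y + 2.0) == pytest.approx(1.7)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            glyph_segments((0, 0), 0.0, self.hatch())


class TestSegment:
    def test_angle_is_undirected(self):
        assert Segment(0, 0, 1, 1).angle_deg == pytest.approx(45.0)
        assert Segment(1, 1, 0, 0).angle_deg == pytest.approx(45.0)

    def test_style_width_positive(self):
        with pytest.raises(ParameterError):
            LineStyle(width=0.0)
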