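"""Incidence maps, threshold regions, lobe splitting, extents, central points."""

import numpy as np
import pandas as pd
import pytest

from thyromap.atlas import (
    IncidenceMap,
    Region,
    build_incidence_map,
    central_point,
    merge_topography,
    region_extents,
    split_lobes,
    threshold_region,
)
from thyromap.raster import AtlasGrid, Mask, rasterize_polygon

from conftest import random_mask


def rect_region(grid, x0, x1, s0, s1, tau=1.0, lobe=""):
    rect = [(x0, s0), (x1, s0), (x1, s1), (x0, s1)]
    return Region(rasterize_polygon(rect, grid).pixels, grid, tau, lobe=lobe)


class TestIncidence:
    def test_identical_masks_give_binary_map(self, rng, small_grid):
        m = random_mask(rng, small_grid)
        imap = build_incidence_map([m] * 6, "native")
        assert set(np.unique(imap.values)) <= {0.0, 1.0}
        assert imap.n_specimens == 6

    def test_fractions_are_count_over_n(self, small_grid):
        masks = []
        for k in range(6):
            px = np.zeros(small_grid.shape, bool)
            if k < 3:
                px[50, 50] = True  # covered by 3 of 6 masks
            px[10, 10] = True
            masks.append(Mask(px, 0.02, "front", grid=small_grid))
        imap = build_incidence_map(masks)
        assert imap.values[50, 50] == pytest.approx(0.5)
        assert imap.values[10, 10] == 1.0

    def test_matches_brute_force_count(self, rng, small_grid):
        masks = [random_mask(rng, small_grid, 0.2, f"m{i}") for i in range(6)]
        imap = build_incidence_map(masks)
        brute = sum(m.pixels.astype(int) for m in masks) / 6.0
        assert np.array_equal(imap.values, brute)

    def test_conservation_of_mean_area(self, rng, small_grid):
        masks = [random_mask(rng, small_grid, 0.3) for _ in range(5)]
        imap = build_incidence_map(masks)
        cell = small_grid.resolution**2
        mean_mask_area = np.mean([m.area_mm2 for m in masks])
        assert imap.values.sum() * cell == pytest.approx(mean_mask_area, abs=1e-9)

    def test_grid_mismatch_rejected(self, rng, small_grid):
        other = AtlasGrid("front", (-2.0, 2.0), (-2.0, 2.0), 0.02)
        with pytest.raises(ValueError):
            build_incidence_map([random_mask(rng, small_grid),
                                 random_mask(rng, other)])


class TestThreshold:
    def test_half_incidence_is_included_at_tau_half(self, small_grid):
        values = np.zeros(small_grid.shape)
        values[5, 5] = 0.5  # exactly 3 of 6
        imap = IncidenceMap("front", small_grid, values, 6)
        assert threshold_region(imap, 0.5).pixels[5, 5]

    def test_nesting(self, rng, small_grid):
        masks = [random_mask(rng, small_grid, 0.4) for _ in range(6)]
        imap = build_incidence_map(masks)
        full = threshold_region(imap, 1.0).pixels
        half = threshold_region(imap, 0.5).pixels
        assert not (full & ~half).any()

    def test_unanimity_region_of_identical_masks_is_the_mask(self, rng, small_grid):
        m = random_mask(rng, small_grid)
        imap = build_incidence_map([m] * 6)
        assert np.array_equal(threshold_region(imap, 1.0).pixels, m.pixels)

    @pytest.mark.parametrize("tau", [0.0, 1.5, -0.2])
    def test_invalid_tau_rejected(self, small_grid, tau):
        imap = IncidenceMap("front", small_grid, np.zeros(small_grid.shape), 1)
        with pytest.raises(ValueError):
            threshold_region(imap, tau)


class TestSplitLobes:
    def test_blobs_astride_midline(self, small_grid):
        region = rect_region(small_grid, 0.2, 0.8, -0.5, 0.5)
        region.pixels |= rect_region(small_grid, -0.8, -0.2, -0.5, 0.5).pixels
        left, right = split_lobes(region)
        assert left.pixels.sum() == right.pixels.sum() > 0
        assert (small_grid.x_centers()[left.pixels.any(axis=0)] > 0).all()

    def test_empty_region_gives_empty_lobes(self, small_grid):
        left, right = split_lobes(Region(np.zeros(small_grid.shape, bool),
                                         small_grid, 1.0))
        assert left.is_empty and right.is_empty

    def test_isthmus_free_fixture_has_one_component_per_side(self, small_grid):
        from scipy import ndimage

        region = rect_region(small_grid, 0.3, 0.7, -0.5, 0.5)
        region.pixels |= rect_region(small_grid, -0.7, -0.3, -0.5, 0.5).pixels
        left, right = split_lobes(region)
        assert ndimage.label(left.pixels)[1] == 1
        assert ndimage.label(right.pixels)[1] == 1


class TestExtents:
    def test_front_rectangle(self):
        grid = AtlasGrid("front", (-4.0, 4.0), (-7.0, 1.0), 0.02)
        r = rect_region(grid, 0.5, 1.5, -3.0, -1.0)
        e = region_extents(r)
        assert e["length_mm"] == pytest.approx(2.0, abs=1e-9)
        assert e["width_mm"] == pytest.approx(1.0, abs=1e-9)
        assert e["medial_mm"] == pytest.approx(0.5, abs=1e-9)
        assert e["lateral_mm"] == pytest.approx(1.5, abs=1e-9)

    def test_section_rectangle_thickness(self):
        grid = AtlasGrid("section", (-3.0, 3.0), (-1.0, 3.0), 0.02)
        r = rect_region(grid, 0.7, 1.3, 0.7, 1.5)
        e = region_extents(r)
        assert e["thickness_mm"] == pytest.approx(0.8, abs=1e-9)
        assert e["width_mm"] == pytest.approx(0.6, abs=1e-9)

    def test_slanted_band_width_is_per_level(self):
        """An oblique lobe band reports its width at a level, not the X span."""
        grid = AtlasGrid("front", (-4.0, 4.0), (-7.0, 1.0), 0.02)
        para = [(0.5, -1.0), (1.1, -1.0), (1.5, -3.0), (0.9, -3.0)]
        r = Region(rasterize_polygon(para, grid).pixels, grid, 1.0)
        e = region_extents(r)
        assert e["width_mm"] == pytest.approx(0.6, abs=2 * 0.02)
        assert e["x_max_mm"] - e["x_min_mm"] == pytest.approx(1.0, abs=2 * 0.02)

    def test_single_pixel(self, small_grid):
        px = np.zeros(small_grid.shape, bool)
        px[50, 60] = True
        e = region_extents(Region(px, small_grid, 1.0))
        assert e["length_mm"] == pytest.approx(small_grid.resolution)
        assert e["width_mm"] == pytest.approx(small_grid.resolution)

    def test_empty_region_rejected(self, small_grid):
        with pytest.raises(ValueError, match="empty"):
            region_extents(Region(np.zeros(small_grid.shape, bool), small_grid, 1.0))


class TestCentralPoint:
    def _sgrid(self):
        return AtlasGrid("section", (-3.0, 3.0), (-1.0, 3.0), 0.02)

    def test_midpoint_rule_with_plane_offset(self):
        r = rect_region(self._sgrid(), 0.5, 1.5, 0.7, 1.5, lobe="left")
        cp = central_point(None, r, plane_offset=-2.0)
        assert cp.x == pytest.approx(1.0, abs=1e-9)
        assert cp.y == -2.0
        assert cp.z == pytest.approx(1.1, abs=1e-9)

    def test_right_lobe_midpoint(self):
        r = rect_region(self._sgrid(), -1.4, -0.4, 0.6, 1.4, lobe="right")
        cp = central_point(None, r, plane_offset=-2.0)
        assert cp.x == pytest.approx(-0.9, abs=1e-9)

    def test_y_from_front_region_when_no_plane_given(self):
        fgrid = AtlasGrid("front", (-4.0, 4.0), (-7.0, 1.0), 0.02)
        front = rect_region(fgrid, 0.5, 1.5, -3.0, -1.0, lobe="left")
        section = rect_region(self._sgrid(), 0.7, 1.3, 0.7, 1.5, lobe="left")
        cp = central_point(front, section)
        assert cp.y == pytest.approx(-2.0, abs=1e-9)

    def test_empty_section_region_rejected(self, small_grid):
        empty = Region(np.zeros(small_grid.shape, bool), small_grid, 1.0)
        with pytest.raises(ValueError):
            central_point(None, empty, plane_offset=-2.0)


class TestTopography:
    def test_single_phase(self, rng, small_grid):
        imap = build_incidence_map([random_mask(rng, small_grid)] * 3, "native")
        topo, table = merge_topography([imap], 0.5)
        assert topo.phases() == ["native"]
        assert not table.empty

    def test_duplicate_phase_rejected(self, rng, small_grid):
        imap = build_incidence_map([random_mask(rng, small_grid)], "native")
        with pytest.raises(ValueError, match="duplicate"):
            merge_topography([imap, imap], 0.5)

    def test_phases_ordered_by_enlargement(self, rng, small_grid):
        maps = [build_incidence_map([random_mask(rng, small_grid)], p)
                for p in ("T>15", "native", "T06-09")]
        topo, _ = merge_topography(maps, 0.5)
        assert topo.phases() == ["native", "T06-09", "T>15"]

    def test_all_empty_maps_warn(self, small_grid):
        empty = Mask(np.zeros(small_grid.shape, bool), 0.02, "front",
                     grid=small_grid)
        imap = build_incidence_map([empty], "native")
        with pytest.warns(UserWarning, match="empty"):
            topo, table = merge_topography([imap], 0.5)
        assert table.empty

    def test_reference_fixtures_grow_monotonically(self):
        """Native -> largest phase: lateral and caudal extents increase."""
        from thyromap.fixtures import reference_polygons
        from thyromap.raster import front_grid

        grid = front_grid()
        maps = []
        for phase in ("native", "T>15"):
            polys = reference_polygons(phase)["front"]
            px = (rasterize_polygon(polys["left"], grid).pixels
                  | rasterize_polygon(polys["right"], grid).pixels)
            maps.append(build_incidence_map(
                [Mask(px, grid.resolution, "front", grid=grid)] * 6, phase))
        _, table = merge_topography(maps, 1.0)
        left = table[table.lobe == "left"].set_index("phase")
        assert left.loc["T>15", "lateral_mm"] >= left.loc["native", "lateral_mm"]
        assert left.loc["T>15", "y_min_mm"] <= left.loc["native", "y_min_mm"]
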