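"""Closed-form frame alignment, mask resampling, and registration residuals."""

import numpy as np
import pytest

from thyromap.frames import build_front_frame, canonical_frame, load_skeleton_template
from thyromap.raster import AtlasGrid, Mask
from thyromap.register import (
    RigidTransform,
    apply_transform,
    estimate_transform,
    residual_error,
)

from conftest import random_mask


def frame_from_rotation(angle_deg, origin_px=(200.0, 100.0), pixel_size=0.01):
    """Front frame whose landmarks were rotated by angle_deg about the origin."""
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    o = np.asarray(origin_px)
    border = [o + [d, 0] @ rot.T for d in (-100, 100)]
    midline = [o + [0, d] @ rot.T for d in (-50, 200)]
    return build_front_frame(border, midline, pixel_size)


class TestEstimate:
    def test_identity_for_equal_frames(self):
        f = frame_from_rotation(17.0)
        t = estimate_transform(f, f)
        assert t.angle == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-9)
        assert t.scale == 1.0

    @pytest.mark.parametrize("angle,shift", [(25.0, (3.0, -1.0)), (-60.0, (0.5, 2.0))])
    def test_recovers_known_frame_motion(self, angle, shift):
        """A frame built from rotated+shifted landmarks maps back exactly."""
        f = frame_from_rotation(angle, origin_px=(200 + shift[0] * 100,
                                                  100 - shift[1] * 100))
        t = estimate_transform(f, canonical_frame("front"))
        # the specimen origin must land on the canonical origin
        o_mm = np.array([f.origin[0], f.origin[1]])
        assert np.allclose(t.apply(o_mm), [0, 0], atol=1e-9)
        # a point 1 mm along the specimen X axis lands at (1, 0)
        assert np.allclose(t.apply(o_mm + f.x_axis), [1, 0], atol=1e-9)

    def test_similarity_scale_from_fossa_spacing(self):
        f = frame_from_rotation(0.0)
        skel = load_skeleton_template()
        # fossae drawn 1.8 mm apart in the image: scale 1 vs the template's 1.8
        spec_lms = {"lateral_fossa_L": (290.0, 160.0), "lateral_fossa_R": (110.0, 160.0)}
        t = estimate_transform(f, canonical_frame("front"), "similarity",
                               specimen_landmarks=spec_lms,
                               template_landmarks=skel.front_landmarks)
        assert t.scale == pytest.approx(1.0)
        # half the spacing in the image: scale 2
        spec_lms = {"lateral_fossa_L": (245.0, 160.0), "lateral_fossa_R": (155.0, 160.0)}
        t = estimate_transform(f, canonical_frame("front"), "similarity",
                               specimen_landmarks=spec_lms,
                               template_landmarks=skel.front_landmarks)
        assert t.scale == pytest.approx(2.0)

    def test_view_mismatch_rejected(self):
        with pytest.raises(ValueError, match="view mismatch"):
            estimate_transform(frame_from_rotation(0.0), canonical_frame("section"))


class TestTransformAlgebra:
    @pytest.mark.parametrize("angle,t,scale", [(0.4, (1.0, -2.0), 1.0),
                                               (-1.2, (0.3, 0.7), 1.7)])
    def test_inverse_round_trip(self, rng, angle, t, scale):
        tr = RigidTransform(angle, *t, scale)
        pts = rng.uniform(-5, 5, size=(30, 2))
        assert np.allclose(tr.inverse().apply(tr.apply(pts)), pts, atol=1e-12)

    def test_compose_matches_sequential_application(self, rng):
        a = RigidTransform(0.3, 1.0, -0.5)
        b = RigidTransform(-0.8, 0.2, 2.0)
        pts = rng.uniform(-3, 3, size=(10, 2))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12)


class TestApply:
    def test_identity_preserves_mask(self, rng, small_grid):
        m = random_mask(rng, small_grid)
        img = Mask(m.pixels, small_grid.resolution, "front")
        # image laid out exactly like the grid: translate image-mm -> canonical
        t = RigidTransform(0.0, small_grid.x_range[0], small_grid.second_range[1])
        out = apply_transform(img, t, small_grid)
        assert np.array_equal(out.pixels, m.pixels)

    def test_integer_cell_translation_is_exact_shift(self, rng, small_grid):
        px = np.zeros(small_grid.shape, bool)
        px[40:60, 30:50] = True
        img = Mask(px, small_grid.resolution, "front")
        base = RigidTransform(0.0, small_grid.x_range[0], small_grid.second_range[1])
        shifted = RigidTransform(0.0, base.tx + 5 * 0.02, base.ty - 3 * 0.02)
        out = apply_transform(img, shifted, small_grid)
        assert np.array_equal(out.pixels, np.roll(np.roll(px, 5, axis=1), 3, axis=0))

    def test_rotation_matches_per_pixel_oracle(self, small_grid):
        """90-degree rotation of an asymmetric L equals a brute-force remap."""
        px = np.zeros(small_grid.shape, bool)
        px[45:55, 45:48] = True
        px[52:55, 45:60] = True
        img = Mask(px, small_grid.resolution, "front")
        t = RigidTransform(np.pi / 2, small_grid.x_range[0], small_grid.second_range[1])
        # oracle: forward-classify each atlas cell center one at a time
        inv = t.inverse()
        expected = np.zeros(small_grid.shape, bool)
        xc = small_grid.x_centers()
        sc = small_grid.second_centers()
        for i in range(small_grid.n_rows):
            for j in range(small_grid.n_cols):
                p = inv.apply(np.array([xc[j], sc[i]]))
                col = int(np.floor(p[0] / img.pixel_size))
                row = int(np.floor(-p[1] / img.pixel_size))
                if 0 <= row < px.shape[0] and 0 <= col < px.shape[1]:
                    expected[i, j] = px[row, col]
        out = apply_transform(img, t, small_grid)
        assert np.array_equal(out.pixels, expected)

    def test_rigid_transform_nearly_preserves_area(self, rng, small_grid):
        px = np.zeros(small_grid.shape, bool)
        px[30:70, 25:65] = True
        img = Mask(px, small_grid.resolution, "front")
        base = RigidTransform(0.35, small_grid.x_range[0] + 0.1,
                              small_grid.second_range[1] - 0.07)
        out = apply_transform(img, base, small_grid)
        perimeter = 2 * (40 + 40) * small_grid.resolution
        assert abs(out.area_mm2 - img.area_mm2) <= 2 * perimeter * small_grid.resolution

    def test_mask_outside_grid_warns_and_is_empty(self, small_grid):
        px = np.zeros(small_grid.shape, bool)
        px[10:20, 10:20] = True
        img = Mask(px, small_grid.resolution, "front")
        t = RigidTransform(0.0, 100.0, 100.0)
        with pytest.warns(UserWarning, match="outside"):
            out = apply_transform(img, t, small_grid)
        assert not out.pixels.any()


class TestResidual:
    def test_exact_correspondence_is_zero(self):
        t = RigidTransform(0.0, 0.0, 0.0)
        lms = {"a": (1.0, 2.0), "b": (-1.0, 0.5)}
        assert residual_error(t, lms, lms) == 0.0

    def test_single_offset_rms(self):
        t = RigidTransform(0.0, 0.0, 0.0)
        spec = {"a": (0.0, 0.0), "b": (1.0, 0.0)}
        tmpl = {"a": (0.0, 0.2), "b": (1.0, 0.0)}
        assert residual_error(t, spec, tmpl) == pytest.approx(0.2 / np.sqrt(2))

    def test_empty_correspondence_rejected(self):
        with pytest.raises(ValueError, match="no corresponding"):
            residual_error(RigidTransform(0, 0, 0), {"a": (0, 0)}, {"b": (0, 0)})


class TestGeneratorJitterRecovery:
    def test_noise_free_landmarks_invert_the_jitter(self):
        """Registration on generator-emitted landmarks recovers the inverse
        of the placement jitter to 1e-6."""
        from thyromap.cohort import CohortConfig, generate_specimen, render_views

        cfg = CohortConfig(seed=7)
        s = generate_specimen(cfg, "T06-09", 1234)
        views = render_views(s)
        lms = views["front_landmarks"]
        frame = build_front_frame(
            [lms["upper_border_1"], lms["upper_border_2"]],
            [lms["midline_1"], lms["midline_2"]],
            views["front"].pixel_size,
        )
        t = estimate_transform(frame, canonical_frame("front"))
        expected = s.front_jitter.inverse()
        assert t.angle == pytest.approx(expected.angle, abs=1e-6)
        assert np.allclose(t.translation, expected.translation, atol=1e-6)
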