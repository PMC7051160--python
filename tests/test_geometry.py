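"""Septal midpoint, landmark-grid construction, bbox, padding, crop/resample."""

import numpy as np
import pytest

from tagstrain.geometry import (
    MalformedContourError,
    build_landmark_grid,
    compute_bbox,
    crop_resample,
    normalize_intensity,
    pad_and_fix_frames,
    septal_midpoint,
)
from tagstrain.phantom import deformation_map, make_contours
from tagstrain.types import BBox, ContourPair, PhantomSpec, TaggedCine


def circle(r, c=(0.0, 0.0), n=180, phase=0.0):
    th = phase + np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.asarray(c) + r * np.stack([np.cos(th), np.sin(th)], axis=1)


def contours_with_insertions(a_deg, p_deg, r_endo=25.0, r_epi=40.0):
    def on_epi(deg):
        th = np.deg2rad(deg)
        return r_epi * np.array([np.cos(th), np.sin(th)])
    return ContourPair(circle(r_endo), circle(r_epi), on_epi(a_deg), on_epi(p_deg))


class TestSeptalMidpoint:
    @pytest.mark.parametrize("a, p, expect", [
        (150.0, 210.0, 180.0),
        (170.0, 190.0, 180.0),
        (350.0, 30.0, 10.0),   # wrap-around: shorter-arc bisection
        (30.0, 350.0, 10.0),
    ])
    def test_bisection(self, a, p, expect):
        ang = np.rad2deg(septal_midpoint(contours_with_insertions(a, p)))
        assert ang == pytest.approx(expect, abs=1e-6)

    def test_coincident_insertions_rejected(self):
        with pytest.raises(ValueError):
            septal_midpoint(contours_with_insertions(120.0, 120.0))


class TestBuildLandmarkGrid:
    def test_168_points_on_circular_annulus(self):
        grid = build_landmark_grid(contours_with_insertions(150, 210))
        frame = grid.coords[0]
        assert frame.shape == (7, 24, 2)
        assert frame.reshape(-1, 2).shape[0] == 168

    def test_ring4_radius_is_transmural_midpoint(self):
        grid = build_landmark_grid(contours_with_insertions(150, 210))
        radii = np.linalg.norm(grid.coords[0, 3], axis=-1)
        # 25 + 15 * 4/8 up to the chordal discretization of the 180-gon contour
        assert np.allclose(radii, 25 + 15 * 4 / 8, atol=5e-3)

    def test_spoke1_points_at_septal_midpoint(self):
        contours = contours_with_insertions(150, 210)
        grid = build_landmark_grid(contours)
        ang = np.arctan2(grid.coords[0, 0, 0, 1], grid.coords[0, 0, 0, 0])
        assert np.mod(ang, 2 * np.pi) == pytest.approx(
            septal_midpoint(contours), abs=1e-6)

    def test_rings_strictly_increasing_along_spokes(self):
        grid = build_landmark_grid(contours_with_insertions(10, 80))
        radii = np.linalg.norm(grid.coords[0], axis=-1)  # (7, 24)
        assert np.all(np.diff(radii, axis=0) > 0)

    def test_endo_outside_epi_rejected(self):
        bad = ContourPair(circle(45.0), circle(40.0),
                          np.array([40.0, 0]), np.array([0, 40.0]))
        with pytest.raises(MalformedContourError):
            build_landmark_grid(bad)


class TestComputeBBox:
    def test_worked_enlargement(self):
        # epi extent x in [50,150], y in [60,140]; 60% growth about the center
        epi = np.array([[50.0, 60.0], [150.0, 60.0], [150.0, 140.0],
                        [50.0, 140.0]])
        cont = ContourPair(circle(5, (100, 100)), epi,
                           np.array([50.0, 100.0]), np.array([100.0, 60.0]))
        box = compute_bbox(cont, 0.6)
        assert (box.x_min, box.x_max) == (pytest.approx(20), pytest.approx(180))
        assert (box.y_min, box.y_max) == (pytest.approx(36), pytest.approx(164))

    def test_zero_enlargement_is_tight_extent(self):
        mask = np.zeros((64, 64), bool)
        mask[10:20, 30:50] = True
        box = compute_bbox(mask, 0.0)
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (30, 10, 50, 20)

    def test_clipping_to_image(self):
        mask = np.zeros((64, 64), bool)
        mask[2:62, 2:62] = True
        box = compute_bbox(mask, 0.6, image_shape=(64, 64))
        assert (box.x_min, box.y_min) == (0, 0)
        assert (box.x_max, box.y_max) == (64, 64)

    def test_empty_extent_rejected(self):
        with pytest.raises(ValueError):
            compute_bbox(np.zeros((8, 8), bool), 0.6)

    def test_enlarged_box_contains_myocardium_at_all_frames(self):
        spec = PhantomSpec(noise_sd=0.0)
        cont = make_contours(spec)
        box = compute_bbox(cont, 0.6, pixel_spacing=spec.pixel_spacing)
        for t in range(1, spec.n_frames + 1):
            pts = deformation_map(spec, t).forward(cont.epi) / spec.pixel_spacing
            assert pts[:, 0].min() >= box.x_min and pts[:, 0].max() <= box.x_max
            assert pts[:, 1].min() >= box.y_min and pts[:, 1].max() <= box.y_max


class TestPadAndFixFrames:
    def test_spatial_padding_split(self):
        cine = TaggedCine(np.ones((20, 256, 174)), 1.4)
        out, (py, px) = pad_and_fix_frames(cine)
        assert out.frames.shape == (20, 256, 256)
        assert (py, px) == (0, 41)
        assert np.all(out.frames[:, :, :41] == 0)
        assert np.all(out.frames[:, :, 215:] == 0)
        assert np.all(out.frames[:, :, 41:215] == 1)

    def test_odd_deficit_extra_trailing(self):
        cine = TaggedCine(np.ones((2, 255, 253)), 1.0)
        out, (py, px) = pad_and_fix_frames(cine)
        assert (py, px) == (0, 1)
        assert np.all(out.frames[:, 255, :] == 0)  # trailing row padded
        assert np.all(out.frames[:2, 0:255, 1:254] == 1)  # later frames are padding

    def test_truncates_to_first_20_frames(self):
        frames = np.arange(23)[:, None, None] * np.ones((23, 8, 8))
        out, _ = pad_and_fix_frames(TaggedCine(frames, 1.0))
        assert out.frames.shape[0] == 20
        assert out.frames[19, 128, 128] == 19

    def test_short_cine_padded_with_invalid_frames(self):
        out, _ = pad_and_fix_frames(TaggedCine(np.ones((18, 8, 8)), 1.0))
        assert out.frames.shape[0] == 20
        assert np.all(out.frames[18:] == 0)
        assert out.valid_frames.tolist() == [True] * 18 + [False] * 2

    def test_oversize_input_rejected(self):
        with pytest.raises(ValueError):
            pad_and_fix_frames(TaggedCine(np.ones((2, 300, 256)), 1.0))


class TestCropResample:
    def test_constant_image_stays_constant(self):
        cine = TaggedCine(np.full((3, 64, 64), 7.0), 1.0)
        out, _ = crop_resample(cine, BBox(10, 5, 50, 45))
        assert out.frames.shape == (3, 128, 128)
        assert np.allclose(out.frames, 7.0)

    def test_output_side_is_128(self, clean_truth):
        out, _ = crop_resample(clean_truth.cine, clean_truth.bbox)
        assert out.frames.shape[1:] == (128, 128)

    def test_transform_round_trip(self):
        cine = TaggedCine(np.zeros((1, 256, 256)), 1.4)
        _, tf = crop_resample(cine, BBox(40.5, 60.25, 200.5, 190.75))
        pts = np.random.default_rng(0).uniform(0, 128, (50, 2))
        back = tf.orig_px_to_cropped(tf.cropped_to_orig_px(pts))
        assert np.abs(back - pts).max() < 1e-9
        mm = np.random.default_rng(1).uniform(50, 250, (50, 2))
        there = tf.cropped_to_mm(tf.mm_to_cropped(mm))
        assert np.abs(there - mm).max() < 1e-9

    def test_degenerate_box_rejected(self):
        cine = TaggedCine(np.zeros((1, 64, 64)), 1.0)
        with pytest.raises(ValueError):
            crop_resample(cine, BBox(10, 10, 80, 40))


def test_normalize_intensity_range():
    f = np.random.default_rng(0).normal(5, 3, (4, 16, 16))
    g = normalize_intensity(f)
    assert g.min() == 0.0 and g.max() == 1.0
    assert np.all(normalize_intensity(np.full((2, 4, 4), 3.0)) == 0.0)
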