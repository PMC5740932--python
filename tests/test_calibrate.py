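"""Calibration: rescaling, marker detection, scale recovery, ROI extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafgp import (
    DegenerateGeometryError,
    InvalidInputError,
    MarkerDetectionError,
    MarkerSet,
    RawImage,
    compute_scale,
    denoise,
    detect_reference_markers,
    extract_tray_roi,
    marker_threshold,
    rescale_to_height,
)
from leafgp.calibrate import CalibratedImage, ImageScale, marker_mask
from leafgp.synthetic import MARKER_RGB, SOIL_RGB, disc_mask

from conftest import raw_from_array


def _soil_image(h, w, seed=0):
    rng = np.random.default_rng(seed)
    img = np.clip(
        np.array(SOIL_RGB)[None, None, :] + rng.normal(0, 4, size=(h, w, 3)), 0, 255
    )
    return img.astype(np.uint8)


def _with_discs(img, centres, radius, colour=MARKER_RGB):
    img = img.copy()
    for cx, cy in centres:
        img[disc_mask(img.shape[:2], (cx, cy), radius)] = colour
    return img


class TestRescale:
    @pytest.mark.parametrize(
        "shape,expected_w",
        [((1944, 2592), 1365), ((2848, 4288), 1542), ((1024, 900), 900)],
    )
    def test_height_normalised_and_aspect_kept(self, shape, expected_w):
        raw = raw_from_array(np.zeros((*shape, 3), dtype=np.uint8))
        out = rescale_to_height(raw)
        assert out.pixels.shape == (1024, expected_w, 3)
        # aspect preserved within a pixel
        assert abs(out.width / out.height - raw.width / raw.height) < 1 / 1024

    def test_identity_when_already_target_height(self):
        raw = raw_from_array(np.full((1024, 640, 3), 90, dtype=np.uint8))
        out = rescale_to_height(raw)
        assert out.pixels.shape == (1024, 640, 3)

    def test_input_object_unmodified(self):
        arr = np.full((200, 300, 3), 120, dtype=np.uint8)
        raw = raw_from_array(arr)
        rescale_to_height(raw, 100)
        assert raw.pixels.shape == (200, 300, 3)
        assert (raw.pixels == 120).all()

    def test_idempotent_in_size(self):
        raw = raw_from_array(np.zeros((777, 1234, 3), dtype=np.uint8))
        once = rescale_to_height(raw)
        twice = rescale_to_height(once)
        assert once.pixels.shape == twice.pixels.shape

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidInputError):
            RawImage(pixels=np.zeros((0, 10, 3), dtype=np.uint8))


class TestMarkerThreshold:
    @pytest.mark.parametrize(
        "pixel,expected",
        [
            ((255, 0, 0), 1),
            ((100, 100, 100), 0),  # fails r > 125
            ((200, 160, 100), 0),  # r - g = 40, fails > 50
            ((200, 100, 230), 0),  # fails b < 225
            ((126, 75, 224), 1),  # all three conditions just pass
        ],
    )
    def test_threshold_rules(self, pixel, expected):
        assert marker_threshold(pixel) == expected

    @given(
        r=st.integers(0, 255), g=st.integers(0, 255),
        b1=st.integers(0, 224), b2=st.integers(0, 224),
    )
    @settings(derandomize=True, max_examples=80)
    def test_blue_independent_below_ceiling(self, r, g, b1, b2):
        assert marker_threshold((r, g, b1)) == marker_threshold((r, g, b2))

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(13, 17, 3), dtype=np.uint8)
        mask = marker_mask(img)
        for y in range(13):
            for x in range(17):
                assert mask[y, x] == bool(marker_threshold(img[y, x]))


class TestMarkerDetection:
    CENTRES = [(40, 40), (600, 40), (600, 460), (40, 460)]

    def test_four_discs_found_with_radius(self):
        img = _with_discs(_soil_image(500, 640), self.CENTRES, 20)
        ms = detect_reference_markers(raw_from_array(img))
        assert len(ms.markers) == 4
        assert ms.mean_radius_px == pytest.approx(20, rel=0.05)
        got = sorted((round(x), round(y)) for x, y, _ in ms.markers)
        assert got == sorted(self.CENTRES)

    def test_red_bar_rejected_by_shape_filter(self):
        img = _with_discs(_soil_image(500, 640), self.CENTRES, 20)
        img[240:248, 280:360] = MARKER_RGB  # 80 x 8 red bar
        ms = detect_reference_markers(raw_from_array(img))
        assert len(ms.markers) == 4
        assert ms.mean_radius_px == pytest.approx(20, rel=0.05)

    def test_extra_disc_resolved_by_corner_proximity(self):
        img = _with_discs(_soil_image(500, 640), self.CENTRES + [(320, 250)], 20)
        ms = detect_reference_markers(raw_from_array(img))
        got = sorted((round(x), round(y)) for x, y, _ in ms.markers)
        assert got == sorted(self.CENTRES)

    def test_no_red_pixels_reports_zero(self):
        with pytest.raises(MarkerDetectionError) as exc:
            detect_reference_markers(raw_from_array(_soil_image(300, 300)))
        assert exc.value.n_found == 0

    def test_three_markers_named_in_error(self):
        img = _with_discs(_soil_image(500, 640), self.CENTRES[:3], 20)
        with pytest.raises(MarkerDetectionError) as exc:
            detect_reference_markers(raw_from_array(img))
        assert exc.value.n_found == 3

    @pytest.mark.parametrize("radius", [10, 20, 40])
    def test_scale_recovery_within_5pct(self, radius):
        margin = 3 * radius
        centres = [(margin, margin), (600, margin), (600, 460), (margin, 460)]
        img = _with_discs(_soil_image(500, 640), centres, radius)
        ms = detect_reference_markers(raw_from_array(img))
        scale = compute_scale(ms, 4.0)
        assert scale.px_per_mm == pytest.approx(radius / 4.0, rel=0.05)


class TestComputeScale:
    def _markers(self, radius):
        return MarkerSet(
            markers=tuple((x, y, radius) for x, y in [(0, 0), (9, 0), (9, 9), (0, 9)])
        )

    def test_arabidopsis_default(self):
        assert compute_scale(self._markers(20), 4.0).px_per_mm == 5.0

    def test_wheat_radius(self):
        assert compute_scale(self._markers(20), 5.0).px_per_mm == 4.0

    def test_zero_radius_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            compute_scale(self._markers(20), 0.0)


class TestExtractRoi:
    def _scale(self):
        return ImageScale(px_per_mm=5.0, marker_radius_mm=4.0)

    def test_axis_aligned_rectangle_is_cropped(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, size=(500, 640, 3), dtype=np.uint8)
        ms = MarkerSet(
            markers=((40.0, 50.0, 20.0), (600.0, 50.0, 20.0),
                     (600.0, 450.0, 20.0), (40.0, 450.0, 20.0))
        )
        roi = extract_tray_roi(raw_from_array(img), ms, self._scale())
        assert roi.pixels.shape == (400, 560, 3)
        # interior pixels match the crop (borders may blur by interpolation)
        crop = img[50:450, 40:600]
        inner = (slice(5, -5), slice(5, -5))
        assert np.mean(np.abs(roi.pixels[inner].astype(int) - crop[inner].astype(int))) < 3

    def test_rotated_square_straightened(self):
        # square of side 300 rotated 30° about the image centre
        c = np.array([400, 400])
        side = 300.0
        base = np.array([(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)]) * side
        th = np.deg2rad(30)
        rot = np.array([(np.cos(th), -np.sin(th)), (np.sin(th), np.cos(th))])
        corners = base @ rot.T + c
        ms = MarkerSet(markers=tuple((x, y, 10.0) for x, y in corners))
        img = raw_from_array(np.zeros((800, 800, 3), dtype=np.uint8))
        roi = extract_tray_roi(img, ms, self._scale())
        assert abs(roi.height - side) <= 1 and abs(roi.width - side) <= 1

    def test_three_markers_rejected_at_construction(self):
        with pytest.raises(MarkerDetectionError):
            MarkerSet(markers=((0, 0, 5), (10, 0, 5), (10, 10, 5)))

    def test_collinear_centres_rejected(self):
        ms = MarkerSet(
            markers=((0.0, 0.0, 5.0), (10.0, 0.0, 5.0), (20.0, 0.0, 5.0), (30.0, 0.0, 5.0))
        )
        with pytest.raises(DegenerateGeometryError):
            extract_tray_roi(
                raw_from_array(np.zeros((100, 100, 3), dtype=np.uint8)),
                ms, self._scale(),
            )

    def test_marker_distance_in_mm_matches_geometry(self, small_tray):
        """End to end: ROI width in mm equals the generated marker spacing."""
        from leafgp import calibrate_image

        params, img, truth = small_tray
        roi = calibrate_image(raw_from_array(img), params.marker_radius_mm)
        x0, y0, x1, y1 = truth.roi_bbox
        expected_mm = (x1 - x0) / truth.px_per_mm
        assert roi.width / roi.scale.px_per_mm == pytest.approx(expected_mm, rel=0.02)


class TestDenoise:
    def _calibrated(self, arr):
        return CalibratedImage(
            pixels=arr, scale=ImageScale(px_per_mm=5.0, marker_radius_mm=4.0)
        )

    def test_uniform_image_unchanged(self):
        img = self._calibrated(np.full((60, 80, 3), 128, dtype=np.uint8))
        out = denoise(img)
        assert (out.pixels == 128).all()

    def test_salt_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        arr = np.full((100, 100, 3), 100, dtype=np.uint8)
        salt = rng.random((100, 100)) < 0.05
        arr[salt] = 255
        out = denoise(self._calibrated(arr))
        assert out.pixels[..., 1].var() < arr[..., 1].var()

    def test_shape_and_scale_preserved(self):
        img = self._calibrated(np.zeros((900, 1024, 3), dtype=np.uint8))
        out = denoise(img)
        assert out.pixels.shape == (900, 1024, 3)
        assert out.scale is img.scale
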