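"""Well detection: thresholding, contour shape filters, grid assignment."""

import numpy as np
import pytest

from cadmilume import (
    PlateLayout,
    RasterImage,
    WellDetection,
    assign_grid,
    binarize,
    default_layout,
    detect_wells,
    to_detection_channel,
)
from cadmilume.errors import (
    DegenerateHistogramError,
    GridInferenceError,
    InputError,
    LayoutMismatchError,
)
from cadmilume.layout import WellRole


def brute_force_otsu(channel):
    """Exhaustive between-class-variance scan over all 8-bit thresholds."""
    hist = np.bincount(channel.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    values = np.arange(256)
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (values[: t + 1] * hist[: t + 1]).sum() / w0
        mu1 = (values[t + 1 :] * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestDetectionChannel:
    @pytest.mark.parametrize(
        "rgb,expected", [((10, 200, 30), 200), ((100, 100, 100), 100), ((0, 0, 0), 0)]
    )
    def test_per_pixel_max(self, rgb, expected):
        img = RasterImage(np.full((4, 5, 3), rgb, dtype=np.uint8))
        assert (to_detection_channel(img) == expected).all()

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(InputError):
            RasterImage(np.zeros((4, 5, 2), dtype=np.uint8))


class TestBinarize:
    def test_two_level_grid_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        channel = np.full((60, 60), 10, dtype=np.uint8)
        yy, xx = np.mgrid[0:60, 0:60]
        disks = ((xx - 20) ** 2 + (yy - 20) ** 2 <= 100) | (
            (xx - 45) ** 2 + (yy - 40) ** 2 <= 100
        )
        channel[disks] = 200
        mask, thresh = binarize(channel, opening_radius=0)
        oracle = brute_force_otsu(channel)
        assert thresh == oracle
        assert (mask == disks).all()

    def test_otsu_equals_oracle_on_random_bimodal_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = rng.normal(60, 10, 800).clip(0, 255)
            b = rng.normal(180, 15, 400).clip(0, 255)
            channel = np.concatenate([a, b]).astype(np.uint8).reshape(40, 30)
            _, thresh = binarize(channel, opening_radius=0)
            assert thresh == brute_force_otsu(channel)

    def test_constant_grid_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            binarize(np.full((10, 10), 50, dtype=np.uint8))

    def test_opening_removes_speck(self):
        channel = np.zeros((40, 40), dtype=np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (xx - 20) ** 2 + (yy - 20) ** 2 <= 64
        channel[disk] = 200
        channel[2, 2] = 200
        channel[2, 3] = 200  # 2-pixel speck
        mask, _ = binarize(channel, opening_radius=1)
        assert not mask[2, 2] and not mask[2, 3]
        assert mask[20, 20]

    def test_fixed_threshold(self):
        channel = np.array([[10, 100], [150, 200]], dtype=np.uint8)
        mask, thresh = binarize(channel, method="fixed", fixed_threshold=120,
                                opening_radius=0)
        assert thresh == 120
        assert mask.tolist() == [[False, False], [True, True]]


class TestDetectWells:
    def test_empty_mask_gives_empty_list(self):
        assert detect_wells(np.zeros((30, 30), dtype=bool)) == []

    def test_disk_centroid_and_radius_match_pixel_oracle(self):
        yy, xx = np.mgrid[0:120, 0:130]
        disk = (xx - 50) ** 2 + (yy - 60) ** 2 <= 20**2
        dets = detect_wells(disk)
        assert len(dets) == 1
        d = dets[0]
        # oracle: centroid and equivalent radius from the exact pixel set
        ys, xs = np.nonzero(disk)
        assert d.center_x == pytest.approx(xs.mean(), abs=1.0)
        assert d.center_y == pytest.approx(ys.mean(), abs=1.0)
        assert d.radius == pytest.approx(np.sqrt(disk.sum() / np.pi), rel=1e-9)
        assert abs(d.radius - 20) / 20 < 0.05
        assert d.area == disk.sum()

    def test_speck_below_min_area_is_dropped(self):
        yy, xx = np.mgrid[0:100, 0:100]
        mask = (xx - 40) ** 2 + (yy - 40) ** 2 <= 20**2
        mask[5, 5:10] = True  # 5-px speck
        dets = detect_wells(mask, min_area=100)
        assert len(dets) == 1
        assert dets[0].area == pytest.approx(np.pi * 400, rel=0.05)

    def test_elongated_streak_fails_circularity(self):
        mask = np.zeros((60, 200), dtype=bool)
        mask[28:33, 10:190] = True  # 5 x 180 glare streak
        assert detect_wells(mask, min_circularity=0.6) == []

    @pytest.mark.parametrize("shift", [(3, 0), (0, 7), (5, 11)])
    def test_translation_equivariance(self, shift):
        dy, dx = shift
        yy, xx = np.mgrid[0:150, 0:150]
        mask = (xx - 40) ** 2 + (yy - 50) ** 2 <= 15**2
        moved = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
        d0, d1 = detect_wells(mask)[0], detect_wells(moved)[0]
        assert d1.center_x - d0.center_x == pytest.approx(dx, abs=1e-9)
        assert d1.center_y - d0.center_y == pytest.approx(dy, abs=1e-9)

    def test_all_wells_found_on_noiseless_render(self, noiseless_spec, noiseless_render):
        image, truth = noiseless_render
        mask, _ = binarize(to_detection_channel(image))
        dets = detect_wells(mask)
        assert len(dets) == len(truth)
        positions = {(r, c): (x, y) for r, c, _, x, y in noiseless_spec.well_positions()}
        dets = assign_grid(dets, noiseless_spec.layout)
        for d in dets:
            x, y = positions[(d.grid_row, d.grid_col)]
            assert d.center_x == pytest.approx(x, abs=1.0)
            assert d.center_y == pytest.approx(y, abs=1.0)


def _detections_at(centers, radius=18.0):
    area = np.pi * radius**2
    return [
        WellDetection(center_x=x, center_y=y, radius=radius, area=area, circularity=0.95)
        for x, y in centers
    ]


def _grid_centers(rows_cols, pitch=60.0, origin=(40.0, 40.0)):
    return [(origin[0] + c * pitch, origin[1] + r * pitch) for r, c in rows_cols]


class TestAssignGrid:
    def test_nine_over_four_matches_layout_convention(self):
        layout = default_layout(n_samples=4)
        cells = [(0, c) for c in range(9)] + [(1, c) for c in range(4)]
        dets = _detections_at(_grid_centers(cells))
        assigned = assign_grid(dets, layout)
        assert [(d.grid_row, d.grid_col) for d in assigned] == cells
        top = [d for d in assigned if d.grid_row == 0]
        assert len(top) == 9  # control + 8 standards in the upper row
        assert all(layout.cells[0][d.grid_col].is_calibration for d in top)
        assert all(layout.cells[1][d.grid_col].role == "sample"
                   for d in assigned if d.grid_row == 1)

    def test_single_detection_single_cell_layout(self):
        layout = PlateLayout(1, 1, [[WellRole("sample", label="S1")]])
        (d,) = assign_grid(_detections_at([(50.0, 50.0)]), layout)
        assert (d.grid_row, d.grid_col) == (0, 0)

    def test_rotation_by_three_degrees_preserves_assignment(self):
        layout = default_layout(n_samples=4)
        cells = [(0, c) for c in range(9)] + [(1, c) for c in range(4)]
        centers = np.array(_grid_centers(cells))
        theta = np.deg2rad(3.0)
        pivot = np.array([280.0, 72.0])
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = (centers - pivot) @ rot.T + pivot
        assigned = assign_grid(_detections_at([tuple(p) for p in rotated]), layout)
        assert [(d.grid_row, d.grid_col) for d in assigned] == cells

    def test_count_mismatch_reports_counts(self):
        layout = default_layout(n_samples=4)
        with pytest.raises(LayoutMismatchError, match="12 detections.*13"):
            assign_grid(_detections_at(_grid_centers([(0, c) for c in range(12)])), layout)

    def test_wrong_row_sizes_fail_inference(self):
        layout = default_layout(n_samples=4)  # expects 9 over 4
        cells = [(0, c) for c in range(7)] + [(1, c) for c in range(6)]
        with pytest.raises(GridInferenceError):
            assign_grid(_detections_at(_grid_centers(cells)), layout)

    def test_assignment_is_bijective(self, noiseless_spec, noiseless_render):
        image, _ = noiseless_render
        mask, _ = binarize(to_detection_channel(image))
        assigned = assign_grid(detect_wells(mask), noiseless_spec.layout)
        keys = [(d.grid_row, d.grid_col) for d in assigned]
        assert len(set(keys)) == len(keys)
        assert set(keys) == {(r, c) for r, c, _ in noiseless_spec.layout.occupied()}
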