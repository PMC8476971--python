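"""DICOM/ROI round trips, polygon rasterization, orientation handling."""

import json

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from ardsqct import dicom_io, phantom


def make_slice(raw, z, spacing=(1.0, 1.0), thickness=5.0, position="HFS"):
    return dicom_io.CTSlice(
        raw_pixels=np.asarray(raw),
        rescale_slope=1.0,
        rescale_intercept=-1024.0,
        pixel_spacing_mm=spacing,
        slice_thickness_mm=thickness,
        z_position_mm=z,
        patient_position=position,
        prone_flag=position in dicom_io.PRONE_POSITIONS,
    )


class TestRawToHu:
    @pytest.mark.parametrize(
        "raw,slope,intercept,expected",
        [(1024, 1.0, -1024.0, 0.0), (0, 1.0, -1024.0, -1024.0), (3000, 0.5, -1000.0, 500.0)],
    )
    def test_rescale_formula(self, raw, slope, intercept, expected):
        sl = make_slice(np.full((2, 2), raw, dtype=np.int32), z=0.0)
        sl.rescale_slope = slope
        sl.rescale_intercept = intercept
        assert dicom_io.raw_to_hu(sl)[0, 0] == expected


class TestDicomSeries:
    def test_round_trip_preserves_hu_spacing_order(self, tmp_path, noiseless_spec):
        vol, _ = phantom.generate_phantom(noiseless_spec)
        dicom_io.write_dicom_series(vol, tmp_path)
        back = dicom_io.read_dicom_series(tmp_path)
        assert np.array_equal(vol.hu(), back.hu())
        assert back.pixel_spacing_mm == vol.pixel_spacing_mm
        assert back.slice_thickness_mm == vol.slice_thickness_mm
        assert [s.z_position_mm for s in back.slices] == [s.z_position_mm for s in vol.slices]

    def test_slices_sorted_cranial_first(self, tmp_path):
        # write slices with shuffled z; cranial (largest z) must come first
        slices = [make_slice(np.full((4, 4), i, dtype=np.int32), z=z)
                  for i, z in enumerate([10.0, 0.0, 20.0])]
        for i, sl in enumerate(slices):
            vol = dicom_io.CTVolume(slices=[sl])
            dicom_io.write_dicom_series(vol, tmp_path / f"s{i}")
        merged = tmp_path / "merged"
        merged.mkdir()
        for i in range(3):
            src = next((tmp_path / f"s{i}").iterdir())
            (merged / f"f{i}.dcm").write_bytes(src.read_bytes())
        back = dicom_io.read_dicom_series(merged)
        assert [s.z_position_mm for s in back.slices] == [20.0, 10.0, 0.0]

    def test_single_file_volume(self, tmp_path):
        vol = dicom_io.CTVolume(slices=[make_slice(np.zeros((4, 4), np.int32), z=0.0)])
        dicom_io.write_dicom_series(vol, tmp_path)
        back = dicom_io.read_dicom_series(tmp_path)
        assert back.shape == (1, 4, 4)

    def test_stored_values_are_hu_plus_1024(self, tmp_path):
        import pydicom

        vol = dicom_io.CTVolume(slices=[make_slice(np.full((2, 2), 524, np.int32), z=0.0)])
        # raw 524 with intercept -1024 means HU = -500
        dicom_io.write_dicom_series(vol, tmp_path)
        ds = pydicom.dcmread(next(tmp_path.iterdir()))
        assert ds.pixel_array[0, 0] == -500 + 1024

    def test_duplicate_z_positions_error(self, tmp_path):
        for i in range(2):
            vol = dicom_io.CTVolume(slices=[make_slice(np.zeros((4, 4), np.int32), z=5.0)])
            dicom_io.write_dicom_series(vol, tmp_path / f"s{i}")
        merged = tmp_path / "merged"
        merged.mkdir()
        for i in range(2):
            src = next((tmp_path / f"s{i}").iterdir())
            (merged / f"f{i}.dcm").write_bytes(src.read_bytes())
        with pytest.raises(ValueError, match="duplicate"):
            dicom_io.read_dicom_series(merged)

    def test_mixed_shapes_error(self):
        with pytest.raises(ValueError, match="mixed"):
            dicom_io.CTVolume(
                slices=[
                    make_slice(np.zeros((4, 4), np.int32), z=0.0),
                    make_slice(np.zeros((8, 8), np.int32), z=5.0),
                ]
            )


class TestROI:
    def test_json_round_trip(self, tmp_path):
        contour = dicom_io.ROIContour(
            {0: [np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0]])],
             2: [np.array([[1.0, 1.0], [3.0, 1.0], [3.0, 3.0], [1.0, 3.0]])]}
        )
        path = tmp_path / "roi.json"
        dicom_io.write_roi(contour, path)
        back = dicom_io.read_roi(path)
        assert set(back.slices) == {0, 2}
        for k in back.slices:
            for a, b in zip(contour.slices[k], back.slices[k]):
                assert np.array_equal(a, b)

    def test_empty_contours_valid(self, tmp_path):
        path = tmp_path / "roi.json"
        path.write_text(json.dumps({"slices": []}))
        back = dicom_io.read_roi(path)
        assert back.slices == {}

    def test_out_of_range_index_error(self, tmp_path):
        path = tmp_path / "roi.json"
        path.write_text(json.dumps({"slices": [{"index": 9, "polygons": [[[0, 0], [1, 0], [1, 1]]]}]}))
        with pytest.raises(ValueError, match="out of volume range"):
            dicom_io.read_roi(path, n_slices=5)

    def test_malformed_polygon_error(self):
        with pytest.raises(ValueError, match="polygon"):
            dicom_io.ROIContour({0: [np.array([[0.0, 0.0], [1.0, 1.0]])]})

    def test_mask_png_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        mask = (rng.random((3, 16, 16)) > 0.5).astype(np.uint8)
        dicom_io.write_mask_pngs(mask, tmp_path)
        back = dicom_io.read_mask_pngs(tmp_path)
        assert np.array_equal(mask, back)


def random_simple_polygon(rng, grid):
    """Random star-convex polygon (simple by construction)."""
    n = int(rng.integers(3, 9))
    cx, cy = rng.uniform(grid * 0.3, grid * 0.7, size=2)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(grid * 0.08, grid * 0.28, size=n)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return np.column_stack([xs, ys])


class TestRasterization:
    def test_no_polygons_gives_empty_mask(self):
        assert dicom_io.rasterize_polygons([], (8, 8)).sum() == 0

    def test_rectangle_with_corners_at_pixel_centers(self):
        poly = [np.array([[0.0, 0.0], [9.0, 0.0], [9.0, 9.0], [0.0, 9.0]])]
        mask = dicom_io.rasterize_polygons(poly, (12, 12))
        assert mask.sum() == 100  # boundary counts as inside

    def test_disjoint_polygons_are_additive(self):
        p1 = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 3.0], [0.0, 3.0]])
        p2 = p1 + 10.0
        m1 = dicom_io.rasterize_polygons([p1], (20, 20))
        m2 = dicom_io.rasterize_polygons([p2], (20, 20))
        both = dicom_io.rasterize_polygons([p1, p2], (20, 20))
        assert both.sum() == m1.sum() + m2.sum()

    def test_matches_shapely_covers_oracle(self, rng):
        """Pixel-center inclusion must agree with an independent geometric oracle."""
        for _ in range(20):
            grid = int(rng.integers(16, 65))
            poly = random_simple_polygon(rng, grid)
            mask = dicom_io.rasterize_polygons([poly], (grid, grid))
            shp = Polygon(poly)
            oracle = np.zeros((grid, grid), dtype=np.uint8)
            for r in range(grid):
                for c in range(grid):
                    if shp.covers(Point(c, r)):
                        oracle[r, c] = 1
            assert np.array_equal(mask, oracle)


class TestOrientation:
    def test_supine_identity(self, noiseless_spec):
        vol, truth = phantom.generate_phantom(noiseless_spec)
        out, mask = dicom_io.orient_supine(vol, truth.mask)
        assert np.array_equal(out.hu(), vol.hu())
        assert np.array_equal(mask, truth.mask)

    def test_rot180_is_involution(self, rng):
        grid = rng.normal(size=(3, 8, 8))
        assert np.array_equal(dicom_io.rot180(dicom_io.rot180(grid)), grid)

    def test_prone_marker_moves_to_opposite_corner(self):
        raw = np.zeros((6, 8), dtype=np.int32)
        raw[1, 2] = 100
        sl = make_slice(raw, z=0.0, position="HFP")
        vol = dicom_io.CTVolume(slices=[sl])
        out, _ = dicom_io.orient_supine(vol)
        rotated = out.slices[0].raw_pixels
        assert rotated[6 - 1 - 1, 8 - 1 - 2] == 100
        assert rotated[1, 2] == 0
        assert out.slices[0].prone_flag is False

    def test_prone_mask_rotated_identically(self):
        raw = np.zeros((4, 4), dtype=np.int32)
        mask = np.zeros((1, 4, 4), dtype=np.uint8)
        mask[0, 0, 1] = 1
        vol = dicom_io.CTVolume(slices=[make_slice(raw, z=0.0, position="FFP")])
        _, out_mask = dicom_io.orient_supine(vol, mask)
        assert out_mask[0, 3, 2] == 1 and out_mask.sum() == 1

    def test_unknown_position_passes_through_with_warning(self, caplog):
        raw = np.arange(16, dtype=np.int32).reshape(4, 4)
        vol = dicom_io.CTVolume(slices=[make_slice(raw, z=0.0, position="other")])
        with caplog.at_level("WARNING"):
            out, _ = dicom_io.orient_supine(vol)
        assert np.array_equal(out.slices[0].raw_pixels, raw)
        assert any("unknown patient position" in m for m in caplog.messages)
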