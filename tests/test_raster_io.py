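from __future__ import annotations

import numpy as np
import pytest
import tifffile
from PIL import Image

from vesselquant.config import AnalysisConfig
from vesselquant.metrics import AnalysisResult, convex_hull
from vesselquant.raster_io import (
    RESULT_COLUMNS,
    FormatError,
    OverlayStyle,
    RasterImage,
    load_image,
    read_results,
    render_overlay,
    render_overlay_array,
    results_frame,
    write_results,
)
from vesselquant.skeleton_graph import build_graph

from conftest import hline, make_mask, plus_skeleton


def _result(image_id="img", **over):
    base = dict(
        explant_area=123.456789012345,
        vessel_area=55.5,
        vessel_density=44.96123456789012,
        total_junctions=7,
        branching_index=0.5671234567890123,
        total_vessel_length=321.0987654321098,
        average_vessel_length=32.1,
        total_endpoints=9,
        mean_lacunarity=1.2345678901234567,
    )
    base.update(over)
    return AnalysisResult(
        lacunarity_curve=((2, 1.5), (4, 1.1)),
        config_echo=AnalysisConfig(),
        image_id=image_id,
        **base,
    )


class TestRasterImage:
    def test_invariants(self):
        img = RasterImage(np.full((4, 5), 7, dtype=np.uint8))
        assert img.height == 4 and img.width == 5
        assert img.bit_depth == 8 and img.intensity_max == 255

    def test_rejects_small(self):
        with pytest.raises(FormatError, match="too small"):
            RasterImage(np.zeros((2, 2), dtype=np.uint8))

    def test_rejects_out_of_range(self):
        with pytest.raises(FormatError, match="range"):
            RasterImage(np.full((4, 4), 300, dtype=np.uint16), bit_depth=8)

    def test_rejects_bad_depth(self):
        with pytest.raises(FormatError, match="bit depth"):
            RasterImage(np.zeros((4, 4), dtype=np.uint8), bit_depth=12)

    def test_normalized(self):
        img = RasterImage(np.full((3, 3), 51, dtype=np.uint8))
        assert np.allclose(img.normalized(), 0.2)


class TestLoadImage:
    def test_grey_tiff_passthrough(self, tmp_path):
        arr = np.full((64, 64), 7, dtype=np.uint8)
        path = tmp_path / "grey.tif"
        tifffile.imwrite(path, arr)
        img = load_image(path)
        assert img.bit_depth == 8
        assert np.array_equal(img.pixels, arr)  # byte-identical
        assert img.source_id == "grey.tif"

    def test_16bit_tiff(self, tmp_path):
        arr = (np.arange(25, dtype=np.uint16) * 1000).reshape(5, 5)
        path = tmp_path / "deep.tif"
        tifffile.imwrite(path, arr)
        img = load_image(path)
        assert img.bit_depth == 16
        assert np.array_equal(img.pixels, arr)

    def test_max_channel(self, tmp_path):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[0, 0] = (255, 0, 0)
        rgb[1, 1] = (10, 20, 30)
        path = tmp_path / "c.png"
        Image.fromarray(rgb).save(path)
        img = load_image(path, channel_policy="max_channel")
        assert img.pixels[0, 0] == 255
        assert img.pixels[1, 1] == 30

    def test_luminance_weighted_sum(self, tmp_path):
        # oracle: 0.299*100 + 0.587*200 + 0.114*50 = 153.0
        rgb = np.zeros((3, 3, 3), dtype=np.uint8)
        rgb[:] = (100, 200, 50)
        path = tmp_path / "l.png"
        Image.fromarray(rgb).save(path)
        img = load_image(path, channel_policy="luminance")
        assert int(img.pixels[1, 1]) == 153

    def test_single_channel_policy(self, tmp_path):
        rgb = np.zeros((3, 3, 3), dtype=np.uint8)
        rgb[:] = (11, 22, 33)
        path = tmp_path / "s.png"
        Image.fromarray(rgb).save(path)
        assert load_image(path, channel_policy="channel:1").pixels[0, 0] == 22

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError, match="does not exist"):
            load_image(tmp_path / "nope.tif")

    def test_unsupported_dtype_names_property(self, tmp_path):
        path = tmp_path / "f.tif"
        tifffile.imwrite(path, np.zeros((4, 4), dtype=np.float32))
        with pytest.raises(FormatError, match="float32"):
            load_image(path)

    def test_idempotent_on_grey(self, tmp_path):
        arr = (np.arange(36) * 7 % 256).astype(np.uint8).reshape(6, 6)
        path = tmp_path / "g.png"
        Image.fromarray(arr).save(path)
        a = load_image(path)
        b = load_image(path)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.pixels, arr)


class TestWriteResults:
    def test_header_and_single_row(self, tmp_path):
        path = write_results([_result()], tmp_path / "r.csv")
        lines = path.read_text().splitlines()
        assert lines[0] == ",".join(RESULT_COLUMNS)
        assert len(lines) == 2

    def test_two_rows_distinguished(self, tmp_path):
        path = write_results([_result("a.tif"), _result("b.tif")], tmp_path / "r.csv")
        frame = read_results(path)
        assert list(frame["image_id"]) == ["a.tif", "b.tif"]
        assert len(frame) == 2

    def test_csv_roundtrip_12_sig_digits(self, tmp_path):
        res = _result()
        path = write_results([res], tmp_path / "r.csv")
        row = read_results(path).iloc[0]
        for col, val in [
            ("explant_area", res.explant_area),
            ("vessel_density_pct", res.vessel_density),
            ("branching_index", res.branching_index),
            ("total_vessel_length", res.total_vessel_length),
            ("mean_lacunarity", res.mean_lacunarity),
        ]:
            assert row[col] == pytest.approx(val, rel=1e-12)
        assert int(row["total_junctions"]) == res.total_junctions
        assert int(row["total_endpoints"]) == res.total_endpoints

    def test_config_echo_columns(self, tmp_path):
        path = write_results([_result()], tmp_path / "r.csv")
        row = read_results(path).iloc[0]
        cfg = AnalysisConfig()
        assert row["v_min"] == cfg.v_min
        assert row["sigmas"] == ";".join(format(s, "g") for s in cfg.sigmas)

    def test_xlsx_mirror(self, tmp_path):
        res = _result()
        path = write_results([res], tmp_path / "r.xlsx", format="xlsx")
        frame = read_results(path, format="xlsx")
        assert list(frame.columns) == RESULT_COLUMNS
        assert frame.iloc[0]["total_junctions"] == res.total_junctions

    def test_requires_results(self, tmp_path):
        with pytest.raises(ValueError):
            results_frame([])


class TestRenderOverlay:
    def _image(self, grid):
        arr = np.where(grid, 200, 10).astype(np.uint8)
        return RasterImage(arr)

    def test_empty_mask_is_background(self):
        img = RasterImage(np.full((12, 12), 30, dtype=np.uint8))
        empty = make_mask(np.zeros((12, 12), bool))
        out = render_overlay_array(img, mask=empty)
        base = np.rint(img.normalized() * 255).astype(np.uint8)
        assert np.array_equal(out, np.stack([base] * 3, axis=2))

    def test_straight_tube_zero_markers_one_polyline(self):
        grid = hline(10, pad=3)
        mask = make_mask(grid)
        graph = build_graph(mask)
        out = render_overlay_array(self._image(grid), mask, graph, convex_hull(mask),
                                   style=OverlayStyle(draw_hull=False))
        style = OverlayStyle()
        junction_px = np.all(out == style.junction_rgb, axis=2)
        assert junction_px.sum() == 0
        skel_px = np.all(out == style.skeleton_rgb, axis=2)
        from scipy import ndimage

        n = ndimage.label(skel_px, structure=np.ones((3, 3)))[1]
        assert n == 1

    def test_plus_network_one_marker(self):
        grid = plus_skeleton(13)
        mask = make_mask(grid)
        graph = build_graph(mask)
        out = render_overlay_array(self._image(grid), mask, graph,
                                   style=OverlayStyle(draw_hull=False))
        style = OverlayStyle()
        junction_px = np.all(out == style.junction_rgb, axis=2)
        from scipy import ndimage

        assert ndimage.label(junction_px, structure=np.ones((3, 3)))[1] == 1

    def test_dimension_mismatch(self):
        img = RasterImage(np.zeros((8, 8), dtype=np.uint8))
        mask = make_mask(np.zeros((9, 9), bool))
        with pytest.raises(ValueError, match="shape"):
            render_overlay_array(img, mask=mask)

    def test_pure_output(self, tmp_path):
        grid = plus_skeleton(13)
        img = self._image(grid)
        before = img.pixels.copy()
        mask = make_mask(grid)
        graph = build_graph(mask)
        skel_before = graph.skeleton.copy()
        render_overlay(img, mask, graph, convex_hull(mask), tmp_path / "o.png")
        assert np.array_equal(img.pixels, before)
        assert np.array_equal(graph.skeleton, skel_before)
        assert (tmp_path / "o.png").exists()

    def test_same_dimensions(self, tmp_path):
        grid = hline(10, pad=3)
        img = self._image(grid)
        out = render_overlay_array(img, make_mask(grid))
        assert out.shape == (img.height, img.width, 3)
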