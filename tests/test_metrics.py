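from __future__ import annotations

import numpy as np
import pytest

from vesselquant.config import AnalysisConfig
from vesselquant.metrics import (
    NoVesselsError,
    UndefinedLacunarityError,
    analyze,
    branching_index,
    convex_hull,
    default_box_sizes,
    lacunarity,
    length_metrics,
    run_pipeline,
    vessel_density,
)
from vesselquant.raster_io import RasterImage
from vesselquant.segment import VesselMask
from vesselquant.skeleton_graph import build_graph
from vesselquant.synthetic import NetworkSpec, degrade, generate_tree

from conftest import hline, make_mask, plus_skeleton, random_masks
from oracles import mc_polygon_area


class TestConvexHull:
    def test_single_pixel_unit_square(self):
        g = np.zeros((5, 5), bool)
        g[2, 3] = True
        hull = convex_hull(make_mask(g))
        assert hull.area == pytest.approx(1.0)

    def test_filled_square(self):
        g = np.zeros((14, 14), bool)
        g[2:12, 2:12] = True
        assert convex_hull(make_mask(g)).area == pytest.approx(100.0)

    def test_triangle_against_monte_carlo(self):
        g = np.zeros((12, 12), bool)
        g[0, 0] = g[0, 9] = g[9, 0] = True
        hull = convex_hull(make_mask(g))
        mc = mc_polygon_area(hull.vertices, n=400_000, seed=4)
        assert hull.area == pytest.approx(mc, rel=0.01)

    def test_contains_foreground_area(self):
        for m in random_masks(20, seed=41):
            mask = make_mask(m)
            assert convex_hull(mask).area >= mask.foreground_count - 1e-9

    def test_pixel_size_scaling(self):
        g = np.zeros((8, 8), bool)
        g[2:6, 2:6] = True
        a1 = convex_hull(VesselMask(g, pixel_size=1.0)).area
        a2 = convex_hull(VesselMask(g, pixel_size=2.0)).area
        assert a2 == pytest.approx(4 * a1)

    def test_empty_mask_defined_empty(self):
        hull = convex_hull(make_mask(np.zeros((5, 5), bool)))
        assert hull.is_empty and hull.area == 0.0
        with pytest.raises(ValueError):
            vessel_density(make_mask(np.zeros((5, 5), bool)), hull)
        with pytest.raises(ValueError):
            branching_index(3, hull)


class TestDensityAndBranching:
    def test_filled_square_density_100(self):
        g = np.zeros((12, 12), bool)
        g[1:11, 1:11] = True
        mask = make_mask(g)
        assert vessel_density(mask, convex_hull(mask)) == pytest.approx(100.0)

    def test_arithmetic(self):
        g = np.zeros((40, 40), bool)
        g[4:9, 4:9] = True  # 25 px
        mask = make_mask(g)
        hull = convex_hull(mask)
        assert vessel_density(mask, hull) == pytest.approx(100 * 25 / hull.area)

    def test_density_in_0_100(self):
        for m in random_masks(20, seed=43):
            mask = make_mask(m)
            d = vessel_density(mask, convex_hull(mask))
            assert 0 < d <= 100 + 1e-9

    def test_branching_index_arithmetic(self):
        g = np.zeros((60, 60), bool)
        g[5:55, 5:55] = True  # hull 2500
        hull = convex_hull(make_mask(g))
        assert branching_index(12, hull, unit_area=1000.0) == pytest.approx(
            12 / 2500 * 1000
        )
        assert branching_index(0, hull) == 0.0

    def test_dimensional_consistency(self):
        g = np.zeros((30, 30), bool)
        g[5:25, 5:25] = True
        h1 = convex_hull(VesselMask(g, pixel_size=1.0))
        h2 = convex_hull(VesselMask(g, pixel_size=2.0))
        # junctions / physical area scales with 1 / pixel_size^2
        assert branching_index(8, h2, unit_area=1.0) == pytest.approx(
            branching_index(8, h1, unit_area=1.0) / 4.0
        )


class TestLengthMetrics:
    def test_single_branch(self):
        graph = build_graph(make_mask(hline(10)))
        total, avg, ends, juncs = length_metrics(graph)
        assert (total, avg, ends, juncs) == (pytest.approx(9.0), pytest.approx(9.0), 2, 0)

    def test_plus_fixture(self):
        graph = build_graph(make_mask(plus_skeleton(11)))
        total, avg, ends, juncs = length_metrics(graph)
        assert total == pytest.approx(16.0)
        assert avg == pytest.approx(4.0)
        assert (ends, juncs) == (4, 1)

    def test_two_disjoint_lines(self):
        g = np.zeros((20, 20), bool)
        g[2, 2:12] = True  # length 9
        g[10, 2:7] = True  # length 4
        total, avg, *_ = length_metrics(build_graph(make_mask(g)))
        assert total == pytest.approx(13.0)
        assert avg == pytest.approx(6.5)

    def test_calibrated(self):
        graph = build_graph(VesselMask(hline(10), pixel_size=3.0))
        total, avg, *_ = length_metrics(graph)
        assert total == pytest.approx(27.0)


class TestLacunarity:
    def test_filled_region_all_ones(self):
        g = np.ones((32, 32), bool)
        curve = lacunarity(make_mask(g), region="image", box_sizes=(1, 2, 4, 8))
        assert curve.lambdas == pytest.approx((1.0, 1.0, 1.0, 1.0))
        assert curve.mean_lacunarity == pytest.approx(1.0)

    def test_lambda1_closed_form(self):
        # 10x10 region, 25 foreground: Lambda(1) = N/k = 4
        g = np.zeros((10, 10), bool)
        g[:5, :5] = True
        curve = lacunarity(make_mask(g), region="image", box_sizes=(1,))
        assert curve.lambdas[0] == pytest.approx(4.0)

    def test_lambda1_random_masks_exact(self):
        for m in random_masks(30, seed=47):
            lam = lacunarity(make_mask(m), region="image", box_sizes=(1,)).lambdas[0]
            n = m.size
            k = int(m.sum())
            assert lam == pytest.approx(n / k, rel=1e-12)

    def test_checkerboard_r2(self):
        g = (np.indices((8, 8)).sum(axis=0) % 2).astype(bool)
        lam = lacunarity(make_mask(g), region="image", box_sizes=(2,)).lambdas[0]
        assert lam == pytest.approx(1.0)

    def test_geq_one_everywhere(self):
        for m in random_masks(40, max_side=20, seed=53):
            curve = lacunarity(make_mask(m), region="image")
            assert all(lam >= 1.0 - 1e-12 for lam in curve.lambdas)

    def test_default_ladder(self):
        assert default_box_sizes((64, 100)) == (2, 4, 8, 16, 32)
        assert default_box_sizes((3, 3)) == (1,)

    def test_box_too_big_rejected(self):
        g = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="exceed"):
            lacunarity(make_mask(g), region="image", box_sizes=(9,))

    def test_empty_region_undefined(self):
        with pytest.raises(UndefinedLacunarityError):
            lacunarity(make_mask(np.zeros((6, 6), bool)), region="hull_bbox")

    def test_hull_bbox_region(self):
        g = np.zeros((40, 40), bool)
        g[10:18, 10:18] = True
        curve = lacunarity(make_mask(g), region="hull_bbox", box_sizes=(2, 4))
        # within its own bbox the mask is solid: uniform masses
        assert curve.lambdas == pytest.approx((1.0, 1.0))


class TestAnalyze:
    CFG = AnalysisConfig()

    def test_tree_fixture_recovery(self):
        fx = generate_tree(NetworkSpec(seed=5, branch_prob=0.8))
        res = analyze(fx.image, self.CFG)
        assert res.total_junctions == fx.truth.junction_count
        assert res.total_endpoints == fx.truth.endpoint_count
        assert res.total_vessel_length == pytest.approx(
            fx.truth.total_length, rel=0.05
        )

    def test_blank_image_raises_named_stage(self):
        blank = RasterImage(np.full((64, 64), 10, dtype=np.uint8))
        with pytest.raises(NoVesselsError) as err:
            analyze(blank, self.CFG)
        assert err.value.stage == "threshold_segment"
        assert "threshold_segment" in str(err.value)

    def test_deterministic(self):
        fx = generate_tree(NetworkSpec(seed=9, branch_prob=0.7))
        assert analyze(fx.image, self.CFG) == analyze(fx.image, self.CFG)

    def test_result_invariants(self):
        fx = generate_tree(NetworkSpec(seed=4, branch_prob=0.8))
        res = analyze(fx.image, self.CFG)
        assert 0 < res.vessel_density <= 100
        assert res.branching_index == pytest.approx(
            res.total_junctions / res.explant_area * self.CFG.unit_area
        )
        assert res.average_vessel_length == pytest.approx(
            res.total_vessel_length / res.branch_count
        )
        assert res.mean_lacunarity >= 1.0
        assert res.average_vessel_length <= res.total_vessel_length
        assert res.config_echo == self.CFG
        assert res.explant_area >= res.vessel_area

    def test_speck_invariance(self):
        import dataclasses

        fx = generate_tree(NetworkSpec(seed=5, branch_prob=0.8))
        specked = degrade(fx, "add_specks", 3e-5, seed=9)
        assert (specked.image.pixels != fx.image.pixels).sum() > 0
        a = dataclasses.replace(analyze(specked.image, self.CFG), image_id="")
        b = dataclasses.replace(analyze(fx.image, self.CFG), image_id="")
        assert a == b

    def test_pipeline_run_stages(self):
        fx = generate_tree(NetworkSpec(seed=5, branch_prob=0.8))
        run = run_pipeline(fx.image, self.CFG)
        assert set(run.stage_stats) == {
            "threshold_segment",
            "remove_small_particles",
            "fill_holes",
            "skeleton_pixels",
        }
        assert run.stage_stats["remove_small_particles"] <= run.stage_stats[
            "threshold_segment"
        ]
        assert run.result.image_id == fx.image.source_id
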