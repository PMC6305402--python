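import math

import numpy as np
import pytest
from shapely.geometry import box

from immunocontext.global_features import (
    CatalogConfig,
    DistanceCriterion,
    FeatureSpec,
    SlideFeatureComputer,
)
from immunocontext.heterogeneity import (
    build_grid,
    compute_heterogeneity_features,
    cov,
    measure_values,
    per_tile_values,
    qcd,
    relative_percentile,
)
from immunocontext.slide_model import RegionSet, SlideObjects, default_object_sets
from immunocontext.synthetic_slides import (
    GenericSlideConfig,
    Hotspot,
    SyntheticSlideConfig,
    generate_generic_slide,
    generate_verification_slide,
)

import brute_force as bf
from conftest import make_random_slide


def square_slide(n=40, edge=1000.0, tumor=None, seed=0):
    rng = np.random.default_rng(seed)
    regions = RegionSet.from_annotations(tissue=box(0, 0, edge, edge), tumor=tumor)
    return SlideObjects.from_arrays(
        "sq", regions,
        x=rng.uniform(0, edge, n), y=rng.uniform(0, edge, n),
        marker=["Ki67"] * n, prolif=[1] * n,
    )


class TestGrid:
    def test_exact_tiling_of_unit_square(self):
        slide = square_slide()
        grid = build_grid(slide, 250.0)
        assert grid.n_tiles == 16
        assert np.allclose(grid.overlap_um2, 250.0 * 250.0)

    def test_low_overlap_tiles_excluded(self):
        # tissue 1000 x 1010: the top row of 250-um tiles overlaps only 4%
        regions = RegionSet.from_annotations(tissue=box(0, 0, 1000, 1010))
        slide = SlideObjects.from_arrays(
            "s", regions, x=[500.0], y=[500.0], marker=["Ki67"], prolif=[1]
        )
        grid = build_grid(slide, 250.0)
        assert grid.n_tiles == 16  # 5th row (overlap 10/250 = 4%) dropped
        grid_all = build_grid(slide, 250.0, min_overlap_fraction=0.0)
        assert grid_all.n_tiles == 20

    def test_tumor_scope_requires_full_containment(self):
        tumor = box(0, 0, 500, 500)  # exactly 4 of the 16 tiles
        slide = square_slide(tumor=tumor)
        grid = build_grid(slide, 250.0, scope="tumor_only")
        assert grid.n_tiles == 4
        # a tumor that covers no complete tile -> no tiles
        slide2 = square_slide(tumor=box(10, 10, 260, 260))
        assert build_grid(slide2, 250.0, scope="tumor_only").n_tiles == 0

    def test_tumor_scope_is_subset_of_entire_scope(self):
        slide = square_slide(tumor=box(0, 0, 600, 800))
        full = build_grid(slide, 250.0)
        tum = build_grid(slide, 250.0, scope="tumor_only")
        full_bounds = {tuple(b) for b in full.bounds}
        assert {tuple(b) for b in tum.bounds} <= full_bounds

    def test_grid_determinism(self):
        slide = make_random_slide(13, n=100)
        g1, g2 = build_grid(slide, 250.0), build_grid(slide, 250.0)
        assert np.array_equal(g1.bounds, g2.bounds)
        assert np.array_equal(g1.overlap_um2, g2.overlap_um2)


class TestPerTileValues:
    def test_counts_partition_region_count_on_exact_tiling(self):
        slide = square_slide(n=200, seed=3)
        grid = build_grid(slide, 250.0)
        spec = FeatureSpec("count", "ki67")
        vals = per_tile_values(slide, spec, grid)
        assert vals.sum() == 200

    def test_uniform_slide_density_near_equal_across_tiles(self):
        slide = square_slide(n=4000, seed=1)
        grid = build_grid(slide, 500.0)
        vals = per_tile_values(slide, FeatureSpec("density", "ki67"), grid)
        assert vals.shape == (4,)
        assert vals.std() / vals.mean() < 0.1

    def test_ieee_semantics_in_tiles(self):
        # one tile holds a Ki67 but no CD8 (x/0 = inf), another holds nothing (0/0 = nan)
        regions = RegionSet.from_annotations(tissue=box(0, 0, 500, 250))
        slide = SlideObjects.from_arrays(
            "s", regions, x=[100.0], y=[100.0], marker=["Ki67"], prolif=[1]
        )
        grid = build_grid(slide, 250.0)
        vals = per_tile_values(slide, FeatureSpec("ratio", "ki67", den="cd8_any"), grid)
        assert math.isinf(vals[0]) and math.isnan(vals[1])

    def test_distances_ignore_tile_boundaries(self):
        # Ki67 and its nearest CD8 sit in different tiles but within 15 um
        regions = RegionSet.from_annotations(tissue=box(0, 0, 500, 250))
        slide = SlideObjects.from_arrays(
            "s", regions, x=[248.0, 252.0], y=[100.0, 100.0],
            marker=["Ki67", "CD8"], prolif=[1, 1],
        )
        grid = build_grid(slide, 250.0)
        crit = DistanceCriterion(("cd8_prolif",), "or", "le", 15.0)
        vals = per_tile_values(slide, FeatureSpec("count", "ki67", criterion=crit), grid)
        assert vals.tolist() == [1.0, 0.0]

    def test_matches_brute_force_tile_evaluation(self):
        slide = make_random_slide(17, n=80)
        sets = default_object_sets()
        grid = build_grid(slide, 250.0)
        crit = DistanceCriterion(("cd8_any",), "or", "le", 50.0)
        specs = [
            FeatureSpec("count", "ki67"),
            FeatureSpec("density", "tcell_any"),
            FeatureSpec("ratio", "cd4_any", den="cd8_any"),
            FeatureSpec("distance_ratio", "ki67", den="ki67", criterion=crit),
        ]
        mat = per_tile_values(slide, specs, grid)
        for row, spec in zip(mat, specs):
            for slot in range(grid.n_tiles):
                expect = bf.bf_tile_value(slide, spec, grid, slot, sets)
                if math.isnan(expect):
                    assert math.isnan(row[slot])
                else:
                    assert row[slot] == pytest.approx(expect, rel=1e-12)


class TestMeasures:
    def test_cov_of_known_pair(self):
        assert cov([1.0, 3.0]) == pytest.approx(math.sqrt(2) / 2)  # 0.7071

    def test_cov_constant_and_degenerate(self):
        assert cov([2.0, 2.0, 2.0]) == 0.0
        assert cov([math.nan, math.nan]) is None
        assert cov([1.0]) is None
        assert cov([1.0, -1.0]) is None  # mean zero

    def test_qcd_known_values(self):
        assert qcd([1, 2, 3, 4, 5]) == pytest.approx(1.0 / 3.0)
        assert qcd([4.0, 4.0]) == 0.0
        assert qcd([0.0, 0.0]) is None

    def test_relative_percentile_known_values(self):
        vals = list(range(1, 101))
        assert relative_percentile(vals, 97) == pytest.approx(
            bf.bf_percentile(vals, 97) / bf.bf_percentile(vals, 50), rel=1e-12
        )
        assert relative_percentile(vals, 97) == pytest.approx(97.03 / 50.5, rel=1e-12)
        assert relative_percentile([5.0, 5.0, 5.0], 3) == 1.0
        assert relative_percentile([-1.0, 1.0], 90) is None  # median zero

    def test_rp_straddles_one_for_positive_data(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=200)
        assert relative_percentile(vals, 3) <= 1.0 <= relative_percentile(vals, 97)

    def test_measures_filter_nonfinite_before_computing(self):
        vals = [1.0, 3.0, math.inf, math.nan]
        assert cov(vals) == pytest.approx(math.sqrt(2) / 2)
        got = measure_values(vals)
        expect = bf.bf_measures(vals)
        for k, v in expect.items():
            assert got[k] == pytest.approx(v, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 3.0, 117.0])
    def test_cov_qcd_scale_invariance(self, c):
        rng = np.random.default_rng(4)
        vals = rng.gamma(2.0, size=50)
        assert cov(c * vals) == pytest.approx(cov(vals), rel=1e-9)
        assert qcd(c * vals) == pytest.approx(qcd(vals), rel=1e-9)

    def test_measures_match_brute_force_on_random_values(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.exponential(size=30), [np.inf, np.nan]])
        got = measure_values(vals)
        expect = bf.bf_measures(vals.tolist())
        for k in expect:
            assert got[k] == pytest.approx(expect[k], rel=1e-12)


class TestCatalogComputation:
    def test_catalog_size_and_unavailability_accounting(self):
        slide = square_slide(n=100, seed=5)  # no tumor
        cfg = CatalogConfig()
        base = [FeatureSpec("count", "ki67"), FeatureSpec("density", "ki67")]
        vals = compute_heterogeneity_features(slide, cfg, base_specs=base)
        assert len(vals) == len(base) * 8 * 3 * 2
        tumor_vals = [v for v in vals if "tumor_only" in v.feature]
        assert all(v.value is None and v.reason == "region_missing" for v in tumor_vals)

    def test_cov_of_uniform_density_near_poisson_expectation(self):
        # ~Poisson counts per tile: COV of counts ~ 1/sqrt(mean count)
        cfg = GenericSlideConfig(intensities={"ki67": 1000.0})
        rows = []
        for seed in range(30):
            slide = generate_generic_slide(cfg, seed=seed)
            grid = build_grid(slide, 250.0)
            vals = per_tile_values(slide, FeatureSpec("density", "ki67"), grid)
            rows.append(cov(vals))
        # mean per-tile count = 1000 / 16 = 62.5 -> expected COV ~ 0.1265
        assert np.mean(rows) == pytest.approx(1 / math.sqrt(62.5), rel=0.15)

    def test_hotspot_increases_density_cov(self):
        base = GenericSlideConfig(intensities={"ki67": 500.0})
        hot = GenericSlideConfig(
            intensities={"ki67": 500.0},
            hotspots=[Hotspot((375.0, 375.0), 125.0, "ki67", 10.0)],
        )
        diffs = []
        for seed in range(10):
            s0 = generate_generic_slide(base, seed=seed)
            s1 = generate_generic_slide(hot, seed=seed)
            g0, g1 = build_grid(s0, 250.0), build_grid(s1, 250.0)
            c0 = cov(per_tile_values(s0, FeatureSpec("density", "ki67"), g0))
            c1 = cov(per_tile_values(s1, FeatureSpec("density", "ki67"), g1))
            diffs.append(c1 - c0)
        assert all(d > 0 for d in diffs)
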