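import math

import numpy as np
import pytest

from immunocontext.global_features import (
    CatalogConfig,
    DistanceCriterion,
    FeatureSpec,
    SlideFeatureComputer,
    count_with_criterion,
    density,
    enumerate_catalog,
    nn_distance,
    ratio,
)
from immunocontext.slide_model import RegionSet, SlideObjects, default_object_sets
from shapely.geometry import box

import brute_force as bf
from conftest import make_random_slide


def tiny_slide(coords, markers, prolif, edge=1000.0, tumor=None):
    regions = RegionSet.from_annotations(tissue=box(0, 0, edge, edge), tumor=tumor)
    xy = np.asarray(coords, dtype=float)
    return SlideObjects.from_arrays(
        "tiny", regions, x=xy[:, 0], y=xy[:, 1], marker=markers, prolif=prolif
    )


class TestBasicOperations:
    def test_density_is_count_over_area(self):
        slide = tiny_slide([(100, 100), (200, 200), (900, 900)],
                           ["Ki67", "Ki67", "CD8"], [1, 1, 0])
        fv = density(slide, "ki67", "entire")
        assert fv.value == pytest.approx(2.0)  # 2 objects on 1 mm^2
        # 50 objects on 2 mm^2 -> 25 per mm^2
        regions = RegionSet.from_annotations(tissue=box(0, 0, 2000, 1000))
        slide2 = SlideObjects.from_arrays(
            "s", regions, x=np.linspace(10, 1990, 50), y=np.full(50, 500.0),
            marker=["Ki67"] * 50, prolif=[1] * 50,
        )
        assert density(slide2, "ki67", "entire").value == pytest.approx(25.0)

    def test_zero_area_region_is_unavailable(self):
        slide = tiny_slide([(100, 100)], ["Ki67"], [1])  # no tumor annotated
        fv = density(slide, "ki67", "tumor")
        assert fv.value is None and fv.reason == "region_missing"

    def test_ratio_special_cases(self):
        slide = tiny_slide(
            [(i * 10 + 5, 500) for i in range(50)], ["CD8"] * 50,
            [1] * 5 + [0] * 45,
        )
        assert ratio(slide, "cd8_prolif", "cd8_any", "entire").value == pytest.approx(0.1)
        assert ratio(slide, "cd8_any", "cd8_any", "entire").value == 1.0
        fv = ratio(slide, "cd8_any", "cd4_any", "entire")  # denominator count 0
        assert fv.value is None and fv.reason == "nonfinite"

    def test_nn_distance_345_triangle_and_empty_set(self):
        slide = tiny_slide([(0, 0), (3, 4)], ["Ki67", "CD8"], [1, 1])
        assert nn_distance(slide, 0, "cd8_prolif") == pytest.approx(5.0)
        assert nn_distance(slide, 0, "cd4_any") == math.inf

    def test_self_exclusion_in_nn_distance(self):
        slide = tiny_slide([(0, 0), (3, 4), (6, 8)], ["CD8"] * 3, [1] * 3)
        # each CD8's nearest CD8 is a neighbor, never itself (distance 0)
        assert nn_distance(slide, 0, "cd8_any") == pytest.approx(5.0)
        assert nn_distance(slide, 1, "cd8_any") == pytest.approx(5.0)

    def test_empty_reference_set_criterion_semantics(self):
        slide = tiny_slide([(100, 100)], ["Ki67"], [1])
        le = DistanceCriterion(("cd4_any",), "or", "le", 100.0)
        gt = DistanceCriterion(("cd4_any",), "or", "gt", 100.0)
        assert count_with_criterion(slide, "ki67", le, "entire").value == 0.0
        assert count_with_criterion(slide, "ki67", gt, "entire").value == 1.0

    def test_threshold_beyond_diagonal_recovers_plain_count(self):
        slide = make_random_slide(5, n=60)
        crit = DistanceCriterion(("cd8_any",), "or", "le", 1e6)
        comp = SlideFeatureComputer(slide, default_object_sets())
        has_ref = comp.count("cd8_any", "entire") > 0
        expected = comp.count("ki67", "entire") if has_ref else 0
        assert count_with_criterion(slide, "ki67", crit, "entire").value == expected


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_naive_point_in_polygon_loop(self, seed):
        slide = make_random_slide(seed, n=60)
        sets = default_object_sets()
        comp = SlideFeatureComputer(slide, sets)
        for name in ("ki67", "cd8_any", "tcell_prolif"):
            for region in ("entire", "tumor", "non_tumor"):
                assert comp.count(name, region) == bf.bf_count(slide, sets[name], region)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_nn_distances_match_quadratic_search(self, seed):
        slide = make_random_slide(seed, n=50)
        sets = default_object_sets()
        comp = SlideFeatureComputer(slide, sets)
        for name in ("ki67", "cd4_prolif", "cd8_any"):
            members = bf.bf_members(slide, sets[name])
            d = comp.nn_dist(name)
            for i in range(slide.n_objects):
                assert d[i] == pytest.approx(bf.bf_nn(slide, i, members), rel=1e-12)

    def test_and_criterion_matches_exhaustive_double_loop(self):
        slide = make_random_slide(9, n=30)
        sets = default_object_sets()
        crit = DistanceCriterion(("cd4_any", "cd8_any"), "and", "le", 150.0)
        got = count_with_criterion(slide, "ki67", crit, "entire").value
        assert got == bf.bf_count_crit(slide, sets["ki67"], sets, crit, "entire")


@pytest.fixture(scope="module")
def computer():
    return SlideFeatureComputer(make_random_slide(21, n=150), default_object_sets())


class TestCriterionIdentities:
    @pytest.mark.parametrize("refs,comb,dual", [
        (("cd8_any",), "or", "or"),
        (("cd4_any", "cd8_any"), "or", "and"),   # not(any d<=t) == all d>t
        (("cd4_any", "cd8_any"), "and", "or"),   # not(all d<=t) == any d>t
    ])
    def test_complement_identity(self, computer, refs, comb, dual):
        for theta in (15.0, 35.0, 100.0):
            le = computer.count("ki67", "entire", DistanceCriterion(refs, comb, "le", theta))
            gt = computer.count("ki67", "entire", DistanceCriterion(refs, dual, "gt", theta))
            assert le + gt == computer.count("ki67", "entire")

    def test_monotonicity_in_theta(self, computer):
        thetas = (15.0, 20.0, 25.0, 30.0, 35.0, 50.0, 100.0)
        le = [computer.count("ki67", "entire",
                             DistanceCriterion(("cd8_any",), "or", "le", t)) for t in thetas]
        gt = [computer.count("ki67", "entire",
                             DistanceCriterion(("cd8_any",), "or", "gt", t)) for t in thetas]
        assert le == sorted(le)
        assert gt == sorted(gt, reverse=True)

    def test_or_dominates_and(self, computer):
        # "any reference passes" is a superset of "all references pass",
        # whichever way the individual comparisons point
        refs = ("cd4_any", "cd8_any")
        for theta in (20.0, 50.0):
            for direction in ("le", "gt"):
                or_c = computer.count("ki67", "entire",
                                      DistanceCriterion(refs, "or", direction, theta))
                and_c = computer.count("ki67", "entire",
                                       DistanceCriterion(refs, "and", direction, theta))
                assert or_c >= and_c

    def test_single_reference_or_equals_and(self, computer):
        for direction in ("le", "gt"):
            a = computer.count("ki67", "entire",
                               DistanceCriterion(("cd8_any",), "or", direction, 25.0))
            b = computer.count("ki67", "entire",
                               DistanceCriterion(("cd8_any",), "and", direction, 25.0))
            assert a == b

    def test_density_times_area_equals_count(self, computer):
        slide = computer.slide
        for region in ("entire", "tumor", "non_tumor"):
            area = slide.regions.area_mm2(region)
            if area <= 0:
                continue
            fv = density(slide, "tcell_any", region)
            assert fv.value * area == pytest.approx(computer.count("tcell_any", region), rel=1e-12)


class TestCatalogComputation:
    def test_computation_is_idempotent_and_complete(self, default_config):
        slide = make_random_slide(2, n=80)
        catalog = enumerate_catalog(default_config, classes={"count", "density", "ratio"})
        comp = SlideFeatureComputer(slide, default_config.object_sets)
        a = [comp.value(s) for s in catalog]
        b = [SlideFeatureComputer(slide, default_config.object_sets).value(s) for s in catalog]
        assert len(a) == len(catalog)
        assert [(v.feature, v.value, v.reason) for v in a] == [
            (v.feature, v.value, v.reason) for v in b
        ]

    def test_absent_type_yields_zero_counts_and_unavailable_ratios(self):
        slide = tiny_slide([(100, 100), (200, 200)], ["Ki67", "CD8"], [1, 1])
        comp = SlideFeatureComputer(slide, default_object_sets())
        assert comp.value(FeatureSpec("count", "cd4_any", region="entire")).value == 0.0
        fv = comp.value(FeatureSpec("ratio", "ki67", den="cd4_any", region="entire"))
        assert fv.value is None and fv.reason == "nonfinite"
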