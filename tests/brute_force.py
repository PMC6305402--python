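"""Independent brute-force oracles for feature computation.

Everything here is deliberately naive: O(n^2) distance loops with
math.hypot, explicit point-in-polygon via shapely Point objects, textbook
linear-interpolation percentiles, and pair-counting AUC.  No KD-trees, no
vectorized ranking — these paths must stay independent of the package
implementation they check.
"""

import math
import statistics

from shapely.geometry import Point


def bf_region_member(slide, i, region):
    if region == "entire":
        return True
    pt = Point(slide.x[i], slide.y[i])
    in_tumor = (not slide.regions.tumor.is_empty) and slide.regions.tumor.covers(pt)
    if region == "tumor":
        return in_tumor
    # non_tumor: in tissue but not in tumor (tumor precedence on boundary)
    return slide.regions.entire.covers(pt) and not in_tumor


def bf_members(slide, oset):
    names = slide.marker_names()
    return [
        i for i in range(slide.n_objects)
        if (names[i], bool(slide.prolif[i])) in oset.atoms
    ]


def bf_count(slide, oset, region):
    return sum(
        1 for i in bf_members_cached(slide, oset) if bf_region_member_cached(slide, i, region)
    )


def bf_nn(slide, i, ref_indices):
    best = math.inf
    for j in ref_indices:
        if j == i:
            continue
        d = math.hypot(slide.x[i] - slide.x[j], slide.y[i] - slide.y[j])
        best = min(best, d)
    return best


# memoization so the quadratic loops stay affordable over many slides; the
# cache lives on the slide object itself, so results are recomputed per slide


def _cache(slide):
    if not hasattr(slide, "_bf_cache"):
        slide._bf_cache = {}
    return slide._bf_cache


def _atoms_key(oset):
    return tuple(sorted(oset.atoms))


def bf_members_cached(slide, oset):
    key = ("members", _atoms_key(oset))
    cache = _cache(slide)
    if key not in cache:
        cache[key] = bf_members(slide, oset)
    return cache[key]


def bf_nn_all(slide, oset):
    """Per-object nearest-member distance to a set, by exhaustive search."""
    key = ("nn", _atoms_key(oset))
    cache = _cache(slide)
    if key not in cache:
        members = bf_members_cached(slide, oset)
        cache[key] = [bf_nn(slide, i, members) for i in range(slide.n_objects)]
    return cache[key]


def bf_region_member_cached(slide, i, region):
    key = ("region", i, region)
    cache = _cache(slide)
    if key not in cache:
        cache[key] = bf_region_member(slide, i, region)
    return cache[key]


def bf_crit_satisfied(slide, i, object_sets, criterion):
    results = []
    for ref in criterion.refs:
        d = bf_nn_all(slide, object_sets[ref])[i]
        ok = d <= criterion.theta
        if criterion.direction == "gt":
            ok = not ok
        results.append(ok)
    return any(results) if criterion.combinator == "or" else all(results)


def bf_count_crit(slide, oset, object_sets, criterion, region):
    return sum(
        1 for i in bf_members_cached(slide, oset)
        if bf_region_member_cached(slide, i, region)
        and bf_crit_satisfied(slide, i, object_sets, criterion)
    )


def bf_spec_value(slide, spec, object_sets):
    """Value of one global FeatureSpec: float, or (None, reason)."""
    region = spec.region
    area = slide.regions.area_mm2(region)
    if area <= 0:
        return None, "region_missing"
    if spec.cls == "count":
        if spec.criterion is None:
            return float(bf_count(slide, object_sets[spec.num], region)), "none"
        return (
            float(bf_count_crit(slide, object_sets[spec.num], object_sets, spec.criterion, region)),
            "none",
        )
    if spec.cls == "density":
        return bf_count(slide, object_sets[spec.num], region) / area, "none"
    if spec.cls == "ratio":
        num = bf_count(slide, object_sets[spec.num], region)
        den = bf_count(slide, object_sets[spec.den], region)
    else:
        num = bf_count_crit(slide, object_sets[spec.num], object_sets, spec.criterion, region)
        if spec.crit_on_den:
            den = bf_count_crit(slide, object_sets[spec.den], object_sets, spec.criterion, region)
        else:
            den = bf_count(slide, object_sets[spec.den], region)
    if den == 0:
        return None, "nonfinite"
    return num / den, "none"


# -- tiles ------------------------------------------------------------------


def bf_tile_of(x, y, grid):
    ix = int(math.floor((x - grid.origin[0]) / grid.edge))
    iy = int(math.floor((y - grid.origin[1]) / grid.edge))
    ix = min(max(ix, 0), grid.nx - 1)
    iy = min(max(iy, 0), grid.ny - 1)
    return grid.slot_of[iy * grid.nx + ix]


def bf_tile_value(slide, spec, grid, slot, object_sets):
    def count(oset_name, criterion):
        total = 0
        for i in bf_members_cached(slide, object_sets[oset_name]):
            if bf_tile_of(slide.x[i], slide.y[i], grid) != slot:
                continue
            if criterion is not None and not bf_crit_satisfied(slide, i, object_sets, criterion):
                continue
            total += 1
        return total

    if spec.cls == "count":
        return float(count(spec.num, spec.criterion))
    if spec.cls == "density":
        return count(spec.num, None) / (grid.overlap_um2[slot] / 1e6)
    if spec.cls == "ratio":
        num, den = count(spec.num, None), count(spec.den, None)
    else:
        num = count(spec.num, spec.criterion)
        den = count(spec.den, spec.criterion if spec.crit_on_den else None)
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


# -- descriptive statistics -------------------------------------------------


def bf_percentile(values, p):
    """Linear interpolation between closest order statistics."""
    v = sorted(values)
    if len(v) == 1:
        return v[0]
    h = (len(v) - 1) * p / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def bf_measures(values):
    """The eight dispersion measures of finite values, None when undefined."""
    v = [x for x in values if math.isfinite(x)]
    out = dict.fromkeys(("cov", "qcd", "rp3", "rp5", "rp10", "rp90", "rp95", "rp97"), None)
    if len(v) < 2:
        return out
    mean = sum(v) / len(v)
    if mean != 0:
        out["cov"] = statistics.stdev(v) / mean
    p25, p75 = bf_percentile(v, 25), bf_percentile(v, 75)
    if p25 + p75 != 0:
        out["qcd"] = (p75 - p25) / (p75 + p25)
    med = bf_percentile(v, 50)
    if med != 0:
        for p in (3, 5, 10, 90, 95, 97):
            out[f"rp{p}"] = bf_percentile(v, p) / med
    return out


def bf_auc(values1, values2):
    """Pair-counting Mann-Whitney AUC with ties counted one half."""
    wins = 0.0
    for a in values1:
        for b in values2:
            if b > a:
                wins += 1.0
            elif b == a:
                wins += 0.5
    return wins / (len(values1) * len(values2))
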