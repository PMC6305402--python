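"""Global density- and distance-based features over slide compartments.

Feature classes
---------------
* ``count``          — number of objects of a set in a region, optionally
  restricted by a cell-to-cell distance criterion.
* ``density``        — count divided by region area (1/mm^2).
* ``ratio``          — ratio of two plain counts in the same region.
* ``distance_ratio`` — ratio of two counts where the numerator (and
  optionally the denominator) is restricted by the same distance criterion.

A distance criterion restricts a count to objects whose nearest-neighbor
distance to one or more reference sets is below (``le``) or above (``gt``)
a threshold theta, combined with OR or AND over the reference sets.
Distances are always computed slide-wide: region (and later tile)
boundaries do not truncate neighbor searches.

Non-finite global ratios (zero denominator) are recorded as UNAVAILABLE
rather than as IEEE infinities; per-tile evaluation (see
:mod:`immunocontext.heterogeneity`) instead keeps IEEE semantics and filters
later.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .slide_model import ObjectSet, SlideObjects, default_object_sets, extended_ratio_sets

#: distance-threshold grid in micrometers
THRESHOLDS = (15.0, 20.0, 25.0, 30.0, 35.0, 50.0, 100.0)
REGIONS = ("entire", "tumor", "non_tumor")

UNAVAILABLE_NONE = "none"
UNAVAILABLE_REGION = "region_missing"
UNAVAILABLE_NONFINITE = "nonfinite"


@dataclass(frozen=True)
class DistanceCriterion:
    """Nearest-neighbor distance restriction: (OR|AND over refs) dist (<=|>) theta."""

    refs: tuple
    combinator: str  # "or" | "and"
    direction: str  # "le" | "gt"
    theta: float

    def __post_init__(self):
        if self.combinator not in ("or", "and"):
            raise ValueError(f"combinator {self.combinator!r}")
        if self.direction not in ("le", "gt"):
            raise ValueError(f"direction {self.direction!r}")
        if not self.refs:
            raise ValueError("need at least one reference set")

    @property
    def key(self) -> str:
        return f"{self.direction}{self.theta:g}_{self.combinator}({','.join(self.refs)})"

    def satisfied(self, nn_dists: dict) -> np.ndarray:
        """Boolean per-object satisfaction given slide-wide NN distances per ref set.

        An empty reference set has distance +inf everywhere, so ``le`` is
        never satisfied and ``gt`` always is — the limiting behavior of the
        threshold comparison.
        """
        per_ref = [nn_dists[r] <= self.theta for r in self.refs]
        if self.direction == "gt":
            per_ref = [~m for m in per_ref]
        stack = np.array(per_ref)
        return stack.any(axis=0) if self.combinator == "or" else stack.all(axis=0)


@dataclass(frozen=True)
class FeatureSpec:
    """Symbolic description of one global feature (or its per-tile base form).

    ``region=None`` denotes the per-region base form used in heterogeneity
    analysis, where each tile plays the role of the region.
    """

    cls: str  # "count" | "density" | "ratio" | "distance_ratio"
    num: str
    den: Optional[str] = None
    criterion: Optional[DistanceCriterion] = None
    crit_on_den: bool = False
    region: Optional[str] = None

    def __post_init__(self):
        if self.cls not in ("count", "density", "ratio", "distance_ratio"):
            raise ValueError(f"feature class {self.cls!r}")
        if self.cls in ("ratio", "distance_ratio") and self.den is None:
            raise ValueError(f"{self.cls} requires a denominator set")
        if self.cls == "distance_ratio" and self.criterion is None:
            raise ValueError("distance_ratio requires a criterion")

    @property
    def key(self) -> str:
        crit = self.criterion.key if self.criterion else "-"
        return (
            f"{self.cls}|num={self.num}|den={self.den or '-'}"
            f"|crit={crit}|denc={int(self.crit_on_den)}|reg={self.region or '-'}"
        )

    @property
    def is_distance_based(self) -> bool:
        return self.criterion is not None

    @property
    def theta(self) -> Optional[float]:
        return self.criterion.theta if self.criterion else None

    def with_region(self, region) -> "FeatureSpec":
        return replace(self, region=region)


@dataclass
class FeatureValue:
    slide_id: str
    feature: str  # canonical FeatureSpec / heterogeneity key
    value: Optional[float]
    reason: str = UNAVAILABLE_NONE

    @property
    def available(self) -> bool:
        return self.value is not None


def _unavailable(slide_id, key, reason) -> FeatureValue:
    return FeatureValue(slide_id, key, None, reason)


# ---------------------------------------------------------------------------
# catalog configuration


@dataclass
class CatalogConfig:
    """The feature catalog: object sets, ratio pairs, distance combinations.

    Defaults reproduce the intended catalog arithmetic:
    (10 counts + 10 densities + 156 ratios) x 3 regions = 528 density-based
    global specs, and 279 distance combinations x 7 thresholds x 3 regions =
    5,859 distance-based global specs.
    """

    object_sets: dict = field(default_factory=default_object_sets)
    count_sets: list = None  # sets enumerated as counts/densities
    ratio_pairs: list = None
    distance_combos: list = None  # list of criterion-free FeatureSpec templates
    thresholds: tuple = THRESHOLDS
    regions: tuple = REGIONS
    distance_catalog_size: int = 279

    def __post_init__(self):
        if self.count_sets is None:
            self.count_sets = list(self.object_sets)
        if self.ratio_pairs is None:
            self.ratio_pairs = default_ratio_pairs()
        if self.distance_combos is None:
            self.distance_combos = default_distance_combos(
                list(self.object_sets), size=self.distance_catalog_size
            )
        # operands referenced by ratio pairs may extend the base catalog
        extra = extended_ratio_sets()
        for a, b in self.ratio_pairs:
            for name in (a, b):
                if name not in self.object_sets:
                    if name not in extra:
                        raise ValueError(f"ratio operand {name!r} not defined")
                    self.object_sets[name] = extra[name]

    @property
    def base_set_names(self) -> list:
        return list(self.count_sets)


def default_ratio_pairs() -> list:
    """All ordered distinct pairs of the 13 ratio operands (10 + 3 unions)."""
    names = list(default_object_sets()) + list(extended_ratio_sets())
    return [(a, b) for a in names for b in names if a != b]


def default_distance_combos(set_names, ref_names=None, size=279):
    """Systematic distance-combination enumeration, truncated to ``size``.

    Blocks, in order: LE fractions (numerator restricted, denominator the
    same set unrestricted), LE counts, GT counts, GT fractions — each over
    all numerator sets x the 7 named single-reference sets.  Multi-reference
    OR/AND combinations follow the single-reference blocks and enter only if
    ``size`` exceeds them.  Each entry is a criterion-carrying
    :class:`FeatureSpec` with ``theta`` left as NaN, to be crossed with the
    threshold grid at enumeration time.
    """
    if ref_names is None:
        ref_names = set_names[:7]  # the seven named (non-union) types
    combos = []

    def crit(refs, comb, direction):
        return DistanceCriterion(tuple(refs), comb, direction, float("nan"))

    for direction, cls_first in (("le", "fraction"), ("le", "count"), ("gt", "count"), ("gt", "fraction")):
        for num in set_names:
            for ref in ref_names:
                c = crit([ref], "or", direction)
                if cls_first == "fraction":
                    combos.append(
                        FeatureSpec("distance_ratio", num, den=num, criterion=c, crit_on_den=False)
                    )
                else:
                    combos.append(FeatureSpec("count", num, criterion=c))
    # paired OR/AND references (matched proliferation status across CD4/CD8)
    for refs in (("cd4_any", "cd8_any"), ("cd4_prolif", "cd8_prolif"), ("cd4_nonprolif", "cd8_nonprolif")):
        for comb in ("or", "and"):
            for direction in ("le", "gt"):
                for num in set_names:
                    combos.append(
                        FeatureSpec(
                            "distance_ratio", num, den=num,
                            criterion=crit(refs, comb, direction), crit_on_den=False,
                        )
                    )
    if size > len(combos):
        raise ValueError(f"distance catalog size {size} exceeds enumeration ({len(combos)})")
    return combos[:size]


def enumerate_catalog(config: CatalogConfig, classes=None, regions=None) -> list:
    """Enumerate the global feature catalog as a deterministic, deduplicated list.

    ``classes`` may restrict to a subset of {"count", "density", "ratio",
    "distance"}; ``regions`` to a subset of the configured regions.  The
    returned list is sorted lexicographically by canonical key, so feature
    ids are stable across runs.
    """
    classes = set(classes) if classes else {"count", "density", "ratio", "distance"}
    regions = tuple(regions) if regions else config.regions
    specs = []
    for base in enumerate_base_specs(config, classes):
        for region in regions:
            specs.append(base.with_region(region))
    keys = [s.key for s in specs]
    if len(set(keys)) != len(keys):
        seen, dup = set(), None
        for k in keys:
            if k in seen:
                dup = k
                break
            seen.add(k)
        raise ValueError(f"duplicate canonical feature key: {dup}")
    return sorted(specs, key=lambda s: s.key)


def enumerate_base_specs(config: CatalogConfig, classes=None) -> list:
    """Per-region base forms (region unset): the heterogeneity base catalog."""
    classes = set(classes) if classes else {"count", "density", "ratio", "distance"}
    base = []
    names = config.base_set_names
    if "count" in classes:
        base += [FeatureSpec("count", n) for n in names]
    if "density" in classes:
        base += [FeatureSpec("density", n) for n in names]
    if "ratio" in classes:
        base += [FeatureSpec("ratio", a, den=b) for a, b in config.ratio_pairs]
    if "distance" in classes:
        for combo in config.distance_combos:
            for theta in config.thresholds:
                base.append(
                    replace(combo, criterion=replace(combo.criterion, theta=float(theta)))
                )
    return base


# ---------------------------------------------------------------------------
# computation


class SlideFeatureComputer:
    """Evaluates feature specs on one slide, caching masks, KD-trees and counts.

    Nearest-neighbor distances are slide-wide and self-excluding: an object
    belonging to the reference set is never its own neighbor (membership is
    decided by array identity, so coincident points of different objects are
    still legitimate neighbors).
    """

    def __init__(self, slide: SlideObjects, object_sets: dict):
        self.slide = slide
        self.object_sets = object_sets
        self._set_masks = {}
        self._nn = {}
        self._crit = {}
        self._counts = {}

    def set_mask(self, name: str) -> np.ndarray:
        if name not in self._set_masks:
            self._set_masks[name] = self.slide.set_mask(self.object_sets[name])
        return self._set_masks[name]

    def nn_dist(self, ref: str) -> np.ndarray:
        """Distance from every object to its nearest member of set ``ref``."""
        if ref in self._nn:
            return self._nn[ref]
        n = self.slide.n_objects
        idx = np.flatnonzero(self.set_mask(ref))
        if idx.size == 0:
            out = np.full(n, np.inf)
        elif n == 0:
            out = np.empty(0)
        else:
            pts = self.slide.points
            tree = cKDTree(pts[idx])
            if idx.size == 1:
                d, _ = tree.query(pts, k=1)
                out = np.asarray(d, dtype=float)
                out[idx[0]] = np.inf
            else:
                d, j = tree.query(pts, k=2)
                nearest_global = idx[j[:, 0]]
                self_hit = nearest_global == np.arange(n)
                out = np.where(self_hit, d[:, 1], d[:, 0])
        self._nn[ref] = out
        return out

    def criterion_mask(self, criterion: DistanceCriterion) -> np.ndarray:
        key = criterion.key
        if key not in self._crit:
            dists = {r: self.nn_dist(r) for r in criterion.refs}
            self._crit[key] = criterion.satisfied(dists)
        return self._crit[key]

    def count(self, num: str, region: str, criterion: DistanceCriterion = None) -> int:
        key = (num, region, criterion.key if criterion else None)
        if key not in self._counts:
            mask = self.set_mask(num) & self.slide.region_mask(region)
            if criterion is not None:
                mask = mask & self.criterion_mask(criterion)
            self._counts[key] = int(mask.sum())
        return self._counts[key]

    def value(self, spec: FeatureSpec) -> FeatureValue:
        sid = self.slide.slide_id
        region = spec.region
        area = self.slide.regions.area_mm2(region)
        if area <= 0.0:
            return _unavailable(sid, spec.key, UNAVAILABLE_REGION)
        if spec.cls == "count":
            return FeatureValue(sid, spec.key, float(self.count(spec.num, region, spec.criterion)))
        if spec.cls == "density":
            return FeatureValue(sid, spec.key, self.count(spec.num, region) / area)
        if spec.cls == "ratio":
            num = self.count(spec.num, region)
            den = self.count(spec.den, region)
        else:  # distance_ratio
            num = self.count(spec.num, region, spec.criterion)
            den = self.count(spec.den, region, spec.criterion if spec.crit_on_den else None)
        if den == 0:
            return _unavailable(sid, spec.key, UNAVAILABLE_NONFINITE)
        return FeatureValue(sid, spec.key, num / den)


def count_objects(slide, oset_name, region, object_sets=None):
    """Plain object count in a region; UNAVAILABLE when the region is absent."""
    comp = SlideFeatureComputer(slide, object_sets or default_object_sets())
    return comp.value(FeatureSpec("count", oset_name, region=region))


def density(slide, oset_name, region, object_sets=None):
    comp = SlideFeatureComputer(slide, object_sets or default_object_sets())
    return comp.value(FeatureSpec("density", oset_name, region=region))


def ratio(slide, num, den, region, object_sets=None):
    comp = SlideFeatureComputer(slide, object_sets or default_object_sets())
    return comp.value(FeatureSpec("ratio", num, den=den, region=region))


def nn_distance(slide, index, oset_name, object_sets=None) -> float:
    """Distance from object ``index`` to the nearest member of a set (self excluded)."""
    comp = SlideFeatureComputer(slide, object_sets or default_object_sets())
    return float(comp.nn_dist(oset_name)[index])


def count_with_criterion(slide, num, criterion, region, object_sets=None):
    comp = SlideFeatureComputer(slide, object_sets or default_object_sets())
    return comp.value(FeatureSpec("count", num, criterion=criterion, region=region))


def distance_ratio(slide, num, den, criterion, region, crit_on_den=True, object_sets=None):
    comp = SlideFeatureComputer(slide, object_sets or default_object_sets())
    return comp.value(
        FeatureSpec("distance_ratio", num, den=den, criterion=criterion,
                    crit_on_den=crit_on_den, region=region)
    )


def compute_global_features(slide: SlideObjects, catalog: list, config: CatalogConfig,
                            computer: SlideFeatureComputer = None) -> list:
    """One FeatureValue per catalog spec, in catalog order."""
    comp = computer or SlideFeatureComputer(slide, config.object_sets)
    return [comp.value(spec) for spec in catalog]
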