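"""Tile-based intratumoral heterogeneity of base features.

The tissue is covered with axis-aligned square tiles (edge 250, 500, or
1000 um by default), anchored at the tissue bounding-box minimum.  Tiles are
retained when their overlap with the tissue is at least 10% of the tile
area; the tumor-restricted scope additionally keeps only tiles lying
entirely inside the tumor compartment.

Each base feature (the per-region form of a global feature) is evaluated
per tile, with the tile playing the role of the region.  Per-tile ratios
follow IEEE semantics (x/0 = inf for x != 0, 0/0 = NaN); non-finite values
are filtered out before any dispersion statistic is computed.

Eight measures summarize the per-tile distribution: the coefficient of
variation (sample standard deviation over mean), the quartile coefficient
of dispersion (p75 - p25)/(p75 + p25), and six relative percentiles
(percentile p over the median, p in {3, 5, 10, 90, 95, 97}).  Percentiles
interpolate linearly between order statistics.  A measure needs at least
two finite tile values and a non-zero normalizer, otherwise it is
unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import box

from .global_features import (
    UNAVAILABLE_NONFINITE,
    UNAVAILABLE_REGION,
    CatalogConfig,
    FeatureSpec,
    FeatureValue,
    SlideFeatureComputer,
    enumerate_base_specs,
)
from .slide_model import SlideObjects

TILE_EDGES = (250.0, 500.0, 1000.0)
SCOPES = ("entire_slide", "tumor_only")
MEASURES = ("cov", "qcd", "rp3", "rp5", "rp10", "rp90", "rp95", "rp97")
RP_PERCENTILES = {"rp3": 3, "rp5": 5, "rp10": 10, "rp90": 90, "rp95": 95, "rp97": 97}
MIN_OVERLAP_FRACTION = 0.1
MIN_FINITE_VALUES = 2


@dataclass(frozen=True)
class HeterogeneitySpec:
    """One heterogeneity feature: measure of a base feature over a tile grid."""

    base: FeatureSpec
    measure: str
    tile_edge: float
    scope: str

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"measure {self.measure!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"scope {self.scope!r}")

    @property
    def key(self) -> str:
        return f"het|{self.measure}|edge={self.tile_edge:g}|scope={self.scope}|{self.base.key}"


@dataclass
class TileGrid:
    """Retained square tiles of one slide at a fixed edge length and scope.

    ``slot_of`` maps a full-grid linear index (iy * nx + ix) to the retained
    tile slot, or -1 for dropped tiles.  Overlap areas are with the entire
    tissue, in um^2.
    """

    edge: float
    origin: tuple
    nx: int
    ny: int
    slot_of: np.ndarray
    overlap_um2: np.ndarray
    bounds: np.ndarray  # (n_tiles, 4) minx, miny, maxx, maxy

    @property
    def n_tiles(self) -> int:
        return int(self.overlap_um2.size)

    @property
    def overlap_mm2(self) -> np.ndarray:
        return self.overlap_um2 / 1e6

    def tile_slot_of_points(self, x, y) -> np.ndarray:
        """Retained-tile slot per point (-1 if in no retained tile).

        Points are binned by floor division from the grid origin; indices are
        clamped so that points exactly on the outer bounding-box edge belong
        to the last tile (closed-region convention, each point in one tile).
        """
        ix = np.floor((np.asarray(x, float) - self.origin[0]) / self.edge).astype(int)
        iy = np.floor((np.asarray(y, float) - self.origin[1]) / self.edge).astype(int)
        np.clip(ix, 0, self.nx - 1, out=ix)
        np.clip(iy, 0, self.ny - 1, out=iy)
        return self.slot_of[iy * self.nx + ix]


def build_grid(slide: SlideObjects, edge: float, scope: str = "entire_slide",
               min_overlap_fraction: float = MIN_OVERLAP_FRACTION,
               origin_offset: tuple = (0.0, 0.0)) -> TileGrid:
    """Deterministic tile grid over the tissue bounding box.

    ``origin_offset`` shifts the grid anchor (for tiling-phase robustness
    experiments); the default anchors at the bounding-box minimum.
    """
    if edge <= 0:
        raise ValueError("tile edge must be positive")
    if scope not in SCOPES:
        raise ValueError(f"scope {scope!r}")
    tissue = slide.regions.entire
    tumor = slide.regions.tumor
    minx, miny, maxx, maxy = tissue.bounds
    ox, oy = minx + origin_offset[0], miny + origin_offset[1]
    if ox > minx:
        ox -= edge
    if oy > miny:
        oy -= edge
    nx = max(1, int(np.ceil((maxx - ox) / edge - 1e-12)))
    ny = max(1, int(np.ceil((maxy - oy) / edge - 1e-12)))
    slot_of = np.full(nx * ny, -1, dtype=int)
    overlaps, bounds = [], []
    min_overlap = min_overlap_fraction * edge * edge
    slot = 0
    for iy in range(ny):
        for ix in range(nx):
            x0, y0 = ox + ix * edge, oy + iy * edge
            tile = box(x0, y0, x0 + edge, y0 + edge)
            ov = tile.intersection(tissue).area
            if ov < min_overlap:
                continue
            if scope == "tumor_only" and not (not tumor.is_empty and tumor.covers(tile)):
                continue
            slot_of[iy * nx + ix] = slot
            overlaps.append(ov)
            bounds.append((x0, y0, x0 + edge, y0 + edge))
            slot += 1
    return TileGrid(
        edge=float(edge), origin=(ox, oy), nx=nx, ny=ny, slot_of=slot_of,
        overlap_um2=np.asarray(overlaps, dtype=float),
        bounds=np.asarray(bounds, dtype=float).reshape(-1, 4),
    )


# ---------------------------------------------------------------------------
# per-tile evaluation


def per_tile_counts(computer: SlideFeatureComputer, grid: TileGrid, num: str,
                    criterion=None) -> np.ndarray:
    """Object count of a set per retained tile (criterion uses slide-wide NN)."""
    slide = computer.slide
    slot = grid.tile_slot_of_points(slide.x, slide.y)
    mask = computer.set_mask(num)
    if criterion is not None:
        mask = mask & computer.criterion_mask(criterion)
    valid = mask & (slot >= 0)
    return np.bincount(slot[valid], minlength=grid.n_tiles).astype(float)


def per_tile_values(slide: SlideObjects, base_specs, grid: TileGrid,
                    computer: SlideFeatureComputer = None,
                    object_sets=None) -> np.ndarray:
    """Matrix (n_base_specs x n_tiles) of per-tile feature values.

    IEEE non-finite values are preserved: downstream measures filter them.
    """
    if computer is None:
        from .slide_model import default_object_sets

        computer = SlideFeatureComputer(slide, object_sets or default_object_sets())
    single = isinstance(base_specs, FeatureSpec)
    specs = [base_specs] if single else list(base_specs)
    count_cache = {}

    def counts(num, criterion):
        key = (num, criterion.key if criterion else None)
        if key not in count_cache:
            count_cache[key] = per_tile_counts(computer, grid, num, criterion)
        return count_cache[key]

    out = np.empty((len(specs), grid.n_tiles))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, spec in enumerate(specs):
            if spec.cls == "count":
                out[i] = counts(spec.num, spec.criterion)
            elif spec.cls == "density":
                out[i] = counts(spec.num, None) / grid.overlap_mm2
            elif spec.cls == "ratio":
                out[i] = counts(spec.num, None) / counts(spec.den, None)
            else:  # distance_ratio
                den_crit = spec.criterion if spec.crit_on_den else None
                out[i] = counts(spec.num, spec.criterion) / counts(spec.den, den_crit)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# dispersion measures


def _finite(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    return v[np.isfinite(v)]


def cov(values) -> Optional[float]:
    """Coefficient of variation: sample (n-1) standard deviation over mean."""
    v = _finite(values)
    if v.size < MIN_FINITE_VALUES:
        return None
    m = v.mean()
    if m == 0.0:
        return None
    return float(v.std(ddof=1) / m)

def qcd(values) -> Optional[float]:
    """Quartile coefficient of dispersion (p75 - p25)/(p75 + p25)."""
    v = _finite(values)
    if v.size < MIN_FINITE_VALUES:
        return None
    p25, p75 = np.percentile(v, [25, 75])
    if p25 + p75 == 0.0:
        return None
    return float((p75 - p25) / (p75 + p25))


def relative_percentile(values, p) -> Optional[float]:
    """Percentile p divided by the median (relative peak height / trough depth)."""
    if p not in (3, 5, 10, 90, 95, 97):
        raise ValueError(f"unsupported percentile {p}")
    v = _finite(values)
    if v.size < MIN_FINITE_VALUES:
        return None
    med = np.percentile(v, 50)
    if med == 0.0:
        return None
    return float(np.percentile(v, p) / med)


def measure_values(values) -> dict:
    """All eight measures of one per-tile value vector, sharing one percentile pass."""
    v = _finite(values)
    out = dict.fromkeys(MEASURES, None)
    if v.size < MIN_FINITE_VALUES:
        return out
    p = np.percentile(v, [3, 5, 10, 25, 50, 75, 90, 95, 97])
    p3, p5, p10, p25, med, p75, p90, p95, p97 = p
    m = v.mean()
    if m != 0.0:
        out["cov"] = float(v.std(ddof=1) / m)
    if p25 + p75 != 0.0:
        out["qcd"] = float((p75 - p25) / (p75 + p25))
    if med != 0.0:
        for name, val in (("rp3", p3), ("rp5", p5), ("rp10", p10),
                          ("rp90", p90), ("rp95", p95), ("rp97", p97)):
            out[name] = float(val / med)
    return out


# ---------------------------------------------------------------------------
# catalog-level computation


def enumerate_heterogeneity_specs(base_specs, tile_edges=TILE_EDGES, scopes=SCOPES,
                                  measures=MEASURES) -> list:
    """All (base, measure, edge, scope) combinations, deterministic order."""
    return [
        HeterogeneitySpec(base=b, measure=m, tile_edge=float(e), scope=s)
        for b in base_specs for e in tile_edges for s in scopes for m in measures
    ]


def compute_heterogeneity_features(slide: SlideObjects, config: CatalogConfig,
                                   base_specs=None, tile_edges=TILE_EDGES, scopes=SCOPES,
                                   measures=MEASURES,
                                   min_overlap_fraction: float = MIN_OVERLAP_FRACTION,
                                   computer: SlideFeatureComputer = None) -> list:
    """One FeatureValue per heterogeneity spec for one slide.

    When a scope has no qualifying tiles (e.g. tumor scope with no tumor
    annotated) all its features are unavailable with reason
    ``region_missing``; rows with fewer than two finite tile values are
    unavailable with reason ``nonfinite``.
    """
    if base_specs is None:
        base_specs = enumerate_base_specs(config)
    comp = computer or SlideFeatureComputer(slide, config.object_sets)
    sid = slide.slide_id
    results = []
    for edge in tile_edges:
        for scope in scopes:
            grid = build_grid(slide, edge, scope, min_overlap_fraction)
            if grid.n_tiles == 0:
                for spec in base_specs:
                    for m in measures:
                        h = HeterogeneitySpec(spec, m, float(edge), scope)
                        results.append(FeatureValue(sid, h.key, None, UNAVAILABLE_REGION))
                continue
            vmat = per_tile_values(slide, base_specs, grid, computer=comp)
            for spec, row in zip(base_specs, vmat):
                mvals = measure_values(row)
                for m in measures:
                    h = HeterogeneitySpec(spec, m, float(edge), scope)
                    val = mvals[m]
                    if val is None:
                        results.append(FeatureValue(sid, h.key, None, UNAVAILABLE_NONFINITE))
                    else:
                        results.append(FeatureValue(sid, h.key, val))
    return results


def tile_values_frame(slide: SlideObjects, base_spec: FeatureSpec, grid: TileGrid,
                      object_sets=None) -> pd.DataFrame:
    """Per-tile values of one base feature as a tidy frame (heatmap export)."""
    vals = per_tile_values(slide, base_spec, grid, object_sets=object_sets)
    return pd.DataFrame(
        {
            "tile": np.arange(grid.n_tiles),
            "minx": grid.bounds[:, 0],
            "miny": grid.bounds[:, 1],
            "maxx": grid.bounds[:, 2],
            "maxy": grid.bounds[:, 3],
            "overlap_mm2": grid.overlap_mm2,
            "value": vals,
        }
    )
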