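"""End-to-end orchestration: load -> global features -> heterogeneity ->
rank -> significance.

Slides are analyzed independently (optionally in parallel processes), each
writing a per-slide sqlite store; the stores are merged at the end, so the
result is identical for any worker count.  Re-running with unchanged slide
content and configuration is a cached no-op, keyed on (slide content hash,
config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tempfile
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import heterogeneity as het
from .discovery import (
    DEFAULT_SCREENING_THRESHOLD,
    FeatureMatrix,
    opm_histogram_frame,
    rank_features,
    significance_null,
)
from .global_features import (
    THRESHOLDS,
    CatalogConfig,
    SlideFeatureComputer,
    compute_global_features,
    enumerate_base_specs,
    enumerate_catalog,
)
from .slide_model import SlideObjects, load_slide
from .store import FeatureStore

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run-wide settings; defaults reproduce the standard analysis.

    Threshold grid {15, 20, 25, 30, 35, 50, 100} um, tile edges
    {250, 500, 1000} um, 10% minimum tile-tissue overlap, OPM screening at
    0.6.
    """

    thresholds: tuple = THRESHOLDS
    tile_edges: tuple = het.TILE_EDGES
    scopes: tuple = het.SCOPES
    min_overlap_fraction: float = het.MIN_OVERLAP_FRACTION
    distance_catalog_size: int = 279
    include_heterogeneity: bool = True
    opm_threshold: float = DEFAULT_SCREENING_THRESHOLD
    null_features: int = 10000
    null_seed: int = 0
    workers: int = 1

    def catalog_config(self) -> CatalogConfig:
        return CatalogConfig(
            thresholds=tuple(float(t) for t in self.thresholds),
            distance_catalog_size=self.distance_catalog_size,
        )

    def config_hash(self) -> str:
        payload = {
            "thresholds": list(self.thresholds),
            "tile_edges": list(self.tile_edges),
            "scopes": list(self.scopes),
            "min_overlap_fraction": self.min_overlap_fraction,
            "distance_catalog_size": self.distance_catalog_size,
            "include_heterogeneity": self.include_heterogeneity,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("thresholds", "tile_edges", "scopes"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def catalog_census(config: RunConfig) -> pd.DataFrame:
    """Feature counts by (global/heterogeneity) x (density/distance-based)."""
    cat = config.catalog_config()
    global_specs = enumerate_catalog(cat)
    g_dist = sum(1 for s in global_specs if s.is_distance_based)
    g_dens = len(global_specs) - g_dist
    base = enumerate_base_specs(cat)
    b_dist = sum(1 for s in base if s.is_distance_based)
    b_dens = len(base) - b_dist
    mult = 8 * len(config.tile_edges) * len(config.scopes)
    rows = [
        ("global", g_dens, g_dist),
        ("heterogeneity", b_dens * mult, b_dist * mult),
    ]
    df = pd.DataFrame(rows, columns=["class", "density_based", "distance_based"])
    df["sum"] = df["density_based"] + df["distance_based"]
    total = df[["density_based", "distance_based", "sum"]].sum()
    df.loc[len(df)] = ["sum", *total]
    return df


def analyze_slide(slide: SlideObjects, config: RunConfig) -> list:
    """All feature values (global + heterogeneity) of one slide."""
    cat = config.catalog_config()
    computer = SlideFeatureComputer(slide, cat.object_sets)
    catalog = enumerate_catalog(cat)
    values = compute_global_features(slide, catalog, cat, computer=computer)
    if config.include_heterogeneity:
        values += het.compute_heterogeneity_features(
            slide, cat,
            tile_edges=config.tile_edges, scopes=config.scopes,
            min_overlap_fraction=config.min_overlap_fraction, computer=computer,
        )
    return values


def _analyze_to_db(args):
    slide, config, db_path = args
    try:
        values = analyze_slide(slide, config)
    except Exception as exc:  # isolate per-slide failures
        return slide.slide_id, f"{type(exc).__name__}: {exc}"
    with FeatureStore(db_path) as s:
        s.write_slide(
            slide.slide_id, values,
            content_hash=slide.content_hash(), config_hash=config.config_hash(),
            n_objects=slide.n_objects,
        )
    return slide.slide_id, None


def run_analyze(slides, config: RunConfig, store_path, workers=None) -> FeatureStore:
    """Analyze a cohort into a merged feature store.

    Unchanged slides already present in the store are skipped.  Failures are
    isolated per slide and logged; the remaining slides are retained.
    Results are independent of the worker count.
    """
    workers = workers or config.workers
    store = FeatureStore(store_path)
    cfg_hash = config.config_hash()
    todo = [s for s in slides if not store.has_slide(s.slide_id, s.content_hash(), cfg_hash)]
    logger.info("analyzing %d/%d slides (%d cached)", len(todo), len(slides),
                len(slides) - len(todo))
    if not todo:
        return store
    with tempfile.TemporaryDirectory(prefix="ic_slides_") as tmp:
        jobs = [
            (s, config, str(Path(tmp) / f"{i:04d}.sqlite")) for i, s in enumerate(todo)
        ]
        if workers > 1:
            with ProcessPoolExecutor(max_workers=workers) as pool:
                outcomes = list(pool.map(_analyze_to_db, jobs))
        else:
            outcomes = [_analyze_to_db(j) for j in jobs]
        failures = []
        for (slide, _cfg, db_path), (sid, err) in zip(jobs, outcomes):
            if err is not None:
                failures.append((sid, err))
                logger.error("slide %s failed: %s", sid, err)
                continue
            store.merge_from(db_path)
    if failures:
        logger.warning("%d slide(s) failed: %s", len(failures), [f[0] for f in failures])
    return store


def load_and_analyze(slide_inputs, config: RunConfig, store_path, workers=None):
    """Like :func:`run_analyze` but from (region_geojson, objects_csv) paths.

    Slides whose inputs fail to parse are reported and skipped, mirroring
    the per-slide isolation of the analysis step.
    """
    slides, failures = [], []
    for region_file, objects_file in slide_inputs:
        try:
            slides.append(load_slide(region_file, objects_file))
        except Exception as exc:
            failures.append((str(objects_file), f"{type(exc).__name__}: {exc}"))
            logger.error("failed to load %s: %s", objects_file, exc)
    store = run_analyze(slides, config, store_path, workers=workers)
    return store, failures


def run_report(store: FeatureStore, labels, config: RunConfig):
    """Rank all stored features and summarize screening counts.

    Returns (ranked frame, screening-by-theta frame, screening-by-class
    frame).
    """
    mat = store.load_matrix()
    if mat.empty:
        raise ValueError("feature store is empty")
    matrix = FeatureMatrix(mat, labels)
    ranked = rank_features(matrix, screening_threshold=config.opm_threshold)
    return ranked, screening_by_theta(ranked), screening_by_class(ranked)


def _feature_theta(key: str):
    # canonical keys embed the criterion as ...|crit=le15_or(...)|...
    part = [p for p in key.split("|") if p.startswith("crit=")][0][5:]
    if part == "-":
        return None
    return float(part[2:].split("_")[0])


def _feature_class(key: str) -> tuple:
    kind = "heterogeneity" if key.startswith("het|") else "global"
    basis = "distance" if "|crit=-" not in key else "density"
    return kind, basis


def screening_by_theta(ranked: pd.DataFrame) -> pd.DataFrame:
    """Potentially-predictive counts per distance threshold (or '(none)')."""
    hits = ranked[ranked["potentially_predictive"]]
    buckets = {}
    for key in hits["feature"]:
        theta = _feature_theta(key)
        label = "(none)" if theta is None else f"{theta:g}"
        buckets[label] = buckets.get(label, 0) + 1
    order = sorted(buckets, key=lambda s: (1, 0.0) if s == "(none)" else (0, float(s)))
    return pd.DataFrame(
        {"theta_um": order, "n_potentially_predictive": [buckets[k] for k in order]}
    )


def screening_by_class(ranked: pd.DataFrame) -> pd.DataFrame:
    """Potentially-predictive counts by (global/heterogeneity) x basis."""
    hits = ranked[ranked["potentially_predictive"]]
    counts = {}
    for key in hits["feature"]:
        counts[_feature_class(key)] = counts.get(_feature_class(key), 0) + 1
    rows = [
        (kind, basis, counts.get((kind, basis), 0))
        for kind in ("global", "heterogeneity") for basis in ("density", "distance")
    ]
    return pd.DataFrame(rows, columns=["class", "basis", "n_potentially_predictive"])


def run_significance(labels, config: RunConfig, real_opm=None, seed=None) -> pd.DataFrame:
    """Null OPM histogram (and optional real-data histogram) as a tidy frame."""
    res = significance_null(
        config.null_features, labels, seed if seed is not None else config.null_seed,
        thresholds=(config.opm_threshold,),
    )
    frames = [opm_histogram_frame(res["opm"], label="null")]
    if real_opm is not None:
        frames.append(opm_histogram_frame(real_opm, label="real"))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["exceedance"] = res["exceedance"]
    return out
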