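"""Domain model for annotated whole-slide object data.

A slide is a set of typed cell points (coordinates in micrometers) together
with tissue-region annotations: the entire (non-excluded) tissue, an optional
tumor region, and optional exclusion polygons.  Three compartments are derived:

* ``entire``    — tissue minus exclusions,
* ``tumor``     — entire tissue intersected with the annotated tumor,
* ``non_tumor`` — entire tissue minus the tumor.

Cell objects carry a base marker (Ki67 single-positive, CD4, CD8) and a
proliferation flag; Ki67 single-positive cells are proliferating by
definition.  Objects outside the tissue or inside an exclusion polygon are
dropped at load time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

MARKERS = ("Ki67", "CD4", "CD8")
_MARKER_CODE = {m: i for i, m in enumerate(MARKERS)}

#: compartment codes used in ``SlideObjects.compartment``
TUMOR, NON_TUMOR, OUTSIDE = 0, 1, 2
COMPARTMENT_NAMES = {TUMOR: "tumor", NON_TUMOR: "non_tumor", OUTSIDE: "outside"}

#: geometric tolerance for area bookkeeping, in mm^2
AREA_TOL_MM2 = 1e-6


class SlideModelError(ValueError):
    """Raised for malformed slide inputs (regions or object tables)."""


# ---------------------------------------------------------------------------
# object types


@dataclass(frozen=True)
class ObjectSet:
    """A named set of cell types, as a union of atomic (marker, prolif) pairs.

    Membership is a pure predicate over ``(base_marker, proliferating)`` so
    that unions such as "any T cell" or "all proliferating cells" are first
    class citizens of the feature catalog.
    """

    name: str
    atoms: frozenset

    def mask(self, marker_code: np.ndarray, prolif: np.ndarray) -> np.ndarray:
        """Vectorized membership over parallel marker-code / prolif arrays."""
        out = np.zeros(marker_code.shape, dtype=bool)
        for m, p in self.atoms:
            out |= (marker_code == _MARKER_CODE[m]) & (prolif == p)
        return out

    def __contains__(self, cell: tuple) -> bool:
        return tuple(cell) in self.atoms


def _oset(name, *atoms):
    return ObjectSet(name, frozenset(atoms))


_KI = ("Ki67", True)
_C4P, _C4N = ("CD4", True), ("CD4", False)
_C8P, _C8N = ("CD8", True), ("CD8", False)


def default_object_sets() -> dict:
    """The default 10-entry object-set catalog.

    Seven named types (Ki67; CD4 any/proliferating/non-proliferating; CD8
    likewise) plus three combined T-cell sets (CD4 or CD8, in the same three
    proliferation variants).  Order is significant: it fixes catalog
    enumeration order.
    """
    sets = [
        _oset("ki67", _KI),
        _oset("cd4_any", _C4P, _C4N),
        _oset("cd4_prolif", _C4P),
        _oset("cd4_nonprolif", _C4N),
        _oset("cd8_any", _C8P, _C8N),
        _oset("cd8_prolif", _C8P),
        _oset("cd8_nonprolif", _C8N),
        _oset("tcell_any", _C4P, _C4N, _C8P, _C8N),
        _oset("tcell_prolif", _C4P, _C8P),
        _oset("tcell_nonprolif", _C4N, _C8N),
    ]
    return {s.name: s for s in sets}


def extended_ratio_sets() -> dict:
    """Three union sets used (with the default 10) as ratio operands.

    All ordered distinct pairs of the resulting 13 operands give the default
    156-pair ratio catalog.
    """
    sets = [
        _oset("all_cells", _KI, _C4P, _C4N, _C8P, _C8N),
        _oset("prolif_all", _KI, _C4P, _C8P),
        _oset("ki67_or_cd8", _KI, _C8P, _C8N),
    ]
    return {s.name: s for s in sets}


# ---------------------------------------------------------------------------
# regions


def _as_multipolygon(geom):
    if geom.is_empty:
        return MultiPolygon([])
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    # GeometryCollection from difference ops: keep polygonal parts only
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    return MultiPolygon(polys)


@dataclass
class RegionSet:
    """Derived tissue compartments of one slide.

    ``entire`` already has exclusions subtracted; ``tumor`` is the
    intersection of the entire tissue with the annotated tumor; ``non_tumor``
    the remainder.  Areas are reported in mm^2 (coordinates are micrometers).
    Boundary points count as inside (closed regions), with tumor taking
    precedence over non-tumor on their shared boundary.
    """

    entire: MultiPolygon
    tumor: MultiPolygon
    non_tumor: MultiPolygon

    @classmethod
    def from_annotations(cls, tissue, tumor=None, exclusions=None) -> "RegionSet":
        tissue_u = unary_union(tissue) if not isinstance(tissue, (Polygon, MultiPolygon)) else tissue
        if tissue_u.is_empty:
            raise SlideModelError("tissue region is empty")
        if exclusions:
            excl_u = unary_union(exclusions)
            tissue_u = tissue_u.difference(excl_u)
        tumor_u = unary_union(tumor) if tumor else MultiPolygon([])
        tumor_region = tissue_u.intersection(tumor_u) if not tumor_u.is_empty else MultiPolygon([])
        non_tumor = tissue_u.difference(tumor_region) if not tumor_region.is_empty else tissue_u
        return cls(
            entire=_as_multipolygon(tissue_u),
            tumor=_as_multipolygon(tumor_region),
            non_tumor=_as_multipolygon(non_tumor),
        )

    def area_mm2(self, region: str) -> float:
        return getattr(self, region).area / 1e6

    @property
    def areas(self) -> dict:
        return {r: self.area_mm2(r) for r in ("entire", "tumor", "non_tumor")}

    def compartment_of_points(self, x, y) -> np.ndarray:
        """Vectorized compartment assignment: TUMOR / NON_TUMOR / OUTSIDE.

        Uses boundary-inclusive point-in-polygon tests (a point on a polygon
        boundary intersects it), so the convention above holds exactly.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, OUTSIDE, dtype=np.int8)
        in_tissue = shapely.intersects_xy(self.entire, x, y)
        out[in_tissue] = NON_TUMOR
        if not self.tumor.is_empty:
            in_tumor = shapely.intersects_xy(self.tumor, x, y)
            out[in_tissue & in_tumor] = TUMOR
        return out


def compartment_of(point, regions: RegionSet) -> str:
    """Compartment of a single (x, y) point in micrometers."""
    code = regions.compartment_of_points([point[0]], [point[1]])[0]
    return COMPARTMENT_NAMES[int(code)]


# ---------------------------------------------------------------------------
# slide container


@dataclass
class SlideObjects:
    """One slide: derived regions plus typed cell points (micrometers).

    Arrays are parallel; every retained object lies in the entire tissue and
    ``compartment`` is TUMOR or NON_TUMOR for each of them.
    """

    slide_id: str
    regions: RegionSet
    x: np.ndarray
    y: np.ndarray
    marker_code: np.ndarray
    prolif: np.ndarray
    compartment: np.ndarray = field(default=None)
    n_dropped_outside: int = 0
    n_dropped_excluded: int = 0

    def __post_init__(self):
        self.x = np.ascontiguousarray(self.x, dtype=float)
        self.y = np.ascontiguousarray(self.y, dtype=float)
        self.marker_code = np.asarray(self.marker_code, dtype=np.int8)
        self.prolif = np.asarray(self.prolif, dtype=bool)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise SlideModelError("object coordinates must be finite")
        if self.compartment is None:
            self.compartment = self.regions.compartment_of_points(self.x, self.y)

    @classmethod
    def from_arrays(cls, slide_id, regions, x, y, marker, prolif) -> "SlideObjects":
        """Build a slide from raw arrays, dropping objects outside the tissue.

        ``marker`` may be marker names or integer codes.  Objects falling
        outside the (exclusion-subtracted) entire tissue are removed and
        counted; exclusions are already part of the region geometry, so this
        single filter implements both drop rules.
        """
        marker = np.asarray(marker)
        if marker.dtype.kind in "UO":
            bad = set(np.unique(marker)) - set(MARKERS)
            if bad:
                raise SlideModelError(f"unknown marker(s): {sorted(bad)}")
            code = np.array([_MARKER_CODE[m] for m in marker], dtype=np.int8)
        else:
            code = np.asarray(marker, dtype=np.int8)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        prolif = np.asarray(prolif, dtype=bool)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise SlideModelError("object coordinates must be finite")
        comp = regions.compartment_of_points(x, y)
        keep = comp != OUTSIDE
        n_out = int((~keep).sum())
        if n_out:
            logger.info("slide %s: dropped %d objects outside tissue/excluded", slide_id, n_out)
        return cls(
            slide_id=slide_id,
            regions=regions,
            x=x[keep],
            y=y[keep],
            marker_code=code[keep],
            prolif=prolif[keep],
            compartment=comp[keep],
            n_dropped_outside=n_out,
        )

    @property
    def n_objects(self) -> int:
        return int(self.x.size)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def marker_names(self) -> np.ndarray:
        return np.array(MARKERS)[self.marker_code]

    def set_mask(self, oset: ObjectSet) -> np.ndarray:
        return oset.mask(self.marker_code, self.prolif)

    def region_mask(self, region: str) -> np.ndarray:
        if region == "entire":
            return np.ones(self.n_objects, dtype=bool)
        if region == "tumor":
            return self.compartment == TUMOR
        if region == "non_tumor":
            return self.compartment == NON_TUMOR
        raise ValueError(f"unknown region {region!r}")

    def content_hash(self) -> str:
        """Stable hash of coordinates, types, and region geometry (for caching)."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.x.tobytes())
        h.update(self.y.tobytes())
        h.update(self.marker_code.tobytes())
        h.update(self.prolif.tobytes())
        h.update(shapely.to_wkb(self.regions.entire))
        h.update(shapely.to_wkb(self.regions.tumor))
        return h.hexdigest()


# ---------------------------------------------------------------------------
# labels


@dataclass
class CohortLabels:
    """Binary endpoint labels, slide_id -> class label (e.g. MSI / MSS)."""

    labels: dict

    def __post_init__(self):
        classes = sorted(set(self.labels.values()))
        if len(classes) != 2:
            raise SlideModelError(f"need exactly 2 classes, got {classes}")
        self.classes = tuple(classes)

    def class_of(self, slide_id: str) -> str:
        return self.labels[slide_id]

    def slide_ids(self, cls=None):
        if cls is None:
            return sorted(self.labels)
        return sorted(s for s, c in self.labels.items() if c == cls)

    @property
    def class_counts(self) -> tuple:
        return tuple(len(self.slide_ids(c)) for c in self.classes)


# ---------------------------------------------------------------------------
# I/O: GeoJSON regions, CSV objects, CSV labels

REGION_ROLES = ("tissue", "tumor", "exclude")
OBJECT_COLUMNS = ["slide_id", "x_um", "y_um", "marker", "proliferating"]


def read_regions_geojson(path) -> RegionSet:
    """Read a FeatureCollection of Polygon/MultiPolygon features.

    Each feature must carry a ``role`` property in {tissue, tumor, exclude};
    coordinates are micrometers.  At least one tissue polygon is required.
    """
    with open(path) as fh:
        doc = json.load(fh)
    buckets = {r: [] for r in REGION_ROLES}
    for feat in doc.get("features", []):
        role = (feat.get("properties") or {}).get("role")
        if role not in REGION_ROLES:
            raise SlideModelError(f"{path}: feature with invalid role {role!r}")
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise SlideModelError(f"{path}: role {role!r} feature is not polygonal")
        buckets[role].append(geom)
    if not buckets["tissue"]:
        raise SlideModelError(f"{path}: no polygon with role 'tissue'")
    return RegionSet.from_annotations(
        tissue=buckets["tissue"], tumor=buckets["tumor"], exclusions=buckets["exclude"]
    )


def write_regions_geojson(path, tissue, tumor=None, exclusions=None) -> None:
    feats = []
    for role, geoms in (("tissue", tissue), ("tumor", tumor or []), ("exclude", exclusions or [])):
        for g in geoms if isinstance(geoms, (list, tuple)) else [geoms]:
            feats.append(
                {"type": "Feature", "properties": {"role": role}, "geometry": mapping(g)}
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_objects_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SlideModelError(f"{path}: missing columns {missing}")
    bad_marker = ~df["marker"].isin(MARKERS)
    if bad_marker.any():
        row = int(df.index[bad_marker][0]) + 2  # 1-based, plus header line
        raise SlideModelError(f"{path}: invalid marker at line {row}")
    bad_pro = ~df["proliferating"].isin([0, 1])
    if bad_pro.any():
        row = int(df.index[bad_pro][0]) + 2
        raise SlideModelError(f"{path}: proliferating must be 0/1 at line {row}")
    ki_np = (df["marker"] == "Ki67") & (df["proliferating"] == 0)
    if ki_np.any():
        row = int(df.index[ki_np][0]) + 2
        raise SlideModelError(f"{path}: Ki67 rows must have proliferating=1 (line {row})")
    bad_xy = ~np.isfinite(df["x_um"]) | ~np.isfinite(df["y_um"])
    if bad_xy.any():
        row = int(df.index[bad_xy][0]) + 2
        raise SlideModelError(f"{path}: non-finite coordinate at line {row}")
    return df


def write_objects_csv(path, slide: SlideObjects) -> None:
    pd.DataFrame(
        {
            "slide_id": slide.slide_id,
            "x_um": slide.x,
            "y_um": slide.y,
            "marker": slide.marker_names(),
            "proliferating": slide.prolif.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.17g")  # lossless float round-trip


def load_slide(region_file, objects_file, slide_id=None) -> SlideObjects:
    """Load one slide from a region GeoJSON and an objects CSV.

    Derives compartments, drops objects outside the tissue or inside
    exclusions (counted in the log), and returns a ready-to-analyze
    :class:`SlideObjects`.
    """
    regions = read_regions_geojson(region_file)
    df = read_objects_csv(objects_file)
    if slide_id is None:
        ids = df["slide_id"].unique()
        if len(ids) > 1:
            raise SlideModelError(f"{objects_file}: multiple slide_ids {list(ids)}")
        slide_id = str(ids[0]) if len(ids) else "slide"
    else:
        df = df[df["slide_id"] == slide_id]
    slide = SlideObjects.from_arrays(
        slide_id=slide_id,
        regions=regions,
        x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(),
        marker=df["marker"].to_numpy(),
        prolif=df["proliferating"].to_numpy(dtype=bool),
    )
    logger.info(
        "slide %s: %d objects retained, areas mm^2 %s",
        slide_id,
        slide.n_objects,
        {k: round(v, 4) for k, v in slide.regions.areas.items()},
    )
    return slide


def load_labels(path) -> CohortLabels:
    df = pd.read_csv(path)
    for col in ("slide_id", "label"):
        if col not in df.columns:
            raise SlideModelError(f"{path}: missing column {col!r}")
    if df["slide_id"].duplicated().any():
        dup = df.loc[df["slide_id"].duplicated(), "slide_id"].iloc[0]
        raise SlideModelError(f"{path}: duplicate slide_id {dup!r}")
    return CohortLabels(dict(zip(df["slide_id"].astype(str), df["label"].astype(str))))


def write_labels(path, labels: CohortLabels) -> None:
    pd.DataFrame(
        {"slide_id": labels.slide_ids(), "label": [labels.class_of(s) for s in labels.slide_ids()]}
    ).to_csv(path, index=False)
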