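"""Synthetic slide generation.

Two generators are provided:

* verification slides — square 1 mm tissue sections with exactly two object
  types (1,000 Ki67 tumor-surrogate cells and 50 proliferating CD8 cells)
  placed uniformly under hard distance constraints.  Group A enforces a
  distance > 15 um between every Ki67 and every CD8; group B enforces it
  for 45 of the CD8 while placing the remaining 5 within 15 um of five
  distinct Ki67 anchors.  A minimum pairwise distance of 10 um between all
  points is enforced in both groups.  By construction the fraction of Ki67
  within 15 um of the closest proliferating CD8 is exactly 0 on every
  A-slide and strictly positive on every B-slide, so it separates the two
  groups perfectly whatever the cohort size.

* generic slides — Poisson point process per cell type over a square
  tissue with an optional embedded tumor compartment and optional circular
  hotspots (local intensity multipliers), for exercising region and
  heterogeneity machinery.

Placement uses rejection sampling with a per-object retry budget; densities
are far below jamming, so this converges quickly.  Every generated slide is
certified post hoc by an independent O(n^2) brute-force constraint check
before being returned.  Generation is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import box

from .slide_model import CohortLabels, RegionSet, SlideObjects


class ConstraintError(RuntimeError):
    """Raised when a placement budget is exhausted or certification fails."""


@dataclass
class SyntheticSlideConfig:
    """Parameters of the verification-slide construction."""

    tissue_edge: float = 1000.0  # um
    n_ki67: int = 1000
    n_cd8: int = 50
    min_pairwise: float = 10.0  # um, between all object points
    cross_threshold: float = 15.0  # um, Ki67-to-CD8 separation being enforced
    group: str = "A"
    n_violators: int = 5  # group B: CD8 placed within cross_threshold of a Ki67
    max_tries: int = 10000

    def __post_init__(self):
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        if self.min_pairwise >= self.tissue_edge:
            raise ValueError("min_pairwise must be smaller than the tissue edge")
        if self.n_violators > self.n_cd8:
            raise ValueError("n_violators cannot exceed the CD8 count")


@dataclass
class Hotspot:
    """Circular region where one type's intensity is multiplied."""

    center: tuple
    radius: float  # um
    type_name: str
    multiplier: float


#: order fixes generation determinism
ATOMIC_TYPES = ("ki67", "cd4_prolif", "cd4_nonprolif", "cd8_prolif", "cd8_nonprolif")
_ATOM_MARKER = {
    "ki67": ("Ki67", True),
    "cd4_prolif": ("CD4", True),
    "cd4_nonprolif": ("CD4", False),
    "cd8_prolif": ("CD8", True),
    "cd8_nonprolif": ("CD8", False),
}

#: default per-type intensities (1/mm^2): a moderately inflamed specimen
DEFAULT_INTENSITIES = {
    "ki67": 800.0,
    "cd4_prolif": 30.0,
    "cd4_nonprolif": 150.0,
    "cd8_prolif": 40.0,
    "cd8_nonprolif": 180.0,
}


@dataclass
class GenericSlideConfig:
    """Parameters of the generic Poisson slide generator."""

    tissue_edge: float = 1000.0
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    tumor_fraction: Optional[float] = None  # centered-square tumor area fraction
    hotspots: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# verification slides


def _place_points(rng, n, edge, others, min_d, forbidden=None, forbid_d=None,
                  max_tries=10000):
    """Sequentially place n uniform points with distance constraints.

    Each point must be >= min_d from everything placed so far (``others``
    plus earlier accepted points) and > forbid_d from every ``forbidden``
    point.  Vectorized candidate checks; raises when the retry budget for a
    single point is exhausted.
    """
    placed = np.empty((0, 2)) if others is None else np.asarray(others, float)
    n_pre = placed.shape[0]
    pts = np.empty((n, 2))
    forbidden = None if forbidden is None or len(forbidden) == 0 else np.asarray(forbidden, float)
    for i in range(n):
        current = np.vstack([placed, pts[:i]]) if i else placed
        for _ in range(max_tries):
            cand = rng.uniform(0.0, edge, size=2)
            if current.shape[0] and np.min(np.hypot(*(current - cand).T)) < min_d:
                continue
            if forbidden is not None and np.min(np.hypot(*(forbidden - cand).T)) <= forbid_d:
                continue
            pts[i] = cand
            break
        else:
            raise ConstraintError(
                f"placement budget exhausted after {n_pre + i} points "
                f"(min_pairwise={min_d}, separation>{forbid_d})"
            )
    return pts


def _square_regions(edge: float) -> RegionSet:
    return RegionSet.from_annotations(tissue=box(0.0, 0.0, edge, edge))


def generate_verification_slide(config: SyntheticSlideConfig, seed,
                                slide_id: Optional[str] = None) -> SlideObjects:
    """One certified group-A or group-B slide (no tumor compartment)."""
    rng = np.random.default_rng(seed)
    edge, min_d, theta = config.tissue_edge, config.min_pairwise, config.cross_threshold
    ki = _place_points(rng, config.n_ki67, edge, None, min_d, max_tries=config.max_tries)

    violators = np.empty((0, 2))
    if config.group == "B" and config.n_violators:
        anchors = rng.choice(config.n_ki67, size=config.n_violators, replace=False)
        vlist = []
        for a in anchors:
            placed = np.vstack([ki, *vlist]) if vlist else ki
            others = np.delete(placed, a, axis=0) if not vlist else np.vstack(
                [np.delete(ki, a, axis=0), *vlist]
            )
            for _ in range(config.max_tries):
                r = rng.uniform(min_d, theta)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                cand = ki[a] + r * np.array([np.cos(phi), np.sin(phi)])
                if not (0.0 <= cand[0] <= edge and 0.0 <= cand[1] <= edge):
                    continue
                if np.min(np.hypot(*(others - cand).T)) < min_d:
                    continue
                vlist.append(cand.reshape(1, 2))
                break
            else:
                raise ConstraintError("could not place a group-B violator CD8 near its anchor")
        violators = np.vstack(vlist)

    n_clean = config.n_cd8 - violators.shape[0]
    clean = _place_points(
        rng, n_clean, edge, np.vstack([ki, violators]), min_d,
        forbidden=ki, forbid_d=theta, max_tries=config.max_tries,
    )
    cd8 = np.vstack([violators, clean])

    certify_verification(ki, cd8, config)

    xy = np.vstack([ki, cd8])
    marker = np.array(["Ki67"] * config.n_ki67 + ["CD8"] * config.n_cd8)
    prolif = np.ones(len(xy), dtype=bool)
    return SlideObjects.from_arrays(
        slide_id=slide_id or f"verif_{config.group}_{seed}",
        regions=_square_regions(edge),
        x=xy[:, 0], y=xy[:, 1], marker=marker, prolif=prolif,
    )


def certify_verification(ki: np.ndarray, cd8: np.ndarray, config: SyntheticSlideConfig,
                         tol: float = 1e-9) -> None:
    """Independent brute-force check of every construction constraint.

    Uses plain pairwise distance matrices (no KD-tree) so it is independent
    of the feature-computation path.  Raises :class:`ConstraintError` on any
    violation; generation never returns an uncertified slide.
    """
    edge, min_d, theta = config.tissue_edge, config.min_pairwise, config.cross_threshold
    allp = np.vstack([ki, cd8])
    if np.any(allp < -tol) or np.any(allp > edge + tol):
        raise ConstraintError("object outside tissue square")
    d_all = cdist(allp, allp)
    np.fill_diagonal(d_all, np.inf)
    if d_all.min() < min_d - tol:
        raise ConstraintError(f"pairwise distance {d_all.min():.3f} < {min_d}")
    d_cross = cdist(cd8, ki).min(axis=1)  # per-CD8 distance to nearest Ki67
    n_close = int((d_cross <= theta).sum())
    expected = 0 if config.group == "A" else config.n_violators
    if n_close != expected:
        raise ConstraintError(
            f"group {config.group}: {n_close} CD8 within {theta} um of a Ki67, expected {expected}"
        )


def generate_verification_cohort(n_per_group: int = 10, seed: int = 0,
                                 config: Optional[SyntheticSlideConfig] = None):
    """n A-slides (class 'groupA') and n B-slides (class 'groupB').

    Per-slide seeds are spawned from a single SeedSequence, so cohorts are
    reproducible and slides mutually independent.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    base = config or SyntheticSlideConfig()
    children = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    slides, labels = [], {}
    from dataclasses import replace

    for i in range(n_per_group):
        for j, group in enumerate(("A", "B")):
            sid = f"verif_{group}{i:02d}"
            cfg = replace(base, group=group)
            slides.append(
                generate_verification_slide(cfg, children[2 * i + j], slide_id=sid)
            )
            labels[sid] = f"group{group}"
    return slides, CohortLabels(labels)


# ---------------------------------------------------------------------------
# generic slides


def generate_generic_slide(config: GenericSlideConfig, seed,
                           slide_id: str = "generic") -> SlideObjects:
    """Poisson slide with optional tumor compartment and hotspots.

    Counts per type are Poisson(intensity x tissue area); hotspot extras are
    Poisson((multiplier - 1) x intensity x disc area) placed uniformly in
    the disc intersected with the tissue.
    """
    rng = np.random.default_rng(seed)
    edge = config.tissue_edge
    area_mm2 = edge * edge / 1e6
    xs, ys, markers, prolifs = [], [], [], []
    for t in ATOMIC_TYPES:
        lam = config.intensities.get(t, 0.0)
        if lam < 0:
            raise ValueError(f"negative intensity for {t}")
        n = rng.poisson(lam * area_mm2)
        pts = rng.uniform(0.0, edge, size=(n, 2))
        xs.append(pts[:, 0]), ys.append(pts[:, 1])
        m, p = _ATOM_MARKER[t]
        markers += [m] * n
        prolifs += [p] * n
    for h in config.hotspots:
        lam = config.intensities.get(h.type_name, 0.0) * (h.multiplier - 1.0)
        if lam <= 0:
            continue
        disc_mm2 = np.pi * h.radius**2 / 1e6
        n = rng.poisson(lam * disc_mm2)
        r = h.radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        px = h.center[0] + r * np.cos(phi)
        py = h.center[1] + r * np.sin(phi)
        keep = (px >= 0) & (px <= edge) & (py >= 0) & (py <= edge)
        xs.append(px[keep]), ys.append(py[keep])
        m, p = _ATOM_MARKER[h.type_name]
        markers += [m] * int(keep.sum())
        prolifs += [p] * int(keep.sum())

    tumor = None
    if config.tumor_fraction:
        side = edge * np.sqrt(config.tumor_fraction)
        lo, hi = (edge - side) / 2.0, (edge + side) / 2.0
        tumor = box(lo, lo, hi, hi)
    regions = RegionSet.from_annotations(tissue=box(0, 0, edge, edge), tumor=tumor)
    return SlideObjects.from_arrays(
        slide_id=slide_id,
        regions=regions,
        x=np.concatenate(xs) if xs else np.empty(0),
        y=np.concatenate(ys) if ys else np.empty(0),
        marker=np.array(markers, dtype=object),
        prolif=np.array(prolifs, dtype=bool),
    )
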