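"""Ranking features by discriminatory power for a binary endpoint.

Each feature is scored by the folded ROC-AUC of its values between the two
classes — the Mann-Whitney AUC with ties counted 1/2, reflected into
[0.5, 1] (separation direction carries no merit) — and by the overall
performance measure (OPM):

    OPM = 2 * (foldedAUC - 0.5) * (C1f / C1) * (C2f / C2)

where C1, C2 are the class sizes and C1f, C2f the numbers of slides per
class on which the feature is available.  OPM lies in [0, 1]; a feature
with no separation (folded AUC 0.5) or zero availability in a class scores
0.  Features at or above a screening threshold (default 0.6) are flagged
potentially predictive.

Significance is assessed against pseudo-random data: a uniform(0, 1)
feature matrix with the same shape and class assignment, fully available.
Since the AUC is invariant under monotone transforms, the uniform null is
representative of any continuous feature distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .slide_model import CohortLabels

DEFAULT_SCREENING_THRESHOLD = 0.6


@dataclass
class FeatureMatrix:
    """Slides x features value table with explicit unavailability.

    ``values`` is a pandas DataFrame indexed by slide_id; unavailable
    entries are NaN.  All available values are finite by construction
    (non-finite global ratios are mapped to unavailable upstream), so NaN
    is unambiguous here.
    """

    values: pd.DataFrame
    labels: CohortLabels

    def __post_init__(self):
        missing = set(self.values.index) - set(self.labels.labels)
        if missing:
            raise ValueError(f"slides without labels: {sorted(missing)[:5]}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_matrices(self):
        c1, c2 = self.labels.classes
        ids1 = [s for s in self.values.index if self.labels.class_of(s) == c1]
        ids2 = [s for s in self.values.index if self.labels.class_of(s) == c2]
        return self.values.loc[ids1], self.values.loc[ids2]


def mann_whitney_auc(values1, values2) -> float:
    """AUC via midranks: P(X2 > X1) + 0.5 P(X2 = X1), class 2 as positive."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    n1, n2 = v1.size, v2.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes need at least one value")
    ranks = rankdata(np.concatenate([v1, v2]))
    r2 = ranks[n1:].sum()
    u2 = r2 - n2 * (n2 + 1) / 2.0
    return float(u2 / (n1 * n2))


def folded_auc(values1, values2) -> float:
    """ROC-AUC folded into [0.5, 1]: 1 - AUC is taken when AUC < 0.5."""
    auc = mann_whitney_auc(values1, values2)
    return max(auc, 1.0 - auc)


def opm(folded: float, c1: int, c2: int, c1f: int, c2f: int) -> float:
    """Overall performance measure: folded AUC rescaled to [0, 1] and
    multiplied by the per-class availability fractions."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("class totals must be positive")
    if not (0 <= c1f <= c1 and 0 <= c2f <= c2):
        raise ValueError("per-class availability cannot exceed class totals")
    return 2.0 * (folded - 0.5) * (c1f / c1) * (c2f / c2)


def _folded_auc_rows(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Vectorized folded AUC per row of two (n_features x n_slides) blocks.

    Rows must be fully available (no NaN).  Midranks handle ties exactly as
    the scalar path does.
    """
    n1, n2 = m1.shape[1], m2.shape[1]
    both = np.concatenate([m1, m2], axis=1)
    ranks = rankdata(both, axis=1)
    r2 = ranks[:, n1:].sum(axis=1)
    auc = (r2 - n2 * (n2 + 1) / 2.0) / (n1 * n2)
    return np.maximum(auc, 1.0 - auc)


def rank_features(matrix: FeatureMatrix,
                  screening_threshold: float = DEFAULT_SCREENING_THRESHOLD) -> pd.DataFrame:
    """Score and rank every feature of a cohort matrix.

    Returns a frame with columns folded_auc, c1f, c2f, opm,
    potentially_predictive, sorted by descending OPM with ties broken by
    canonical feature id.  Features with zero availability in either class
    are unrankable: folded_auc is NaN and OPM 0.
    """
    m1df, m2df = matrix.class_matrices()
    c1, c2 = m1df.shape[0], m2df.shape[0]
    if c1 == 0 or c2 == 0:
        raise ValueError("both classes must be non-empty")
    feats = matrix.values.columns
    m1 = m1df.to_numpy(dtype=float).T  # features x slides
    m2 = m2df.to_numpy(dtype=float).T
    av1 = ~np.isnan(m1)
    av2 = ~np.isnan(m2)
    c1f = av1.sum(axis=1)
    c2f = av2.sum(axis=1)
    folded = np.full(len(feats), np.nan)
    rankable = (c1f > 0) & (c2f > 0)

    # group features by availability pattern so each group ranks vectorized
    pattern = np.concatenate([av1, av2], axis=1)
    full = pattern.all(axis=1) & rankable
    if full.any():
        folded[full] = _folded_auc_rows(m1[full], m2[full])
    rest = rankable & ~full
    if rest.any():
        idx_rest = np.flatnonzero(rest)
        keys = {}
        for i in idx_rest:
            keys.setdefault(pattern[i].tobytes(), []).append(i)
        for rows in keys.values():
            rows = np.asarray(rows)
            sel1 = av1[rows[0]]
            sel2 = av2[rows[0]]
            folded[rows] = _folded_auc_rows(m1[rows][:, sel1], m2[rows][:, sel2])

    opm_vals = np.where(
        rankable, 2.0 * (np.nan_to_num(folded, nan=0.5) - 0.5) * (c1f / c1) * (c2f / c2), 0.0
    )
    out = pd.DataFrame(
        {
            "feature": feats,
            "folded_auc": folded,
            "c1f": c1f,
            "c2f": c2f,
            "opm": opm_vals,
            "potentially_predictive": opm_vals >= screening_threshold,
        }
    )
    out = out.sort_values(["opm", "feature"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def significance_null(n_features: int, labels: CohortLabels, seed: int,
                      thresholds=(DEFAULT_SCREENING_THRESHOLD,), n_bins: int = 50) -> dict:
    """OPM distribution of a fully-available uniform-random feature matrix.

    The matrix has one column per labeled slide and ``n_features`` rows of
    iid uniform(0, 1) values; class assignment matches the cohort.  Returns
    the OPM values, a histogram on [0, 1], and exceedance counts at the
    given thresholds.  Fully deterministic given ``seed``.
    """
    c1, c2 = labels.class_counts
    if c1 == 0 or c2 == 0:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    m1 = rng.random((n_features, c1))
    m2 = rng.random((n_features, c2))
    folded = _folded_auc_rows(m1, m2)
    opm_vals = 2.0 * (folded - 0.5)  # full availability
    counts, edges = np.histogram(opm_vals, bins=n_bins, range=(0.0, 1.0))
    return {
        "opm": opm_vals,
        "histogram": (edges, counts),
        "exceedance": {float(t): int((opm_vals >= t).sum()) for t in thresholds},
        "n_features": int(n_features),
        "class_sizes": (c1, c2),
        "seed": int(seed),
    }


def opm_histogram_frame(opm_values, n_bins: int = 50, label: str = "real") -> pd.DataFrame:
    """Histogram of OPM values as a tidy frame (for null-vs-real comparison)."""
    counts, edges = np.histogram(np.asarray(opm_values, float), bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts, "which": label}
    )
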