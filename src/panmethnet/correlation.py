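"""Pearson correlation engine and correlation-profile clustering.

Correlations run over arbitrary feature-set pairs — expression against
expression, 450K probeset betas, or RPPA protein levels — either pooled
over all samples or per cohort, with pairwise-complete missing handling
(RPPA panels differ by cohort, so listwise deletion would discard data).

Significance is a two-sided p from the t transform ``t = r·√((n−2)/(1−r²))``
with n − 2 degrees of freedom; a pair is flagged significant when
|r| ≥ r_min and p ≤ p_max. Defaults: (0.3, 0.05) for
expression/protein runs, (0.3, 0.01) for per-cohort methylation–expression
runs — both plain config values, never hard-coded downstream.

:func:`cluster_profiles` groups features by their correlation profiles with
agglomerative average-linkage clustering on Euclidean distances, cut to a
fixed number of clusters (seven by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .data_model import OmicsMatrix

logger = logging.getLogger("panmethnet")

DEFAULT_R_MIN = 0.3
DEFAULT_P_MAX = 0.05
METHYLATION_P_MAX = 0.01

RESULT_COLUMNS = (
    "feature_a", "feature_b", "cohort", "r", "p_value", "n", "significant",
)


@dataclass(frozen=True)
class CorrelationThresholds:
    r_min: float = DEFAULT_R_MIN
    p_max: float = DEFAULT_P_MAX


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with a two-sided p from the t transform.

    Missing values are removed pairwise. Fewer than 3 complete pairs or a
    constant vector yields (nan, nan, n) with a logged reason.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        logger.info("pearson skipped: only %d complete pairs", n)
        return float("nan"), float("nan"), n
    sx = x.std(ddof=0)
    sy = y.std(ddof=0)
    if sx == 0.0 or sy == 0.0:
        logger.info("pearson skipped: constant input")
        return float("nan"), float("nan"), n
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def _pairwise_block(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pairwise-complete Pearson between the rows of a and b.

    Returns (r, p, n) arrays of shape (a_rows, b_rows). Entries with fewer
    than 3 complete pairs or zero variance are NaN.
    """
    a_ok = ~np.isnan(a)
    b_ok = ~np.isnan(b)
    az = np.where(a_ok, a, 0.0)
    bz = np.where(b_ok, b, 0.0)
    n = a_ok.astype(float) @ b_ok.T.astype(float)
    s_a = az @ b_ok.T.astype(float)
    s_b = a_ok.astype(float) @ bz.T
    s_ab = az @ bz.T
    s_aa = (az * az) @ b_ok.T.astype(float)
    s_bb = a_ok.astype(float) @ (bz * bz).T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ab - s_a * s_b / n
        var_a = s_aa - s_a * s_a / n
        var_b = s_bb - s_b * s_b / n
        r = cov / np.sqrt(var_a * var_b)
        r = np.clip(r, -1.0, 1.0)
        bad = (n < 3) | (var_a <= 0) | (var_b <= 0)
        r = np.where(bad, np.nan, r)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        p = np.where(np.isnan(r), np.nan, p)
    return r, p, n.astype(int)


def correlate_sets(
    a: OmicsMatrix,
    b: OmicsMatrix,
    metadata: pd.DataFrame | None = None,
    mode: str = "pooled",
    thresholds: CorrelationThresholds = CorrelationThresholds(),
    source: str | None = None,
) -> pd.DataFrame:
    """All (feature of a) × (feature of b) correlations over shared samples.

    ``mode='per_cohort'`` restricts to each cohort's samples (requires
    metadata); ``source`` optionally restricts to tumor or normal samples.
    Pairs with fewer than 3 complete observations are skipped and logged.
    """
    if mode not in ("pooled", "per_cohort"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if metadata is not None:
        meta = metadata.set_index("sample_id")
        shared = [s for s in shared if s in meta.index]
        if source is not None:
            shared = [s for s in shared if meta.loc[s, "source"] == source]
    elif mode == "per_cohort":
        raise ValueError("per_cohort mode requires sample metadata")
    if not shared:
        raise ValueError("no shared samples between matrices")

    av = a.values.loc[:, shared]
    bv = b.values.loc[:, shared]
    if mode == "pooled":
        groups = [("pooled", np.ones(len(shared), dtype=bool))]
    else:
        cohorts = meta.loc[shared, "cohort"].to_numpy()
        groups = [(str(c), cohorts == c) for c in pd.unique(cohorts)]

    rows = []
    n_skipped = 0
    for label, mask in groups:
        r_blk, p_blk, n_blk = _pairwise_block(
            av.to_numpy()[:, mask], bv.to_numpy()[:, mask]
        )
        for i, fa in enumerate(av.index):
            for j, fb in enumerate(bv.index):
                n_ij = int(n_blk[i, j])
                if n_ij < 3 or np.isnan(r_blk[i, j]):
                    n_skipped += 1
                    continue
                r_ij = float(r_blk[i, j])
                p_ij = float(p_blk[i, j])
                sig = abs(r_ij) >= thresholds.r_min and p_ij <= thresholds.p_max
                rows.append((fa, fb, label, r_ij, p_ij, n_ij, sig))
    if n_skipped:
        logger.info("correlate_sets: skipped %d pairs with n < 3 or no variance",
                    n_skipped)
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def correlation_grid(table: pd.DataFrame, cohort: str = "pooled") -> pd.DataFrame:
    """Pivot a long correlation table into a feature_a × feature_b r-grid."""
    sub = table[table["cohort"] == cohort]
    return sub.pivot(index="feature_a", columns="feature_b", values="r")


def cluster_profiles(correlation_grid: pd.DataFrame, k: int) -> pd.Series:
    """Average-linkage / Euclidean agglomerative clustering of the grid's
    rows, cut to exactly k clusters.

    Missing r entries are treated as 0 (logged). Rows are processed in
    lexicographic feature order and cluster labels renumbered by first
    appearance, so the labeling is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > correlation_grid.shape[0]:
        raise ValueError(
            f"k={k} exceeds the number of rows ({correlation_grid.shape[0]})"
        )
    grid = correlation_grid.sort_index()
    arr = grid.to_numpy(dtype=float)
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        logger.info("cluster_profiles: %d missing r values treated as 0", n_missing)
        arr = np.nan_to_num(arr, nan=0.0)
    if arr.shape[0] == 1:
        raw = np.array([1])
    else:
        tree = linkage(arr, method="average", metric="euclidean")
        raw = fcluster(tree, t=k, criterion="maxclust")
    # renumber by first appearance for determinism
    mapping: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels.append(mapping[lab])
    return pd.Series(labels, index=grid.index, name="cluster")
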