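"""Differential analysis: signed fold change plus Welch's t-test.

The fold change between two groups of log2 expression values is
``±2^|mean2 − mean1|`` on the linear scale, so |FC| ≥ 1 always; the sign is
positive when group 2 has the larger mean and negative when group 1 does
(equal means give +1). Significance comes from a two-tailed unpaired t-test,
Welch's unequal-variance form by default. A feature is called up when
FC ≥ +fc_min and p ≤ p_max, down when FC ≤ −fc_min and p ≤ p_max (defaults
1.4 and 0.05). No multiple-testing correction enters the calls; a
Benjamini–Hochberg column is emitted for reference only.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import OmicsMatrix

logger = logging.getLogger("panmethnet")

DEFAULT_FC_MIN = 1.4
DEFAULT_P_MAX = 0.05

RESULT_COLUMNS = (
    "feature_id", "group1", "group2", "cohort", "n1", "n2", "mean1", "mean2",
    "fc", "t_stat", "p_value", "q_value", "call",
)


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def fold_change(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Signed fold change ±2^|mean2 − mean1| over log2 values.

    Positive when mean(group2) > mean(group1), negative when smaller,
    +1.0 on ties. Missing values are dropped; an entirely-missing group is
    an error.
    """
    g1, g2 = _clean(group1), _clean(group2)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("fold_change requires at least one value per group")
    delta = g2.mean() - g1.mean()
    magnitude = 2.0 ** abs(delta)
    if delta > 0:
        return magnitude
    if delta < 0:
        return -magnitude
    return 1.0


def unpaired_t_test(
    group1: Sequence[float],
    group2: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-tailed unpaired t-test; Welch (unequal variance) by default.

    The t statistic follows the group1 − group2 sign convention. Groups with
    fewer than two values or zero total variance yield (nan, nan) with a
    logged warning rather than an exception, so sparse features survive.
    """
    g1, g2 = _clean(group1), _clean(group2)
    if g1.size < 2 or g2.size < 2:
        logger.warning("t-test skipped: group sizes %d/%d < 2", g1.size, g2.size)
        return float("nan"), float("nan")
    if g1.var(ddof=1) == 0.0 and g2.var(ddof=1) == 0.0:
        if g1.mean() == g2.mean():
            return 0.0, 1.0
        logger.warning("t-test skipped: zero variance in both groups")
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)


def _classify(fc: float, p: float, fc_min: float, p_max: float) -> str:
    if np.isnan(p) or p > p_max:
        return "none"
    if fc >= fc_min:
        return "up"
    if fc <= -fc_min:
        return "down"
    return "none"


def differential_table(
    expression: OmicsMatrix,
    metadata: pd.DataFrame,
    mode: str = "per_cohort",
    thresholds: tuple[float, float] = (DEFAULT_FC_MIN, DEFAULT_P_MAX),
    group1: str = "normal",
    group2: str = "tumor",
    equal_var: bool = False,
) -> pd.DataFrame:
    """One row per feature per comparison (pooled, or each cohort vs its
    matched normals). Cohorts lacking either group are skipped with a
    logged reason. Adds a BH q-value column per comparison (reference only —
    calls use the raw p)."""
    if mode not in ("pooled", "per_cohort"):
        raise ValueError(f"unknown mode {mode!r}")
    fc_min, p_max = thresholds
    meta = metadata.set_index("sample_id")
    samples = [s for s in expression.sample_ids if s in meta.index]
    source = meta.loc[samples, "source"]
    cohort = meta.loc[samples, "cohort"]
    values = expression.values.loc[:, samples]

    comparisons: list[tuple[str, np.ndarray, np.ndarray]] = []
    if mode == "pooled":
        comparisons.append(
            ("pooled", (source == group1).to_numpy(), (source == group2).to_numpy())
        )
    else:
        for c in pd.unique(cohort):
            in_c = (cohort == c).to_numpy()
            m1 = in_c & (source == group1).to_numpy()
            m2 = in_c & (source == group2).to_numpy()
            if m1.sum() == 0 or m2.sum() == 0:
                logger.info("differential_table: cohort %s lacks a %s group, skipped",
                            c, group1 if m1.sum() == 0 else group2)
                continue
            comparisons.append((str(c), m1, m2))

    rows = []
    arr = values.to_numpy()
    for label, m1, m2 in comparisons:
        for i, fid in enumerate(values.index):
            g1 = arr[i, m1]
            g2 = arr[i, m2]
            g1 = g1[~np.isnan(g1)]
            g2 = g2[~np.isnan(g2)]
            if g1.size == 0 or g2.size == 0:
                logger.info("differential_table: %s in %s has an empty group, skipped",
                            fid, label)
                continue
            fc = fold_change(g1, g2)
            t, p = unpaired_t_test(g1, g2, equal_var=equal_var)
            rows.append((fid, group1, group2, label, g1.size, g2.size,
                         float(g1.mean()), float(g2.mean()), fc, t, p))
    table = pd.DataFrame(
        rows, columns=[c for c in RESULT_COLUMNS if c not in ("q_value", "call")]
    )
    qvals = np.full(len(table), np.nan)
    for label in table["cohort"].unique():
        mask = (table["cohort"] == label).to_numpy()
        p = table.loc[mask, "p_value"].to_numpy()
        ok = ~np.isnan(p)
        if ok.any():
            adj = np.full(p.shape, np.nan)
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            qvals[mask] = adj
    table["q_value"] = qvals
    table["call"] = [
        _classify(fc, p, fc_min, p_max)
        for fc, p in zip(table["fc"], table["p_value"])
    ]
    return table[list(RESULT_COLUMNS)]


def cohort_call_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Percentage of cohorts in which each feature is called up / down
    (the per-feature regulation-frequency statistic)."""
    percohort = table[table["cohort"] != "pooled"]
    out = []
    n_cohorts = percohort["cohort"].nunique()
    for fid, sub in percohort.groupby("feature_id", sort=False):
        n_up = int((sub["call"] == "up").sum())
        n_down = int((sub["call"] == "down").sum())
        out.append((fid, n_cohorts, n_up, n_down,
                    100.0 * n_up / n_cohorts if n_cohorts else float("nan"),
                    100.0 * n_down / n_cohorts if n_cohorts else float("nan")))
    return pd.DataFrame(
        out, columns=["feature_id", "n_cohorts", "n_up", "n_down",
                      "pct_up", "pct_down"],
    )


def volcano_table(table: pd.DataFrame) -> pd.DataFrame:
    """(feature, cohort, fc, −log10 p) rows for external volcano plotting."""
    out = table.loc[:, ["feature_id", "cohort", "fc", "p_value", "call"]].copy()
    with np.errstate(divide="ignore"):
        out["minus_log10_p"] = -np.log10(out["p_value"])
    return out
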