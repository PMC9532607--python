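"""Kaplan–Meier / log-rank annotation of features against OS and PFI.

Each feature is dichotomized at the median of the included samples (ties to
the low group), the two groups are compared with the standard two-group
log-rank chi-square test (1 df, hypergeometric variance at each distinct
event time), and a favorable/unfavorable direction is called when p ≤ 0.05:
favorable when the high-feature group shows the better survival curve —
operationalized as the higher restricted-mean survival over the observed
horizon — unfavorable otherwise.

The log-rank computation is delegated to lifelines; restricted means come
from Kaplan–Meier fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time

from .data_model import OmicsMatrix

logger = logging.getLogger("panmethnet")

DEFAULT_P_MAX = 0.05

ANNOTATION_COLUMNS = (
    "feature_id", "cohort", "endpoint", "logrank_stat", "p_value",
    "direction", "high_group_better", "n_high", "n_low",
)


@dataclass(frozen=True)
class SurvivalAnnotation:
    feature_id: str
    cohort: str
    endpoint: str
    logrank_stat: float
    p_value: float
    direction: str  # favorable | unfavorable | none
    high_group_better: bool
    n_high: int
    n_low: int


def logrank(
    times_1: Sequence[float], events_1: Sequence[int],
    times_2: Sequence[float], events_2: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p.

    Zero events overall returns (0, 1) with a logged note rather than an
    error.
    """
    t1 = np.asarray(times_1, dtype=float)
    t2 = np.asarray(times_2, dtype=float)
    e1 = np.asarray(events_1, dtype=int)
    e2 = np.asarray(events_2, dtype=int)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("logrank requires both groups non-empty")
    if e1.sum() + e2.sum() == 0:
        logger.info("logrank: no events in either group")
        return 0.0, 1.0
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def _restricted_mean(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    km = KaplanMeierFitter().fit(times, events)
    return float(restricted_mean_survival_time(km, t=horizon))


def annotate_feature(
    values: pd.Series,
    survival: pd.DataFrame,
    endpoint: str,
    split: str = "median",
    feature_id: str = "",
    cohort: str = "",
    p_max: float = DEFAULT_P_MAX,
) -> SurvivalAnnotation | None:
    """Median-split log-rank annotation of one feature in one cohort.

    ``values`` is indexed by sample id. Samples need both a value and a
    survival record; fewer than 4 such samples, or an empty group after the
    split, skips the annotation with a logged reason.
    """
    if split != "median":
        raise ValueError(f"unsupported split {split!r}")
    records = survival[survival["endpoint"] == endpoint].set_index("sample_id")
    shared = [s for s in values.index if s in records.index and not np.isnan(values[s])]
    if len(shared) < 4:
        logger.info("annotate_feature skipped for %s/%s: %d usable samples",
                    feature_id, cohort, len(shared))
        return None
    v = values.loc[shared].to_numpy(dtype=float)
    med = float(np.median(v))
    high = v > med  # ties to the low group
    if high.sum() == 0 or (~high).sum() == 0:
        logger.info("annotate_feature skipped for %s/%s: single group after split",
                    feature_id, cohort)
        return None
    times = records.loc[shared, "time"].to_numpy(dtype=float)
    events = records.loc[shared, "event"].to_numpy(dtype=int)
    stat, p = logrank(times[high], events[high], times[~high], events[~high])
    horizon = float(times.max())
    rm_high = _restricted_mean(times[high], events[high], horizon)
    rm_low = _restricted_mean(times[~high], events[~high], horizon)
    high_better = rm_high > rm_low
    if p <= p_max:
        direction = "favorable" if high_better else "unfavorable"
    else:
        direction = "none"
    return SurvivalAnnotation(
        feature_id, cohort, endpoint, stat, p, direction, bool(high_better),
        int(high.sum()), int((~high).sum()),
    )


def annotate_matrix(
    matrix: OmicsMatrix,
    metadata: pd.DataFrame,
    survival: pd.DataFrame,
    endpoints: Sequence[str] = ("OS", "PFI"),
    split: str = "median",
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Annotate every feature of the matrix per cohort and endpoint."""
    meta = metadata.set_index("sample_id")
    samples = [
        s for s in matrix.sample_ids
        if s in meta.index and meta.loc[s, "source"] == "tumor"
    ]
    cohorts = meta.loc[samples, "cohort"]
    rows = []
    for c in pd.unique(cohorts):
        cols = [s for s in samples if cohorts[s] == c]
        for fid in matrix.feature_ids:
            values = matrix.values.loc[fid, cols]
            for endpoint in endpoints:
                ann = annotate_feature(
                    values, survival, endpoint, split=split,
                    feature_id=fid, cohort=str(c), p_max=p_max,
                )
                if ann is not None:
                    rows.append(tuple(getattr(ann, f) for f in ANNOTATION_COLUMNS))
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def survival_volcano(annotations: pd.DataFrame) -> pd.DataFrame:
    """Volcano-ready rows: signed log-rank statistic (negative = the
    high-feature group fares better, i.e. favorable) and −log10 p."""
    out = annotations.loc[:, ["feature_id", "cohort", "endpoint"]].copy()
    sign = np.where(annotations["high_group_better"], -1.0, 1.0)
    out["signed_stat"] = sign * annotations["logrank_stat"].to_numpy()
    with np.errstate(divide="ignore"):
        out["minus_log10_p"] = -np.log10(annotations["p_value"].to_numpy())
    out["minus_log10_p"] = out["minus_log10_p"].replace(-0.0, 0.0)
    out["direction"] = annotations["direction"].to_numpy()
    return out.sort_values(
        ["endpoint", "cohort", "feature_id"], kind="stable"
    ).reset_index(drop=True)
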