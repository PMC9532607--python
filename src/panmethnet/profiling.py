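"""Expression and methylation profiling against reference distributions.

Three callers:

* :func:`quartile_call` labels a tumor cohort's median expression against
  the interquartile range of the matched normal tissue (above the 3rd or
  below the 1st quartile). Quantiles use linear interpolation (R type-7).
* :func:`outlier_flag` marks a cohort median as abnormally up-/down-
  regulated relative to the medians of all cohorts, using Tukey 1.5×IQR
  fences — the standard boxplot rule.
* :func:`methylation_state` categorizes a probeset in a cohort by its
  median beta value: methylated at ≥ 0.6, unmethylated at ≤ 0.2, partial
  in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import OmicsMatrix

logger = logging.getLogger("panmethnet")

METHYLATED_MIN = 0.6
UNMETHYLATED_MAX = 0.2


@dataclass(frozen=True)
class ProfileSummary:
    feature_id: str
    cohort: str
    median: float
    q1: float
    q3: float
    quartile_call: str  # above_q3 | below_q1 | none
    outlier_flag: str = "none"  # upper | lower | none

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class MethylationState:
    probeset_id: str
    cohort: str
    median_beta: float
    state: str  # methylated | partial | unmethylated


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def quartile_call(
    tumor_values: Sequence[float],
    normal_values: Sequence[float],
    feature_id: str = "",
    cohort: str = "",
) -> ProfileSummary | None:
    """Label the tumor median against the normal-tissue IQR.

    Returns None (with a logged reason) when fewer than 4 normal values are
    available. Type-7 linear-interpolation quantiles.
    """
    tumor = _clean(tumor_values)
    normal = _clean(normal_values)
    if tumor.size < 1:
        logger.info("quartile_call skipped for %s/%s: no tumor values",
                    feature_id, cohort)
        return None
    if normal.size < 4:
        logger.info("quartile_call skipped for %s/%s: only %d normal values",
                    feature_id, cohort, normal.size)
        return None
    q1, q3 = np.quantile(normal, [0.25, 0.75], method="linear")
    med = float(np.median(tumor))
    if med > q3:
        call = "above_q3"
    elif med < q1:
        call = "below_q1"
    else:
        call = "none"
    return ProfileSummary(feature_id, cohort, med, float(q1), float(q3), call)


def outlier_flag(cohort_medians: Sequence[float], candidate: float) -> str:
    """Tukey-fence flag of a candidate median against all cohort medians."""
    medians = _clean(cohort_medians)
    if medians.size < 4:
        raise ValueError("outlier_flag requires at least 4 cohort medians")
    q1, q3 = np.quantile(medians, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    if candidate > q3 + 1.5 * iqr:
        return "upper"
    if candidate < q1 - 1.5 * iqr:
        return "lower"
    return "none"


def methylation_state(
    beta_values: Sequence[float],
    probeset_id: str = "",
    cohort: str = "",
) -> MethylationState | None:
    """Median-beta state: methylated ≥ 0.6, unmethylated ≤ 0.2, else partial."""
    betas = _clean(beta_values)
    if betas.size == 0:
        logger.info("methylation_state skipped for %s/%s: all values missing",
                    probeset_id, cohort)
        return None
    med = float(np.median(betas))
    if med >= METHYLATED_MIN:
        state = "methylated"
    elif med <= UNMETHYLATED_MAX:
        state = "unmethylated"
    else:
        state = "partial"
    return MethylationState(probeset_id, cohort, med, state)


# ---------------------------------------------------------------------------
# matrix-level profiling
# ---------------------------------------------------------------------------

def profile_expression(
    expression: OmicsMatrix, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per feature per cohort: tumor median vs normal IQR call, plus a
    Tukey outlier flag of the cohort median against all cohort medians."""
    meta = metadata.set_index("sample_id")
    samples = [s for s in expression.sample_ids if s in meta.index]
    values = expression.values.loc[:, samples]
    source = meta.loc[samples, "source"].to_numpy()
    cohort = meta.loc[samples, "cohort"].to_numpy()
    arr = values.to_numpy()

    rows: list[ProfileSummary] = []
    for i, fid in enumerate(values.index):
        summaries = []
        for c in pd.unique(cohort):
            in_c = cohort == c
            summary = quartile_call(
                arr[i, in_c & (source == "tumor")],
                arr[i, in_c & (source == "normal")],
                feature_id=fid,
                cohort=str(c),
            )
            if summary is not None:
                summaries.append(summary)
        medians = [s.median for s in summaries]
        if len(medians) >= 4:
            summaries = [
                ProfileSummary(s.feature_id, s.cohort, s.median, s.q1, s.q3,
                               s.quartile_call, outlier_flag(medians, s.median))
                for s in summaries
            ]
        rows.extend(summaries)
    return pd.DataFrame(
        [(s.feature_id, s.cohort, s.median, s.q1, s.q3, s.iqr,
          s.quartile_call, s.outlier_flag) for s in rows],
        columns=["feature_id", "cohort", "median", "q1", "q3", "iqr",
                 "quartile_call", "outlier_flag"],
    )


def profile_methylation(
    methylation: OmicsMatrix, metadata: pd.DataFrame, source: str = "tumor"
) -> pd.DataFrame:
    """Per probeset per cohort: median beta and methylation state over the
    chosen sample source, plus an outlier flag across cohorts."""
    meta = metadata.set_index("sample_id")
    samples = [
        s for s in methylation.sample_ids
        if s in meta.index and meta.loc[s, "source"] == source
    ]
    values = methylation.values.loc[:, samples]
    cohort = meta.loc[samples, "cohort"].to_numpy()
    arr = values.to_numpy()
    rows = []
    for i, pid in enumerate(values.index):
        states = []
        for c in pd.unique(cohort):
            st = methylation_state(arr[i, cohort == c], probeset_id=pid,
                                   cohort=str(c))
            if st is not None:
                states.append(st)
        medians = [s.median_beta for s in states]
        for s in states:
            flag = outlier_flag(medians, s.median_beta) if len(medians) >= 4 else "none"
            rows.append((s.probeset_id, s.cohort, s.median_beta, s.state, flag))
    return pd.DataFrame(
        rows, columns=["feature_id", "cohort", "median", "state", "outlier_flag"]
    )


def call_matrix(
    profiles: pd.DataFrame,
    value_column: str | None = None,
) -> pd.DataFrame:
    """Pivot a long profile table into a cohort × feature call grid.

    The cell holds the quartile call (or methylation state); an outlier flag
    is appended as ``call|flag`` when the flag is not ``none``. The grid is
    TSV-exportable for heatmap tools.
    """
    if profiles.empty:
        raise ValueError("call_matrix requires a non-empty profile table")
    col = value_column or ("quartile_call" if "quartile_call" in profiles else "state")
    calls = profiles[col].astype(str)
    if "outlier_flag" in profiles:
        flagged = profiles["outlier_flag"].astype(str) != "none"
        calls = calls.where(~flagged, calls + "|" + profiles["outlier_flag"].astype(str))
    wide = pd.DataFrame({
        "cohort": profiles["cohort"],
        "feature_id": profiles["feature_id"],
        "call": calls,
    }).pivot(index="cohort", columns="feature_id", values="call")
    return wide
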