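"""Four-group promoter/body methylation stratification.

Tumor samples are split at the central value (median by default, mean
optionally) of a promoter probeset and of a gene-body probeset, computed
over all included samples, giving four groups:

    1 — promoter low  / body high   (expected highest expression)
    2 — promoter low  / body low
    3 — promoter high / body high
    4 — promoter high / body low    (expected lowest expression)

"low" means value ≤ center, "high" means value > center (boundary samples
go low — deterministic and documented). Expression differences between all
six group pairs are then tested with the signed fold change and Welch's t,
with group medians and interquartile ranges reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import OmicsMatrix
from .diffexpr import fold_change, unpaired_t_test

logger = logging.getLogger("panmethnet")

GROUP_DEFINITIONS = {
    1: ("low", "high"),
    2: ("low", "low"),
    3: ("high", "high"),
    4: ("high", "low"),
}


@dataclass
class StratifiedGroups:
    promoter_probe: str
    body_probe: str
    split_value_promoter: float
    split_value_body: float
    assignment: pd.Series  # sample_id -> group 1..4
    n_unassigned: int
    center: str = "median"

    def samples_in(self, group: int) -> list[str]:
        return list(self.assignment.index[self.assignment == group])


def stratify(
    methylation: OmicsMatrix,
    promoter_probe: str,
    body_probe: str,
    center: str = "median",
    sample_ids: list[str] | None = None,
) -> StratifiedGroups:
    """Assign samples to the four promoter/body methylation groups.

    Splits at the median (or mean) of each probe over all included samples;
    samples missing either probe are unassigned and counted.
    """
    if center not in ("median", "mean"):
        raise ValueError(f"unknown center {center!r}")
    for probe in (promoter_probe, body_probe):
        if probe not in methylation.values.index:
            raise ValueError(f"probeset {probe!r} not in methylation matrix")
    cols = sample_ids if sample_ids is not None else methylation.sample_ids
    prom = methylation.values.loc[promoter_probe, cols]
    body = methylation.values.loc[body_probe, cols]
    ok = ~(prom.isna() | body.isna())
    n_unassigned = int((~ok).sum())
    if ok.sum() < 4:
        raise ValueError("stratify requires at least 4 samples with both probes")
    agg = np.median if center == "median" else np.mean
    split_p = float(agg(prom[ok]))
    split_b = float(agg(body[ok]))
    prom_level = np.where(prom[ok] <= split_p, "low", "high")
    body_level = np.where(body[ok] <= split_b, "low", "high")
    lookup = {v: k for k, v in GROUP_DEFINITIONS.items()}
    groups = [lookup[(p, b)] for p, b in zip(prom_level, body_level)]
    assignment = pd.Series(groups, index=prom[ok].index, name="group", dtype=int)
    if n_unassigned:
        logger.info("stratify: %d samples missing a probe value, unassigned",
                    n_unassigned)
    return StratifiedGroups(
        promoter_probe, body_probe, split_p, split_b, assignment,
        n_unassigned, center,
    )


def group_differential(
    expression: OmicsMatrix,
    groups: StratifiedGroups,
    target_feature: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """FC and Welch p for all six unordered group pairs of the target
    feature, with each group's median and IQ range. Pairs with a group of
    fewer than 2 samples are skipped and logged."""
    if target_feature not in expression.values.index:
        raise ValueError(f"feature {target_feature!r} not in expression matrix")
    row = expression.values.loc[target_feature]
    values: dict[int, np.ndarray] = {}
    for g in (1, 2, 3, 4):
        samples = [s for s in groups.samples_in(g) if s in row.index]
        v = row.loc[samples].to_numpy(dtype=float)
        values[g] = v[~np.isnan(v)]
    rows = []
    for g1 in (1, 2, 3):
        for g2 in range(g1 + 1, 5):
            v1, v2 = values[g1], values[g2]
            if v1.size < 2 or v2.size < 2:
                logger.info("group_differential: pair (%d, %d) skipped, "
                            "group sizes %d/%d", g1, g2, v1.size, v2.size)
                continue
            fc = fold_change(v1, v2)
            t, p = unpaired_t_test(v1, v2, equal_var=equal_var)
            q1a, meda, q3a = np.quantile(v1, [0.25, 0.5, 0.75], method="linear")
            q1b, medb, q3b = np.quantile(v2, [0.25, 0.5, 0.75], method="linear")
            rows.append((target_feature, g1, g2, v1.size, v2.size, fc, t, p,
                         float(meda), float(q1a), float(q3a),
                         float(medb), float(q1b), float(q3b)))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "group1", "group2", "n1", "n2", "fc", "t_stat",
                 "p_value", "median1", "q1_1", "q3_1", "median2", "q1_2", "q3_2"],
    )


def group_medians(expression: OmicsMatrix, groups: StratifiedGroups,
                  target_feature: str) -> pd.Series:
    """Median expression of the target feature per group (1..4)."""
    row = expression.values.loc[target_feature]
    meds = {}
    for g in (1, 2, 3, 4):
        samples = [s for s in groups.samples_in(g) if s in row.index]
        v = row.loc[samples].dropna()
        meds[g] = float(v.median()) if len(v) else float("nan")
    return pd.Series(meds, name="median_expression")
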