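"""Correlation and group-comparison layer relating descent measurements to
clinical covariates and to the presence of other posterior-compartment
disorders.

Spearman rank correlations (pairwise complete, average ranks for ties) relate
each descent measure to each numeric covariate, starred at the 0.05 and 0.01
two-sided levels. Independent-samples t-tests (pooled variance by default,
Welch optionally) compare descent between patients with and without each
binary condition. No multiple-testing correction is applied — the tables are
exploratory, one unadjusted p per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError


def significance_marker(p_value: float) -> str:
    if np.isnan(p_value):
        return ""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    measure: str
    covariate: str
    spearman_r: float
    p_value: float
    n: int
    marker: str
    undefined: bool = False


@dataclass(frozen=True)
class GroupComparison:
    condition: str
    measure: str
    mean_present: float
    sd_present: float
    n_present: int
    mean_absent: float
    sd_absent: float
    n_absent: int
    t_statistic: float
    p_value: float
    marker: str


def spearman_pair(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman correlation of one (measure, covariate) pair, pairwise complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"Spearman needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        # constant variable: correlation undefined, flagged rather than raised
        return CorrelationResult("", "", float("nan"), float("nan"), n, "", True)
    r, p = stats.spearmanr(x, y)
    return CorrelationResult("", "", float(r), float(p), n, significance_marker(p))


def spearman_table(
    measures: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """All-pairs Spearman correlations of descent measures with covariates.

    Both inputs are per-patient tables sharing an index; every (covariate,
    measure) cell gets r, two-sided p, n and a star marker.
    """
    measures, covariates = measures.align(covariates, join="inner", axis=0)
    rows = []
    for cov in covariates.columns:
        for meas in measures.columns:
            res = spearman_pair(measures[meas].to_numpy(), covariates[cov].to_numpy())
            rows.append(
                {
                    "covariate": cov,
                    "measure": meas,
                    "spearman_r": res.spearman_r,
                    "p_value": res.p_value,
                    "n": res.n,
                    "marker": res.marker,
                    "undefined": res.undefined,
                }
            )
    return pd.DataFrame(rows)


def ttest_by_condition(
    values: np.ndarray,
    status: np.ndarray,
    condition: str = "",
    measure: str = "",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided independent-samples t-test of a measurement by condition.

    Pooled-variance (classic) test by default; pass ``equal_var=False`` for
    Welch. Group means and SDs are reported in mm.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status, dtype=float)
    keep = ~(np.isnan(values) | np.isnan(status))
    values, status = values[keep], status[keep]
    present = values[status == 1]
    absent = values[status == 0]
    if present.size < 2 or absent.size < 2:
        raise InsufficientDataError(
            f"t-test needs >= 2 complete cases per group, got "
            f"{present.size} present / {absent.size} absent"
        )
    if present.std(ddof=1) == 0.0 and absent.std(ddof=1) == 0.0:
        t, p = (0.0, 1.0) if present.mean() == absent.mean() else (float("inf"), 0.0)
    else:
        t, p = stats.ttest_ind(present, absent, equal_var=equal_var)
    return GroupComparison(
        condition=condition,
        measure=measure,
        mean_present=float(present.mean()),
        sd_present=float(present.std(ddof=1)),
        n_present=int(present.size),
        mean_absent=float(absent.mean()),
        sd_absent=float(absent.std(ddof=1)),
        n_absent=int(absent.size),
        t_statistic=float(t),
        p_value=float(p),
        marker=significance_marker(float(p)),
    )


def condition_table(
    measures: pd.DataFrame, conditions: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Descent-by-condition comparison table: one row per (condition, measure)."""
    measures, conditions = measures.align(conditions, join="inner", axis=0)
    rows = []
    for cond in conditions.columns:
        for meas in measures.columns:
            try:
                res = ttest_by_condition(
                    measures[meas].to_numpy(),
                    conditions[cond].to_numpy(),
                    condition=cond,
                    measure=meas,
                    equal_var=equal_var,
                )
            except InsufficientDataError:
                continue
            rows.append(
                {
                    "condition": cond,
                    "measure": meas,
                    "mean_present": res.mean_present,
                    "sd_present": res.sd_present,
                    "n_present": res.n_present,
                    "mean_absent": res.mean_absent,
                    "sd_absent": res.sd_absent,
                    "n_absent": res.n_absent,
                    "t": res.t_statistic,
                    "p_value": res.p_value,
                    "marker": res.marker,
                }
            )
    return pd.DataFrame(rows)
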