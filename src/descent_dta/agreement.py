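"""Interobserver and between-modality agreement statistics.

Interobserver agreement uses the intraclass correlation coefficient from a
two-way random-effects model with a consistency definition, single measure —
ICC(C,1) in McGraw & Wong's taxonomy. Repeatability bands: below 0.50 poor,
0.50-0.75 moderate, 0.75-0.90 good, above 0.90 excellent.

Between-modality agreement uses Bland-Altman limits of agreement,
LOA = delta +/- 1.96 * SDd, where delta is the mean of the per-subject
differences A - B and SDd their sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

Z95 = 1.96

ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"))


def icc_category(icc: float) -> str:
    """Map an ICC value to its repeatability band."""
    for upper, label in ICC_BANDS:
        if icc < upper or (label == "good" and icc <= upper):
            return label
    return "excellent"


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    mean_diff: float
    sd_diff: float
    n_pairs: int
    category: str


@dataclass(frozen=True)
class BlandAltmanResult:
    delta: float
    sd_d: float
    loa_lower: float
    loa_upper: float
    delta_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    n_pairs: int


def icc_consistency(
    obs1: np.ndarray, obs2: np.ndarray, alpha: float = 0.05
) -> AgreementResult:
    """Single-measure consistency ICC for two raters, ICC(C,1).

    Computed from the two-way ANOVA decomposition with subjects and raters as
    crossed factors:

        ICC(C,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)

    with k = 2 raters; MS_error is the residual (subject x rater interaction)
    mean square, so a constant offset between raters does not lower the ICC.
    The 95% CI is the standard F-based interval for ICC(C,1). Subjects with a
    missing value in either column are dropped.
    """
    x = np.asarray(obs1, dtype=float)
    y = np.asarray(obs2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observer vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    k = 2
    if n < 3:
        raise InsufficientDataError(
            f"ICC needs >= 3 complete subject pairs, got {n}"
        )
    data = np.column_stack([x, y])
    grand = data.mean()
    subject_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_subjects = k * ((subject_means - grand) ** 2).sum()
    ss_raters = n * ((rater_means - grand) ** 2).sum()
    # the residual SS is nonnegative by construction; cancellation can leave
    # it a few ulp off zero either way, so snap near-zero residuals to zero
    # (constant-offset raters must return ICC exactly 1)
    ss_error = ss_total - ss_subjects - ss_raters
    if ss_error <= 1e-12 * ss_total:
        ss_error = 0.0
    if ss_total == 0.0:
        raise DegenerateInputError("all measurements identical; ICC undefined")
    ms_subjects = ss_subjects / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))

    if ms_subjects + (k - 1) * ms_error == 0.0:
        raise DegenerateInputError("zero between- and within-subject variance")
    if ms_error == 0.0:
        icc, lo, hi = 1.0, 1.0, 1.0
    else:
        icc = (ms_subjects - ms_error) / (ms_subjects + (k - 1) * ms_error)
        f_obs = ms_subjects / ms_error
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_upper = stats.f.ppf(1 - alpha / 2, df1, df2)
        f_lower = stats.f.ppf(1 - alpha / 2, df2, df1)
        fl = f_obs / f_upper
        fu = f_obs * f_lower
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)

    diffs = x - y
    return AgreementResult(
        icc=float(icc),
        icc_ci_low=float(lo),
        icc_ci_high=float(hi),
        mean_diff=float(diffs.mean()),
        sd_diff=float(diffs.std(ddof=1)),
        n_pairs=int(n),
        category=icc_category(float(icc)),
    )


def average_observers(records: pd.DataFrame) -> pd.DataFrame:
    """Consensus measurement per patient-modality: mean of available observers.

    Input is the long-format measurement table. If only one observer read an
    exam, that single reading is the consensus; if both are absent the entry
    stays absent. Returns a long table indexed by (patient_id, modality) with
    static_mm / valsalva_mm / dynamic_mm columns.
    """
    value_cols = [c for c in ("static_mm", "valsalva_mm", "dynamic_mm") if c in records]
    return (
        records.groupby(["patient_id", "modality"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def consensus_wide(records: pd.DataFrame, measure: str = "dynamic_mm") -> pd.DataFrame:
    """Patients x modalities table of consensus values for one measure."""
    avg = average_observers(records)
    return avg.pivot(index="patient_id", columns="modality", values=measure)


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements A and B.

    delta = mean(A - B); SDd = sample SD of the differences (n-1 denominator);
    LOA = delta +/- 1.96 SDd. The CI of delta uses SE = SDd/sqrt(n); the CIs
    of the LOA use the large-sample approximation SE(LOA) = SDd * sqrt(3/n).
    Subjects missing either measurement are dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"Bland-Altman needs >= 3 complete pairs, got {n}")
    delta = float(d.mean())
    sd_d = float(d.std(ddof=1))
    loa_lower = delta - Z95 * sd_d
    loa_upper = delta + Z95 * sd_d
    se_delta = sd_d / np.sqrt(n)
    se_loa = sd_d * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        delta=delta,
        sd_d=sd_d,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        delta_ci=(delta - Z95 * se_delta, delta + Z95 * se_delta),
        loa_lower_ci=(loa_lower - Z95 * se_loa, loa_lower + Z95 * se_loa),
        loa_upper_ci=(loa_upper - Z95 * se_loa, loa_upper + Z95 * se_loa),
        n_pairs=int(n),
    )


def limits_of_agreement(delta: float, sd_d: float) -> tuple[float, float]:
    """LOA bounds from a reported bias and difference SD (no raw data needed)."""
    return delta - Z95 * sd_d, delta + Z95 * sd_d


# --- report builders ---------------------------------------------------------

MEASURE_LABELS = {"static_mm": "Static", "valsalva_mm": "Valsalva", "dynamic_mm": "Dynamic"}


def interobserver_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-modality, per-measure interobserver agreement report.

    One row per measurement type and modality with ICC (95% CI), the mean
    observer-1-minus-observer-2 difference and its SD.
    """
    rows = []
    for measure, label in MEASURE_LABELS.items():
        wide = records.pivot_table(
            index=["patient_id", "modality"],
            columns="observer",
            values=measure,
            aggfunc="first",
        )
        if wide.empty or wide.shape[1] < 2:
            continue
        for modality, sub in wide.groupby(level="modality"):
            pair = sub.dropna()
            if len(pair) < 3:
                continue
            res = icc_consistency(pair[1].to_numpy(), pair[2].to_numpy())
            rows.append(
                {
                    "measure": label,
                    "modality": modality,
                    "icc": res.icc,
                    "icc_ci_low": res.icc_ci_low,
                    "icc_ci_high": res.icc_ci_high,
                    "mean_diff_mm": res.mean_diff,
                    "sd_diff_mm": res.sd_diff,
                    "n": res.n_pairs,
                    "category": res.category,
                }
            )
    return pd.DataFrame(rows)


#: modality pairs reported in the between-modality agreement table, in order
DEFAULT_PAIRS = [
    ("EP", "MRI", "static_mm"),
    ("EP", "MRI", "valsalva_mm"),
    ("EP", "MRI", "dynamic_mm"),
    ("EP", "TPUS", "dynamic_mm"),
    ("EP", "EVUS", "dynamic_mm"),
    ("MRI", "TPUS", "dynamic_mm"),
    ("MRI", "EVUS", "dynamic_mm"),
    ("TPUS", "EVUS", "dynamic_mm"),
]


def between_modality_table(
    records: pd.DataFrame,
    pairs: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Bland-Altman (plus ICC) agreement between modality pairs.

    Consensus (observer-averaged) values feed the comparison, as in the
    source analysis. One row per (modality A, modality B, measure).
    """
    avg = average_observers(records)
    rows = []
    for mod_a, mod_b, measure in pairs or DEFAULT_PAIRS:
        wide = avg.pivot(index="patient_id", columns="modality", values=measure)
        if mod_a not in wide or mod_b not in wide:
            continue
        pair = wide[[mod_a, mod_b]].dropna()
        if len(pair) < 3:
            continue
        a = pair[mod_a].to_numpy()
        b = pair[mod_b].to_numpy()
        ba = bland_altman(a, b)
        icc = icc_consistency(a, b)
        rows.append(
            {
                "modality_a": mod_a,
                "modality_b": mod_b,
                "measure": MEASURE_LABELS[measure],
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "delta": ba.delta,
                "delta_ci_low": ba.delta_ci[0],
                "delta_ci_high": ba.delta_ci[1],
                "sd_d": ba.sd_d,
                "loa_lower": ba.loa_lower,
                "loa_lower_ci_low": ba.loa_lower_ci[0],
                "loa_lower_ci_high": ba.loa_lower_ci[1],
                "loa_upper": ba.loa_upper,
                "loa_upper_ci_low": ba.loa_upper_ci[0],
                "loa_upper_ci_high": ba.loa_upper_ci[1],
                "icc": icc.icc,
                "icc_ci_low": icc.icc_ci_low,
                "icc_ci_high": icc.icc_ci_high,
                "n": ba.n_pairs,
            }
        )
    return pd.DataFrame(rows)
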