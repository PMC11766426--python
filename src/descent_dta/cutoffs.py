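"""Cut-off establishment: Youden-maximised ROC on the reference modality and
ordinary-least-squares transfer of that cut-off to the other modalities.

The reference modality (evacuation proctography) has literature cut-offs only
for descent *at Valsalva* (30/40/50 mm below the pubococcygeal line). The
study's construction — reproduced by :func:`calibrate_reference_cutoff` —
thresholds Valsalva descent at such a literature value to obtain a
pseudo-reference label, then picks the dynamic-descent cut-off that maximises
Youden's J = sensitivity + specificity - 1 against it. Cut-offs transfer to
the other modalities through a linear regression of each modality's dynamic
descent on the reference modality's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC over all candidate thresholds (positive iff value > t)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "youden_j": self.youden,
            }
        )


@dataclass(frozen=True)
class CutoffSet:
    """Per-modality dynamic-descent cut-offs (mm); raw regression predictions
    kept alongside the reported (rounded) values."""

    cutoffs: dict[str, float]
    raw: dict[str, float] = field(default_factory=dict)
    reference: str = "EP"

    def __getitem__(self, modality: str) -> float:
        return self.cutoffs[modality]

    def as_dict(self) -> dict:
        return {
            "reference": self.reference,
            "cutoffs_mm": dict(self.cutoffs),
            "raw_mm": dict(self.raw),
        }


def roc_youden(
    values: np.ndarray, reference: np.ndarray
) -> tuple[ROCCurve, float]:
    """ROC curve over observed thresholds and the Youden-optimal cut-off.

    Candidate thresholds are the unique observed values plus -inf (the
    classify-everything-positive corner). A subject is test-positive iff its
    value strictly exceeds the threshold. Ties in J break toward the smallest
    threshold, favouring sensitivity.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    keep = ~(np.isnan(values) | np.isnan(reference))
    values, reference = values[keep], reference[keep]
    if not np.isfinite(values).all():
        raise ValueError("measurement values must be finite")
    pos = reference == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both reference classes must be represented")
    thresholds = np.concatenate([[-np.inf], np.unique(values)])
    sens = np.array([(values[pos] > t).mean() for t in thresholds])
    spec = np.array([(values[~pos] <= t).mean() for t in thresholds])
    curve = ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)
    j = curve.youden
    best = float(thresholds[int(np.argmax(j))])  # argmax takes first = smallest
    return curve, best


def transfer_cutoff(
    reference_values: np.ndarray,
    target_values: np.ndarray,
    reference_cutoff: float,
    round_to: float | None = 5.0,
) -> tuple[float, float]:
    """Map the reference cut-off onto a target modality's scale by OLS.

    Fits target = a + b * reference on complete pairs and evaluates the fit at
    the reference cut-off. Returns (reported, raw): the raw prediction and,
    for reporting, the prediction rounded to the nearest ``round_to`` mm
    (clinical cut-offs are quoted on a 5 mm grid; pass None to disable).
    """
    x = np.asarray(reference_values, dtype=float)
    y = np.asarray(target_values, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(f"regression transfer needs >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("reference values have zero variance; fit is singular")
    slope, intercept = np.polyfit(x, y, 1)
    raw = float(intercept + slope * reference_cutoff)
    reported = raw if round_to is None else float(round_to * round(raw / round_to))
    return reported, raw


def calibrate_reference_cutoff(
    dynamic_values: np.ndarray,
    valsalva_values: np.ndarray,
    pseudo_reference_threshold: float = 40.0,
) -> tuple[ROCCurve, float]:
    """Youden cut-off for dynamic descent against a Valsalva pseudo-reference.

    The pseudo-reference labels a subject abnormal when descent at Valsalva
    strictly exceeds ``pseudo_reference_threshold`` (a literature value: 30,
    40 or 50 mm below the reference line). Returns the ROC of dynamic descent
    against that label and the Youden-optimal dynamic cut-off.
    """
    valsalva = np.asarray(valsalva_values, dtype=float)
    labels = np.where(np.isnan(valsalva), np.nan, (valsalva > pseudo_reference_threshold))
    return roc_youden(np.asarray(dynamic_values, dtype=float), labels)


def calibrate_cutoffs(
    consensus: pd.DataFrame,
    valsalva: pd.DataFrame,
    reference: str = "EP",
    pseudo_reference_threshold: float = 40.0,
    round_to: float | None = 5.0,
) -> tuple[CutoffSet, ROCCurve]:
    """Full calibration: reference Youden cut-off, then regression transfer.

    ``consensus`` is a patients x modalities table of averaged dynamic descent
    (mm); ``valsalva`` the matching table of Valsalva descent (needed for the
    reference modality only). The reference cut-off is itself rounded to the
    reporting grid before transfer, so the transferred cut-offs correspond to
    the cut-off actually quoted.
    """
    ref_dyn = consensus[reference]
    curve, ref_raw = calibrate_reference_cutoff(
        ref_dyn.to_numpy(),
        valsalva[reference].to_numpy(),
        pseudo_reference_threshold,
    )
    ref_cut = ref_raw if round_to is None else float(round_to * round(ref_raw / round_to))
    cutoffs = {reference: ref_cut}
    raw = {reference: float(ref_raw)}
    for modality in consensus.columns:
        if modality == reference:
            continue
        reported, raw_pred = transfer_cutoff(
            ref_dyn.to_numpy(),
            consensus[modality].to_numpy(),
            ref_cut,
            round_to=round_to,
        )
        cutoffs[modality] = reported
        raw[modality] = raw_pred
    return CutoffSet(cutoffs=cutoffs, raw=raw, reference=reference), curve
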