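"""Synthetic cohort generator for perineal-descent imaging measurements.

Emulates the latent structure the downstream analysis assumes: each patient
carries an unobserved binary state ("abnormal descent" vs "normal"), each
imaging modality (EP, MRI, TPUS, EVUS) measures dynamic perineal descent with
a modality-specific class-conditional normal distribution, and two blinded
observers read each exam with additive, independent observer noise.
Measurements follow the pelvic-floor sign convention: positive millimetres lie
below the pubococcygeal line (caudal), negative above it.

EP and MRI additionally yield static descent (anorectal-junction position at
rest) and descent at Valsalva; dynamic descent is their difference by
construction, so the identity ``dynamic = valsalva - static`` holds exactly in
every generated record. Exams go missing completely at random, per modality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SchemaError

MODALITIES = ("EP", "MRI", "TPUS", "EVUS")
#: Modalities on which the bony reference line is visible, yielding static and
#: Valsalva positions in addition to dynamic descent.
STATIC_MODALITIES = ("EP", "MRI")
OBSERVERS = (1, 2)

MEASUREMENT_COLUMNS = [
    "patient_id",
    "modality",
    "observer",
    "static_mm",
    "valsalva_mm",
    "dynamic_mm",
]


@dataclass(frozen=True)
class ModalityParams:
    """Class-conditional measurement model for one imaging modality.

    Parameters are in millimetres of dynamic descent. ``observer_sd`` is the
    SD of a single observer's additive reading error; the SD of the
    between-observer difference is therefore ``sqrt(2) * observer_sd``.
    """

    diseased_mean: float
    healthy_mean: float
    sd: float
    observer_sd: float
    missing_rate: float = 0.0
    #: optional systematic reading offset per observer (default none)
    observer_offsets: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        if self.sd < 0 or self.observer_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")


@dataclass(frozen=True)
class StaticParams:
    """Marginal distribution of static (at-rest) descent for EP/MRI.

    ``corr_dynamic`` is the correlation between a patient's true static and
    true dynamic descent. It is negative in this population (patients with a
    low pelvic floor at rest have little room left to move), and it controls
    the marginal SD of descent at Valsalva via
    Var(valsalva) = Var(static) + Var(dynamic) + 2 cov.
    """

    mean: float
    sd: float
    corr_dynamic: float = 0.0

    def validate(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("static sd must be >= 0")
        if not -1.0 <= self.corr_dynamic <= 1.0:
            raise ConfigurationError("corr_dynamic must be in [-1, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full generative specification of a synthetic cohort."""

    n_patients: int = 131
    prevalence: float = 0.55
    modalities: dict[str, ModalityParams] = field(default_factory=dict)
    statics: dict[str, StaticParams] = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError("prevalence must be in [0, 1]")
        if not self.modalities:
            raise ConfigurationError("at least one modality must be configured")
        for name, params in self.modalities.items():
            if name not in MODALITIES:
                raise ConfigurationError(f"unknown modality {name!r}")
            params.validate()
        for name, params in self.statics.items():
            if name not in STATIC_MODALITIES:
                raise ConfigurationError(
                    f"static descent is only defined for {STATIC_MODALITIES}, got {name!r}"
                )
            params.validate()


@dataclass(frozen=True)
class LatentStatus:
    patient_id: str
    diseased: bool


@dataclass(frozen=True)
class MeasurementRecord:
    """One observer's descent readings for one patient on one modality."""

    patient_id: str
    modality: str
    observer: int
    dynamic_mm: float
    static_mm: float | None = None
    valsalva_mm: float | None = None


def class_conditional_from_operating_point(
    cutoff: float,
    sensitivity: float,
    specificity: float,
    marginal_sd: float,
    prevalence: float,
) -> tuple[float, float, float]:
    """Solve class-conditional normal parameters from a target operating point.

    Finds (diseased_mean, healthy_mean, sd) such that a normal measurement
    exceeds ``cutoff`` with probability ``sensitivity`` in the diseased class
    and stays at or below it with probability ``specificity`` in the healthy
    class, while the two-component mixture has the requested marginal SD:

        sd      = marginal_sd / sqrt(1 + p(1-p) (z_sens + z_spec)^2)
        mu_dis  = cutoff + z_sens * sd
        mu_heal = cutoff - z_spec * sd

    with z_* the standard-normal quantiles of sensitivity and specificity.
    """
    if not (0.0 < sensitivity < 1.0 and 0.0 < specificity < 1.0):
        raise ConfigurationError("sensitivity and specificity must be in (0, 1)")
    z_sens = stats.norm.ppf(sensitivity)
    z_spec = stats.norm.ppf(specificity)
    spread = z_sens + z_spec
    sd = marginal_sd / math.sqrt(1.0 + prevalence * (1.0 - prevalence) * spread**2)
    return cutoff + z_sens * sd, cutoff - z_spec * sd, sd


def default_config(n_patients: int = 131, rng_seed: int = 0) -> CohortConfig:
    """Cohort defaults emulating the study conditions.

    Class-conditional means/SDs are calibrated so that, at the study's
    per-modality cut-offs (EP 20, MRI 35, TPUS 15, EVUS 15 mm), a noiseless
    binarised measurement reproduces the study's sensitivity/specificity
    operating points, while the marginal SD of dynamic descent matches the
    reported per-modality SDs. Observer-noise SDs come from the reported SDs
    of the between-observer differences (divided by sqrt(2)); missingness
    rates reflect the study's unanalysable-exam counts (1/131 EP, 9/131 MRI,
    4/131 TPUS, 0/131 EVUS).
    """
    # (cutoff mm, sensitivity, specificity, marginal SD mm, diff SD mm, missing)
    operating = {
        "EP": (20.0, 0.784, 0.730, 10.8, 13.1, 1 / 131),
        "MRI": (35.0, 0.743, 0.762, 16.4, 11.9, 9 / 131),
        "TPUS": (15.0, 0.653, 0.762, 9.7, 12.4, 4 / 131),
        "EVUS": (15.0, 0.582, 0.775, 11.3, 7.5, 0.0),
    }
    prevalence = 0.55
    modalities = {}
    for name, (cutoff, sens, spec, marg_sd, diff_sd, miss) in operating.items():
        mu_d, mu_h, sd = class_conditional_from_operating_point(
            cutoff, sens, spec, marg_sd, prevalence
        )
        modalities[name] = ModalityParams(
            diseased_mean=mu_d,
            healthy_mean=mu_h,
            sd=sd,
            observer_sd=diff_sd / math.sqrt(2.0),
            missing_rate=miss,
        )
    # static-dynamic correlations implied by the reported marginal SDs:
    # 2 cov = SD(valsalva)^2 - SD(static)^2 - SD(dynamic)^2
    # (EP: 12.6/10.3/10.8 -> rho -0.29; MRI: 16.5/11.7/16.4 -> rho -0.35)
    statics = {
        "EP": StaticParams(mean=26.0, sd=10.3, corr_dynamic=-0.288),
        "MRI": StaticParams(mean=16.5, sd=11.7, corr_dynamic=-0.348),
    }
    return CohortConfig(
        n_patients=n_patients,
        prevalence=prevalence,
        modalities=modalities,
        statics=statics,
        rng_seed=rng_seed,
    )


def noiseless(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with observer noise and missingness switched off."""
    mods = {
        name: replace(p, observer_sd=0.0, missing_rate=0.0, observer_offsets=(0.0, 0.0))
        for name, p in config.modalities.items()
    }
    return replace(config, modalities=mods)


def _round_mm(x: float) -> float:
    # 0.1 mm grid, matching clinical reporting precision
    return round(x, 1)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[LatentStatus], list[MeasurementRecord]]:
    """Draw a synthetic cohort.

    Per patient: latent state ~ Bernoulli(prevalence). Per modality: one true
    dynamic-descent value from the class-conditional normal; for EP/MRI also a
    true static value, with Valsalva defined as their sum. Per observer: the
    true values plus independent zero-mean observer noise (applied to static
    and dynamic; the observer's Valsalva reading is their sum, so the
    dynamic = valsalva - static identity survives rounding). Whole exams go
    missing completely at random per modality. Deterministic given rng_seed.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients
    width = max(3, len(str(n)))
    ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]

    diseased = rng.random(n) < config.prevalence
    statuses = [LatentStatus(pid, bool(d)) for pid, d in zip(ids, diseased)]

    records: list[MeasurementRecord] = []
    for modality in MODALITIES:
        if modality not in config.modalities:
            continue
        p = config.modalities[modality]
        means = np.where(diseased, p.diseased_mean, p.healthy_mean)
        true_dynamic = means + p.sd * rng.standard_normal(n)
        has_static = modality in config.statics
        if has_static:
            # static descent correlated with dynamic through the marginal
            # z-score of the true dynamic value, preserving both marginals
            sp = config.statics[modality]
            marg_mean = (
                config.prevalence * p.diseased_mean
                + (1.0 - config.prevalence) * p.healthy_mean
            )
            marg_var = p.sd**2 + config.prevalence * (1.0 - config.prevalence) * (
                p.diseased_mean - p.healthy_mean
            ) ** 2
            if marg_var > 0:
                z_dyn = (true_dynamic - marg_mean) / math.sqrt(marg_var)
            else:
                z_dyn = np.zeros(n)
            rho = sp.corr_dynamic
            true_static = sp.mean + sp.sd * (
                rho * z_dyn + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
            )
        missing = rng.random(n) < p.missing_rate
        for observer in OBSERVERS:
            offset = p.observer_offsets[observer - 1]
            obs_dynamic = (
                true_dynamic + offset + p.observer_sd * rng.standard_normal(n)
            )
            if has_static:
                obs_static = true_static + p.observer_sd * rng.standard_normal(n)
            for i in range(n):
                if missing[i]:
                    continue
                dyn = _round_mm(obs_dynamic[i])
                if has_static:
                    sta = _round_mm(obs_static[i])
                    records.append(
                        MeasurementRecord(
                            patient_id=ids[i],
                            modality=modality,
                            observer=observer,
                            dynamic_mm=dyn,
                            static_mm=sta,
                            valsalva_mm=_round_mm(sta + dyn),
                        )
                    )
                else:
                    records.append(
                        MeasurementRecord(
                            patient_id=ids[i],
                            modality=modality,
                            observer=observer,
                            dynamic_mm=dyn,
                        )
                    )
    return statuses, records


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    """Long-format measurement table (one row per patient-modality-observer)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "modality": r.modality,
            "observer": r.observer,
            "static_mm": r.static_mm,
            "valsalva_mm": r.valsalva_mm,
            "dynamic_mm": r.dynamic_mm,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return frame


def statuses_to_frame(statuses: list[LatentStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"patient_id": s.patient_id, "diseased": s.diseased} for s in statuses],
        columns=["patient_id", "diseased"],
    )


def validate_measurement_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a long-format measurement table."""
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"measurement table is missing columns: {missing_cols}")
    if frame.empty:
        raise SchemaError("measurement table is empty")
    bad = set(frame["modality"].unique()) - set(MODALITIES)
    if bad:
        raise SchemaError(f"unknown modalities in table: {sorted(bad)}")
    return frame


def binarise(averaged: pd.DataFrame, cutoffs: dict[str, float]) -> pd.DataFrame:
    """Dichotomise averaged dynamic descent at per-modality cut-offs.

    ``averaged`` is a wide table (patients x modalities) of consensus dynamic
    descent in mm. An entry is positive iff it strictly exceeds the modality's
    cut-off ("below normal, above abnormal"; equality counts as negative).
    Missing entries stay missing. Returns a float frame with 1.0 / 0.0 / NaN.
    """
    for modality in averaged.columns:
        if modality not in cutoffs:
            raise ConfigurationError(f"no cut-off configured for modality {modality!r}")
    out = pd.DataFrame(index=averaged.index, columns=averaged.columns, dtype=float)
    for modality in averaged.columns:
        values = averaged[modality]
        out[modality] = (values > cutoffs[modality]).astype(float)
        out.loc[values.isna(), modality] = np.nan
    return out


def simulate_binary_tests(
    n_patients: int,
    prevalence: float,
    sensitivity: dict[str, float],
    specificity: dict[str, float],
    rng_seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw a binary test matrix directly from a two-class model.

    Each patient's latent state is Bernoulli(prevalence); test j is positive
    with probability sensitivity[j] when diseased and 1 - specificity[j] when
    healthy, independently across tests given the state. Returns the latent
    state vector and the patients x tests 0/1 matrix.
    """
    if set(sensitivity) != set(specificity):
        raise ConfigurationError("sensitivity and specificity must name the same tests")
    rng = np.random.default_rng(rng_seed)
    tests = list(sensitivity)
    diseased = rng.random(n_patients) < prevalence
    cols = {}
    for name in tests:
        p_pos = np.where(diseased, sensitivity[name], 1.0 - specificity[name])
        cols[name] = (rng.random(n_patients) < p_pos).astype(float)
    ids = [f"P{i:05d}" for i in range(1, n_patients + 1)]
    return diseased, pd.DataFrame(cols, index=pd.Index(ids, name="patient_id"))


# --- optional clinical covariates / condition labels (pipeline plumbing) ----

CONDITIONS = ("rectocele", "enterocele", "intussusception", "anismus", "lam_avulsion")
COVARIATES = ("age", "bmi", "parity", "renzi_total")


def generate_clinical_labels(
    statuses: list[LatentStatus], rng_seed: int = 0
) -> pd.DataFrame:
    """Illustrative per-patient covariates and binary condition labels.

    Covariates are drawn from the study's marginal distributions (age 53.6
    (14.3) y, BMI 26.7 (4.9) kg/m^2, parity 2.3 (1.3), ODS symptom score 8.8
    (4.3)), with a mild dependence on the latent descent state so association
    tables have signal. Condition labels are Bernoulli with class-dependent
    rates. These labels exist so the association stage can run end-to-end on
    synthetic data; they are not part of the measurement model.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(statuses)
    d = np.array([s.diseased for s in statuses], dtype=float)
    frame = pd.DataFrame({"patient_id": [s.patient_id for s in statuses]})
    frame["age"] = np.round(53.6 - 4.0 * d + 14.0 * rng.standard_normal(n), 0)
    frame["bmi"] = np.round(26.7 + 4.9 * rng.standard_normal(n), 1)
    frame["parity"] = rng.integers(0, 7, size=n)
    frame["renzi_total"] = np.clip(
        np.round(8.0 + 2.0 * d + 4.0 * rng.standard_normal(n)), 0, 20
    ).astype(int)
    # condition rates per (healthy, diseased) class, loosely matching the
    # reported condition frequencies and their direction of association
    rates = {
        "rectocele": (0.30, 0.55),
        "enterocele": (0.10, 0.22),
        "intussusception": (0.25, 0.45),
        "anismus": (0.13, 0.04),
        "lam_avulsion": (0.12, 0.18),
    }
    for name, (r0, r1) in rates.items():
        p = np.where(d > 0, r1, r0)
        frame[name] = (rng.random(n) < p).astype(int)
    return frame
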