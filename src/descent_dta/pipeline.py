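"""End-to-end orchestration of the descent-harmonisation workflow.

Stage order mirrors the analysis plan: synthesise or ingest measurements ->
interobserver agreement -> observer averaging -> between-modality
Bland-Altman -> cut-off calibration (or a fixed cut-off set) -> binarisation
-> latent-class diagnostic accuracy -> association tables -> report bundle.
Every stage's randomness derives deterministically from one global seed, so
reruns with the same configuration reproduce the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, associations, io, lca, synthetic
from .cutoffs import CutoffSet, calibrate_cutoffs
from .errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "csv"
    measurements_csv: str | None = None
    covariates_csv: str | None = None
    conditions_csv: str | None = None
    n_patients: int = 131
    reference: str = "EP"
    cutoff_source: str = "calibrate"  # "calibrate" | "fixed"
    fixed_cutoffs: dict[str, float] | None = None
    pseudo_reference_threshold: float = 40.0
    lca: lca.LCAConfig = field(default_factory=lca.LCAConfig)
    out_dir: str = "results/run"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ConfigurationError(f"unknown input mode {self.mode!r}")
        if self.mode == "csv" and not self.measurements_csv:
            raise ConfigurationError("csv mode requires measurements_csv")
        if self.cutoff_source not in ("calibrate", "fixed"):
            raise ConfigurationError(f"unknown cutoff source {self.cutoff_source!r}")
        if self.cutoff_source == "fixed" and not self.fixed_cutoffs:
            raise ConfigurationError("fixed cut-off source requires fixed_cutoffs")
        self.lca.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        lca_cfg = lca.LCAConfig(**raw.pop("lca", {}))
        return cls(lca=lca_cfg, **raw)

    def analytic_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analytic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Independent per-stage substream seeds derived from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory tables and the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.rng_seed)
    bundle: dict = {}
    t0 = time.perf_counter()

    # stage 1: measurements
    if config.mode == "synthetic":
        cohort_cfg = synthetic.default_config(
            n_patients=config.n_patients, rng_seed=seeds[0]
        )
        statuses, records = synthetic.generate_cohort(cohort_cfg)
        measurements = synthetic.records_to_frame(records)
        io.write_measurements(measurements, out / "measurements.csv")
        synthetic.statuses_to_frame(statuses).to_csv(
            out / "latent_truth.csv", index=False
        )
        clinical = synthetic.generate_clinical_labels(statuses, rng_seed=seeds[1])
        covariates = clinical.set_index("patient_id")[list(synthetic.COVARIATES)]
        conditions = clinical.set_index("patient_id")[list(synthetic.CONDITIONS)]
    else:
        measurements = io.read_measurements(config.measurements_csv)
        covariates = conditions = None
        if config.covariates_csv:
            covariates = pd.read_csv(
                config.covariates_csv, dtype={"patient_id": str}
            ).set_index("patient_id")
        if config.conditions_csv:
            conditions = pd.read_csv(
                config.conditions_csv, dtype={"patient_id": str}
            ).set_index("patient_id")
    synthetic.validate_measurement_frame(measurements)
    logger.info("stage measurements: %d records", len(measurements))

    # stage 2: interobserver agreement (Table-1 style)
    table1 = agreement.interobserver_table(measurements)
    table1.to_csv(out / "table1_interobserver.csv", index=False)
    bundle["table1"] = table1

    # stage 3: between-modality Bland-Altman (Table-2 style)
    table2 = agreement.between_modality_table(measurements)
    table2.to_csv(out / "table2_between_modality.csv", index=False)
    bundle["table2"] = table2

    # stage 4: cut-offs
    consensus = agreement.consensus_wide(measurements, "dynamic_mm")
    if config.cutoff_source == "calibrate":
        valsalva = agreement.consensus_wide(measurements, "valsalva_mm")
        if config.reference not in valsalva:
            raise SchemaError(
                f"reference modality {config.reference!r} has no Valsalva values"
            )
        cutoffs, roc = calibrate_cutoffs(
            consensus,
            valsalva,
            reference=config.reference,
            pseudo_reference_threshold=config.pseudo_reference_threshold,
        )
        roc.to_frame().to_csv(out / "roc_reference.csv", index=False)
    else:
        cutoffs = CutoffSet(cutoffs=dict(config.fixed_cutoffs), reference=config.reference)
    io.write_cutoffs(cutoffs, out / "cutoffs.yaml")
    bundle["cutoffs"] = cutoffs
    logger.info("stage cutoffs: %s", cutoffs.cutoffs)

    # stage 5: binarisation + latent class DTA (Table-3 style)
    matrix = synthetic.binarise(consensus, cutoffs.cutoffs)
    io.write_matrix(matrix, out / "binary_matrix.csv")
    lca_cfg = dataclasses.replace(config.lca, rng_seed=seeds[2])
    posterior = lca.gibbs_lca(matrix, lca_cfg)
    table3 = lca.derive_metrics(posterior)
    table3.to_csv(out / "table3_dta.csv", index=False)
    diag = lca.diagnostics(posterior)
    diag.to_csv(out / "lca_diagnostics.csv", index=False)
    bundle["table3"] = table3
    bundle["diagnostics"] = diag
    bundle["posterior"] = posterior

    # stage 6: associations (Table-4/6 style), when clinical data exist
    measures = consensus.copy()
    measures.columns = [f"dynamic_{m}" for m in measures.columns]
    for mod in synthetic.STATIC_MODALITIES:
        static = agreement.consensus_wide(measurements, "static_mm")
        if mod in static:
            measures[f"static_{mod}"] = static[mod]
    if covariates is not None:
        table4 = associations.spearman_table(measures, covariates)
        table4.to_csv(out / "table4_correlations.csv", index=False)
        bundle["table4"] = table4
    if conditions is not None:
        table6 = associations.condition_table(measures, conditions)
        table6.to_csv(out / "table6_conditions.csv", index=False)
        bundle["table6"] = table6

    manifest = {
        "seed": config.rng_seed,
        "stage_seeds": seeds,
        "config_hash": config.config_hash(),
        "config": config.analytic_dict(),
        "n_records": int(len(measurements)),
        "cutoffs_mm": cutoffs.cutoffs,
    }
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle
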