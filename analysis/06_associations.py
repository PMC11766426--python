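"""Clinical relevance: correlations and group differences.

Spearman correlations of per-patient consensus descent measures with the
clinical covariates, and pooled-variance t-tests of descent by presence of
each posterior-compartment condition. On synthetic data these tables exercise
the reporting layer; the generator plants a mild dependence of covariates and
condition rates on the latent state, so directions - not magnitudes - are the
interesting output.
"""

from pathlib import Path

import pandas as pd

from descent_dta import agreement, associations, io, synthetic

MEAS = Path("results/cohort/measurements.csv")
CLINICAL = Path("results/cohort/clinical_labels.csv")
OUT = Path("results/tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = io.read_measurements(MEAS)
    clinical = pd.read_csv(CLINICAL, dtype={"patient_id": str}).set_index("patient_id")

    measures = agreement.consensus_wide(records, "dynamic_mm")
    measures.columns = [f"dynamic_{m}" for m in measures.columns]
    static = agreement.consensus_wide(records, "static_mm")
    for mod in synthetic.STATIC_MODALITIES:
        if mod in static:
            measures[f"static_{mod}"] = static[mod]

    covariates = clinical[list(synthetic.COVARIATES)]
    conditions = clinical[list(synthetic.CONDITIONS)]

    table4 = associations.spearman_table(measures, covariates)
    table4.to_csv(OUT / "table4_correlations.csv", index=False)
    table6 = associations.condition_table(measures, conditions)
    table6.to_csv(OUT / "table6_conditions.csv", index=False)

    starred = table4[table4.marker != ""]
    print(f"correlations: {len(starred)}/{len(table4)} starred at p<0.05")
    if not starred.empty:
        print(starred[["covariate", "measure", "spearman_r", "marker"]]
              .round(2).to_string(index=False))
    sig = table6[table6.marker != ""]
    print(f"\ncondition comparisons: {len(sig)}/{len(table6)} significant")
    if not sig.empty:
        show = sig[["condition", "measure", "mean_present", "mean_absent",
                    "p_value", "marker"]].round(3)
        print(show.to_string(index=False))


if __name__ == "__main__":
    main()
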