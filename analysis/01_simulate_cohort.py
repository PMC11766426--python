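"""Generate the synthetic study cohort.

131 women with obstructed-defaecation symptoms, a latent abnormal-descent
state at 55% prevalence, dynamic perineal descent measured on EP, MRI, TPUS
and EVUS by two blinded observers, and the study's per-modality missingness.
Writes the long-format measurement table and the (sequestered) latent truth.
"""

from pathlib import Path

from descent_dta import io, synthetic

OUT = Path("results/cohort")
SEED = 20250921


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = synthetic.default_config(n_patients=131, rng_seed=SEED)
    statuses, records = synthetic.generate_cohort(config)
    frame = synthetic.records_to_frame(records)
    io.write_measurements(frame, OUT / "measurements.csv")
    synthetic.statuses_to_frame(statuses).to_csv(OUT / "latent_truth.csv", index=False)
    clinical = synthetic.generate_clinical_labels(statuses, rng_seed=SEED + 1)
    clinical.to_csv(OUT / "clinical_labels.csv", index=False)

    n_diseased = sum(s.diseased for s in statuses)
    print(f"cohort: {len(statuses)} patients, {n_diseased} with abnormal descent "
          f"({n_diseased / len(statuses):.0%})")
    per_mod = frame.groupby("modality")["patient_id"].nunique()
    print("patients with an analysable exam per modality:")
    print(per_mod.to_string())
    print(f"wrote {OUT}/measurements.csv ({len(frame)} observer-readings)")


if __name__ == "__main__":
    main()
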