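"""Establish per-modality cut-offs for abnormal dynamic descent.

The reference modality (EP) gets its cut-off from a Youden-maximised ROC of
dynamic descent against a pseudo-reference label - descent at Valsalva beyond
the 40 mm literature threshold. The cut-off then transfers to MRI, TPUS and
EVUS through a linear regression of each modality's consensus dynamic descent
on EP's, evaluated at the EP cut-off and reported on the clinical 5 mm grid.
"""

from pathlib import Path

from descent_dta import agreement, io
from descent_dta.cutoffs import calibrate_cutoffs

IN = Path("results/cohort/measurements.csv")
OUT = Path("results/tables")
PSEUDO_REFERENCE_MM = 40.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = io.read_measurements(IN)
    consensus = agreement.consensus_wide(records, "dynamic_mm")
    valsalva = agreement.consensus_wide(records, "valsalva_mm")
    cutoffs, roc = calibrate_cutoffs(
        consensus, valsalva, reference="EP",
        pseudo_reference_threshold=PSEUDO_REFERENCE_MM,
    )
    io.write_cutoffs(cutoffs, OUT / "cutoffs.yaml")
    roc.to_frame().to_csv(OUT / "roc_reference.csv", index=False)

    best = roc.to_frame().sort_values("youden_j", ascending=False).iloc[0]
    print(f"reference ROC (EP dynamic vs Valsalva > {PSEUDO_REFERENCE_MM:.0f} mm): "
          f"max Youden J = {best.youden_j:.2f} at {best.threshold:.1f} mm "
          f"(sens {best.sensitivity:.2f}, spec {best.specificity:.2f})")
    print("calibrated cut-offs for abnormal dynamic descent (mm):")
    for m in ("EP", "MRI", "TPUS", "EVUS"):
        print(f"  {m:<5} {cutoffs.cutoffs[m]:>5.0f}  (raw regression value "
              f"{cutoffs.raw[m]:.1f})")


if __name__ == "__main__":
    main()
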