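"""CSV/YAML readers and writers for the pipeline's interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .cutoffs import CutoffSet
from .synthetic import MEASUREMENT_COLUMNS, validate_measurement_frame


def write_measurements(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.1f")


def read_measurements(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    return validate_measurement_frame(frame)[MEASUREMENT_COLUMNS]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Binary test matrix: patient_id index, one 0/1/NA column per modality."""
    matrix.to_csv(path, index_label="patient_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")


def write_cutoffs(cutoffs: CutoffSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cutoffs.as_dict(), fh, sort_keys=True)


def read_cutoffs(path: str | Path) -> CutoffSet:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CutoffSet(
        cutoffs={k: float(v) for k, v in data["cutoffs_mm"].items()},
        raw={k: float(v) for k, v in data.get("raw_mm", {}).items()},
        reference=data.get("reference", "EP"),
    )
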