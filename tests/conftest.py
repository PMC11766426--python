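import numpy as np
import pandas as pd
import pytest

from descent_dta import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One medium synthetic cohort shared across read-only tests."""
    cfg = synthetic.default_config(n_patients=131, rng_seed=20)
    statuses, records = synthetic.generate_cohort(cfg)
    return cfg, statuses, synthetic.records_to_frame(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_observer_frame(values1, values2, modality="EP"):
    """Build a minimal long-format measurement table from two observer vectors."""
    rows = []
    for i, (v1, v2) in enumerate(zip(values1, values2), start=1):
        for obs, v in ((1, v1), (2, v2)):
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "modality": modality,
                    "observer": obs,
                    "static_mm": np.nan,
                    "valsalva_mm": np.nan,
                    "dynamic_mm": v,
                }
            )
    return pd.DataFrame(rows)
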