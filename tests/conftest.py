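import numpy as np
import pandas as pd
import pytest

from compera_bpa.config import default_config
from compera_bpa.stratification import load_policies
from compera_bpa.synthetic_cohort import generate_cohort


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def policies(config):
    return load_policies(config)


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-patient synthetic cohort shared across read-only tests."""
    return generate_cohort(seed=20260926, n_patients=250)


@pytest.fixture()
def toy_risk_table():
    """Hand-built risk table: four patients with known first-session flows
    under the original 4-S policy (low->low, iL->low, iH->iL, high->high)."""
    rows = []
    flows = {
        "A": ("low", "low"),
        "B": ("intermediate-low", "low"),
        "C": ("intermediate-high", "intermediate-low"),
        "D": ("high", "high"),
    }
    rank = {"low": 1, "intermediate-low": 2, "intermediate-high": 3, "high": 4}
    for pid, (pre, post) in flows.items():
        for timing, lab in (("pre", pre), ("post", post)):
            rows.append(
                {
                    "patient_id": pid,
                    "session_index": 1,
                    "timing": timing,
                    "original-4S": lab,
                    "rank_original-4S": rank[lab],
                }
            )
    return pd.DataFrame(rows)
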