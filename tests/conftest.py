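import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import srmquant as sq
from srmquant.simulate import ResponseModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_panel() -> sq.AnalytePanel:
    """The builtin 34-analyte diabetes biomarker panel."""
    return sq.load_panel("diabetes-t1d-34")


@pytest.fixture(scope="session")
def small_panel() -> sq.AnalytePanel:
    """A 3-entity programmatic panel with ISTDs, for fast round trips."""
    return sq.synthetic_panel(3)


@pytest.fixture()
def noise_free_model() -> ResponseModel:
    return ResponseModel(proportional_cv=0.0, baseline_noise_sd=0.0, istd_cv=0.0,
                         rt_jitter_sd=0.0)


def make_clinical(n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """A minimal clinical table with the standard covariate columns."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "group": np.repeat([0, 1], n_per_group),
        }
    )
    for cov in ("age", "bmi", "hba1c", "egfr", "sbp", "total_cholesterol",
                "total_triglycerides", "diabetes_duration", "insulin_dose"):
        df[cov] = rng.normal(50, 10, size=n)
    for cov in ("sex", "smoking", "antihypertensive_medication", "statin_medication"):
        df[cov] = rng.integers(0, 2, size=n)
    return df
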