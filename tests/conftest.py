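import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from psadose.synthetic import SimConfig, simulate_cohort
from psadose.cohort import select_patients

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def confounded_cohort():
    """Mid-sized severity-confounded analysis table with hidden truth columns.

    Missingness and dose switching are disabled so every patient is eligible
    and estimator behaviour is isolated from missing-data handling.
    """
    cfg = SimConfig(n_patients=1500, seed=42, missing_rates={}, switch_rate=0.0)
    analysis, _ = select_patients(simulate_cohort(cfg))
    analysis["bmi_high"] = (analysis["bmi"] > 32.5).astype(float)
    return analysis


@pytest.fixture()
def toy_visits():
    """Hand-built visit table exercising each eligibility rule.

    p1: complete, dose stable             -> included (Visit-3 endpoint)
    p2: Visit-3 outcome missing, V4 there -> included (Visit-4 fallback)
    p3: dose changes 150 -> 300 by V3     -> excluded
    p4: started 6 weeks before baseline   -> excluded
    p5: no follow-up outcome at V3 or V4  -> excluded
    p6: baseline outcome missing          -> excluded
    """
    rows = []

    def visit(pid, v, week, dose, psaid, offset=0):
        rows.append(
            {
                "patient_id": pid,
                "visit_index": v,
                "week": week,
                "dose": dose,
                "psaid": psaid,
                "treatment_start_offset_weeks": offset,
                "bmi": 28.0,
            }
        )

    visit("p1", 1, 0, 150, 6.0)
    visit("p1", 3, 16, 150, 4.0)
    visit("p2", 1, 0, 300, 7.0, offset=-2)
    visit("p2", 3, 16, 300, np.nan, offset=-2)
    visit("p2", 4, 28, 300, 3.5, offset=-2)
    visit("p3", 1, 0, 150, 5.0)
    visit("p3", 3, 16, 300, 3.0)
    visit("p4", 1, 0, 150, 6.0, offset=-6)
    visit("p4", 3, 16, 150, 4.0, offset=-6)
    visit("p5", 1, 0, 300, 6.0)
    visit("p5", 3, 16, 300, np.nan)
    visit("p5", 4, 28, 300, np.nan)
    visit("p6", 1, 0, 150, np.nan)
    visit("p6", 3, 16, 150, 4.0)
    return pd.DataFrame(rows)
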