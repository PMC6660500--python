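import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def endpoint_fixture_cohort() -> pd.DataFrame:
    """170-record cohort whose event composition matches the published
    breakdown: 25 sustained VT, 22 appropriate ICD therapy, 8 resuscitated
    arrests, 14 SCD, 101 event-free."""
    rows = []
    composition = (
        ("sustained_VT", 25),
        ("appropriate_ICD_therapy", 22),
        ("resuscitated_arrest", 8),
        ("SCD", 14),
    )
    i = 0
    for event_type, count in composition:
        for _ in range(count):
            month = 1.0 + (i % 40)
            rows.append(
                {
                    "id": f"F{i:03d}",
                    "event_type": event_type,
                    "event_month": month,
                    "followup_months": month,
                }
            )
            i += 1
    for _ in range(101):
        rows.append(
            {
                "id": f"F{i:03d}",
                "event_type": "none",
                "event_month": np.nan,
                "followup_months": 12.0 + (i % 39),
            }
        )
        i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def hm_fixture_values() -> np.ndarray:
    """170 late H/M values: 8 below 1.2, 51 above 1.6, the rest in between."""
    low = np.linspace(0.8, 1.19, 8)
    high = np.linspace(1.61, 2.4, 51)
    mid = np.linspace(1.2, 1.6, 170 - 8 - 51)
    return np.concatenate([low, mid, high])
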