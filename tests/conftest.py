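"""Shared fixtures: synthetic data and fitted chart sets.

Expensive fits are session-scoped so the chart-construction cost is
paid once and reused across chart, scoring and acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

from funsi.charts import ChartConfig, fit_chart, fit_chart_set
from funsi.features import (
    FEATURE_NAMES,
    apply_eligibility,
    filter_feature_outliers,
    select_per_person,
)
from funsi.simulate import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def location_shift_chart():
    """Chart fitted on y = 2 + 0.1*ser + N(0, 0.5^2), n = 20,000.

    The true conditional quantiles are the closed form
    2 + 0.1*ser + 0.5*z_tau, which makes this the calibration and
    accuracy workhorse.
    """
    rng = np.random.default_rng(20240)
    n = 20_000
    ser = rng.uniform(-12.0, 0.0, n)
    y = 2.0 + 0.1 * ser + rng.normal(0.0, 0.5, n)
    chart = fit_chart(ser, y, feature_name="toy")
    return chart, ser, y


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter synthetic cohort of 5,000 persons."""
    params = SimParams(n_persons=5000, seed=11)
    persons, eyes = simulate_cohort(params)
    return params, persons, eyes


@pytest.fixture(scope="session")
def fitted_chart_set(default_cohort):
    """Chart set fitted on the default cohort after the standard
    filter/selection pipeline (one random eye per person)."""
    _, _, eyes = default_cohort
    kept, _ = apply_eligibility(eyes)
    kept, _ = filter_feature_outliers(kept, 0.001)
    selected = select_per_person(kept, "random_one", seed=11)
    charts = fit_chart_set(selected, provenance={"seed": 11})
    return charts, selected


def make_eyes_frame(
    n_persons: int = 50, seed: int = 0, both_eyes: bool = True
) -> pd.DataFrame:
    """Small hand-rolled eye table for filter/selection unit tests."""
    rng = np.random.default_rng(seed)
    if both_eyes:
        n_eyes = 2 * n_persons
        person_id = np.repeat(np.arange(n_persons), 2)
        eye = np.tile(["L", "R"], n_persons)
    else:
        n_eyes = n_persons
        person_id = np.arange(n_persons)
        eye = np.resize(["L", "R"], n_persons)
    df = pd.DataFrame(
        {
            "person_id": person_id,
            "eye": eye,
            "ser": rng.uniform(-11.0, -0.1, n_eyes),
        }
    )
    for name in FEATURE_NAMES:
        df[name] = rng.normal(1.0, 0.2, n_eyes)
    return df
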