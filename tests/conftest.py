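from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ctcsurv.synthetic import default_study_spec, generate_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_spec():
    return default_study_spec(seed=20240101)


@pytest.fixture(scope="session")
def study_cohort(default_spec):
    """One 382-patient cohort drawn from the default study emulation."""
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def big_cohort(default_spec):
    """A 10,000-patient draw for distributional checks."""
    from dataclasses import replace

    return generate_cohort(replace(default_spec, n_patients=10_000), seed=7)


def toy_survival_frame(n, seed, log_hr=0.0, event_scale=5.0, censor_high=10.0):
    """Small censored dataset with a binary covariate and a known log-HR."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    rate = np.exp(log_hr * x) / event_scale
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, censor_high, n)
    return pd.DataFrame({
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "x": x,
    })
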