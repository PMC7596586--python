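import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mhcfinemap as mfm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: same structure as the default, smaller quotas."""
    return mfm.SimulationConfig(
        n_cases=150, n_controls=1500, baseline_prevalence=0.05, seed=20240917
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return mfm.generate_cohort(small_config)


@pytest.fixture(scope="session")
def marker_table(small_sim):
    return mfm.build_marker_table(
        small_sim.dosages, small_sim.dictionary, small_sim.cohort["status"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def toy_logistic_data(n=20, k=1, seed=5):
    """A fixed small dataset for oracle comparisons."""
    r = np.random.default_rng(seed)
    X = pd.DataFrame({"intercept": np.ones(n)})
    for j in range(k):
        X[f"x{j}"] = r.normal(size=n)
    eta = 0.3 + (0.8 * X.get("x0", 0.0) if k else 0.0)
    y = (r.random(n) < 1.0 / (1.0 + np.exp(-np.asarray(eta)))).astype(float)
    return y, X
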