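"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lakebnm import synth, priors, inference
from lakebnm.core import LakePanel, ModelConfig

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario():
    """4 lakes × 45 years, moderate noise, universally positive AT→WT."""
    return synth.generate_scenario(n_lakes=4, n_years=45, seed=11)


@pytest.fixture(scope="session")
def panels(scenario):
    full = synth.forward_simulate(scenario, seed=12)
    return synth.apply_missingness(
        full, {"CHL": 0.3, "WT": 0.2, "CATCH": 0.1}, seed=13)


@pytest.fixture(scope="session")
def stocking(scenario):
    return scenario.stocking_flags()


@pytest.fixture(scope="session")
def prior_spec(panels, stocking):
    return priors.build_priors(panels, stocking)


@pytest.fixture(scope="session")
def posterior(panels, prior_spec, stocking):
    """Short 3-chain run, long enough for stable quartiles."""
    cfg = ModelConfig(chains=3, burn_in=300, retained=800, seed=5)
    return inference.run_mcmc(panels, prior_spec, cfg, stocking=stocking)


@pytest.fixture()
def toy_panel():
    """Hand-built 12-year panel with complete records."""
    years = np.arange(2000, 2012)
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "year": years,
        "AT": 15 + rng.normal(0, 1, 12),
        "PRE": 1.0 + rng.normal(0, 0.1, 12),
        "PE": 0.9 + rng.normal(0, 0.05, 12),
        "LUag": 30 + rng.normal(0, 2, 12),
        "WT": 18 + rng.normal(0, 1, 12),
        "WL": 100 + np.cumsum(rng.normal(0, 0.2, 12)),
        "CHL": np.exp(2.5 + rng.normal(0, 0.3, 12)),
        "CATCH": np.exp(4.0 + rng.normal(0, 0.3, 12)),
        "ST": np.exp(4.5 + rng.normal(0, 0.3, 12)),
        "EFF": np.exp(rng.normal(0, 0.2, 12)),
    })
    return LakePanel("toy", df)
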