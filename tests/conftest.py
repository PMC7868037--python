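import numpy as np
import pandas as pd
import pytest

from cortkin import (
    KineticsParams,
    SamplerSettings,
    StudyDesign,
    simulate_study,
)


@pytest.fixture(scope="session")
def default_params() -> KineticsParams:
    return KineticsParams()


@pytest.fixture(scope="session")
def default_design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def sim_table(default_design, default_params) -> pd.DataFrame:
    """One full two-trial simulated dataset, shared across tests."""
    return simulate_study(default_design, default_params, seed=11)


@pytest.fixture(scope="session")
def fast_settings() -> SamplerSettings:
    """Reduced-iteration sampler settings for quick fits."""
    return SamplerSettings(chains=3, iterations=2000, thin=1, burnin_draws=100, seed=5)


def make_cubic_data(
    coeffs, times, reps: int, sigma: float, seed: int
) -> pd.DataFrame:
    """Observations from a known cubic plus iid Gaussian noise."""
    rng = np.random.default_rng(seed)
    t = np.tile(np.asarray(times, dtype=float), reps)
    X = np.vander(t, 4, increasing=True)
    y = X @ np.asarray(coeffs, dtype=float) + rng.normal(0.0, sigma, t.size)
    return pd.DataFrame({"time_h": t, "cortisol_ng_ml": y})
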