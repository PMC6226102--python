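import numpy as np
import pytest

from batscape.landscape import standardize
from batscape.occupancy import McmcConfig, ModelSpec, fit_mcmc
from batscape.pipeline import PipelineConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A 38-cell, 2-year synthetic study with a moderate forest effect."""
    cfg = PipelineConfig(seed=42, n_cells=38)
    design, covariates, truth, detections = simulate_study(cfg)
    return {"config": cfg, "design": design, "covariates": covariates,
            "truth": truth, "detections": detections}


@pytest.fixture(scope="session")
def tiny_mcmc():
    return McmcConfig(n_chains=2, n_burnin=200, n_sampling=400, thin=4, seed=7)


@pytest.fixture(scope="session")
def fitted_draws(small_study, tiny_mcmc):
    """One short fit of the forest model on the small study, reused widely."""
    cov_std, _ = standardize(small_study["covariates"])
    spec = ModelSpec("forest", occupancy=("Forest",), detection=("duration",))
    return fit_mcmc(small_study["detections"], cov_std, spec, tiny_mcmc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
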