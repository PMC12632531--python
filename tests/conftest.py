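import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from feverspike import synthetic
from feverspike.config import SyntheticCohortConfig
from feverspike.pipeline import extract_features

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-cell cohort with sweeps retained, for feature-level tests."""
    cfg = SyntheticCohortConfig(n_cells=12, seed=3)
    sweeps, truth = synthetic.generate_pn_cohort(cfg)
    return cfg, sweeps, truth


@pytest.fixture(scope="session")
def cohort200():
    """The 200-cell recovery cohort at the default 0.2 mV noise.

    Sweeps are not retained (only the derived tables), to keep the
    session memory footprint small.
    """
    cfg = SyntheticCohortConfig(n_cells=200, seed=1)
    sweeps, truth = synthetic.generate_pn_cohort(cfg)
    feats, cells = extract_features(sweeps)
    del sweeps
    return cfg, truth, cells


@pytest.fixture(scope="session")
def unit_population_633():
    """The default 633-unit population with the bimodal duration mixture."""
    return synthetic.generate_unit_population(n_units=633, interneuron_frac=0.221, seed=7)
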