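import numpy as np
import pytest

import sucroscreen as ss


@pytest.fixture(scope="session")
def big_cohort() -> ss.StudyDataset:
    """Large synthetic cohort at the default study conditions."""
    return ss.simulate_cohort(ss.SimulationConfig(n_foals=2000, seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> ss.StudyDataset:
    """Study-sized cohort: 45 foals, two occasions."""
    return ss.simulate_cohort(ss.SimulationConfig(n_foals=45, seed=5))


@pytest.fixture(scope="session")
def truth_params() -> ss.LCParameters:
    """Latent class parameters near the study's posterior point estimates."""
    return ss.LCParameters(pi_pre=0.42, pi_post=0.92, se_s45=0.89, sp_s45=0.83,
                           se_s90=0.81, sp_s90=0.95, se_endo=0.81, sp_endo=0.99,
                           cov_se=0.05, cov_sp=0.01)


@pytest.fixture(scope="session")
def sim_counts(truth_params) -> ss.CrossClassifiedCounts:
    """Counts simulated from the truth at n = 1000 per population."""
    return ss.simulate_crossclassified(truth_params, 1000, 1000, seed=7)
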