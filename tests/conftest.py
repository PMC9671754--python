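import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from widqec.discovery import estimate_immune_fractions
from widqec.synthetic import (
    SimulationConfig,
    generate_reference_profiles,
    simulate_beta_matrix,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    return generate_reference_profiles(n_cpgs=2000, seed=11)


@pytest.fixture(scope="session")
def reference_cohort(profiles):
    """The package's reference study conditions: 200 samples, 2,000 CpGs,
    3 planted regions, effect 0.3, beta noise 0.05."""
    cfg = SimulationConfig(seed=11)
    beta, meta, truth, immune = simulate_beta_matrix(cfg, profiles)
    return {"config": cfg, "beta": beta, "meta": meta,
            "truth": truth, "immune": immune}


@pytest.fixture(scope="session")
def estimated_immune(profiles, reference_cohort):
    return estimate_immune_fractions(
        reference_cohort["beta"],
        profiles.epithelial_mean,
        profiles.immune_mean,
    )
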