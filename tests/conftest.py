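import numpy as np
import pytest

from qitraj import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured simulated world shared across tests."""
    config = SimulationConfig(
        n_regions=6, n_areas=40, n_periods=5,
        group_probs=(0.5, 0.3, 0.2),
        group_logit_curves=(
            (1.0,) * 5,
            (0.2,) * 5,
            tuple(np.linspace(-0.6, 0.0, 5)),
        ),
        seed=7,
    )
    panel, truth, covariates = simulate_panel(config)
    return {"config": config, "panel": panel, "truth": truth, "covariates": covariates}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
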