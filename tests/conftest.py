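import logging
import warnings

import numpy as np
import pytest

from fcpredict.synth import generate_study
from fcpredict.types import PlantedResponseModel, SpikeTrain

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_study():
    """A reduced planted-signal study shared across tests: 3 chips x 2
    networks, ~35-45 neurons, 4-min recordings, strongest-neighbor signal."""
    model = PlantedResponseModel(neighbor_weight=1.0, noise_sd=0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study(
            n_chips=3,
            networks_per_chip=2,
            n_neurons=(35, 45),
            duration=240.0,
            response_model=model,
            seed=101,
        )


@pytest.fixture()
def poisson_trains():
    """Independent homogeneous Poisson trains (no structure)."""

    def make(n=10, rate=2.0, duration=120.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            k = rng.poisson(rate * duration)
            out.append(SpikeTrain(i, np.sort(rng.uniform(0, duration, k)), duration))
        return out

    return make
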