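import numpy as np
import pytest

from mbwater.potentials import (
    DistortionSpec,
    make_surrogate_potential,
    make_truth_potential,
    local_minimize,
)
from mbwater.synthetic import (
    hexamer_templates,
    sample_dimer_set,
    sample_trimer_set,
)

np.seterr(over="ignore", invalid="ignore")


@pytest.fixture(scope="session")
def truth():
    return make_truth_potential()


@pytest.fixture(scope="session")
def surrogate(truth):
    return make_surrogate_potential(
        truth, DistortionSpec(0.05, 0.05, 0.10, label="surrogate-mid")
    )


@pytest.fixture(scope="session")
def dimers_small():
    return sample_dimer_set(40, (2.3, 7.8), seed=101)


@pytest.fixture(scope="session")
def trimers_small():
    return sample_trimer_set(40, (2.5, 6.5), seed=102)


@pytest.fixture(scope="session")
def minimized_dimer(truth):
    dims = sample_dimer_set(50, (2.7, 3.2), seed=4)
    best = min(dims, key=truth.energy)
    return local_minimize(truth, best, gtol=1e-5)


@pytest.fixture(scope="session")
def minimized_hexamers(truth):
    return {name: local_minimize(truth, cfg, gtol=1e-4)
            for name, cfg in hexamer_templates().items()}


@pytest.fixture(scope="session")
def compact_hexamer(minimized_hexamers):
    return minimized_hexamers["prism"]
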