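import numpy as np
import pytest

import ptsei as P


@pytest.fixture(scope="session")
def network():
    return P.build_network("all_forms")


@pytest.fixture(scope="session")
def truth():
    return P.make_truth_params(0)


@pytest.fixture(scope="session")
def ref_env(truth):
    return P.Environment(T=truth.T0, pH=truth.pH0)


@pytest.fixture(scope="session")
def model(truth, ref_env):
    return P.ReducedModel(P.apply_environment(truth, ref_env))


@pytest.fixture(scope="session")
def random_independent_values(network):
    """A reproducible positive assignment of the independent constants."""
    basis = P.detailed_balance_basis(network)
    rng = np.random.default_rng(42)
    return {k: float(10.0 ** rng.uniform(-3, 3)) for k in basis.independent}
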