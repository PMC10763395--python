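"""Shared fixtures: small metabolic networks with known geometry.

All fixtures are generated programmatically; the expensive ones (preprocessed
flux spaces) are session-scoped since they are read-only.
"""

import numpy as np
import pytest

import looplessflux as lf


@pytest.fixture(scope="session")
def chain_model():
    """->A->B->: uptake, one conversion, secretion — a 1-D flux line."""
    spec = lf.ToyNetworkSpec(n_cycles=0, backbone=1, seed=11)
    return lf.make_toy_network(spec)


@pytest.fixture(scope="session")
def cycle3_model():
    """Canonical 3-cycle fixture: exchanges ->A and C->, internal A->B,
    B->C and a reversible chord C->A closing the loop; dim null(S_int)=1."""
    spec = lf.ToyNetworkSpec(n_cycles=1, cycle_lengths=[3], backbone=2, seed=1)
    return lf.make_toy_network(spec)


@pytest.fixture(scope="session")
def two_cycle_model():
    """Two edge-disjoint 3-cycles over a backbone; dim null(S_int)=2."""
    spec = lf.ToyNetworkSpec(n_cycles=2, cycle_lengths=[3, 3], backbone=4, seed=2)
    return lf.make_toy_network(spec)


@pytest.fixture(scope="session")
def cycle3_space(cycle3_model):
    return lf.build_flux_space(cycle3_model, seed=0)


@pytest.fixture(scope="session")
def chain_space(chain_model):
    return lf.build_flux_space(chain_model, seed=0)


@pytest.fixture(scope="session")
def box_space():
    """Unit box [0,1]^5, no stoichiometry: closed-form uniform moments."""
    model = lf.make_box_model(np.zeros(5), np.ones(5))
    return lf.build_flux_space(model, seed=0)


@pytest.fixture(scope="session")
def loopfree_branched_space():
    """Loop-free network with a >=3-dimensional polytope (extra exchanges)."""
    spec = lf.ToyNetworkSpec(n_cycles=0, backbone=6, seed=5, extra_exchanges=3)
    return lf.build_flux_space(lf.make_toy_network(spec), seed=0)


def random_internal_network(rng, m_max=4, n_max=7):
    """Random small all-internal stoichiometry for oracle cross-validation.

    Columns are resampled until none is all-zero or single-signed, so every
    reaction is a genuine internal conversion.
    """
    m = int(rng.integers(2, m_max + 1))
    n = int(rng.integers(2, n_max + 1))
    S = np.zeros((m, n))
    for j in range(n):
        for _ in range(100):
            col = rng.choice([-1.0, 0.0, 1.0], size=m, p=[0.35, 0.3, 0.35])
            if np.any(col > 0) and np.any(col < 0):
                S[:, j] = col
                break
        else:  # fall back to a deterministic conversion column
            S[0, j], S[(j + 1) % m or 1, j] = -1.0, 1.0
    return S
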