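import numpy as np
import pytest

from mutunet import (Community, GuildState, ModelParams, assemble_network,
                     carrying_capacity, find_equilibrium)


@pytest.fixture
def ref_params():
    """Reference parameter set of the model."""
    return ModelParams()


@pytest.fixture
def competition_only():
    """Parameters with mutualism switched off (single-guild limit)."""
    return ModelParams(c=0.0)


def make_random_equilibrium(rng, params=None, n_max=4, m_max=4):
    """A random viable community driven to its stable equilibrium."""
    if params is None:
        params = ModelParams().with_kernels(
            sigma_C=float(rng.uniform(0.2, 0.8)),
            sigma_m=float(rng.uniform(0.3, 1.2)),
            sigma_A=float(rng.uniform(0.8, 2.0)))
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    comm = Community(
        GuildState(rng.normal(params.x_Amax, 0.8, n),
                   rng.uniform(20, 300, n)),
        GuildState(rng.normal(params.y_Pmax, 0.8, m),
                   rng.uniform(20, 300, m)),
        params)
    eq = find_equilibrium(comm)
    return eq


@pytest.fixture
def random_equilibria():
    """Factory producing random equilibrated communities."""
    def factory(seed, count, **kw):
        rng = np.random.default_rng(seed)
        out = []
        while len(out) < count:
            eq = make_random_equilibrium(rng, **kw)
            if eq.converged and eq.community.n and eq.community.m:
                out.append(eq.community)
        return out
    return factory


@pytest.fixture(scope="session")
def small_network():
    """One assembled small native network (four branching events)."""
    params = ModelParams().with_kernels(sigma_C=np.exp(-3),
                                        sigma_m=np.exp(-2.25),
                                        sigma_A=np.exp(0.75))
    log = assemble_network(params, target_events=4)
    assert log.converged and log.n_events == 4
    return log


@pytest.fixture
def single_logistic():
    """A single animal morph at its logistic equilibrium (no mutualism)."""
    p = ModelParams(c=0.0)
    K = float(carrying_capacity(p.x_Amax, "animal", p))
    return Community(GuildState([p.x_Amax], [K]), GuildState([], []), p)
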