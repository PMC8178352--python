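import numpy as np
import pytest

from islandiicr import Bounds, IslandDemography, log_grid


@pytest.fixture
def grid32():
    return log_grid(1e-2, 1e2, 32)


@pytest.fixture
def stationary():
    return IslandDemography(n=2, event_times=(), migration_rates=(1.0,))


@pytest.fixture
def two_component():
    return IslandDemography(n=10, event_times=(1.5,), migration_rates=(5.0, 0.7))


@pytest.fixture
def wide_bounds():
    def make(gamma):
        return Bounds.uniform(gamma, n=(2, 50), t=(0.05, 100.0), M=(0.05, 100.0))

    return make


def stationary_closed_form(n, M, s, times):
    """Independent spectral oracle for the one-component model.

    Solves the 2x2 transient system by numpy.linalg.eig and returns
    (survival, density, iicr) at the requested times — no matrix
    exponentials, no propagation.
    """
    A = np.array([[-(1.0 / s + M), M], [M / (n - 1), -M / (n - 1)]])
    lam, V = np.linalg.eig(A)
    # p(t) = p0 expm(tA) = p0 V e^{diag(lam t)} V^{-1}
    p0 = np.array([1.0, 0.0])
    coeff = p0 @ V
    Vinv = np.linalg.inv(V)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    states = np.einsum("k,tk,kj->tj", coeff, np.exp(np.outer(times, lam)), Vinv)
    surv = states.sum(axis=1)
    dens = states[:, 0] / s
    return surv, dens, surv / dens
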