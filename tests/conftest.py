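import numpy as np
import pytest

from lineagetraj.model import BranchingSDEModel, InitialLaw, Potential


def flat_potential() -> Potential:
    return Potential(
        value=lambda t, x: np.zeros(np.atleast_2d(np.asarray(x, float)).shape[0]),
        gradient=lambda t, x: np.zeros_like(np.asarray(x, dtype=float)),
    )


def quadratic_potential(k: float = 0.5) -> Potential:
    def value(t, x):
        x = np.atleast_2d(np.asarray(x, float))
        return k * (x ** 2).sum(axis=1)

    def gradient(t, x):
        return 2.0 * k * np.asarray(x, dtype=float)

    return Potential(value, gradient)


def make_model(
    potential=None,
    b=0.0,
    d=0.0,
    tau=0.2,
    q=1.0,
    dim=1,
    domain=None,
    T=1.0,
    init_center=0.0,
    init_sd=0.3,
):
    """Small configurable branching-SDE model for tests."""
    if potential is None:
        potential = flat_potential()
    if domain is None:
        domain = [(-6.0, 6.0)] * dim
    center = np.full(dim, init_center, dtype=float)
    return BranchingSDEModel(
        potential=potential,
        diffusivity=tau,
        birth_rate=b,
        death_rate=d,
        subsampling=(q if callable(q) else (lambda t, _q=q: _q)),
        dimension=dim,
        domain=domain,
        t_final=T,
        initial_law=InitialLaw(lambda rng: rng.normal(center, init_sd)),
        name="test",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
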