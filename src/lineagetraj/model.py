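"""Branching-SDE model definitions.

A branching SDE describes a population of cells in gene-expression space
``X ⊂ R^g``.  Each cell diffuses according to

    dX_t = -∇Ψ(t, X_t) dt + sqrt(τ) dB_t,

and, independently of the others, divides into two cells at rate ``b(t, x)``
or dies at rate ``d(t, x)``.  Observation at a time ``t`` keeps each living
cell independently with probability ``q(t)`` (subsampling).

This module holds the model container, a generic constructor accepting
arbitrary potential/rate closures, and the two built-in reference models used
throughout the package: a two-well landscape with proliferation biased toward
one well (``"doublewell"``), and a landscape with a shallow but highly
proliferative well near ``x1 ≈ 6`` (``"shallowwell"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Potential",
    "BranchingSDEModel",
    "InitialLaw",
    "finite_difference_gradient_check",
    "builtin_model",
    "model_from_config",
    "geometric_subsampling_schedule",
    "piecewise_linear_schedule",
]


@dataclass(frozen=True)
class Potential:
    """A scalar energy landscape Ψ(t, x) together with its spatial gradient.

    Both callables take a scalar time and a state array of shape ``(g,)`` or
    ``(n, g)`` and are vectorised over the leading axis.
    """

    value: Callable[[float, np.ndarray], np.ndarray]
    gradient: Callable[[float, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class InitialLaw:
    """Law of the single founder cell of each tree at t = 0."""

    sampler: Callable[[np.random.Generator], np.ndarray]
    description: str = ""

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return np.asarray([self.sampler(rng) for _ in range(n)], dtype=float)


def _as_rate(r) -> Callable[[float, np.ndarray], np.ndarray]:
    if callable(r):
        return r
    c = float(r)

    def const(t, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.full(x.shape[0], c)

    return const


@dataclass
class BranchingSDEModel:
    """Container for a branching SDE: potential, rates, diffusivity, domain.

    Parameters
    ----------
    potential:
        Energy landscape driving the drift ``-∇Ψ``.
    diffusivity:
        Constant diffusion coefficient ``τ > 0``.
    birth_rate, death_rate:
        Nonnegative rate functions ``(t, x) -> rate`` (vectorised over cells).
    subsampling:
        ``q(t) in (0, 1]``, the probability of keeping each cell when the
        population is observed at time ``t``.
    dimension:
        Number of coordinates g of the state space.
    domain:
        Axis-aligned box ``[(lo, hi)] * g``; the simulator reflects at its
        faces so long runs cannot leak mass.
    t_final:
        Horizon ``T`` of the experiment, used for the boundedness check.
    """

    potential: Potential
    diffusivity: float
    birth_rate: Callable[[float, np.ndarray], np.ndarray]
    death_rate: Callable[[float, np.ndarray], np.ndarray]
    subsampling: Callable[[float], float]
    dimension: int
    domain: np.ndarray
    t_final: float = 1.0
    initial_law: InitialLaw | None = None
    name: str = "custom"
    rate_bound: float = field(init=False, default=np.nan)

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise ValueError("diffusivity tau must be > 0")
        self.domain = np.asarray(self.domain, dtype=float).reshape(self.dimension, 2)
        if np.any(self.domain[:, 0] >= self.domain[:, 1]):
            raise ValueError("domain must be a nondegenerate box")
        self.birth_rate = _as_rate(self.birth_rate)
        self.death_rate = _as_rate(self.death_rate)
        self.rate_bound = self._sup_rates()
        if not np.isfinite(self.rate_bound):
            raise ValueError("sup of b + d over domain x [0, T] must be finite")
        for t in np.linspace(0.0, self.t_final, 7):
            q = self.subsampling(float(t))
            if not (0.0 < q <= 1.0):
                raise ValueError(f"q({t}) = {q} outside (0, 1]")

    def _sup_rates(self, n_grid: int = 12, n_times: int = 5) -> float:
        axes = [np.linspace(lo, hi, n_grid) for lo, hi in self.domain]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, self.dimension)
        sup = 0.0
        for t in np.linspace(0.0, self.t_final, n_times):
            tot = np.asarray(self.birth_rate(t, pts)) + np.asarray(self.death_rate(t, pts))
            if not np.all(np.isfinite(tot)):
                return np.inf
            sup = max(sup, float(tot.max()))
        return sup

    def drift(self, t: float, x: np.ndarray) -> np.ndarray:
        """Drift field ``-∇Ψ(t, x)``."""
        return -np.asarray(self.potential.gradient(t, x), dtype=float)

    def reflect(self, x: np.ndarray) -> np.ndarray:
        """Fold states back into the domain box (reflecting boundary)."""
        lo, hi = self.domain[:, 0], self.domain[:, 1]
        span = hi - lo
        y = np.mod(np.asarray(x, dtype=float) - lo, 2.0 * span)
        y = np.where(y > span, 2.0 * span - y, y)
        return y + lo


def finite_difference_gradient_check(
    potential: Potential,
    probes: Sequence[tuple[float, np.ndarray]],
    step: float = 1e-5,
) -> float:
    """Max relative discrepancy between the declared gradient and central
    finite differences of the value, over the probe points.

    Raises ``ValueError`` on a non-finite value or gradient at any probe.
    """
    worst = 0.0
    for t, x in probes:
        x = np.asarray(x, dtype=float)
        g = np.asarray(potential.gradient(t, x), dtype=float).reshape(-1)
        v0 = float(np.squeeze(potential.value(t, x)))
        if not (np.all(np.isfinite(g)) and np.isfinite(v0)):
            raise ValueError(f"non-finite potential or gradient at probe {x}")
        num = np.empty_like(g)
        for j in range(x.size):
            e = np.zeros_like(x)
            e[j] = step
            vp = float(np.squeeze(potential.value(t, x + e)))
            vm = float(np.squeeze(potential.value(t, x - e)))
            num[j] = (vp - vm) / (2.0 * step)
        scale = max(np.linalg.norm(g), np.linalg.norm(num), 1.0)
        worst = max(worst, float(np.linalg.norm(g - num) / scale))
    return worst


def piecewise_linear_schedule(knots: Sequence[Sequence[float]]) -> Callable[[float], float]:
    """q(t) interpolated linearly between (time, rate) knots, clamped at the ends."""
    ts = np.asarray([k[0] for k in knots], dtype=float)
    qs = np.asarray([k[1] for k in knots], dtype=float)
    order = np.argsort(ts)
    ts, qs = ts[order], qs[order]

    def q(t: float) -> float:
        return float(np.interp(t, ts, qs))

    return q


def geometric_subsampling_schedule(q_final: float, t_final: float) -> Callable[[float], float]:
    """Decreasing schedule from q(0) = 1 to q(T) = ``q_final``, log-linear in t.

    Emulates an experiment where early (small) populations are sampled near
    exhaustively while late, large populations are sparsely sampled.
    """
    if not (0.0 < q_final <= 1.0):
        raise ValueError("q_final must be in (0, 1]")

    def q(t: float) -> float:
        return float(q_final ** (np.clip(t / t_final, 0.0, 1.0)))

    return q


# ---------------------------------------------------------------------------
# Built-in reference models
# ---------------------------------------------------------------------------

def _doublewell_potential() -> Potential:
    # V1(x) = (x1^2 - 1)^2 + x2^2 : two wells at x1 = ±1.
    def value(t, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x[:, 0] ** 2 - 1.0) ** 2 + x[:, 1] ** 2

    def gradient(t, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        g = np.empty_like(x)
        g[:, 0] = 4.0 * x[:, 0] * (x[:, 0] ** 2 - 1.0)
        g[:, 1] = 2.0 * x[:, 1]
        return g[0] if single else g

    return Potential(value, gradient)


def _shallowwell_potential() -> Potential:
    # V2: a deeper, narrow well near x1 = 1 and a shallow, wide well near
    # x1 = 6 (both Gaussian), a weak quadratic confinement along x1, and a
    # harmonic term in x2.  Barriers are comparable to tau so rare lineages
    # cross within the horizon; the x1 = 6 well retains cells only weakly
    # (it is shallow) but carries a high birth rate.
    A0, S0 = 0.12, 0.8
    A1, S1 = 0.30, 1.5
    CONF = 0.005

    def value(t, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x1, x2 = x[:, 0], x[:, 1]
        return (A0 * (1.0 - np.exp(-(x1 - 1.0) ** 2 / (2 * S0 ** 2)))
                - A1 * np.exp(-(x1 - 6.0) ** 2 / (2 * S1 ** 2))
                + CONF * (x1 - 3.0) ** 2 + 0.25 * x2 ** 2)

    def gradient(t, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        x1, x2 = x[:, 0], x[:, 1]
        g = np.empty_like(x)
        g[:, 0] = (A0 * np.exp(-(x1 - 1.0) ** 2 / (2 * S0 ** 2)) * (x1 - 1.0) / S0 ** 2
                   + A1 * np.exp(-(x1 - 6.0) ** 2 / (2 * S1 ** 2)) * (x1 - 6.0) / S1 ** 2
                   + 2 * CONF * (x1 - 3.0))
        g[:, 1] = 0.5 * x2
        return g[0] if single else g

    return Potential(value, gradient)


def builtin_model(name: str, q_final: float = 1.0) -> BranchingSDEModel:
    """Construct one of the two reference branching SDEs.

    ``"doublewell"``: two wells at x1 = ±1, zero death, birth rate higher in
    the right well, so the branching population is biased rightward while the
    underlying SDE is symmetric.

    ``"shallowwell"``: a deeper well near the origin and a shallow well near
    x1 = 6 where the birth rate peaks; cells that wander into the shallow well
    proliferate heavily, so the raw empirical measure strongly overweights it.

    ``q_final`` < 1 installs a subsampling schedule decreasing linearly from
    1 at t = 0 to ``q_final`` at the horizon; the default observes every leaf.
    """
    if name == "doublewell":
        T = 3.0
        pot = _doublewell_potential()

        def birth(t, x):
            x = np.atleast_2d(np.asarray(x, dtype=float))
            return 0.35 + 1.05 * 0.5 * (1.0 + np.tanh(2.0 * x[:, 0]))

        def init(rng: np.random.Generator) -> np.ndarray:
            return rng.normal([0.0, 0.0], 0.3)

        model = BranchingSDEModel(
            potential=pot,
            diffusivity=0.25,
            birth_rate=birth,
            death_rate=0.0,
            subsampling=piecewise_linear_schedule([[0.0, 1.0], [T, q_final]]),
            dimension=2,
            domain=[(-3.0, 3.0), (-3.0, 3.0)],
            t_final=T,
            initial_law=InitialLaw(init, "N((0,0), 0.3^2): undecided founders"),
            name="doublewell",
        )
        return model
    if name == "shallowwell":
        T = 4.0
        pot = _shallowwell_potential()

        def birth(t, x):
            x = np.atleast_2d(np.asarray(x, dtype=float))
            r2 = (x[:, 0] - 6.0) ** 2 + x[:, 1] ** 2
            return 1.1 + 2.5 * np.exp(-r2 / (2 * 1.2 ** 2))

        def init(rng: np.random.Generator) -> np.ndarray:
            return rng.normal([1.0, 0.0], 0.3)

        model = BranchingSDEModel(
            potential=pot,
            diffusivity=0.9,
            birth_rate=birth,
            death_rate=0.0,
            subsampling=piecewise_linear_schedule([[0.0, 1.0], [T, q_final]]),
            dimension=2,
            domain=[(-2.5, 9.5), (-3.5, 3.5)],
            t_final=T,
            initial_law=InitialLaw(init, "N((1,0), 0.3^2): founders in the deep well"),
            name="shallowwell",
        )
        return model
    raise ValueError(f"unknown builtin model {name!r}; choose 'doublewell' or 'shallowwell'")


def model_from_config(cfg: dict | str) -> BranchingSDEModel:
    """Build a model from a JSON config (path, JSON string, or dict).

    Either ``{"name": "doublewell", "q_final": 0.05}`` for a builtin, or an
    explicit spec with a builtin potential key plus scalar rates::

        {"potential": "doublewell", "tau": 0.1, "birth": 1.0, "death": 0.0,
         "q": [[0.0, 1.0], [2.0, 0.05]], "domain": [[-3, 3], [-3, 3]], "T": 2.0}
    """
    if isinstance(cfg, str):
        try:
            cfg = json.loads(cfg)
        except json.JSONDecodeError:
            with open(cfg) as fh:
                cfg = json.load(fh)
    if "name" in cfg:
        return builtin_model(cfg["name"], q_final=cfg.get("q_final", 1.0))
    potentials = {"doublewell": _doublewell_potential, "shallowwell": _shallowwell_potential}
    key = cfg["potential"]
    if key not in potentials:
        raise ValueError(f"unknown potential key {key!r}")
    pot = potentials[key]()
    domain = cfg["domain"]
    T = float(cfg.get("T", 1.0))
    q = piecewise_linear_schedule(cfg["q"]) if "q" in cfg else (lambda t: 1.0)
    dim = len(domain)
    center = np.array([(lo + hi) / 2.0 for lo, hi in domain])

    def init(rng: np.random.Generator) -> np.ndarray:
        return rng.normal(center, 0.3)

    return BranchingSDEModel(
        potential=pot,
        diffusivity=float(cfg["tau"]),
        birth_rate=cfg.get("birth", 0.0),
        death_rate=cfg.get("death", 0.0),
        subsampling=q,
        dimension=dim,
        domain=domain,
        t_final=T,
        initial_law=InitialLaw(init, "gaussian at domain center"),
        name=f"config:{key}",
    )
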