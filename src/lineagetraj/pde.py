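"""Finite-difference solvers for the master equations of the branching SDE.

These solvers serve as independent oracles for the Monte-Carlo machinery and
compute the survival probability / drift bias induced by death and
subsampling.  They are deliberately desk-scale: 1D or 2D uniform grids,
explicit time stepping (upwind in the drift, centred in the diffusion),
no-flux boundaries.

Equations handled (densities in the weak sense, ``L* p = div(p ∇Ψ) + τ/2 Δp``):

* Fokker–Planck of the underlying SDE:         ∂_t p = L* p
* branching-SDE intensity:                     ∂_t ρ = L* ρ + (b - d) ρ
* generation-resolved ladder:                  ∂_t ρ(m) = L* ρ(m) + 2b ρ(m-1) - (b+d) ρ(m)
* dyadic reweighting                           ρ̄ = Σ 2^(-m) ρ(m) solves ∂_t ρ̄ = L* ρ̄ - d ρ̄
* branch-survival probability S (backward):    the non-survival u solves
      ∂_s u = L u + b u² + d - (b+d) u,  u(0, ·) = 1 - q(t_i),
  with L the generator (-∇Ψ·∇ + τ/2 Δ) and S = 1 - u
* biased generation system (observable m̃, conditioned on survival):
      ∂_t ρ(m̃) = L*_{Ψ - τ ln S} ρ(m̃) + 2bS ρ(m̃-1) - bS ρ(m̃)
  whose dyadic sum solves the pure transport-diffusion ∂_t ρ̄ = L*_{Ψ - τ ln S} ρ̄.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BranchingSDEModel

__all__ = ["Grid", "GenerationDensities", "solve_fokker_planck",
           "solve_generation_system", "SurvivalProbability",
           "survival_probability", "solve_biased_system"]


@dataclass
class Grid:
    """Uniform tensor grid over (a subset of) the model domain, 1D or 2D."""

    axes: list[np.ndarray]

    def __post_init__(self):
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        if len(self.axes) not in (1, 2):
            raise ValueError("oracle grids are 1D or 2D only")
        self.h = [float(a[1] - a[0]) for a in self.axes]
        self.shape = tuple(len(a) for a in self.axes)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def points(self) -> np.ndarray:
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.reshape(-1) for m in mesh], axis=-1)

    def cell_volume(self) -> float:
        return float(np.prod(self.h))

    def integrate(self, f: np.ndarray) -> float:
        return float(f.sum() * self.cell_volume())

    def gaussian(self, center, sigma) -> np.ndarray:
        """Normalised Gaussian bump usable as an initial density."""
        pts = self.points()
        c = np.broadcast_to(np.asarray(center, dtype=float), (self.ndim,))
        d2 = ((pts - c) ** 2 / (2.0 * np.asarray(sigma, dtype=float) ** 2)).sum(axis=1)
        g = np.exp(-d2).reshape(self.shape)
        return g / self.integrate(g)


def _face_velocity(model: BranchingSDEModel, grid: Grid, t: float, axis: int) -> np.ndarray:
    """Drift component -∂Ψ/∂x_axis at the interior cell faces along ``axis``."""
    axes = [a.copy() for a in grid.axes]
    axes[axis] = 0.5 * (grid.axes[axis][1:] + grid.axes[axis][:-1])
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.reshape(-1) for m in mesh], axis=-1)
    vel = -np.asarray(model.potential.gradient(t, pts), dtype=float)[:, axis]
    return vel.reshape(mesh[0].shape)


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (e^x - 1), the Scharfetter-Gummel weight (B(0) = 1)."""
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-10
    out[nz] = x[nz] / np.expm1(x[nz])
    return out


def _fp_rhs(p: np.ndarray, faces: list[np.ndarray], grid: Grid, tau: float) -> np.ndarray:
    """Conservative advection-diffusion with Scharfetter-Gummel fluxes and
    no-flux walls.  Exponential fitting makes the Gibbs density e^{-2Ψ/τ}
    an exact stationary state of the discretisation."""
    D = tau / 2.0
    out = np.zeros_like(p)
    for ax in range(grid.ndim):
        h = grid.h[ax]
        pm = np.moveaxis(p, ax, 0)
        um = np.moveaxis(faces[ax], ax, 0)
        w = um * h / D
        F = (D / h) * (_bernoulli(-w) * pm[:-1] - _bernoulli(w) * pm[1:])
        div = np.zeros_like(pm)
        div[:-1] += F / h
        div[1:] -= F / h
        out += np.moveaxis(-div, 0, ax)
    return out


def _stable_dt(model: BranchingSDEModel, grid: Grid, extra_rate: float = 0.0,
               cfl: float = 0.4) -> float:
    pts = grid.points()
    vmax = np.abs(model.potential.gradient(0.0, pts)).max()
    denom = sum(model.diffusivity / h ** 2 + (vmax + 1e-12) / h for h in grid.h)
    denom += extra_rate
    return cfl / denom


def solve_fokker_planck(
    model: BranchingSDEModel,
    initial: np.ndarray,
    t_end: float,
    grid: Grid,
    t_start: float = 0.0,
) -> np.ndarray:
    """Evolve a probability density under ∂_t p = div(p∇Ψ) + τ/2 Δp.

    Mass is conserved to machine precision by the finite-volume form.
    """
    p = np.asarray(initial, dtype=float).reshape(grid.shape).copy()
    if np.any(p < 0):
        raise ValueError("initial density must be nonnegative")
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    dt = _stable_dt(model, grid)
    t = t_start
    faces = [_face_velocity(model, grid, t, ax) for ax in range(grid.ndim)]
    while t < t_end - 1e-14:
        step = min(dt, t_end - t)
        k1 = _fp_rhs(p, faces, grid, model.diffusivity)
        k2 = _fp_rhs(p + step * k1, faces, grid, model.diffusivity)
        p = np.clip(p + 0.5 * step * (k1 + k2), 0.0, None)
        t += step
    return p


@dataclass
class GenerationDensities:
    """Stack of per-generation densities ρ(m), m = 0..M_max, at one time."""

    rho: np.ndarray  # shape (M_max + 1, *grid.shape)
    grid: Grid
    time: float

    def total(self) -> np.ndarray:
        return self.rho.sum(axis=0)

    def reweighted(self) -> np.ndarray:
        m = np.arange(self.rho.shape[0])
        return np.tensordot(2.0 ** (-m), self.rho, axes=(0, 0))

    def masses(self) -> np.ndarray:
        return np.array([self.grid.integrate(self.rho[m]) for m in range(self.rho.shape[0])])

    def check_tail(self, rel_tol: float = 1e-3):
        masses = self.masses()
        if masses.sum() > 0 and masses[-1] > rel_tol * masses.sum():
            raise ValueError(
                f"generation truncation too small: tail mass fraction "
                f"{masses[-1] / masses.sum():.2e} > {rel_tol:g}")


def solve_generation_system(
    model: BranchingSDEModel,
    initial: np.ndarray,
    t_end: float,
    grid: Grid,
    M_max: int = 40,
) -> GenerationDensities:
    """Solve the generation ladder ∂_t ρ(m) = L*ρ(m) + 2bρ(m-1) - (b+d)ρ(m)
    with ρ_0(m) = μ_0 1_{m=0}."""
    pts = grid.points()
    b = np.asarray(model.birth_rate(0.0, pts)).reshape(grid.shape)
    d = np.asarray(model.death_rate(0.0, pts)).reshape(grid.shape)
    rho = np.zeros((M_max + 1,) + grid.shape)
    rho[0] = np.asarray(initial, dtype=float).reshape(grid.shape)
    dt = _stable_dt(model, grid, extra_rate=float((b + d).max()) + 2.0 * float(b.max()))
    faces = [_face_velocity(model, grid, 0.0, ax) for ax in range(grid.ndim)]
    def ladder_rhs(r):
        out = np.empty_like(r)
        for m in range(M_max + 1):
            rhs = _fp_rhs(r[m], faces, grid, model.diffusivity) - (b + d) * r[m]
            if m > 0:
                rhs = rhs + 2.0 * b * r[m - 1]
            out[m] = rhs
        return out

    t = 0.0
    while t < t_end - 1e-14:
        step = min(dt, t_end - t)
        k1 = ladder_rhs(rho)
        k2 = ladder_rhs(rho + step * k1)
        rho = np.clip(rho + 0.5 * step * (k1 + k2), 0.0, None)
        t += step
    out = GenerationDensities(rho=rho, grid=grid, time=t_end)
    out.check_tail()
    return out


@dataclass
class SurvivalProbability:
    """S^{t_i}(t, x): probability that a cell at (t, x) has ≥ 1 observed
    descendant at the measurement time t_i.  Stored on the grid at a ladder
    of times and interpolated linearly in t."""

    times: np.ndarray           # increasing, in [0, t_i]
    values: np.ndarray          # shape (len(times), *grid.shape), in (0, 1]
    grid: Grid
    t_i: float

    def __call__(self, t: float) -> np.ndarray:
        ts = self.times
        if t <= ts[0]:
            return self.values[0]
        if t >= ts[-1]:
            return self.values[-1]
        j = int(np.searchsorted(ts, t) - 1)
        w = (t - ts[j]) / (ts[j + 1] - ts[j])
        return (1 - w) * self.values[j] + w * self.values[j + 1]

    def log_gradient(self, t: float) -> list[np.ndarray]:
        """∇ ln S at cell faces along each axis (for the bias drift τ∇ln S)."""
        S = self(t)
        out = []
        for ax in range(self.grid.ndim):
            h = self.grid.h[ax]
            Sm = np.moveaxis(S, ax, 0)
            g = (np.log(Sm[1:]) - np.log(Sm[:-1])) / h
            out.append(np.moveaxis(g, 0, ax))
        return out


def survival_probability(
    model: BranchingSDEModel,
    t_i: float,
    grid: Grid,
    n_save: int = 65,
) -> SurvivalProbability:
    """Solve the backward reaction–diffusion equation for branch survival.

    Writing u(s, x) for the probability that a cell at x, a time s before the
    measurement, leaves NO observed descendant, u solves

        ∂_s u = -∇Ψ·∇u + (τ/2) Δu + b u² + d - (b + d) u,   u(0) = 1 - q(t_i),

    (a division leaves no observed branch iff both daughters leave none,
    hence the u² term).  Then S^{t_i}(t, x) = 1 - u(t_i - t, x).
    """
    pts = grid.points()
    b = np.asarray(model.birth_rate(0.0, pts)).reshape(grid.shape)
    d = np.asarray(model.death_rate(0.0, pts)).reshape(grid.shape)
    q = float(model.subsampling(t_i))
    u = np.full(grid.shape, 1.0 - q)
    # node-centred drift for the non-conservative backward operator
    vel = [-np.asarray(model.potential.gradient(0.0, pts), dtype=float)[:, ax]
           .reshape(grid.shape) for ax in range(grid.ndim)]
    dt = _stable_dt(model, grid, extra_rate=float((b + d).max()) + 2.0 * float(b.max()))
    save_times = np.linspace(0.0, t_i, n_save)
    saved = [u.copy()]
    next_save = 1
    s = 0.0
    while s < t_i - 1e-14:
        step = min(dt, t_i - s)
        rhs = np.zeros_like(u)
        for ax in range(grid.ndim):
            h = grid.h[ax]
            um = np.moveaxis(u, ax, 0)
            vm = np.moveaxis(vel[ax], ax, 0)
            # one-sided upwind gradient, Neumann at walls
            fwd = np.empty_like(um)
            fwd[:-1] = (um[1:] - um[:-1]) / h
            fwd[-1] = 0.0
            bwd = np.empty_like(um)
            bwd[1:] = (um[1:] - um[:-1]) / h
            bwd[0] = 0.0
            adv = np.where(vm > 0, vm * fwd, vm * bwd)
            lap = np.zeros_like(um)
            lap[1:-1] = (um[2:] - 2 * um[1:-1] + um[:-2]) / h ** 2
            lap[0] = (um[1] - um[0]) / h ** 2 * 2.0
            lap[-1] = (um[-2] - um[-1]) / h ** 2 * 2.0
            rhs += np.moveaxis(adv + (model.diffusivity / 2.0) * lap, 0, ax)
        rhs += b * u ** 2 + d - (b + d) * u
        u = np.clip(u + step * rhs, 0.0, 1.0)
        s += step
        while next_save < n_save and s >= save_times[next_save] - 1e-12:
            saved.append(u.copy())
            next_save += 1
    while len(saved) < n_save:
        saved.append(u.copy())
    S_slab = 1.0 - np.asarray(saved)          # indexed by s = t_i - t
    S_slab = np.clip(S_slab, 1e-12, 1.0)
    if S_slab.min() <= 1e-12:
        raise ValueError("survival probability underflow: regime unusable")
    # reorder to be indexed by t in [0, t_i]
    times = t_i - save_times[::-1]
    values = S_slab[::-1]
    return SurvivalProbability(times=times, values=values, grid=grid, t_i=t_i)


def solve_biased_system(
    model: BranchingSDEModel,
    t_i: float,
    grid: Grid,
    initial: np.ndarray,
    M_max: int = 40,
    S: SurvivalProbability | None = None,
) -> GenerationDensities:
    """Generation-resolved densities of the observable process conditioned on
    having an observed descendant at ``t_i``.

    Solves ∂_t ρ(m̃) = L*_{Ψ - τ ln S, τ} ρ(m̃) + 2bS ρ(m̃-1) - bS ρ(m̃)
    with initial condition ∝ μ_0 S(0, ·) 1_{m̃=0}; the modified potential
    adds the bias drift +τ∇ln S to the true drift.
    """
    if S is None:
        S = survival_probability(model, t_i, grid)
    pts = grid.points()
    b = np.asarray(model.birth_rate(0.0, pts)).reshape(grid.shape)
    mu0 = np.asarray(initial, dtype=float).reshape(grid.shape)
    rho0 = mu0 * S(0.0)
    Z = grid.integrate(rho0)
    if Z <= 0:
        raise ValueError("initial mass vanished under survival conditioning")
    rho = np.zeros((M_max + 1,) + grid.shape)
    rho[0] = rho0 / Z
    dt = _stable_dt(model, grid, extra_rate=3.0 * float(b.max()))
    # bias drift can steepen the velocity; be conservative
    dt *= 0.5
    t = 0.0
    base_faces = [_face_velocity(model, grid, 0.0, ax) for ax in range(grid.ndim)]
    def ladder_rhs(r, faces, bS):
        out = np.empty_like(r)
        for m in range(M_max + 1):
            rhs = _fp_rhs(r[m], faces, grid, model.diffusivity) - bS * r[m]
            if m > 0:
                rhs = rhs + 2.0 * bS * r[m - 1]
            out[m] = rhs
        return out

    while t < t_i - 1e-14:
        step = min(dt, t_i - t)
        St = S(t)
        grads = S.log_gradient(t)
        faces = [base_faces[ax] + model.diffusivity * grads[ax]
                 for ax in range(grid.ndim)]
        bS = b * St
        k1 = ladder_rhs(rho, faces, bS)
        k2 = ladder_rhs(rho + step * k1, faces, bS)
        rho = np.clip(rho + 0.5 * step * (k1 + k2), 0.0, None)
        t += step
    out = GenerationDensities(rho=rho, grid=grid, time=t_i)
    out.check_tail()
    return out
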