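"""Desk-scale dynamics: overdamped Langevin, steered pulls, and
multiple-walker well-tempered metadynamics with a shared bias.

The integrator is Euler–Maruyama overdamped Langevin,

    x ← x − (Δt/γ_f)·∇U + sqrt(2·k_B·T·Δt/γ_f)·ξ,

with friction γ_f in 1/ps, energies in kcal/mol and time in ps. It stands in
for full thermostatted MD: the object of study here is the bias/free-energy
machinery (hill deposition, shared-bias walkers, FES reconstruction), not
force fields. All stochastic entry points take explicit seeds and the same
(seed, inputs) pair reproduces every output bit-identically, including the
walker interleaving.

Well-tempered metadynamics deposits, every ``pace`` steps, a Gaussian hill of
height h0·exp(−V(s)/((γ−1)·k_B·T)) at the walker's current CV value s, where V
is the bias already accumulated there and γ > 1 the bias factor. All walkers
read and write one shared :class:`BiasState`, synchronised at each deposition
round in deterministic round-robin order by walker id. The free-energy
estimate is F(s) = −(γ/(γ−1))·V(s), shifted to min 0; hills are truncated at
5σ (relative error below exp(−12.5) ≈ 4e−6 of a hill's height).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import kbt
from .core import Structure
from .exceptions import ConfigError, DivergenceError
from .fes import Axis, FesGrid

__all__ = [
    "ToySystem",
    "Hill",
    "BiasState",
    "LangevinResult",
    "SteeredResult",
    "MetadResult",
    "run_langevin",
    "run_steered",
    "run_metadynamics",
    "reconstruct_fes",
    "with_harmonic_walls",
]

# A sampler CV maps the system state to (value, gradient-with-state-shape).
CvFunc = Callable[[np.ndarray], tuple[float, np.ndarray]]

_TRUNC = 5.0  # hill truncation radius in units of sigma


@dataclass
class ToySystem:
    """A toy system the sampler can integrate.

    ``potential``/``gradient`` act on the state array (any shape: a scalar
    coordinate vector for analytic landscapes, an (n, 3) coordinate array for
    bead models). ``structure`` attaches an atom table when the state is a
    bead-model conformation.
    """

    potential: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    x0: np.ndarray
    temperature: float = 300.0
    friction: float = 1.0
    timestep: float = 0.005
    structure: Structure | None = None

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class Hill:
    """One deposited Gaussian: center and width per CV, height in kcal/mol."""

    center: np.ndarray
    sigma: np.ndarray
    height: float
    deposit_time: float

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.sigma.shape != self.center.shape:
            self.sigma = np.broadcast_to(self.sigma, self.center.shape).copy()
        if np.any(self.sigma <= 0):
            raise ValueError("hill sigma must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")


class BiasState:
    """The deposited hills plus the well-tempered bias factor.

    This is the sufficient statistic for FES reconstruction. Evaluation is
    vectorised over hills with 5σ truncation; the hill arrays are cached and
    rebuilt lazily as hills are added.
    """

    def __init__(self, bias_factor: float, cv_names: Sequence[str], hills=None):
        if not bias_factor > 1:
            raise ConfigError("well-tempered bias factor must exceed 1")
        self.bias_factor = float(bias_factor)
        self.cv_names = list(cv_names)
        self.hills: list[Hill] = list(hills) if hills else []
        for h in self.hills:
            self._check_dim(h)
        self._cache = None
        self._grid = None  # (axes, V values, list of dV/ds_k values)

    @property
    def n_cvs(self) -> int:
        return len(self.cv_names)

    def _check_dim(self, hill: Hill) -> None:
        if len(hill.center) != self.n_cvs:
            raise ConfigError(
                f"hill dimension {len(hill.center)} does not match {self.n_cvs} CVs"
            )

    def add_hill(self, hill: Hill) -> None:
        self._check_dim(hill)
        self.hills.append(hill)
        self._cache = None
        if self._grid is not None:
            self._grid_add(hill)

    # -- grid cache: O(1) per-step evaluation during dynamics ---------------

    def attach_grid(self, axes: Sequence[Axis]) -> None:
        """Cache the bias (and its CV gradient) on a regular grid.

        Each deposited hill is accumulated onto the grid once; evaluation then
        uses multilinear interpolation instead of summing over all hills.
        Points outside the grid fall back to the exact hill sum. The
        reconstruction path never uses the cache.
        """
        if len(axes) != self.n_cvs:
            raise ConfigError("grid dimensionality must match the number of CVs")
        mesh = np.meshgrid(*[ax.centers for ax in axes], indexing="ij")
        shape = mesh[0].shape
        self._grid = (
            list(axes),
            [m.ravel() for m in mesh],
            np.zeros(int(np.prod(shape))),
            [np.zeros(int(np.prod(shape))) for _ in range(self.n_cvs)],
            shape,
        )
        for h in self.hills:
            self._grid_add(h)

    def _grid_add(self, hill: Hill) -> None:
        axes, flat_mesh, v, grads, shape = self._grid
        zs = [(m - c) / s for m, c, s in zip(flat_mesh, hill.center, hill.sigma)]
        mask = np.ones(len(flat_mesh[0]), dtype=bool)
        for z in zs:
            mask &= np.abs(z) <= _TRUNC
        if not mask.any():
            return
        expo = np.zeros(mask.sum())
        for z in zs:
            expo += z[mask] ** 2
        g = hill.height * np.exp(-0.5 * expo)
        v[mask] += g
        for k, z in enumerate(zs):
            grads[k][mask] += -g * z[mask] / hill.sigma[k]

    def _grid_interp(self, s: np.ndarray):
        axes, _, v, grads, shape = self._grid
        pos = []
        for val, ax in zip(s, axes):
            p = (val - ax.lo) / ax.width - 0.5
            if p < 0.0 or p > ax.nbins - 1:
                return None  # outside the cached range
            pos.append(p)
        idx0 = [int(p) for p in pos]
        idx0 = [min(i, ax.nbins - 2) if ax.nbins > 1 else 0 for i, ax in zip(idx0, axes)]
        frac = [p - i for p, i in zip(pos, idx0)]
        vg = v.reshape(shape)
        gg = [g.reshape(shape) for g in grads]
        if len(axes) == 1:
            i, f = idx0[0], frac[0]
            value = vg[i] * (1 - f) + vg[i + 1] * f
            grad = np.array([gg[0][i] * (1 - f) + gg[0][i + 1] * f])
            return float(value), grad
        i, j = idx0
        fx, fy = frac
        w = np.array(
            [(1 - fx) * (1 - fy), (1 - fx) * fy, fx * (1 - fy), fx * fy]
        )
        corners = [(i, j), (i, j + 1), (i + 1, j), (i + 1, j + 1)]
        value = sum(wk * vg[c] for wk, c in zip(w, corners))
        grad = np.array(
            [sum(wk * g[c] for wk, c in zip(w, corners)) for g in gg]
        )
        return float(value), grad

    def _arrays(self):
        if self._cache is None:
            if self.hills:
                centers = np.array([h.center for h in self.hills])
                sigmas = np.array([h.sigma for h in self.hills])
                heights = np.array([h.height for h in self.hills])
            else:
                centers = np.zeros((0, self.n_cvs))
                sigmas = np.ones((0, self.n_cvs))
                heights = np.zeros(0)
            self._cache = (centers, sigmas, heights)
        return self._cache

    def potential(self, s: np.ndarray) -> float:
        """Bias potential at one CV point (kcal/mol)."""
        return self.potential_and_grad(s)[0]

    def potential_and_grad(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        """Bias potential and its gradient w.r.t. the CVs at one point."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self._grid is not None:
            hit = self._grid_interp(s)
            if hit is not None:
                return hit
        centers, sigmas, heights = self._arrays()
        if len(heights) == 0:
            return 0.0, np.zeros_like(s)
        z = (s - centers) / sigmas
        inside = np.all(np.abs(z) <= _TRUNC, axis=1)
        if not inside.any():
            return 0.0, np.zeros_like(s)
        z = z[inside]
        g = heights[inside] * np.exp(-0.5 * np.sum(z * z, axis=1))
        v = float(g.sum())
        grad = -(g[:, None] * z / sigmas[inside]).sum(axis=0)
        return v, grad

    def potential_batch(self, points: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Bias potential at many CV points, shape (m, n_cvs) → (m,)."""
        points = np.asarray(points, dtype=float).reshape(-1, self.n_cvs)
        centers, sigmas, heights = self._arrays()
        out = np.zeros(len(points))
        if len(heights) == 0:
            return out
        for lo in range(0, len(points), chunk):
            pts = points[lo : lo + chunk]
            z = (pts[:, None, :] - centers[None, :, :]) / sigmas[None, :, :]
            expo = np.sum(z * z, axis=2)
            mask = np.all(np.abs(z) <= _TRUNC, axis=2)
            out[lo : lo + chunk] = np.sum(
                np.where(mask, heights[None, :] * np.exp(-0.5 * expo), 0.0), axis=1
            )
        return out

    def truncated(self, time: float) -> "BiasState":
        """A new bias containing only hills deposited at or before ``time``."""
        return BiasState(
            self.bias_factor,
            self.cv_names,
            [h for h in self.hills if h.deposit_time <= time],
        )


def with_harmonic_walls(
    system: ToySystem, lo: float, hi: float, k: float = 30.0, coordinate: int = 0
) -> ToySystem:
    """Confine one coordinate of a toy system with one-sided harmonic walls.

    Adds 0.5·k·(x−hi)² above ``hi`` and 0.5·k·(x−lo)² below ``lo`` to the
    potential — the standard device for keeping enhanced sampling inside the
    CV region of interest instead of pouring bias into irrelevant tails.
    """
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    u0, g0 = system.potential, system.gradient

    def pot(x):
        xi = x[coordinate]
        wall = 0.0
        if xi > hi:
            wall = 0.5 * k * (xi - hi) ** 2
        elif xi < lo:
            wall = 0.5 * k * (xi - lo) ** 2
        return u0(x) + wall

    def grad(x):
        g = np.array(g0(x), dtype=float, copy=True)
        xi = x[coordinate]
        if xi > hi:
            g[coordinate] += k * (xi - hi)
        elif xi < lo:
            g[coordinate] += k * (xi - lo)
        return g

    return ToySystem(
        pot, grad, system.x0, system.temperature, system.friction,
        system.timestep, system.structure,
    )


# ---------------------------------------------------------------------------
# integration


@dataclass
class LangevinResult:
    times: np.ndarray
    positions: np.ndarray
    cvs: np.ndarray | None
    final_x: np.ndarray


@dataclass
class SteeredResult:
    times: np.ndarray
    positions: np.ndarray
    cv: np.ndarray
    centers: np.ndarray
    work: np.ndarray
    final_x: np.ndarray


@dataclass
class MetadResult:
    bias: BiasState
    times: list[np.ndarray]
    positions: list[np.ndarray]
    cvs: list[np.ndarray]


def _bias_force(x, cv_funcs, bias: BiasState):
    values, grads = [], []
    for f in cv_funcs:
        v, g = f(x)
        values.append(v)
        grads.append(g)
    s = np.array(values)
    _, dv_ds = bias.potential_and_grad(s)
    force = np.zeros_like(x, dtype=float)
    for dv, g in zip(dv_ds, grads):
        force -= dv * g
    return s, force


def _integrate(
    system: ToySystem,
    steps: int,
    rng: np.random.Generator,
    x: np.ndarray,
    cv_funcs=None,
    bias: BiasState | None = None,
    spring=None,  # (cv_func, k, centers array of length steps+1) or None
    record_every: int = 1,
    step_offset: int = 0,
):
    dt = system.timestep
    friction = system.friction
    noise = np.sqrt(2.0 * kbt(system.temperature) * dt / friction)
    recorded_t, recorded_x, recorded_cv, work_series = [], [], [], []
    work = 0.0

    def record(i):
        recorded_t.append((step_offset + i) * dt)
        recorded_x.append(x.copy())
        if cv_funcs:
            recorded_cv.append([f(x)[0] for f in cv_funcs])
        if spring is not None:
            work_series.append(work)

    record(0)
    for i in range(steps):
        u = system.potential(x)
        if not np.isfinite(u):
            raise DivergenceError(step_offset + i)
        force = -system.gradient(x)
        if bias is not None and cv_funcs:
            _, fb = _bias_force(x, cv_funcs, bias)
            force = force + fb
        if spring is not None:
            cv_func, k, centers = spring
            s, g = cv_func(x)
            c_old, c_new = centers[i], centers[i + 1]
            work += 0.5 * k * ((s - c_new) ** 2 - (s - c_old) ** 2)
            force = force - k * (s - c_new) * g
        x = x + (dt / friction) * force
        if noise > 0:
            x = x + noise * rng.standard_normal(x.shape)
        if (i + 1) % record_every == 0 or i == steps - 1:
            record(i + 1)
    return x, recorded_t, recorded_x, recorded_cv, work_series


def run_langevin(
    system: ToySystem,
    steps: int,
    seed: int,
    bias: BiasState | None = None,
    cv_funcs: list[CvFunc] | None = None,
    restraint: tuple[CvFunc, float, float] | None = None,
    record_every: int = 1,
) -> LangevinResult:
    """Plain overdamped Langevin run, optionally under a bias or a static
    harmonic restraint ``(cv_func, spring_k, center)``.

    The seed is mandatory; identical (seed, inputs) give a bit-identical
    trajectory. Non-finite energies raise :class:`DivergenceError` with the
    offending step index.
    """
    rng = np.random.default_rng(seed)
    spring = None
    if restraint is not None:
        cv_func, k, center = restraint
        spring = (cv_func, k, np.full(steps + 1, float(center)))
    x, t, xs, cvs, _ = _integrate(
        system, steps, rng, system.x0.copy(), cv_funcs, bias, spring, record_every
    )
    return LangevinResult(
        np.array(t),
        np.array(xs),
        np.array(cvs) if cvs else None,
        x,
    )


def run_steered(
    system: ToySystem,
    cv_func: CvFunc,
    schedule: tuple[float, float, int],
    spring_k: float,
    seed: int,
    record_every: int = 1,
) -> SteeredResult:
    """Steered run: a harmonic restraint whose center moves linearly.

    ``schedule = (start, end, steps)`` moves the restraint center from start
    to end over the run; ``spring_k`` is in kcal/mol per CV-unit². The
    accumulated external work W = Σ_i [U_spring(x_i, c_{i+1}) −
    U_spring(x_i, c_i)] is reported per recorded frame. For a sufficiently
    stiff spring and slow schedule the final CV value tracks the endpoint
    (checked, not guaranteed).
    """
    if spring_k <= 0:
        raise ValueError("spring constant must be positive")
    start, end, steps = schedule
    centers = np.linspace(float(start), float(end), steps + 1)
    rng = np.random.default_rng(seed)
    x, t, xs, cvs, work = _integrate(
        system,
        steps,
        rng,
        system.x0.copy(),
        cv_funcs=[cv_func],
        spring=(cv_func, spring_k, centers),
        record_every=record_every,
    )
    rec_idx = (np.array(t) / system.timestep).round().astype(int)
    return SteeredResult(
        np.array(t),
        np.array(xs),
        np.array(cvs)[:, 0],
        centers[rec_idx],
        np.array(work),
        x,
    )


def run_metadynamics(
    system: ToySystem,
    cv_funcs: list[CvFunc],
    *,
    steps: int,
    walkers: int = 1,
    pace: int = 500,
    h0: float = 0.3,
    sigma: float | Sequence[float] = 0.1,
    bias_factor: float = 10.0,
    seed: int | None = None,
    seeds: Sequence[int] | None = None,
    cv_names: Sequence[str] | None = None,
    x0s: Sequence[np.ndarray] | None = None,
    bias: BiasState | None = None,
    bias_grid: Sequence[Axis] | None = None,
    record_every: int | None = None,
) -> MetadResult:
    """Multiple-walker well-tempered metadynamics with one shared bias.

    ``steps`` is the per-walker step count. Every ``pace`` steps each walker
    deposits a hill of height h0·exp(−V(s)/((γ−1)·k_B·T)) at its current CV
    value; deposits within a round happen in ascending walker id, each walker
    seeing the hills the previous ones just laid down. Per-walker seeds are
    either given explicitly or spawned deterministically from ``seed``.
    """
    if walkers < 1:
        raise ConfigError("walkers must be at least 1")
    if pace < 1:
        raise ConfigError("pace must be at least 1")
    if h0 <= 0:
        raise ConfigError("initial hill height must be positive")
    if not bias_factor > 1:
        raise ConfigError("well-tempered bias factor must exceed 1")
    if seeds is None:
        if seed is None:
            raise ConfigError("provide either seed or per-walker seeds")
        seqs = np.random.SeedSequence(seed).spawn(walkers)
        rngs = [np.random.default_rng(s) for s in seqs]
    else:
        if len(seeds) != walkers:
            raise ConfigError("need one seed per walker")
        rngs = [np.random.default_rng(int(s)) for s in seeds]
    if cv_names is None:
        cv_names = [f"cv{i}" for i in range(len(cv_funcs))]
    if bias is None:
        bias = BiasState(bias_factor, cv_names)
    if bias_grid is not None:
        bias.attach_grid(bias_grid)
    sigma_arr = np.broadcast_to(np.atleast_1d(np.asarray(sigma, dtype=float)),
                                (len(cv_funcs),)).copy()
    if x0s is None:
        states = [system.x0.copy() for _ in range(walkers)]
    else:
        states = [np.asarray(x, dtype=float).copy() for x in x0s]
    if record_every is None:
        record_every = pace
    dt = system.timestep
    wt_denom = (bias.bias_factor - 1.0) * kbt(system.temperature)

    times = [[] for _ in range(walkers)]
    positions = [[] for _ in range(walkers)]
    cv_series = [[] for _ in range(walkers)]
    done = 0
    while done < steps:
        block = min(pace, steps - done)
        for w in range(walkers):
            x, t, xs, cvs, _ = _integrate(
                system,
                block,
                rngs[w],
                states[w],
                cv_funcs=cv_funcs,
                bias=bias,
                record_every=record_every,
                step_offset=done,
            )
            states[w] = x
            # skip the duplicate t=offset sample on continuation blocks
            start = 1 if done > 0 else 0
            times[w].extend(t[start:])
            positions[w].extend(xs[start:])
            cv_series[w].extend(cvs[start:])
        done += block
        if block == pace:
            t_dep = done * dt
            for w in range(walkers):
                s = np.array([f(states[w])[0] for f in cv_funcs])
                v = bias.potential(s)
                height = h0 * np.exp(-v / wt_denom)
                bias.add_hill(Hill(s, sigma_arr, height, t_dep))
    return MetadResult(
        bias,
        [np.array(t) for t in times],
        [np.array(p) for p in positions],
        [np.array(c) for c in cv_series],
    )


def reconstruct_fes(
    bias: BiasState, axes: list[Axis], warn_empty: bool = True
) -> FesGrid:
    """Free-energy surface from the deposited hills.

    F(s) = −(γ/(γ−1))·V_hills(s) on the grid, shifted so min F = 0. As γ→∞
    the prefactor tends to 1 and the standard (non-tempered) estimator −V is
    recovered. Hills are evaluated with 5σ truncation. An empty bias yields an
    all-zero grid with a warning.
    """
    if len(axes) != bias.n_cvs:
        raise ConfigError(
            f"grid has {len(axes)} axes but the bias carries {bias.n_cvs} CVs"
        )
    if not bias.hills:
        if warn_empty:
            warnings.warn("reconstructing from an empty bias: all-zero surface")
        shape = tuple(ax.nbins for ax in axes)
        return FesGrid(list(axes), np.zeros(shape))
    grids = np.meshgrid(*[ax.centers for ax in axes], indexing="ij")
    points = np.stack([g.ravel() for g in grids], axis=-1)
    v = bias.potential_batch(points).reshape(grids[0].shape)
    gamma = bias.bias_factor
    f = -(gamma / (gamma - 1.0)) * v
    return FesGrid(list(axes), f - f.min())
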