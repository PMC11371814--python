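"""Free-energy-surface post-processing and the combined energy ledger.

Everything that happens after sampling: marginalizing a 2D potential of mean
force down to one coordinate (log-sum-exp Boltzmann integration), locating
metastable states and the barriers between them, monitoring convergence of a
growing bias, leader-style clustering of trajectory frames, concatenating
stage profiles into one overall reaction profile, and converting between
rates and activation barriers with the Eyring transition-state-theory
expression k = (k_B*T/h)·exp(−E_A/k_B*T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import eyring_prefactor, kbt
from .core import Selection, Trajectory
from .cv import superpose_rmsd

__all__ = [
    "Axis",
    "FesGrid",
    "StateSet",
    "Minimum",
    "Barrier",
    "Stage",
    "LedgerResult",
    "Cluster",
    "marginalize_fes",
    "find_states",
    "convergence_profile",
    "cluster_frames",
    "compose_energy_ledger",
    "eyring_convert",
    "rate_to_barrier",
    "barrier_to_rate",
]


@dataclass
class Axis:
    """One named, regularly binned CV axis. Values live at bin midpoints."""

    name: str
    lo: float
    hi: float
    nbins: int
    units: str = ""

    def __post_init__(self):
        if self.nbins < 1:
            raise ValueError("axis needs at least one bin")
        if not self.hi > self.lo:
            raise ValueError(f"axis {self.name!r}: hi must exceed lo")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.nbins

    @property
    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.nbins) + 0.5) * self.width


@dataclass
class FesGrid:
    """Free energy (kcal/mol) on a regular 1D or 2D grid of CV bins."""

    axes: list[Axis]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.axes) not in (1, 2):
            raise ValueError("FesGrid supports 1 or 2 axes")
        expected = tuple(ax.nbins for ax in self.axes)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape}, expected {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite free-energy values")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def normalized(self) -> "FesGrid":
        """Same surface shifted so the minimum is zero."""
        return FesGrid(list(self.axes), self.values - self.values.min())


def marginalize_fes(fes2d: FesGrid, keep_axis: str, T: float = 300.0) -> FesGrid:
    """Integrate one axis of a 2D surface out at temperature ``T``.

    F1(x) = −k_B·T · ln Σ_y exp(−F2(x, y)/k_B·T)·Δy, evaluated with
    log-sum-exp over bin midpoints, then shifted to min 0. Raises on 1D input.
    """
    if fes2d.ndim != 2:
        raise ValueError("marginalize_fes requires a 2D grid")
    if T <= 0:
        raise ValueError("temperature must be positive")
    names = [ax.name for ax in fes2d.axes]
    if keep_axis not in names:
        raise ValueError(f"no axis named {keep_axis!r} (have {names})")
    keep = names.index(keep_axis)
    drop = 1 - keep
    beta = 1.0 / kbt(T)
    log_dy = math.log(fes2d.axes[drop].width)
    log_z = logsumexp(-beta * fes2d.values, axis=drop) + log_dy
    f1 = -log_z / beta
    return FesGrid([fes2d.axes[keep]], f1 - f1.min())


# ---------------------------------------------------------------------------
# state and barrier detection


@dataclass
class Minimum:
    label: str
    position: float
    energy: float


@dataclass
class Barrier:
    from_label: str
    to_label: str
    energy: float
    position: float


@dataclass
class StateSet:
    """Metastable minima and the saddle energies between adjacent ones."""

    minima: list[Minimum]
    barriers: list[Barrier]

    def __post_init__(self):
        by_label = {m.label: m.energy for m in self.minima}
        for b in self.barriers:
            if b.energy < max(by_label[b.from_label], by_label[b.to_label]) - 1e-9:
                raise ValueError(
                    f"barrier {b.from_label}->{b.to_label} below an adjacent minimum"
                )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    padded = np.pad(values.astype(float), half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _local_minima(f: np.ndarray) -> list[int]:
    """Interior local minima; plateaus report their leftmost bin."""
    n = len(f)
    minima = []
    i = 1
    while i < n - 1:
        if f[i] < f[i - 1]:
            j = i
            while j + 1 < n and f[j + 1] == f[i]:
                j += 1
            if j < n - 1 and f[j + 1] > f[i]:
                minima.append(i)
            i = j + 1
        else:
            i += 1
    return minima


def _persistence(f: np.ndarray, i: int) -> float:
    """Depth of basin ``i``: lowest pass to any strictly lower point, − f[i].

    Scans left and right until a value below f[i] appears, tracking the
    running maximum; a side that never drops below f[i] contributes +inf
    (the global minimum therefore has infinite persistence).
    """
    left = -np.inf
    side_left = np.inf
    for j in range(i - 1, -1, -1):
        left = max(left, f[j])
        if f[j] < f[i]:
            side_left = left - f[i]
            break
    right = -np.inf
    side_right = np.inf
    for j in range(i + 1, len(f)):
        right = max(right, f[j])
        if f[j] < f[i]:
            side_right = right - f[i]
            break
    return min(side_left, side_right)


def find_states(
    fes1d: FesGrid, min_depth: float, smooth_window: int = 3
) -> StateSet:
    """Locate metastable minima of a 1D profile and the barriers between them.

    The profile is smoothed with a moving average (``smooth_window`` bins,
    1 disables), interior local minima are pruned when their basin depth
    (persistence) falls below ``min_depth``, and the barrier between adjacent
    surviving minima is the maximum of the smoothed profile on the connecting
    interval (argmax ties broken toward the lower CV value). A monotone
    profile yields an empty state set.
    """
    if fes1d.ndim != 1:
        raise ValueError("find_states requires a 1D grid")
    f = _smooth(fes1d.values, smooth_window)
    centers = fes1d.axes[0].centers
    kept = [i for i in _local_minima(f) if _persistence(f, i) >= min_depth]
    labels = [f"S{k}" for k in range(len(kept))]
    minima = [Minimum(lbl, float(centers[i]), float(f[i])) for lbl, i in zip(labels, kept)]
    barriers = []
    for k in range(len(kept) - 1):
        lo, hi = kept[k], kept[k + 1]
        seg = f[lo : hi + 1]
        j = int(np.argmax(seg)) + lo  # np.argmax returns the first (lower-CV) tie
        barriers.append(
            Barrier(labels[k], labels[k + 1], float(f[j]), float(centers[j]))
        )
    return StateSet(minima, barriers)


def convergence_profile(
    bias,
    axes: list[Axis],
    checkpoints,
    threshold: float = 10.0,
) -> np.ndarray:
    """RMS deviation of the running FES estimate from the final one.

    For each checkpoint time t, the surface is reconstructed from hills
    deposited up to t and compared (RMS, kcal/mol) with the final surface over
    the region where the final free energy is at most ``threshold``. The
    series is non-negative and ends at exactly 0.
    """
    from .sampling import reconstruct_fes  # local import to avoid a cycle

    final = reconstruct_fes(bias, axes)
    region = final.values <= threshold
    if not region.any():
        raise ValueError("threshold excludes every grid bin")
    out = []
    for t in checkpoints:
        sub = bias.truncated(t)
        part = reconstruct_fes(sub, axes, warn_empty=False)
        out.append(float(np.sqrt(np.mean((part.values[region] - final.values[region]) ** 2))))
    return np.array(out)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class Cluster:
    centroid: int
    members: list[int]


def cluster_frames(traj: Trajectory, sel: Selection, cutoff: float) -> list[Cluster]:
    """Leader-style (GROMOS) clustering on pairwise superposed RMSD.

    Iteratively takes the frame with the most neighbours within ``cutoff``
    (nm) as a cluster centroid, removes the cluster, and repeats; ties are
    broken toward the earliest frame. Empty trajectories give an empty list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = traj.n_frames
    if n == 0:
        return []
    within = np.zeros((n, n), dtype=bool)
    for i in range(n):
        within[i, i] = True
        for j in range(i + 1, n):
            _, _, r = superpose_rmsd(traj.coords[j], traj.coords[i], sel)
            within[i, j] = within[j, i] = r <= cutoff
    alive = np.ones(n, dtype=bool)
    clusters = []
    while alive.any():
        counts = (within & alive).sum(axis=1)
        counts[~alive] = -1
        centroid = int(np.argmax(counts))  # first maximum = earliest frame
        members = np.nonzero(within[centroid] & alive)[0]
        clusters.append(Cluster(centroid, members.tolist()))
        alive[members] = False
    return clusters


# ---------------------------------------------------------------------------
# energy ledger


@dataclass
class Stage:
    """One reaction stage: either a full 1D profile or a (ΔG‡, ΔG) summary.

    ``barrier`` is the stage's activation free energy relative to its own
    reactant; ``delta_g`` the stage reaction free energy. Alternatively a 1D
    :class:`FesGrid` profile may be supplied, whose first/last bins define the
    reactant/product levels.
    """

    name: str
    barrier: float | None = None
    delta_g: float | None = None
    profile: FesGrid | None = None

    def __post_init__(self):
        if self.profile is not None:
            if self.profile.ndim != 1:
                raise ValueError("stage profiles must be 1D")
            f = self.profile.values
            self.barrier = float(f.max() - f[0])
            self.delta_g = float(f[-1] - f[0])
        if self.barrier is None or self.delta_g is None:
            raise ValueError(f"stage {self.name!r} needs (barrier, delta_g) or a profile")

    def node_energies(self) -> np.ndarray:
        """Stage profile relative to its own reactant level."""
        if self.profile is not None:
            return self.profile.values - self.profile.values[0]
        return np.array([0.0, self.barrier, self.delta_g])


@dataclass
class LedgerResult:
    """A composed multi-stage reaction profile, anchored at the first reactant.

    ``stage_levels[k]`` is the reactant level of stage k; ``nodes`` the full
    composed profile as (stage name, energy) pairs; ``per_stage_barriers`` each
    stage's peak measured from the global reactant.
    """

    stages: list[Stage]
    stage_levels: list[float]
    nodes: list[tuple[str, float]]
    overall_barrier: float
    overall_delta_g: float
    per_stage_barriers: list[float] = field(default_factory=list)


def compose_energy_ledger(stages: list[Stage]) -> LedgerResult:
    """Concatenate stage profiles into one overall reaction profile.

    Each stage's reactant level is anchored at the previous stage's product
    level. The overall barrier is the maximum of the composed profile minus
    the first reactant level; the overall ΔG is the final level minus the
    first reactant level. Appending a (0, 0) identity stage changes nothing.
    """
    if not stages:
        raise ValueError("need at least one stage")
    level = 0.0
    levels, nodes, per_stage = [], [], []
    for st in stages:
        levels.append(level)
        energies = st.node_energies() + level
        nodes.extend((st.name, float(e)) for e in energies)
        per_stage.append(float(energies.max()))
        level += st.delta_g
    peak = max(e for _, e in nodes)
    return LedgerResult(
        stages=list(stages),
        stage_levels=levels,
        nodes=nodes,
        overall_barrier=float(peak),
        overall_delta_g=float(level),
        per_stage_barriers=per_stage,
    )


# ---------------------------------------------------------------------------
# transition-state theory


def rate_to_barrier(rate: float, T: float = 300.0) -> float:
    """Activation barrier (kcal/mol) from a first-order rate (1/s), Eyring TST.

    E_A = k_B·T · ln((k_B·T/h) / k), transmission coefficient 1.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return kbt(T) * math.log(eyring_prefactor(T) / rate)


def barrier_to_rate(barrier: float, T: float = 300.0) -> float:
    """First-order rate (1/s) from an activation barrier (kcal/mol), Eyring TST."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return eyring_prefactor(T) * math.exp(-barrier / kbt(T))


def eyring_convert(direction: str, value: float, T: float = 300.0) -> float:
    """Dispatch between ``"rate_to_barrier"`` and ``"barrier_to_rate"``."""
    if direction == "rate_to_barrier":
        return rate_to_barrier(value, T)
    if direction == "barrier_to_rate":
        return barrier_to_rate(value, T)
    raise ValueError(f"unknown direction {direction!r}")
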