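"""Synthetic inputs with known ground truth.

Every input class the pipeline consumes can be generated here offline:

- analytic 1D/2D energy landscapes whose free-energy surface is known in
  closed form (or by high-precision quadrature for coupled 2D forms),
- two-domain bead models with distinct inactive/active reference
  conformations differing by a recorded domain rotation and COM shift —
  defaults emulate the geometry of a sensor-kinase activation (57° rotation,
  COM distance 2.55 → 1.92 nm),
- trajectories with prescribed per-residue-pair contact probabilities,
- a toy group-transfer reaction center (P, bridging O, acceptor N, and a
  divalent cation with an octahedral oxygen shell),
- ideal peptide backbones built from prescribed (φ, ψ) torsions.

All generators are seed-deterministic and return their truth metadata next to
the data. Bead models are Cα-only pseudo-residues (ALA) with synthetic chain
ids, valid for the package's PDB-subset writer, so the whole pipeline can run
on files. Interpolated transition frames are linear in Cartesian coordinates
(no internal-coordinate morphing) — sufficient for CV and geometry testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import kbt
from .core import ReferencePair, Selection, Structure, Trajectory, select_atoms
from .fes import Axis, FesGrid
from .sampling import ToySystem

__all__ = [
    "LandscapeSpec",
    "LandscapeResult",
    "TwoDomainSpec",
    "TwoDomainResult",
    "ContactTrajectoryResult",
    "ReactionCenterGeometry",
    "gen_landscape",
    "gen_two_domain",
    "gen_contact_trajectory",
    "gen_reaction_center",
    "gen_peptide_backbone",
]


# ---------------------------------------------------------------------------
# analytic landscapes


@dataclass
class LandscapeSpec:
    """An analytic toy landscape with exactly known free-energy surface.

    Forms: ``double_well_1d`` U(x) = barrier·((x/a)² − 1)²;
    ``two_basin_asym`` adds a linear tilt; ``double_well_2d`` adds a harmonic
    y-mode 0.5·k_y·y² and a bilinear coupling·x·y term (coupling ≠ 0 makes the
    marginals non-trivial). Energies kcal/mol, positions in CV units.
    """

    form: str = "double_well_1d"
    barrier: float = 3.0
    well_position: float = 1.0
    tilt: float = 0.0
    k_y: float = 2.0
    coupling: float = 0.0
    temperature: float = 300.0
    grid_halfwidth: float = 2.0
    nbins: int = 200

    def __post_init__(self):
        if self.form not in ("double_well_1d", "double_well_2d", "two_basin_asym"):
            raise ValueError(f"unknown landscape form {self.form!r}")
        if self.barrier <= 0 or self.well_position <= 0:
            raise ValueError("barrier and well position must be positive")
        if self.form == "double_well_2d" and self.k_y <= 0:
            raise ValueError("k_y must be positive")


@dataclass
class LandscapeResult:
    """Toy system plus its exact reference FES (joint and marginals for 2D)."""

    system: ToySystem
    fes: FesGrid
    marginal_x: FesGrid | None
    marginal_y: FesGrid | None
    spec: LandscapeSpec


def _dw(x, barrier, a, tilt=0.0):
    return barrier * ((x / a) ** 2 - 1.0) ** 2 + tilt * x


def _dw_grad(x, barrier, a, tilt=0.0):
    return 4.0 * barrier * x * ((x / a) ** 2 - 1.0) / a**2 + tilt


def _gauss_legendre_marginal(u_xy, x_vals, y_lo, y_hi, T, panels=100, order=100):
    """−k_B·T · ln ∫ exp(−U(x, y)/k_B·T) dy by composite Gauss–Legendre."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(y_lo, y_hi, panels + 1)
    beta = 1.0 / kbt(T)
    out = np.empty(len(x_vals))
    for i, x in enumerate(x_vals):
        total = 0.0
        for k in range(panels):
            mid = 0.5 * (edges[k] + edges[k + 1])
            half = 0.5 * (edges[k + 1] - edges[k])
            y = mid + half * nodes
            total += half * np.sum(weights * np.exp(-beta * u_xy(x, y)))
        out[i] = -math.log(total) / beta
    return out


def gen_landscape(spec: LandscapeSpec) -> LandscapeResult:
    """Build the toy system and its exact reference free-energy surface.

    For 1D forms the FES equals the potential (min-shifted). For the 2D form
    both marginals over the grid domain are computed by high-order composite
    Gauss–Legendre quadrature (10⁴ nodes — machine precision for these smooth
    integrands), so the reference marginals use the same finite CV domain as
    any sampled estimate they are compared with.
    """
    a = spec.well_position
    b = spec.barrier
    x_axis = Axis("x", -spec.grid_halfwidth, spec.grid_halfwidth, spec.nbins, "cv")
    if spec.form in ("double_well_1d", "two_basin_asym"):
        tilt = spec.tilt if spec.form == "two_basin_asym" else 0.0

        def pot(x):
            return float(_dw(x[0], b, a, tilt))

        def grad(x):
            return np.array([_dw_grad(x[0], b, a, tilt)])

        system = ToySystem(pot, grad, np.array([-a]), spec.temperature)
        f = _dw(x_axis.centers, b, a, tilt)
        return LandscapeResult(system, FesGrid([x_axis], f - f.min()), None, None, spec)

    ky, c = spec.k_y, spec.coupling
    y_axis = Axis("y", -spec.grid_halfwidth, spec.grid_halfwidth, spec.nbins, "cv")

    def pot2(x):
        return float(_dw(x[0], b, a) + 0.5 * ky * x[1] ** 2 + c * x[0] * x[1])

    def grad2(x):
        return np.array(
            [_dw_grad(x[0], b, a) + c * x[1], ky * x[1] + c * x[0]]
        )

    system = ToySystem(pot2, grad2, np.array([-a, 0.0]), spec.temperature)
    xg, yg = np.meshgrid(x_axis.centers, y_axis.centers, indexing="ij")
    joint = _dw(xg, b, a) + 0.5 * ky * yg**2 + c * xg * yg
    fes = FesGrid([x_axis, y_axis], joint - joint.min())
    # marginals over the grid domain by high-order composite quadrature
    # (machine-precision for these smooth integrands)
    fx = _gauss_legendre_marginal(
        lambda x, y: _dw(x, b, a) + 0.5 * ky * y**2 + c * x * y,
        x_axis.centers,
        y_axis.lo,
        y_axis.hi,
        spec.temperature,
    )
    marginal_x = FesGrid([x_axis], fx - fx.min())
    fy = _gauss_legendre_marginal(
        lambda y, x: _dw(x, b, a) + 0.5 * ky * y**2 + c * x * y,
        y_axis.centers,
        x_axis.lo,
        x_axis.hi,
        spec.temperature,
    )
    marginal_y = FesGrid([y_axis], fy - fy.min())
    return LandscapeResult(system, fes, marginal_x, marginal_y, spec)


# ---------------------------------------------------------------------------
# two-domain bead models


@dataclass
class TwoDomainSpec:
    """A two-domain bead model with a known inactive→active transformation.

    The active conformation rotates the mobile domain by
    ``rotation_angle_deg`` about a recorded axis through its COM and moves its
    COM ``com_shift`` nm toward the fixed domain (defaults emulate a 57°
    domain rotation with the inter-domain COM distance closing 2.55→1.92 nm).
    ``jitter`` adds per-frame Gaussian coordinate noise to the interpolated
    transition trajectory.
    """

    beads_per_domain: int = 30
    linker_beads: int = 4
    rotation_angle_deg: float = 57.0
    com_separation: float = 2.55
    com_shift: float = 0.63
    domain_radius: float = 0.35
    jitter: float = 0.0
    n_frames: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rotation_angle_deg <= 180.0:
            raise ValueError("rotation angle must lie in [0, 180] degrees")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.beads_per_domain < 4:
            raise ValueError("need at least 4 beads per domain")


@dataclass
class TwoDomainResult:
    pair: ReferencePair
    fixed_sel: Selection
    mobile_sel: Selection
    rotation_axis: np.ndarray
    trajectory: Trajectory | None
    spec: TwoDomainSpec


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def _bead_structure(coords: np.ndarray, chains, resids) -> Structure:
    n = len(coords)
    return Structure(
        atom_names=["CA"] * n,
        residue_names=["ALA"] * n,
        residue_indices=resids,
        chain_ids=chains,
        elements=["C"] * n,
        coords=coords,
    )


def gen_two_domain(spec: TwoDomainSpec) -> TwoDomainResult:
    """Generate the endpoint pair (and optional transition trajectory)."""
    rng = np.random.default_rng(spec.seed)
    nb = spec.beads_per_domain
    fixed = rng.normal(scale=spec.domain_radius, size=(nb, 3))
    fixed -= fixed.mean(axis=0)
    mobile = rng.normal(scale=spec.domain_radius, size=(nb, 3))
    mobile -= mobile.mean(axis=0)
    mobile_inactive = mobile + np.array([spec.com_separation, 0.0, 0.0])

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = _rotation_matrix(axis, math.radians(spec.rotation_angle_deg))
    com = mobile_inactive.mean(axis=0)
    shift_dir = -com / np.linalg.norm(com)  # toward the fixed domain at the origin
    mobile_active = (mobile_inactive - com) @ rot.T + com + spec.com_shift * shift_dir

    def linker(mob_coords):
        if spec.linker_beads == 0:
            return np.zeros((0, 3))
        frac = np.linspace(0, 1, spec.linker_beads + 2)[1:-1]
        return frac[:, None] * mob_coords.mean(axis=0)[None, :]

    chains = ["A"] * nb + ["A"] * spec.linker_beads + ["B"] * nb
    resids = list(range(1, nb + spec.linker_beads + 1)) + list(range(1, nb + 1))
    inactive = _bead_structure(
        np.vstack([fixed, linker(mobile_inactive), mobile_inactive]), chains, resids
    )
    active = _bead_structure(
        np.vstack([fixed, linker(mobile_active), mobile_active]), chains, resids
    )
    fixed_sel = select_atoms(inactive, f"chain A and resid 1-{nb}")
    mobile_sel = select_atoms(inactive, "chain B")
    pair = ReferencePair(inactive, active)

    trajectory = None
    if spec.n_frames > 0:
        lam = (
            np.linspace(0.0, 1.0, spec.n_frames)
            if spec.n_frames > 1
            else np.array([0.0])
        )
        frames = (
            (1 - lam)[:, None, None] * inactive.coords[None]
            + lam[:, None, None] * active.coords[None]
        )
        if spec.jitter > 0:
            frames = frames + rng.normal(scale=spec.jitter, size=frames.shape)
        trajectory = Trajectory(inactive, frames, np.arange(spec.n_frames, dtype=float))
    return TwoDomainResult(pair, fixed_sel, mobile_sel, axis, trajectory, spec)


def elastic_network_system(
    result: TwoDomainResult,
    k: float = 50.0,
    temperature: float = 0.5,
    timestep: float = 0.001,
    friction: float = 1.0,
) -> ToySystem:
    """Intra-domain elastic network for a two-domain bead model.

    Harmonic springs connect every bead pair within the fixed domain and
    within the mobile domain, with equilibrium lengths from the inactive
    conformation. Because each domain moves rigidly between the endpoints,
    the network is at its minimum in both the inactive and the active
    conformation — it preserves domain shape while leaving the inter-domain
    arrangement (and the linker) free, which is exactly what a steered
    difference-of-RMSD pull needs to act against.

    The default temperature is low (0.5 K): along a quasi-static pull the
    rigid-body modes orthogonal to the pulled coordinate are unrestrained, and
    thermal diffusion along them would wander off the minimal-motion path that
    connects the endpoints.
    """
    ref = result.pair.inactive.coords
    pairs = []
    for sel in (result.fixed_sel, result.mobile_sel):
        idx = sel.atom_indices
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = int(idx[a]), int(idx[b])
                pairs.append((i, j, float(np.linalg.norm(ref[i] - ref[j]))))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    d0 = np.array([p[2] for p in pairs])

    def pot(x):
        d = np.linalg.norm(x[ii] - x[jj], axis=1)
        return float(0.5 * k * np.sum((d - d0) ** 2))

    def grad(x):
        diff = x[ii] - x[jj]
        d = np.linalg.norm(diff, axis=1)
        coef = k * (d - d0) / np.maximum(d, 1e-12)
        g = np.zeros_like(x)
        np.add.at(g, ii, coef[:, None] * diff)
        np.add.at(g, jj, -coef[:, None] * diff)
        return g

    return ToySystem(pot, grad, ref.copy(), temperature, friction, timestep)


# ---------------------------------------------------------------------------
# contact trajectories


@dataclass
class ContactTrajectoryResult:
    trajectory: Trajectory
    truth: np.ndarray
    rows: Selection
    cols: Selection


def gen_contact_trajectory(
    pattern: np.ndarray,
    frames: int,
    seed: int,
    contact_distance: float = 0.30,
    far_distance: float = 0.80,
    cell: float = 10.0,
) -> ContactTrajectoryResult:
    """Trajectory whose residue-pair contacts are independent Bernoulli draws.

    ``pattern[i, j]`` is the probability that row residue i (chain A) and col
    residue j (chain B) are in contact in a given frame. Each (i, j) pair owns
    a dedicated atom pair in its own spatial cell (cells ``cell`` nm apart),
    placed ``contact_distance`` apart on a draw of 1 and ``far_distance``
    otherwise, so draws are geometrically independent. Returns the trajectory
    together with the truth probability matrix.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 2:
        raise ValueError("pattern must be a 2D probability matrix")
    if np.any(pattern < 0) or np.any(pattern > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if frames < 1:
        raise ValueError("need at least one frame")
    nr, nc = pattern.shape
    rng = np.random.default_rng(seed)
    # atom (i, j) of a row residue sits at the cell anchor; the matching col
    # atom sits directly above it at the drawn separation
    anchors = np.zeros((nr, nc, 3))
    anchors[..., 0] = np.arange(nr)[:, None] * cell
    anchors[..., 1] = np.arange(nc)[None, :] * cell

    atom_names, resnames, resids, chains, elements = [], [], [], [], []
    for i in range(nr):
        for j in range(nc):
            atom_names.append(f"C{j + 1}")
            resnames.append("ALA")
            resids.append(i + 1)
            chains.append("A")
            elements.append("C")
    for j in range(nc):
        for i in range(nr):
            atom_names.append(f"C{i + 1}")
            resnames.append("ALA")
            resids.append(j + 1)
            chains.append("B")
            elements.append("C")

    draws = rng.random(size=(frames, nr, nc)) < pattern[None, :, :]
    sep = np.where(draws, contact_distance, far_distance)
    coords = np.empty((frames, 2 * nr * nc, 3))
    coords[:, : nr * nc, :] = anchors.reshape(-1, 3)[None]
    # column atoms are stored in (j, i) order: transpose anchors and draws
    coords[:, nr * nc :, :] = anchors.transpose(1, 0, 2).reshape(-1, 3)[None]
    coords[:, nr * nc :, 2] += sep.transpose(0, 2, 1).reshape(frames, nr * nc)
    structure = Structure(atom_names, resnames, resids, chains, elements, coords[0])
    traj = Trajectory(structure, coords, np.arange(frames, dtype=float))
    rows = select_atoms(structure, "chain A")
    cols = select_atoms(structure, "chain B")
    return ContactTrajectoryResult(traj, pattern.copy(), rows, cols)


# ---------------------------------------------------------------------------
# reaction center


@dataclass
class ReactionCenterGeometry:
    name: str
    d_po: float
    d_pn: float


_GEOMETRIES = {
    # transition-state-like distances: P–O 2.17 Å, P–N 2.53 Å; reactant and
    # product swap the short/long bonding pattern
    "reactant": ReactionCenterGeometry("reactant", 0.17, 0.33),
    "ts_like": ReactionCenterGeometry("ts_like", 0.217, 0.253),
    "product": ReactionCenterGeometry("product", 0.33, 0.17),
}

MG_LIGAND_DISTANCE = 0.21


def gen_reaction_center(
    geometry: str, seed: int | None = None, jitter: float = 0.0
) -> Structure:
    """Toy group-transfer reaction center.

    Places the transferring P atom between a donor bridging oxygen and an
    acceptor nitrogen at the distances of the requested geometry, plus a
    divalent cation with six octahedral oxygen ligands at 0.21 nm. With
    ``jitter`` > 0 a seeded Gaussian displacement is added to every atom.
    """
    try:
        geo = _GEOMETRIES[geometry]
    except KeyError:
        raise ValueError(
            f"unknown geometry {geometry!r}; choose from {sorted(_GEOMETRIES)}"
        ) from None
    p = np.array([0.0, 0.0, 0.0])
    o_bridge = np.array([-geo.d_po, 0.0, 0.0])
    n_acc = np.array([geo.d_pn, 0.0, 0.0])
    mg = np.array([0.0, 0.45, 0.0])
    octa = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    ligands = mg + MG_LIGAND_DISTANCE * octa
    coords = np.vstack([p, o_bridge, n_acc, mg, ligands])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    names = ["PG", "O3B", "NE2", "MG"] + ["O"] * 6
    resnames = ["ATP", "ATP", "HIS", "MG"] + ["HOH"] * 6
    resids = [1, 1, 2, 3] + list(range(4, 10))
    chains = ["A"] * 10
    elements = ["P", "O", "N", "MG"] + ["O"] * 6
    return Structure(names, resnames, resids, chains, elements, coords)


# ---------------------------------------------------------------------------
# ideal peptide backbones


_R_N_CA = 0.1458
_R_CA_C = 0.1525
_R_C_N = 0.1329
_ANG_N_CA_C = math.radians(111.2)
_ANG_CA_C_N = math.radians(116.2)
_ANG_C_N_CA = math.radians(121.7)


def _place(a, b, c, r, theta, phi):
    """NeRF atom placement: |cd| = r, angle(b,c,d) = theta, dihedral(a,b,c,d) = phi."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -r * math.cos(theta),
            r * math.cos(phi) * math.sin(theta),
            r * math.sin(phi) * math.sin(theta),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def gen_peptide_backbone(phis, psis, chain: str = "A") -> Structure:
    """Ideal N–CA–C backbone built from prescribed torsions (radians).

    ``phis[i]`` is φ of residue i+1 (the first residue has no φ) and
    ``psis[i]`` is ψ of residue i (the last residue has no ψ); both lists have
    length n_residues − 1. ω is fixed at 180° and bond geometry at standard
    values, so the stated torsions are recovered exactly by
    :func:`metadesk.cv.backbone_dihedrals`.
    """
    phis = list(phis)
    psis = list(psis)
    if len(phis) != len(psis):
        raise ValueError("phis and psis must have equal length (n_residues − 1)")
    n_res = len(phis) + 1
    coords = np.zeros((3 * n_res, 3))
    coords[0] = [0.0, 0.0, 0.0]  # N0
    coords[1] = [_R_N_CA, 0.0, 0.0]  # CA0
    coords[2] = coords[1] + _R_CA_C * np.array(
        [-math.cos(_ANG_N_CA_C), math.sin(_ANG_N_CA_C), 0.0]
    )  # C0
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = _place(n_prev, ca_prev, c_prev, _R_C_N, _ANG_CA_C_N, psis[i - 1])
        ca_i = _place(ca_prev, c_prev, n_i, _R_N_CA, _ANG_C_N_CA, math.pi)
        c_i = _place(c_prev, n_i, ca_i, _R_CA_C, _ANG_N_CA_C, phis[i - 1])
        coords[3 * i : 3 * i + 3] = [n_i, ca_i, c_i]
    names = ["N", "CA", "C"] * n_res
    resids = np.repeat(np.arange(1, n_res + 1), 3)
    return Structure(
        names,
        ["ALA"] * (3 * n_res),
        resids,
        [chain] * (3 * n_res),
        ["N", "C", "C"] * n_res,
        coords,
    )
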