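"""Collective variables: the reaction coordinates and geometric observables.

Implements the coordinates used to describe and bias a two-domain kinase
activation and the subsequent group-transfer chemistry on desk-scale models:

- ``superpose_rmsd`` / ``delta_rmsd``: optimal-superposition RMSD (Kabsch) and
  the difference of RMSDs to two reference endpoint structures (ΔRMSD). The
  sign convention is RMSD-to-inactive minus RMSD-to-active, so the inactive
  basin sits at negative values.
- ``com_torsion``: the dihedral angle of four group centers of mass (the
  inter-domain torsion, "COMTOR"-style coordinate).
- ``antisym_stretch``: d(b,a) − d(b,c), the antisymmetric stretch that tracks
  transfer of a central atom/group between a donor and an acceptor.
- ``coordination_count``: hard-cutoff ligand count around a center (e.g. the
  Mg²⁺ coordination sphere).
- ``backbone_dihedrals``: per-frame φ/ψ series for Ramachandran-style checks.

Differentiable CVs return analytic per-atom gradients (needed by the sampler's
bias forces); the gradient of superposition RMSDs treats the optimal rotation
as locally constant, the standard approximation, validated against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ReferencePair, Selection, Structure, Trajectory, center_of_mass
from .exceptions import CongruenceError, GeometryError

__all__ = [
    "CvSpec",
    "CvValue",
    "superpose_rmsd",
    "delta_rmsd",
    "com_torsion",
    "antisym_stretch",
    "coordination_count",
    "backbone_dihedrals",
    "dihedral",
    "evaluate_cv",
]


# ---------------------------------------------------------------------------
# superposition


def _check_nondegenerate(points: np.ndarray, label: str) -> None:
    if len(points) < 3:
        raise GeometryError(f"{label}: need at least 3 atoms, got {len(points)}")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-10:
        raise GeometryError(f"{label}: selected atoms are collinear")


def superpose_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    sel: Selection | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where ``rotation`` is a proper
    rotation (det = +1) and ``rotation @ x + translation`` maps mobile
    coordinates into the reference frame; ``rmsd`` (nm) is the minimum over
    all rigid transforms (Kabsch, centroid removal, no mass weighting),
    computed over ``sel`` (default: all atoms).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sel is not None:
        mobile = mobile[sel.atom_indices]
        reference = reference[sel.atom_indices]
    if mobile.shape != reference.shape:
        raise CongruenceError(
            f"mobile has shape {mobile.shape}, reference {reference.shape}"
        )
    _check_nondegenerate(mobile, "mobile")
    _check_nondegenerate(reference, "reference")
    mx = mobile.mean(axis=0)
    my = reference.mean(axis=0)
    xc = mobile - mx
    yc = reference - my
    u, _, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    resid = xc @ rot.T - yc
    rmsd = float(np.sqrt((resid**2).sum() / len(mobile)))
    trans = my - rot @ mx
    return rot, trans, rmsd


def _rmsd_and_gradient(
    frame: np.ndarray, reference: np.ndarray, sel: Selection
) -> tuple[float, np.ndarray]:
    """RMSD over ``sel`` plus its gradient w.r.t. the full frame (zeros outside).

    The optimal rotation is treated as locally constant; its first-order
    variation vanishes at the optimum, and the centroid terms cancel because
    superposition residuals sum to zero.
    """
    rot, trans, rmsd = superpose_rmsd(frame, reference, sel)
    idx = sel.atom_indices
    grad = np.zeros_like(frame)
    if rmsd > 1e-12:
        resid = frame[idx] @ rot.T + trans - reference[idx]
        grad[idx] = (resid @ rot) / (len(idx) * rmsd)
    return rmsd, grad


def delta_rmsd(
    frame: np.ndarray, refs: ReferencePair, gradient: bool = False
) -> float | tuple[float, np.ndarray]:
    """Difference of superposition RMSDs to the two endpoint references (nm).

    value = rmsd(frame, inactive) − rmsd(frame, active); negative near the
    inactive endpoint, positive near the active one. Swapping the endpoints
    negates the value exactly.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != refs.inactive.coords.shape:
        raise CongruenceError(
            f"frame shape {frame.shape} does not match the reference atom table "
            f"{refs.inactive.coords.shape}"
        )
    sel = refs.align_selection
    if gradient:
        ri, gi = _rmsd_and_gradient(frame, refs.inactive.coords, sel)
        ra, ga = _rmsd_and_gradient(frame, refs.active.coords, sel)
        return ri - ra, gi - ga
    _, _, ri = superpose_rmsd(frame, refs.inactive.coords, sel)
    _, _, ra = superpose_rmsd(frame, refs.active.coords, sel)
    return ri - ra


# ---------------------------------------------------------------------------
# torsions


def dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle of four points, radians in (−π, π], IUPAC sign convention.

    Accepts arrays with leading batch dimensions (shape (..., 3)); returns a
    scalar or an array of angles accordingly.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    phi = np.arctan2(y, x)
    phi = np.where(phi == -np.pi, np.pi, phi)
    return float(phi) if phi.ndim == 0 else phi


def _dihedral_gradient(p1, p2, p3, p4) -> tuple[np.ndarray, ...]:
    """Analytic gradient of the dihedral w.r.t. the four points."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = n1 @ n1
    n2sq = n2 @ n2
    if n1sq < 1e-24 or n2sq < 1e-24:
        raise GeometryError("dihedral gradient undefined: collinear points")
    g1 = -(nb2 / n1sq) * n1
    g4 = (nb2 / n2sq) * n2
    a = (b1 @ b2) / nb2**2
    b = (b3 @ b2) / nb2**2
    g2 = -(1.0 + a) * g1 + b * g4
    g3 = a * g1 - (1.0 + b) * g4
    return g1, g2, g3, g4


def _group_coms(
    frame: np.ndarray,
    structure: Structure | None,
    groups: list[Selection],
    weighting: str,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """COM of each group plus per-atom weights (fractions summing to one)."""
    coms, weights = [], []
    for sel in groups:
        if len(sel) == 0:
            raise ValueError("COM group selections must be non-empty")
        pts = frame[sel.atom_indices]
        if weighting == "mass":
            if structure is None:
                raise ValueError("mass weighting requires the structure's atom table")
            w = structure.masses[sel.atom_indices]
            w = w / w.sum()
        else:
            w = np.full(len(sel), 1.0 / len(sel))
        coms.append((w[:, None] * pts).sum(axis=0))
        weights.append(w)
    return np.array(coms), weights


def com_torsion(
    frame: np.ndarray,
    groups: list[Selection],
    structure: Structure | None = None,
    weighting: str = "geometric",
    gradient: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Torsion angle COM1–COM2–COM3–COM4 of four atom groups, radians.

    The per-atom gradient distributes each COM-point gradient over the group's
    atoms with the COM weights (uniform by default, mass fractions with
    ``weighting="mass"``).
    """
    frame = np.asarray(frame, dtype=float)
    if len(groups) != 4:
        raise ValueError(f"com_torsion requires exactly 4 groups, got {len(groups)}")
    coms, weights = _group_coms(frame, structure, groups, weighting)
    for k in range(3):
        if np.linalg.norm(coms[k + 1] - coms[k]) < 1e-9:
            raise GeometryError(f"consecutive group centers {k} and {k + 1} coincide")
    phi = dihedral(*coms)
    if not gradient:
        return phi
    point_grads = _dihedral_gradient(*coms)
    grad = np.zeros_like(frame)
    for sel, w, gp in zip(groups, weights, point_grads):
        grad[sel.atom_indices] += w[:, None] * gp
    return phi, grad


# ---------------------------------------------------------------------------
# stretches and coordination


def antisym_stretch(
    frame: np.ndarray, a: int, b: int, c: int, gradient: bool = False
) -> float | tuple[float, np.ndarray]:
    """Antisymmetric stretch |b−a| − |b−c| (nm) with central atom ``b``.

    Grows positive as the central atom migrates toward ``c``; the package's
    group-transfer convention (which endpoint is donor vs acceptor) is fixed
    by argument order at the call site.
    """
    if len({a, b, c}) != 3:
        raise ValueError("antisym_stretch requires three distinct atom indices")
    frame = np.asarray(frame, dtype=float)
    v1 = frame[b] - frame[a]
    v2 = frame[b] - frame[c]
    d1 = np.linalg.norm(v1)
    d2 = np.linalg.norm(v2)
    value = float(d1 - d2)
    if not gradient:
        return value
    grad = np.zeros_like(frame)
    grad[a] = -v1 / d1
    grad[b] = v1 / d1 - v2 / d2
    grad[c] = v2 / d2
    return value, grad


def coordination_count(
    frame: np.ndarray, center: int, candidates: Selection, cutoff: float
) -> tuple[int, np.ndarray]:
    """Hard-cutoff ligand count: candidates with |x − center| ≤ cutoff (nm).

    Returns the count and the identities (atom indices) of the ligands. No
    switching function is applied — counts are integers by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frame = np.asarray(frame, dtype=float)
    idx = candidates.atom_indices
    idx = idx[idx != center]
    if len(idx) == 0:
        return 0, np.array([], dtype=int)
    dists = np.linalg.norm(frame[idx] - frame[center], axis=1)
    ligands = idx[dists <= cutoff]
    return int(len(ligands)), ligands


# ---------------------------------------------------------------------------
# backbone dihedrals


def backbone_dihedrals(
    traj: Trajectory, residues, chain: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (φ, ψ) series over the given residue indices, radians.

    Returns two arrays of shape (n_frames, n_residues). Terminal residues with
    a missing neighbour are reported as NaN (absent), not an error; a residue
    in the range missing one of its own N/CA/C backbone atoms raises an error
    naming the atom.
    """
    structure = traj.structure
    if chain is None:
        chains = set(structure.chain_ids)
        if len(chains) != 1:
            raise ValueError("structure has multiple chains; specify one")
        chain = chains.pop()
    lookup: dict[tuple[int, str], int] = {}
    present: set[int] = set()
    for i in range(structure.n_atoms):
        if structure.chain_ids[i] == chain:
            lookup[(int(structure.residue_indices[i]), structure.atom_names[i])] = i
            present.add(int(structure.residue_indices[i]))

    def _atom(res: int, name: str) -> int:
        try:
            return lookup[(res, name)]
        except KeyError:
            raise CongruenceError(
                f"residue {res} of chain {chain} is missing backbone atom {name}"
            ) from None

    residues = list(residues)
    phi = np.full((traj.n_frames, len(residues)), np.nan)
    psi = np.full((traj.n_frames, len(residues)), np.nan)
    xyz = traj.coords
    for j, r in enumerate(residues):
        if r not in present:
            raise CongruenceError(f"residue {r} absent from chain {chain}")
        n_i = _atom(r, "N")
        ca_i = _atom(r, "CA")
        c_i = _atom(r, "C")
        if (r - 1) in present:
            c_prev = _atom(r - 1, "C")
            phi[:, j] = dihedral(xyz[:, c_prev], xyz[:, n_i], xyz[:, ca_i], xyz[:, c_i])
        if (r + 1) in present:
            n_next = _atom(r + 1, "N")
            psi[:, j] = dihedral(xyz[:, n_i], xyz[:, ca_i], xyz[:, c_i], xyz[:, n_next])
    return phi, psi


# ---------------------------------------------------------------------------
# CV specification objects

_DIFFERENTIABLE = {"rmsd", "delta_rmsd", "com_torsion", "antisym_stretch", "distance"}
_KINDS = _DIFFERENTIABLE | {"coordination"}


@dataclass
class CvSpec:
    """Declarative description of one collective variable.

    kind: one of rmsd / delta_rmsd / com_torsion / antisym_stretch /
    distance / coordination. ``groups`` are atom selections (meaning depends
    on the kind), ``references`` the endpoint pair for (Δ)RMSD kinds,
    ``atoms`` explicit atom indices for stretch (a, b, c) and coordination
    (center,), ``cutoff`` the coordination cutoff in nm.
    """

    kind: str
    name: str = ""
    groups: list[Selection] = field(default_factory=list)
    references: ReferencePair | None = None
    atoms: tuple[int, ...] = ()
    cutoff: float | None = None
    weighting: str = "geometric"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if not self.name:
            self.name = self.kind
        if self.kind in ("rmsd", "delta_rmsd") and self.references is None:
            raise ValueError(f"{self.kind} requires a ReferencePair")
        if self.kind == "com_torsion" and len(self.groups) != 4:
            raise ValueError("com_torsion requires 4 groups")
        if self.kind == "distance" and len(self.groups) != 2:
            raise ValueError("distance requires 2 groups")
        if self.kind == "antisym_stretch" and len(self.atoms) != 3:
            raise ValueError("antisym_stretch requires atoms=(a, b, c)")
        if self.kind == "coordination":
            if len(self.atoms) != 1 or len(self.groups) != 1:
                raise ValueError("coordination requires atoms=(center,) and one group")
            if self.cutoff is None or self.cutoff <= 0:
                raise ValueError("coordination requires a positive cutoff")


@dataclass
class CvValue:
    """A CV evaluation: scalar value plus the per-atom gradient.

    ``gradient`` is None for non-differentiable kinds (coordination counts);
    otherwise an (n_atoms, 3) array, zero outside the CV's groups.
    """

    value: float
    gradient: np.ndarray | None = None


def evaluate_cv(
    spec: CvSpec,
    frame: np.ndarray,
    structure: Structure | None = None,
    gradient: bool = True,
) -> CvValue:
    """Evaluate a :class:`CvSpec` on one coordinate frame (n_atoms, 3)."""
    frame = np.asarray(frame, dtype=float)
    if spec.kind == "delta_rmsd":
        if gradient:
            v, g = delta_rmsd(frame, spec.references, gradient=True)
            return CvValue(v, g)
        return CvValue(delta_rmsd(frame, spec.references))
    if spec.kind == "rmsd":
        sel = spec.groups[0] if spec.groups else spec.references.align_selection
        v, g = _rmsd_and_gradient(frame, spec.references.inactive.coords, sel)
        return CvValue(v, g if gradient else None)
    if spec.kind == "com_torsion":
        if gradient:
            v, g = com_torsion(
                frame, spec.groups, structure, spec.weighting, gradient=True
            )
            return CvValue(v, g)
        return CvValue(com_torsion(frame, spec.groups, structure, spec.weighting))
    if spec.kind == "antisym_stretch":
        a, b, c = spec.atoms
        if gradient:
            v, g = antisym_stretch(frame, a, b, c, gradient=True)
            return CvValue(v, g)
        return CvValue(antisym_stretch(frame, a, b, c))
    if spec.kind == "distance":
        ga, gb = spec.groups
        coms, weights = _group_coms(frame, structure, [ga, gb], spec.weighting)
        diff = coms[0] - coms[1]
        d = float(np.linalg.norm(diff))
        if not gradient:
            return CvValue(d)
        if d < 1e-12:
            raise GeometryError("distance gradient undefined for coincident centers")
        grad = np.zeros_like(frame)
        grad[ga.atom_indices] += weights[0][:, None] * (diff / d)
        grad[gb.atom_indices] -= weights[1][:, None] * (diff / d)
        return CvValue(d, grad)
    if spec.kind == "coordination":
        count, _ = coordination_count(frame, spec.atoms[0], spec.groups[0], spec.cutoff)
        return CvValue(float(count), None)
    raise ValueError(f"unknown CV kind {spec.kind!r}")
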