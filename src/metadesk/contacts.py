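"""Trajectory-ensemble contact statistics and inter-domain geometry.

A contact is any heavy-atom pair between two residues within a cutoff
(0.45 nm by default, the convention used for residue-level contact maps of
two-domain kinases). Maps aggregate per residue with OR semantics over the
atom pairs; differential maps subtract two state maps and are bounded in
[−1, 1]. Salt bridges pair basic side-chain nitrogens with acidic carboxylate
oxygens. ``domain_geometry`` measures the rotation of a mobile domain and the
fixed–mobile center-of-mass distance against a reference endpoint pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from .core import ReferencePair, Selection, Structure, Trajectory, center_of_mass
from .cv import superpose_rmsd
from .exceptions import CongruenceError

__all__ = [
    "ContactMap",
    "DifferentialMap",
    "SaltBridge",
    "contact_frequency",
    "differential_map",
    "salt_bridge_census",
    "domain_geometry",
    "HYDROPHOBIC_RESIDUES",
]

# Hydrophobic/aromatic subset used for reduced contact maps.
HYDROPHOBIC_RESIDUES = ("VAL", "PHE", "ILE", "MET", "LEU", "TYR")

# Side-chain atoms that define a salt bridge.
_BASIC_NITROGENS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
_BASIC_NITROGENS_HIS = {"HIS": ("ND1", "NE2")}
_ACIDIC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class ContactMap:
    """Per-residue contact frequencies over a trajectory.

    ``frequency[i, j]`` is the fraction of frames in which residues
    ``row_residues[i]`` and ``col_residues[j]`` share at least one heavy-atom
    pair within ``cutoff`` (nm). Residue identifiers are (chain, index, name)
    tuples.
    """

    row_residues: list[tuple[str, int, str]]
    col_residues: list[tuple[str, int, str]]
    frequency: np.ndarray
    cutoff: float
    definition: str = "any-heavy-atom"

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.frequency.shape != (len(self.row_residues), len(self.col_residues)):
            raise ValueError("frequency shape does not match residue lists")
        if np.any(self.frequency < 0) or np.any(self.frequency > 1):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class DifferentialMap:
    """Contact-frequency difference final − initial, entries in [−1, 1].

    −1 marks contacts present entirely in the initial state and missing in
    the final one; +1 the reverse.
    """

    row_residues: list[tuple[str, int, str]]
    col_residues: list[tuple[str, int, str]]
    delta: np.ndarray
    cutoff: float
    state_labels: tuple[str, str] = ("initial", "final")

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.delta < -1) or np.any(self.delta > 1):
            raise ValueError("differential entries must lie in [-1, 1]")


def _residue_groups(structure: Structure, sel: Selection):
    """Heavy atoms of a selection grouped by residue, order of first appearance."""
    heavy = structure.is_heavy
    keys = structure.residue_keys()
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i in sel.atom_indices:
        if heavy[i]:
            groups.setdefault(keys[i], []).append(i)
    return list(groups.keys()), [np.array(v) for v in groups.values()]


def contact_frequency(
    traj: Trajectory,
    rows: Selection,
    cols: Selection,
    cutoff: float = 0.45,
    exclude_neighbors: int = 1,
) -> ContactMap:
    """Residue-level contact frequencies between two selections.

    Entry (i, j) is the fraction of frames in which ANY heavy-atom pair
    between residue i (rows) and residue j (cols) lies within ``cutoff`` nm.
    When rows and cols cover the same residue set, the diagonal and sequence
    neighbours up to ``exclude_neighbors`` apart (same chain) are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if traj.n_frames == 0:
        raise ValueError("contact frequencies need at least one frame")
    structure = traj.structure
    row_keys, row_groups = _residue_groups(structure, rows)
    col_keys, col_groups = _residue_groups(structure, cols)
    same_sets = row_keys == col_keys
    counts = np.zeros((len(row_keys), len(col_keys)))
    row_atoms = np.concatenate(row_groups) if row_groups else np.array([], dtype=int)
    col_atoms = np.concatenate(col_groups) if col_groups else np.array([], dtype=int)
    row_of = np.repeat(np.arange(len(row_groups)), [len(g) for g in row_groups])
    col_of = np.repeat(np.arange(len(col_groups)), [len(g) for g in col_groups])
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        close = cdist(xyz[row_atoms], xyz[col_atoms]) <= cutoff
        ri, cj = np.nonzero(close)
        if len(ri):
            pairs = np.unique(np.stack([row_of[ri], col_of[cj]], axis=1), axis=0)
            counts[pairs[:, 0], pairs[:, 1]] += 1
    freq = counts / traj.n_frames
    if same_sets and exclude_neighbors >= 0:
        for i, (ch_i, ri_, _) in enumerate(row_keys):
            for j, (ch_j, rj_, _) in enumerate(col_keys):
                if ch_i == ch_j and abs(ri_ - rj_) <= exclude_neighbors:
                    freq[i, j] = 0.0
    return ContactMap(row_keys, col_keys, freq, cutoff)


def differential_map(initial: ContactMap, final: ContactMap) -> DifferentialMap:
    """Elementwise difference final − initial of two congruent contact maps."""
    if (
        initial.row_residues != final.row_residues
        or initial.col_residues != final.col_residues
        or initial.cutoff != final.cutoff
    ):
        raise CongruenceError("contact maps differ in residue axes or cutoff")
    return DifferentialMap(
        initial.row_residues,
        initial.col_residues,
        final.frequency - initial.frequency,
        initial.cutoff,
    )


@dataclass
class SaltBridge:
    basic: tuple[str, int, str]
    acidic: tuple[str, int, str]
    frequency: float


def salt_bridge_census(
    traj: Trajectory,
    cutoff: float = 0.40,
    min_frequency: float = 0.5,
    include_his: bool = False,
) -> list[SaltBridge]:
    """Basic-N to acidic-O salt-bridge pairs and their frame frequencies.

    A pair is reported when any side-chain nitrogen (Arg NE/NH1/NH2, Lys NZ;
    His ND1/NE2 with ``include_his``) lies within ``cutoff`` nm of a
    carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2) in at least
    ``min_frequency`` of the frames. Sorted by frequency (descending), ties
    lexicographically by residue identifiers.
    """
    structure = traj.structure
    basic_table = dict(_BASIC_NITROGENS)
    if include_his:
        basic_table.update(_BASIC_NITROGENS_HIS)
    keys = structure.residue_keys()
    basic_groups: dict[tuple[str, int, str], list[int]] = {}
    acidic_groups: dict[tuple[str, int, str], list[int]] = {}
    for i, key in enumerate(keys):
        resname = key[2]
        if resname in basic_table and structure.atom_names[i] in basic_table[resname]:
            basic_groups.setdefault(key, []).append(i)
        if resname in _ACIDIC_OXYGENS and structure.atom_names[i] in _ACIDIC_OXYGENS[resname]:
            acidic_groups.setdefault(key, []).append(i)
    bridges = []
    for bkey, batoms in basic_groups.items():
        for akey, aatoms in acidic_groups.items():
            hits = 0
            for f in range(traj.n_frames):
                d = cdist(traj.coords[f][batoms], traj.coords[f][aatoms])
                if d.min() <= cutoff:
                    hits += 1
            freq = hits / traj.n_frames
            if freq >= min_frequency:
                bridges.append(SaltBridge(bkey, akey, freq))
    bridges.sort(key=lambda b: (-b.frequency, b.basic, b.acidic))
    return bridges


def domain_geometry(
    frame: np.ndarray,
    refs: ReferencePair,
    fixed_sel: Selection,
    mobile_sel: Selection,
) -> tuple[float, float]:
    """Mobile-domain rotation angle (degrees) and fixed–mobile COM distance (nm).

    The frame is first superposed onto the inactive reference over the fixed
    domain; the angle is then the axis-angle magnitude of the optimal rotation
    mapping the reference's mobile domain onto the (fixed-frame-aligned)
    mobile domain of the frame. The COM distance is measured in the frame
    itself (superposition-invariant).
    """
    frame = np.asarray(frame, dtype=float)
    ref = refs.inactive
    if frame.shape != ref.coords.shape:
        raise CongruenceError("frame does not match the reference atom table")
    rot0, trans0, _ = superpose_rmsd(frame, ref.coords, fixed_sel)
    aligned = frame @ rot0.T + trans0
    rot1, _, _ = superpose_rmsd(
        ref.coords[mobile_sel.atom_indices], aligned[mobile_sel.atom_indices]
    )
    angle = float(np.degrees(Rotation.from_matrix(rot1).magnitude()))
    com_fixed = center_of_mass(ref, fixed_sel, coords=frame)
    com_mobile = center_of_mass(ref, mobile_sel, coords=frame)
    distance = float(np.linalg.norm(com_fixed - com_mobile))
    return angle, distance
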