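"""Structures, trajectories, atom selections and reference-state pairs.

These are the containers every downstream stage consumes: a :class:`Structure`
holds one conformation (atom table + coordinates in nm), a :class:`Trajectory`
is an ordered stack of frames congruent with one structure, a
:class:`Selection` is an ordered list of 0-based atom indices, and a
:class:`ReferencePair` bundles the two endpoint conformations (e.g. the
inactive and active states of a two-domain sensor kinase) between which
difference-of-RMSD coordinates and domain-geometry observables are defined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CongruenceError, SelectionError

__all__ = [
    "Structure",
    "Trajectory",
    "Selection",
    "ReferencePair",
    "select_atoms",
    "center_of_mass",
    "ELEMENT_MASSES",
]

# Atomic masses (u) for the elements that occur in protein/nucleotide systems
# plus the divalent cations we model. Mass weighting of a selection containing
# an element outside this table is an error rather than a silent default.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "MG": 24.305,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
}


@dataclass
class Structure:
    """One conformation: parallel per-atom arrays plus coordinates in nm.

    Invariants enforced at construction: finite coordinates, congruent array
    lengths, and uniqueness of (chain_id, residue_index, atom_name).
    """

    atom_names: np.ndarray
    residue_names: np.ndarray
    residue_indices: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    occupancies: np.ndarray | None = None
    bfactors: np.ndarray | None = None

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.residue_names = np.asarray(self.residue_names, dtype="U3")
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U1")
        self.elements = np.asarray([e.upper() for e in self.elements], dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        for name, arr in (
            ("residue_names", self.residue_names),
            ("residue_indices", self.residue_indices),
            ("chain_ids", self.chain_ids),
            ("elements", self.elements),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape}, expected ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_ids, self.residue_indices, self.atom_names))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue_index, atom_name) entries")
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        else:
            self.occupancies = np.asarray(self.occupancies, dtype=float)
        if self.bfactors is None:
            self.bfactors = np.zeros(n)
        else:
            self.bfactors = np.asarray(self.bfactors, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def is_heavy(self) -> np.ndarray:
        """Boolean mask: every atom whose element is not hydrogen."""
        return self.elements != "H"

    @property
    def masses(self) -> np.ndarray:
        try:
            return np.array([ELEMENT_MASSES[e] for e in self.elements])
        except KeyError as exc:
            raise ValueError(f"no mass tabulated for element {exc.args[0]!r}") from None

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-atom (chain, residue_index, residue_name) keys."""
        return list(zip(self.chain_ids, self.residue_indices, self.residue_names))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same atom table)."""
        return Structure(
            self.atom_names,
            self.residue_names,
            self.residue_indices,
            self.chain_ids,
            self.elements,
            np.asarray(coords, dtype=float),
            self.occupancies,
            self.bfactors,
        )

    def same_atom_table(self, other: "Structure", indices=None) -> bool:
        idx = slice(None) if indices is None else np.asarray(indices, dtype=int)
        return (
            np.array_equal(self.atom_names[idx], other.atom_names[idx])
            and np.array_equal(self.residue_indices[idx], other.residue_indices[idx])
            and np.array_equal(self.chain_ids[idx], other.chain_ids[idx])
            and np.array_equal(self.residue_names[idx], other.residue_names[idx])
        )


@dataclass
class Selection:
    """Ordered, unique 0-based indices into a structure's atom table."""

    atom_indices: np.ndarray

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        if self.atom_indices.ndim != 1:
            raise ValueError("atom_indices must be one-dimensional")
        if len(np.unique(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("atom indices must be unique")
        if len(self.atom_indices) and self.atom_indices.min() < 0:
            raise ValueError("atom indices must be non-negative")

    def __len__(self) -> int:
        return len(self.atom_indices)

    def validate_bounds(self, n_atoms: int) -> None:
        if len(self.atom_indices) and self.atom_indices.max() >= n_atoms:
            raise ValueError(
                f"selection index {self.atom_indices.max()} out of bounds for {n_atoms} atoms"
            )


@dataclass
class Trajectory:
    """Ordered frames sharing one structure's atom table.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; ``times`` (ps) must be
    strictly increasing.
    """

    structure: Structure
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise CongruenceError(
                f"frames have {self.coords.shape[1]} atoms, structure has "
                f"{self.structure.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class ReferencePair:
    """Inactive/active endpoint structures plus the alignment selection.

    Both structures must present an identical atom table over
    ``align_selection`` (the atoms RMSDs are measured on).
    """

    inactive: Structure
    active: Structure
    align_selection: Selection = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.align_selection is None:
            if self.inactive.n_atoms != self.active.n_atoms:
                raise CongruenceError("endpoint structures differ in atom count")
            self.align_selection = Selection(np.arange(self.inactive.n_atoms))
        self.align_selection.validate_bounds(self.inactive.n_atoms)
        self.align_selection.validate_bounds(self.active.n_atoms)
        idx = self.align_selection.atom_indices
        if not self.inactive.same_atom_table(self.active, idx):
            raise CongruenceError(
                "inactive and active structures disagree on the atom table over "
                "the alignment selection"
            )

    def swapped(self) -> "ReferencePair":
        """The same pair with the roles of the two endpoints exchanged."""
        return ReferencePair(self.active, self.inactive, self.align_selection)


_KEYWORDS = {"chain", "resid", "name", "resname", "heavy", "all"}


def _parse_resid_token(token: str) -> tuple[int, int]:
    m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", token)
    if m is None:
        raise SelectionError(f"malformed residue range token {token!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) is not None else lo
    if hi < lo:
        raise SelectionError(f"empty residue range token {token!r}")
    return lo, hi


def select_atoms(structure: Structure, expression: str) -> Selection:
    """Evaluate a selection expression against a structure.

    The grammar is a conjunction of clauses joined by ``and``:

    - ``chain A [B ...]``: chain identifier in the listed set
    - ``resid 454-610 [5 7-9 ...]``: residue index in the listed ranges
    - ``name CA [CB ...]``: atom name in the listed set
    - ``resname VAL PHE ...``: residue name in the listed set
    - ``heavy``: element is not hydrogen
    - ``all``: every atom

    Returns a deterministic, ascending-index :class:`Selection`; an expression
    matching nothing yields an empty selection (not an error). Malformed input
    raises :class:`SelectionError` naming the offending token.
    """
    if not expression.strip():
        raise SelectionError("empty selection expression")
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in re.split(r"\band\b", expression):
        tokens = clause.split()
        if not tokens:
            raise SelectionError("empty clause (dangling 'and')")
        kw, args = tokens[0], tokens[1:]
        if kw not in _KEYWORDS:
            raise SelectionError(f"unknown selection keyword {kw!r}")
        if kw in ("heavy", "all"):
            if args:
                raise SelectionError(f"keyword {kw!r} takes no arguments, got {args[0]!r}")
            if kw == "heavy":
                mask &= structure.is_heavy
            continue
        if not args:
            raise SelectionError(f"keyword {kw!r} requires at least one argument")
        if kw == "chain":
            mask &= np.isin(structure.chain_ids, args)
        elif kw == "name":
            mask &= np.isin(structure.atom_names, [a.upper() for a in args])
        elif kw == "resname":
            mask &= np.isin(structure.residue_names, [a.upper() for a in args])
        elif kw == "resid":
            sub = np.zeros(structure.n_atoms, dtype=bool)
            for token in args:
                lo, hi = _parse_resid_token(token)
                sub |= (structure.residue_indices >= lo) & (structure.residue_indices <= hi)
            mask &= sub
    return Selection(np.nonzero(mask)[0])


def center_of_mass(
    structure: Structure,
    sel: Selection,
    weighting: str = "geometric",
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Center of a selection, nm.

    ``weighting="geometric"`` (default) is the unweighted centroid;
    ``weighting="mass"`` uses tabulated atomic masses. ``coords`` overrides the
    structure's own coordinates (e.g. a trajectory frame congruent with it).
    """
    if len(sel) == 0:
        raise ValueError("center of an empty selection is undefined")
    sel.validate_bounds(structure.n_atoms)
    xyz = structure.coords if coords is None else np.asarray(coords, dtype=float)
    pts = xyz[sel.atom_indices]
    if weighting == "geometric":
        return pts.mean(axis=0)
    if weighting == "mass":
        w = structure.masses[sel.atom_indices]
        return (w[:, None] * pts).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")
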