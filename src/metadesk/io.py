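"""Readers and writers for every file format the pipeline touches.

All formats are whitespace text with ``#`` headers so runs diff cleanly:

- PDB subset (ATOM/HETATM/TER/END; altlocs and insertion codes are rejected
  with the line number; coordinates are converted Å→nm on read),
- multi-frame trajectories (``frame <t_ps>`` headers, one ``x y z`` line per
  atom, nm),
- HILLS-style bias records (``# FIELDS time <cv...> <sigma_...> height
  biasf``),
- FES grids (``# axis <name> <lo> <hi> <nbins>`` headers + value rows),
- COLVAR-style CV time series,
- contact maps / salt-bridge censuses as labelled tables,
- the structured YAML run configuration (unknown keys rejected).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml

from .constants import ANGSTROM_PER_NM
from .contacts import ContactMap, SaltBridge
from .core import ELEMENT_MASSES, Structure, Trajectory
from .exceptions import ConfigError, FormatError
from .fes import Axis, FesGrid
from .sampling import BiasState, Hill

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_hills",
    "write_hills",
    "read_fes",
    "write_fes",
    "read_colvar",
    "write_colvar",
    "read_contact_map",
    "write_contact_map",
    "write_salt_bridges",
    "read_config",
    "write_config",
]

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_TWO_LETTER_ELEMENTS = {"MG", "NA", "CL", "FE", "ZN", "MN"}


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped.upper() in _TWO_LETTER_ELEMENTS:
        return stripped.upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_pdb(path) -> Structure:
    """Parse a PDB-subset file into a :class:`Structure` (coordinates in nm).

    Only ATOM/HETATM records carry data; TER/END are accepted and other
    records skipped. Altloc or insertion-code fields raise a
    :class:`FormatError` naming the line.
    """
    names, resnames, resids, chains, elements = [], [], [], [], []
    occs, bfs, coords = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FormatError(f"line {lineno}: truncated {rec} record")
            if line[16] not in (" ", ""):
                raise FormatError(
                    f"line {lineno}: alternate locations are not supported "
                    f"(altloc {line[16]!r})"
                )
            if line[26] not in (" ", ""):
                raise FormatError(
                    f"line {lineno}: insertion codes are not supported "
                    f"(icode {line[26]!r})"
                )
            try:
                names.append(line[12:16].strip())
                resnames.append(line[17:20].strip())
                chains.append(line[21])
                resids.append(int(line[22:26]))
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            occs.append(float(line[54:60]) if line[54:60].strip() else 1.0)
            bfs.append(float(line[60:66]) if line[60:66].strip() else 0.0)
            element = line[76:78].strip() if len(line) >= 78 else ""
            elements.append(element.upper() if element else _infer_element(names[-1]))
    if not names:
        raise FormatError("no ATOM/HETATM records found")
    return Structure(
        names,
        resnames,
        resids,
        chains,
        elements,
        np.asarray(coords) / ANGSTROM_PER_NM,
        occs,
        bfs,
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a :class:`Structure` as a PDB-subset file (coordinates in Å)."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            rec = "ATOM" if structure.residue_names[i] in _STANDARD_RESIDUES else "HETATM"
            name = structure.atom_names[i]
            name_field = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = structure.coords[i] * ANGSTROM_PER_NM
            fh.write(
                f"{rec:<6s}{i + 1:>5d} {name_field:<4s} {structure.residue_names[i]:<3s} "
                f"{structure.chain_ids[i]}{structure.residue_indices[i]:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{structure.occupancies[i]:6.2f}"
                f"{structure.bfactors[i]:6.2f}          {structure.elements[i]:>2s}\n"
            )
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# metadesk trajectory natoms={traj.structure.n_atoms}\n")
        for f in range(traj.n_frames):
            fh.write(f"frame {traj.times[f]:.10g}\n")
            for x, y, z in traj.coords[f]:
                fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")


def read_trajectory(path, structure: Structure) -> Trajectory:
    """Read a multi-frame text trajectory congruent with ``structure``."""
    frames, times, current = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("frame"):
                if current:
                    frames.append(current)
                    current = []
                try:
                    times.append(float(line.split()[1]))
                except (IndexError, ValueError):
                    raise FormatError(f"line {lineno}: malformed frame header") from None
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(
                        f"line {lineno}: expected 3 coordinates, got {len(parts)}"
                    )
                try:
                    current.append([float(p) for p in parts])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from None
    if current:
        frames.append(current)
    if not frames:
        raise FormatError("no frames found")
    for k, fr in enumerate(frames):
        if len(fr) != structure.n_atoms:
            raise FormatError(
                f"frame {k} has {len(fr)} atoms, structure has {structure.n_atoms}"
            )
    return Trajectory(structure, np.asarray(frames, dtype=float), np.asarray(times))


# ---------------------------------------------------------------------------
# HILLS-style bias records


def write_hills(bias: BiasState, path) -> None:
    names = bias.cv_names
    with open(path, "w") as fh:
        fields = ["time", *names, *[f"sigma_{n}" for n in names], "height", "biasf"]
        fh.write("# FIELDS " + " ".join(fields) + "\n")
        fh.write(f"# SET biasf {bias.bias_factor:.17g}\n")
        for h in bias.hills:
            row = [h.deposit_time, *h.center, *h.sigma, h.height, bias.bias_factor]
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_hills(path) -> BiasState:
    """Read a HILLS-style file back into a :class:`BiasState` (lossless)."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("# FIELDS"):
        raise FormatError("line 1: missing '# FIELDS' header")
    fields = lines[0].split()[2:]
    if fields[0] != "time" or fields[-2:] != ["height", "biasf"]:
        raise FormatError("line 1: header must be 'time <cv...> <sigma...> height biasf'")
    body = fields[1:-2]
    if len(body) % 2 != 0:
        raise FormatError("line 1: unpaired CV/sigma columns")
    k = len(body) // 2
    names = body[:k]
    if body[k:] != [f"sigma_{n}" for n in names]:
        raise FormatError("line 1: sigma columns do not match CV names")
    bias_factor = None
    hills = []
    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if stripped.startswith("# SET biasf"):
            bias_factor = float(stripped.split()[-1])
            continue
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != len(fields):
            raise FormatError(
                f"line {lineno}: expected {len(fields)} columns, got {len(parts)}"
            )
        vals = [float(p) for p in parts]
        row_gamma = vals[-1]
        if bias_factor is None:
            bias_factor = row_gamma
        elif abs(row_gamma - bias_factor) > 1e-12 * max(1.0, abs(bias_factor)):
            raise FormatError(f"line {lineno}: inconsistent bias factor")
        hills.append(Hill(np.array(vals[1 : 1 + k]), np.array(vals[1 + k : 1 + 2 * k]),
                          vals[-2], vals[0]))
    if bias_factor is None:
        raise FormatError("no '# SET biasf' line and no hill rows: bias factor unknown")
    return BiasState(bias_factor, names, hills)


# ---------------------------------------------------------------------------
# FES grids


def write_fes(grid: FesGrid, path) -> None:
    with open(path, "w") as fh:
        for ax in grid.axes:
            fh.write(f"# axis {ax.name} {ax.lo:.17g} {ax.hi:.17g} {ax.nbins} {ax.units}\n")
        if grid.ndim == 1:
            for v in grid.values:
                fh.write(f"{v:.17g}\n")
        else:
            for row in grid.values:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_fes(path) -> FesGrid:
    axes, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("# axis"):
                parts = stripped.split()
                if len(parts) < 6:
                    raise FormatError(f"line {lineno}: malformed axis header")
                units = parts[6] if len(parts) > 6 else ""
                axes.append(Axis(parts[2], float(parts[3]), float(parts[4]),
                                 int(parts[5]), units))
            elif stripped and not stripped.startswith("#"):
                try:
                    rows.append([float(p) for p in stripped.split()])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from None
    if not axes:
        raise FormatError("no axis headers found")
    values = np.array(rows)
    if len(axes) == 1:
        values = values.reshape(-1)
    return FesGrid(axes, values)


# ---------------------------------------------------------------------------
# COLVAR-style CV series


def write_colvar(path, times, names, values) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(times):
        values = values.T
    with open(path, "w") as fh:
        fh.write("# FIELDS time " + " ".join(names) + "\n")
        for t, row in zip(times, values):
            fh.write(f"{t:.10g} " + " ".join(f"{v:.10g}" for v in row) + "\n")


def read_colvar(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("# FIELDS time"):
        raise FormatError("line 1: missing '# FIELDS time' header")
    names = lines[0].split()[3:]
    data = []
    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != len(names) + 1:
            raise FormatError(f"line {lineno}: expected {len(names) + 1} columns")
        data.append([float(p) for p in parts])
    arr = np.array(data)
    return arr[:, 0], names, arr[:, 1:]


# ---------------------------------------------------------------------------
# contact maps and censuses


def _residue_label(key) -> str:
    chain, resid, resname = key
    return f"{chain}:{resid}:{resname}"


def _parse_residue_label(label: str):
    chain, resid, resname = label.split(":")
    return (chain, int(resid), resname)


def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# contact map cutoff={cmap.cutoff:.10g} definition={cmap.definition}\n")
        fh.write("# cols " + " ".join(_residue_label(k) for k in cmap.col_residues) + "\n")
        for key, row in zip(cmap.row_residues, cmap.frequency):
            fh.write(_residue_label(key) + " " + " ".join(f"{v:.10g}" for v in row) + "\n")


def read_contact_map(path) -> ContactMap:
    cutoff, definition, cols = None, "any-heavy-atom", None
    rows, freq = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("# contact map"):
                for token in stripped.split()[3:]:
                    key, _, val = token.partition("=")
                    if key == "cutoff":
                        cutoff = float(val)
                    elif key == "definition":
                        definition = val
            elif stripped.startswith("# cols"):
                cols = [_parse_residue_label(t) for t in stripped.split()[2:]]
            elif stripped and not stripped.startswith("#"):
                parts = stripped.split()
                rows.append(_parse_residue_label(parts[0]))
                freq.append([float(p) for p in parts[1:]])
    if cutoff is None or cols is None:
        raise FormatError("missing contact-map headers")
    return ContactMap(rows, cols, np.array(freq), cutoff, definition)


def write_salt_bridges(bridges: list[SaltBridge], path_or_handle) -> None:
    fh = path_or_handle if isinstance(path_or_handle, _io.TextIOBase) else open(
        path_or_handle, "w"
    )
    try:
        fh.write("# basic acidic frequency\n")
        for b in bridges:
            fh.write(
                f"{_residue_label(b.basic)} {_residue_label(b.acidic)} {b.frequency:.6g}\n"
            )
    finally:
        if fh is not path_or_handle:
            fh.close()


# ---------------------------------------------------------------------------
# CvSpec <-> config mappings


def cvspec_to_dict(spec) -> dict:
    """Serialize a :class:`metadesk.cv.CvSpec` into a config mapping."""
    out = {"kind": spec.kind, "name": spec.name}
    if spec.groups:
        out["groups"] = [[int(i) for i in g.atom_indices] for g in spec.groups]
    if spec.atoms:
        out["atoms"] = [int(a) for a in spec.atoms]
    if spec.cutoff is not None:
        out["cutoff"] = float(spec.cutoff)
    if spec.weighting != "geometric":
        out["weighting"] = spec.weighting
    return out


def cvspec_from_dict(entry: dict, structure=None, references=None):
    """Build a :class:`metadesk.cv.CvSpec` from a config mapping.

    Groups may be given either as explicit index lists or as selection
    expressions (requires ``structure``); (Δ)RMSD kinds take their endpoint
    pair from ``references``.
    """
    from .core import Selection, select_atoms
    from .cv import CvSpec

    known = {"kind", "name", "groups", "atoms", "cutoff", "weighting"}
    unknown = set(entry) - known
    if unknown:
        raise ConfigError(f"unknown CV keys: {sorted(unknown)}")
    groups = []
    for g in entry.get("groups", []):
        if isinstance(g, str):
            if structure is None:
                raise ConfigError("selection-expression groups require a structure")
            groups.append(select_atoms(structure, g))
        else:
            groups.append(Selection(np.asarray(g, dtype=int)))
    return CvSpec(
        kind=entry["kind"],
        name=entry.get("name", ""),
        groups=groups,
        references=references,
        atoms=tuple(entry.get("atoms", ())),
        cutoff=entry.get("cutoff"),
        weighting=entry.get("weighting", "geometric"),
    )


# ---------------------------------------------------------------------------
# run configuration

_TOP_KEYS = {"system", "cv", "sampling", "analysis", "output"}


def read_config(path) -> dict:
    """Load a structured run configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return cfg


def write_config(cfg: dict, path) -> None:
    """Emit a resolved-config copy for provenance (recorded seeds included)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
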