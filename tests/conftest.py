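import numpy as np
import pytest

from metadesk.core import Structure


def make_structure(rows, coords):
    """Build a Structure from (name, resname, resid, chain, element) rows."""
    names, resnames, resids, chains, elements = zip(*rows)
    return Structure(names, resnames, resids, chains, elements, np.asarray(coords, dtype=float))


@pytest.fixture
def two_chain_structure():
    """Two chains of Cα-traced residues 454-460 plus a few full residues.

    Chain A residues 454-460 (CA only, mixed residue names including the
    hydrophobic set), chain B the same indices, plus one residue with
    hydrogens to exercise heavy-atom filtering.
    """
    rows, coords = [], []
    resnames = ["VAL", "PHE", "ILE", "MET", "LEU", "TYR", "GLY"]
    k = 0
    for chain in "AB":
        for i, resid in enumerate(range(454, 461)):
            rows.append(("CA", resnames[i], resid, chain, "C"))
            coords.append([0.1 * k, 0.0, 0.0])
            k += 1
    # residue with a hydrogen and a sidechain atom (chain A resid 461)
    rows.append(("CA", "ALA", 461, "A", "C"))
    coords.append([0.1 * k, 0.0, 0.0])
    rows.append(("HA", "ALA", 461, "A", "H"))
    coords.append([0.1 * k, 0.1, 0.0])
    rows.append(("CB", "ALA", 461, "A", "C"))
    coords.append([0.1 * k, 0.2, 0.0])
    return make_structure(rows, coords)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
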