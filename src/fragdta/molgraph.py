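"""Molecular graphs for the drug graph-convolution branch.

Atoms are nodes carrying a 78-dimensional one-hot/binary feature vector;
chemical bonds are undirected edges.  Hydrogens stay implicit (heavy-atom
graph).  The featurization follows the global-pooling graph-network
convention for this task: element symbol (44), degree (11), total hydrogen
count (11), implicit valence (11), and an aromaticity flag (1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = ["MolecularGraph", "smiles_to_graph", "ATOM_FEATURE_DIM"]

_ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "X",  # "X" absorbs anything else
]
_RANGE11 = list(range(11))

ATOM_FEATURE_DIM = len(_ELEMENTS) + 3 * len(_RANGE11) + 1  # 78


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of one molecule.

    ``edges`` stores each bond once as an (i, j) pair; consumers interpret
    the list symmetrically.  No self-loops are stored — graph-convolution
    layers add them internally.
    """

    node_features: np.ndarray  # (atom_count, 78)
    edges: tuple[tuple[int, int], ...]
    atom_count: int
    smiles: str = ""


class SmilesParseError(ValueError):
    def __init__(self, smiles: str):
        super().__init__(f"could not parse SMILES: {smiles!r}")
        self.smiles = smiles


def _one_hot(value, choices: list) -> list[int]:
    if value not in choices:
        value = choices[-1]
    return [int(value == c) for c in choices]


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises :class:`SmilesParseError` for strings RDKit cannot parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    feats = []
    for atom in mol.GetAtoms():
        row = (
            _one_hot(atom.GetSymbol(), _ELEMENTS)
            + _one_hot(atom.GetDegree(), _RANGE11)
            + _one_hot(atom.GetTotalNumHs(), _RANGE11)
            + _one_hot(atom.GetImplicitValence(), _RANGE11)
            + [int(atom.GetIsAromatic())]
        )
        feats.append(row)
    edges = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    return MolecularGraph(
        node_features=np.array(feats, dtype=np.float64),
        edges=edges,
        atom_count=mol.GetNumAtoms(),
        smiles=smiles,
    )
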