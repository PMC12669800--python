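"""Atom-level drug graph with fixed-width one-hot features.

Atoms are encoded as 82-d vectors formed by concatenated one-hot
blocks; bonds as 6-d vectors (bond-order one-hot plus conjugation and
ring flags). The partition of the 82 dimensions is declared once in
this module (and surfaced in the config) so it can be swapped without
touching downstream code:

    atom type (44 elements + other)      45
    degree 0–10                          11
    explicit valence 0–10                11
    implicit valence 0–10                11
    aromaticity (true / false)            2
    formal-charge sign (+ / −) flags      2
                                  total  82

The charge slots are indicator flags (both zero for neutral atoms), so
for neutral molecules every atom row sums to 5 — one per one-hot block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import MoleculeRecord

__all__ = [
    "DrugGraph",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
    "ATOM_TYPES",
    "featurize_atoms",
    "featurize_bonds",
    "build_drug_graph",
]

ATOM_TYPES = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "W",
]
_MAX_DEGREE = 10
_MAX_VALENCE = 10
ATOM_FEATURE_DIM = (len(ATOM_TYPES) + 1) + 11 + 11 + 11 + 2 + 2  # = 82
BOND_FEATURE_DIM = 6
_BOND_ORDERS = ("single", "double", "triple", "aromatic")


@dataclass
class DrugGraph:
    """Undirected molecular graph G_d with atom and bond feature matrices."""

    atom_features: np.ndarray          # (N_d, 82)
    bonds: np.ndarray                  # (|E_d|, 2) int, undirected pairs
    bond_features: np.ndarray          # (|E_d|, 6)
    coords: np.ndarray | None = None   # (N_d, 3) Å when a pose is known

    @property
    def n_atoms(self) -> int:
        return len(self.atom_features)

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Both directions of every bond, with matching feature rows."""
        if len(self.bonds) == 0:
            return (np.zeros((0, 2), dtype=np.intp),
                    np.zeros((0, BOND_FEATURE_DIM)))
        fwd, rev = self.bonds, self.bonds[:, ::-1]
        edges = np.concatenate([fwd, rev], axis=0)
        feats = np.concatenate([self.bond_features, self.bond_features], axis=0)
        return edges.astype(np.intp), feats


def _one_hot(value: int, size: int) -> np.ndarray:
    """One-hot with a trailing "other" slot for out-of-range values."""
    v = np.zeros(size)
    v[value if 0 <= value < size - 1 else size - 1] = 1.0
    return v


def featurize_atoms(mol: MoleculeRecord) -> np.ndarray:
    rows = np.zeros((mol.n_atoms, ATOM_FEATURE_DIM))
    for i, atom in enumerate(mol.atoms):
        try:
            t = ATOM_TYPES.index(atom["element"])
        except ValueError:
            t = len(ATOM_TYPES)
        blocks = [
            _one_hot(t, len(ATOM_TYPES) + 1),
            _one_hot(atom["degree"], _MAX_DEGREE + 1),
            _one_hot(atom["explicit_valence"], _MAX_VALENCE + 1),
            _one_hot(atom["implicit_valence"], _MAX_VALENCE + 1),
            np.array([1.0, 0.0]) if atom["aromatic"] else np.array([0.0, 1.0]),
            np.array([float(atom["formal_charge"] > 0),
                      float(atom["formal_charge"] < 0)]),
        ]
        rows[i] = np.concatenate(blocks)
    return rows


def featurize_bonds(mol: MoleculeRecord) -> tuple[np.ndarray, np.ndarray]:
    """Undirected bond list plus the |E_d| × 6 feature matrix."""
    n = len(mol.bonds)
    pairs = np.zeros((n, 2), dtype=np.intp)
    feats = np.zeros((n, BOND_FEATURE_DIM))
    for r, bond in enumerate(mol.bonds):
        pairs[r] = (bond["i"], bond["j"])
        feats[r, _BOND_ORDERS.index(bond["order"])] = 1.0
        feats[r, 4] = float(bond["conjugated"])
        feats[r, 5] = float(bond["in_ring"])
    return pairs, feats


def build_drug_graph(mol: MoleculeRecord) -> DrugGraph:
    bonds, bond_feats = featurize_bonds(mol)
    return DrugGraph(atom_features=featurize_atoms(mol), bonds=bonds,
                     bond_features=bond_feats, coords=mol.coords)
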