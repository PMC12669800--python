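"""Pocket-centered directed heterogeneous residue↔atom interface graph.

For affinity estimation the protein pocket and the posed ligand are
joined into a bipartite directed graph: each pocket residue connects to
its k nearest drug atoms (p→d edges) and each drug atom to its k
nearest pocket residues (d→p edges), k = 6 by default, distances taken
between drug heavy atoms and residue α-carbons. Every edge carries the
same 8-d rotation-invariant descriptor family as the intra-protein
graph — relative position in the target node's interface frame, a
Gaussian distance encoding, and the quaternion between the two
interface frames.

Interface frames are anchored on the partner molecule: a residue frame
has ẑ toward its nearest drug atom with the x̂ẑ plane set by the
preceding residue's Cα; an atom frame has ẑ toward its nearest residue
Cα with the x̂ẑ plane set by the atom's nearest neighboring atom.
Because the frames are built from the complex itself, the features are
invariant under global rigid motion but respond to any relative motion
of ligand versus protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import (LocalFrame, fallback_frame, gram_schmidt_frame,
                       local_coordinates, rbf, relative_quaternion)
from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

__all__ = [
    "HeteroComplexGraph",
    "build_interface_frames",
    "build_hetero_edges",
    "compute_hetero_edge_features",
    "build_hetero_graph",
]

DEFAULT_K = 6


@dataclass
class HeteroComplexGraph:
    """Bipartite interface graph G_h over pocket residues and drug atoms."""

    n_residues: int
    n_atoms: int
    edges_p2d: np.ndarray        # (E1, 2) rows (residue i, atom j)
    edges_d2p: np.ndarray        # (E2, 2) rows (atom j, residue i)
    features_p2d: np.ndarray     # (E1, 8)
    features_d2p: np.ndarray     # (E2, 8)
    residue_frames: list[LocalFrame]
    atom_frames: list[LocalFrame]


def _knn(sources: np.ndarray, targets: np.ndarray, k: int) -> list[np.ndarray]:
    """Indices of the k nearest targets per source; ties break low-index."""
    d = cdist(sources, targets)
    k_eff = min(k, targets.shape[0])
    out = []
    for row in d:
        order = np.lexsort((np.arange(len(row)), row))
        out.append(order[:k_eff])
    return out


def build_interface_frames(pocket: ProteinStructure,
                           drug_coords: np.ndarray
                           ) -> tuple[list[LocalFrame], list[LocalFrame]]:
    """Interface frames for every pocket residue and every drug atom."""
    drug_coords = np.asarray(drug_coords, dtype=np.float64)
    if pocket.n_residues == 0:
        raise ValueError("pocket is empty")
    if len(drug_coords) < 2:
        raise ValueError("drug needs at least 2 atoms for interface frames")
    ca = pocket.ca_coordinates()

    residue_frames: list[LocalFrame] = []
    for i in range(pocket.n_residues):
        nearest = drug_coords[np.argmin(np.linalg.norm(drug_coords - ca[i], axis=1))]
        z = nearest - ca[i]
        # x̂ẑ plane from the preceding residue's Cα (succeeding for the first)
        ref = ca[i - 1] if i > 0 else ca[min(i + 1, pocket.n_residues - 1)]
        in_plane = ref - ca[i]
        frame = _frame_with_z(ca[i], z, in_plane)
        residue_frames.append(frame)

    atom_frames: list[LocalFrame] = []
    for j in range(len(drug_coords)):
        nearest_ca = ca[np.argmin(np.linalg.norm(ca - drug_coords[j], axis=1))]
        z = nearest_ca - drug_coords[j]
        others = np.delete(np.arange(len(drug_coords)), j)
        nn = others[np.argmin(np.linalg.norm(
            drug_coords[others] - drug_coords[j], axis=1))]
        in_plane = drug_coords[nn] - drug_coords[j]
        atom_frames.append(_frame_with_z(drug_coords[j], z, in_plane))
    return residue_frames, atom_frames


def _frame_with_z(origin: np.ndarray, z_dir: np.ndarray,
                  in_plane: np.ndarray) -> LocalFrame:
    """Right-handed frame with ẑ along ``z_dir`` and x̂ in the plane of
    (ẑ, ``in_plane``); falls back to a global-axis completion when the
    two directions are degenerate."""
    frame = gram_schmidt_frame(origin, z_dir, in_plane)
    if frame is None:
        logger.warning("degenerate interface frame at %s; global-axis fallback",
                       origin)
        frame = fallback_frame(origin, z_dir)
    # gram_schmidt puts the primary axis on x̂; reorder to (x̂, ŷ, ẑ) with
    # ẑ = primary, keeping right-handedness: new x̂ = old ŷ, ŷ = old ẑ.
    x, y, z = frame.basis
    return LocalFrame(origin=origin, basis=np.stack([y, z, x]))


def build_hetero_edges(pocket_ca: np.ndarray, drug_coords: np.ndarray,
                       k: int = DEFAULT_K) -> tuple[np.ndarray, np.ndarray]:
    """Directed k-NN edge lists (p→d and d→p) over the interface.

    Each residue gets min(k, N_d) outgoing p→d edges and each atom
    min(k, N_residues) outgoing d→p edges; exact ties break toward the
    lower index so the edge set is deterministic.
    """
    pocket_ca = np.asarray(pocket_ca, dtype=np.float64)
    drug_coords = np.asarray(drug_coords, dtype=np.float64)
    if len(pocket_ca) == 0 or len(drug_coords) == 0:
        raise ValueError("both node sets must be nonempty")
    p2d = [(i, j) for i, nbrs in enumerate(_knn(pocket_ca, drug_coords, k))
           for j in nbrs]
    d2p = [(j, i) for j, nbrs in enumerate(_knn(drug_coords, pocket_ca, k))
           for i in nbrs]
    return (np.array(p2d, dtype=np.intp).reshape(-1, 2),
            np.array(d2p, dtype=np.intp).reshape(-1, 2))


def compute_hetero_edge_features(residue_frames: list[LocalFrame],
                                 atom_frames: list[LocalFrame],
                                 pocket_ca: np.ndarray,
                                 drug_coords: np.ndarray,
                                 edges_p2d: np.ndarray,
                                 edges_d2p: np.ndarray,
                                 sigma: float = 1.0
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """8-d features for both edge directions.

    A p→d edge (residue i, atom j) encodes the residue position in the
    atom's frame, φ(d_ij), and the quaternion from the atom-j frame to
    the residue-i frame; a d→p edge encodes the symmetric counterpart
    in the residue's frame.
    """
    pocket_ca = np.asarray(pocket_ca, dtype=np.float64)
    drug_coords = np.asarray(drug_coords, dtype=np.float64)

    f_p2d = np.zeros((len(edges_p2d), 8))
    for r, (i, j) in enumerate(edges_p2d):
        d = np.linalg.norm(pocket_ca[i] - drug_coords[j])
        f_p2d[r, :3] = local_coordinates(atom_frames[j], pocket_ca[i])
        f_p2d[r, 3] = rbf(d, sigma)
        f_p2d[r, 4:] = relative_quaternion(atom_frames[j], residue_frames[i])

    f_d2p = np.zeros((len(edges_d2p), 8))
    for r, (j, i) in enumerate(edges_d2p):
        d = np.linalg.norm(pocket_ca[i] - drug_coords[j])
        f_d2p[r, :3] = local_coordinates(residue_frames[i], drug_coords[j])
        f_d2p[r, 3] = rbf(d, sigma)
        f_d2p[r, 4:] = relative_quaternion(residue_frames[i], atom_frames[j])
    return f_p2d, f_d2p


def build_hetero_graph(pocket: ProteinStructure, drug_coords: np.ndarray,
                       k: int = DEFAULT_K, sigma: float = 1.0
                       ) -> HeteroComplexGraph:
    """Assemble the full interface graph for one pocket–ligand complex."""
    drug_coords = np.asarray(drug_coords, dtype=np.float64)
    residue_frames, atom_frames = build_interface_frames(pocket, drug_coords)
    ca = pocket.ca_coordinates()
    edges_p2d, edges_d2p = build_hetero_edges(ca, drug_coords, k=k)
    f_p2d, f_d2p = compute_hetero_edge_features(
        residue_frames, atom_frames, ca, drug_coords, edges_p2d, edges_d2p,
        sigma=sigma)
    return HeteroComplexGraph(
        n_residues=pocket.n_residues, n_atoms=len(drug_coords),
        edges_p2d=edges_p2d, edges_d2p=edges_d2p,
        features_p2d=f_p2d, features_d2p=f_d2p,
        residue_frames=residue_frames, atom_frames=atom_frames)
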