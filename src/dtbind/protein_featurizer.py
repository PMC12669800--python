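"""Residue-level directed protein graph with geometric edge features.

A protein of N residues becomes a directed graph: nodes carry a 1024-d
sequence embedding, edges connect residue pairs whose α-carbons lie
within a 12 Å cutoff (both directions), and each edge carries an 8-d
rotation-invariant descriptor

    e_ij = [x_ij, y_ij, z_ij, φ(d_ij), q_ij]

where (x, y, z) are the coordinates of residue j's α-carbon in residue
i's local backbone frame, φ is a Gaussian radial basis of the distance,
and q is the unit quaternion relating the two frames. A 10-d surface
descriptor per residue (see :mod:`dtbind.surface`) completes the
representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import (LocalFrame, fallback_frame, gram_schmidt_frame,
                       local_coordinates, rbf, relative_quaternion)
from .structure_io import ProteinStructure
from .surface import compute_surface_features

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceEmbedder",
    "ResidueGraph",
    "build_residue_frames",
    "build_residue_edges",
    "compute_edge_features",
    "embed_sequence",
    "build_residue_graph",
]

EMBEDDING_DIM = 1024
DEFAULT_CUTOFF = 12.0
DEFAULT_SIGMA = 1.0


@runtime_checkable
class SequenceEmbedder(Protocol):
    """Anything mapping a 1-letter sequence to an (N, 1024) matrix.

    Stands in for a pretrained protein language model; the bundled
    deterministic hash embedder (:func:`dtbind.fixtures.stub_embedder`)
    satisfies it, and a real model can be plugged in unchanged.
    """

    name: str
    dimension: int
    deterministic: bool

    def __call__(self, sequence: str) -> np.ndarray: ...


@dataclass
class ResidueGraph:
    """Directed residue graph G_p plus surface tensor and local frames."""

    node_features: np.ndarray     # (N, 1024)
    edges: np.ndarray             # (E, 2) int, directed (i, j)
    edge_features: np.ndarray     # (E, 8)
    surface_features: np.ndarray  # (N, 10)
    frames: list[LocalFrame]
    ca_coords: np.ndarray         # (N, 3)

    @property
    def n_residues(self) -> int:
        return len(self.ca_coords)


def build_residue_frames(structure: ProteinStructure) -> list[LocalFrame]:
    """One right-handed orthonormal frame per residue, origin at Cα.

    x̂ along Cα→C, ŷ the Gram–Schmidt orthogonalization of Cα→N,
    ẑ = x̂ × ŷ. Residues with missing or collinear backbone atoms fall
    back to a frame built from the chain direction (toward the next
    residue's Cα, or the previous one at the C-terminus), completed
    against a global axis; the fallback is logged.
    """
    frames: list[LocalFrame] = []
    ca = structure.ca_coordinates()
    n = structure.n_residues
    for i, res in enumerate(structure.residues):
        origin = ca[i]
        atom_n, atom_c = res.atom("N"), res.atom("C")
        frame = None
        if atom_n is not None and atom_c is not None:
            frame = gram_schmidt_frame(origin, atom_c.xyz - origin,
                                       atom_n.xyz - origin)
        if frame is None:
            if n > 1:
                other = ca[i + 1] if i + 1 < n else ca[i - 1]
                primary = other - origin
            else:
                primary = np.array([1.0, 0.0, 0.0])
            frame = fallback_frame(origin, primary)
            logger.warning("residue %s: degenerate backbone, fallback frame",
                           res.key)
        frames.append(frame)
    return frames


def build_residue_edges(structure: ProteinStructure,
                        cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Directed edges between residue pairs with Cα–Cα distance ≤ cutoff.

    Both directions are present for every qualifying pair, there are no
    self-edges, and rows are ordered lexicographically in (i, j).
    """
    ca = structure.ca_coordinates()
    d = cdist(ca, ca)
    i_idx, j_idx = np.nonzero((d <= cutoff) & ~np.eye(len(ca), dtype=bool))
    return np.column_stack([i_idx, j_idx]).astype(np.intp)


def compute_edge_features(frames: list[LocalFrame], ca_coords: np.ndarray,
                          edges: np.ndarray,
                          sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """The |E| × 8 matrix [local coords, φ(d), quaternion] per edge."""
    ca_coords = np.asarray(ca_coords, dtype=np.float64)
    out = np.zeros((len(edges), 8))
    for row, (i, j) in enumerate(edges):
        local = local_coordinates(frames[i], ca_coords[j])
        d = np.linalg.norm(ca_coords[j] - ca_coords[i])
        q = relative_quaternion(frames[i], frames[j])
        out[row, :3] = local
        out[row, 3] = rbf(d, sigma)
        out[row, 4:] = q
    return out


def embed_sequence(sequence: str, embedder: SequenceEmbedder) -> np.ndarray:
    """Run the embedder and validate alignment with the sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    emb = np.asarray(embedder(sequence), dtype=np.float64)
    if emb.shape != (len(sequence), embedder.dimension):
        raise ValueError(
            f"embedder returned {emb.shape}, expected "
            f"({len(sequence)}, {embedder.dimension})")
    return emb


def build_residue_graph(structure: ProteinStructure,
                        embedder: SequenceEmbedder,
                        cutoff: float = DEFAULT_CUTOFF,
                        sigma: float = DEFAULT_SIGMA,
                        surface_grid: float = 1.0,
                        with_surface: bool = True) -> ResidueGraph:
    """Assemble the full residue graph for one protein (or pocket).

    Multi-chain proteins are embedded per chain and the rows
    concatenated in residue order.
    """
    frames = build_residue_frames(structure)
    ca = structure.ca_coordinates()
    edges = build_residue_edges(structure, cutoff=cutoff)
    edge_feats = compute_edge_features(frames, ca, edges, sigma=sigma)
    chunks = [embed_sequence(seq, embedder)
              for seq in structure.sequences_by_chain().values()]
    nodes = np.concatenate(chunks, axis=0)
    if len(nodes) != structure.n_residues:
        raise ValueError("embedding rows do not match residue count")
    if with_surface:
        surf = compute_surface_features(structure, grid=surface_grid)
    else:
        surf = np.zeros((structure.n_residues, 10))
    return ResidueGraph(node_features=nodes, edges=edges,
                        edge_features=edge_feats, surface_features=surf,
                        frames=frames, ca_coords=ca)
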