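"""Graph encoders for proteins and drugs.

The protein encoder runs T rounds of attention-weighted message passing
over the residue graph. The attention coefficient on each directed edge
blends two normalized similarities — node–node and edge–edge — with a
mixing weight λ (default 0.5):

    α_ij = λ·softmax_j((W_Q h_j)·(W_K h_i)/√d) + (1−λ)·softmax_j(s(e_ij))

with both softmaxes taken over the in-neighborhood of node i. Messages
m_ij = α_ij (W_v h_j + W_e e_ij) are summed and passed through a
residual update h_i ← σ(W_out(h_i + Σ m)) + h_i. After the final layer
the residue embeddings are concatenated with projected surface features
and fused by an MLP.

The drug encoder is a message-passing network over the bond graph:
m_ij = σ(W_u [h_j ∥ e_ij]), h_i ← W_C [h_i ∥ Σ m], T layers.

Raw 8-d geometric edge features are linearly lifted to the hidden width
before entering the attention/message arithmetic, mirroring the node
projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_softmax, segment_sum
from .config import ModelConfig
from .drug_featurizer import BOND_FEATURE_DIM, ATOM_FEATURE_DIM, DrugGraph
from .protein_featurizer import EMBEDDING_DIM, ResidueGraph

__all__ = ["Module", "ProteinEncoder", "DrugEncoder",
           "ProteinEncoding", "DrugEncoding"]


@dataclass
class ProteinEncoding:
    """Per-residue embeddings H_p^final (N_p × h1)."""
    embeddings: Tensor


@dataclass
class DrugEncoding:
    """Per-atom embeddings H_d^final (N_d × h3)."""
    embeddings: Tensor


class Module:
    """Minimal parameter container shared by encoders and decoders."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def param(self, name: str, shape: tuple[int, ...],
              rng: np.random.Generator, zero: bool = False) -> Tensor:
        if zero:
            data = np.zeros(shape)
        elif len(shape) == 1:
            data = np.zeros(shape)
        else:
            fan_in, fan_out = shape[-2], shape[-1]
            bound = math.sqrt(6.0 / (fan_in + fan_out))
            data = rng.uniform(-bound, bound, size=shape)
        t = Tensor(data, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def named_parameters(self) -> dict[str, Tensor]:
        return dict(self._params)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self._params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k}")
            if state[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{state[k].shape} vs {t.data.shape}")
            t.data = np.asarray(state[k], dtype=np.float64).copy()


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = x @ w
    return out + b if b is not None else out


class ProteinEncoder(Module):
    """Residue-graph encoder with λ-blended attention and surface fusion."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        h1, h2 = config.h1, config.h2
        self.param("node_proj_w", (EMBEDDING_DIM, h1), rng)
        self.param("node_proj_b", (h1,), rng)
        self.param("surf_proj_w", (10, h2), rng)
        self.param("surf_proj_b", (h2,), rng)
        self.param("edge_proj_w", (8, h1), rng)
        for t in range(config.layers):
            for name in ("Wv", "We", "WQv", "WKv", "WQe", "WKe", "Wout"):
                self.param(f"layer{t}_{name}", (h1, h1), rng)
        self.param("fuse_w1", (h1 + h2, h1), rng)
        self.param("fuse_b1", (h1,), rng)
        self.param("fuse_w2", (h1, h1), rng)
        self.param("fuse_b2", (h1,), rng)

    def __call__(self, graph: ResidueGraph) -> ProteinEncoding:
        p = self._params
        cfg = self.config
        n = graph.n_residues
        if graph.node_features.shape[1] != EMBEDDING_DIM:
            raise ValueError("node features must be 1024-d (node projection)")
        h = linear(Tensor(graph.node_features),
                   p["node_proj_w"], p["node_proj_b"]).leaky_relu()
        s = linear(Tensor(graph.surface_features),
                   p["surf_proj_w"], p["surf_proj_b"]).leaky_relu()

        edges = graph.edges
        has_edges = len(edges) > 0
        self.last_attention: list[np.ndarray] = []  # per-layer α (|E|,)
        if has_edges:
            e = linear(Tensor(graph.edge_features), p["edge_proj_w"])
            target = edges[:, 0]
            source = edges[:, 1]
        for t in range(cfg.layers):
            if has_edges:
                hi = gather_rows(h, target)
                hj = gather_rows(h, source)
                scale = 1.0 / math.sqrt(cfg.h1)
                s_node = ((hj @ p[f"layer{t}_WQv"])
                          * (hi @ p[f"layer{t}_WKv"])).sum(axis=1) * scale
                s_edge = ((e @ p[f"layer{t}_WQe"])
                          * (e @ p[f"layer{t}_WKe"])).sum(axis=1) * scale
                alpha = (cfg.lam * segment_softmax(s_node, target, n)
                         + (1.0 - cfg.lam) * segment_softmax(s_edge, target, n))
                self.last_attention.append(alpha.data.copy())
                msg = alpha.reshape(-1, 1) * (hj @ p[f"layer{t}_Wv"]
                                              + e @ p[f"layer{t}_We"])
                agg = segment_sum(msg, target, n)
                h = ((h + agg) @ p[f"layer{t}_Wout"]).leaky_relu() + h
            else:
                h = (h @ p[f"layer{t}_Wout"]).leaky_relu() + h

        fused = concat([h, s], axis=1)
        fused = linear(fused, p["fuse_w1"], p["fuse_b1"]).leaky_relu()
        fused = linear(fused, p["fuse_w2"], p["fuse_b2"])
        return ProteinEncoding(embeddings=fused)


class DrugEncoder(Module):
    """Bond-graph message-passing encoder for molecules."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        h3 = config.h3
        self.param("node_proj_w", (ATOM_FEATURE_DIM, h3), rng)
        self.param("node_proj_b", (h3,), rng)
        for t in range(config.layers):
            self.param(f"layer{t}_Wu", (h3 + BOND_FEATURE_DIM, h3), rng)
            self.param(f"layer{t}_WC", (2 * h3, h3), rng)

    def __call__(self, graph: DrugGraph) -> DrugEncoding:
        p = self._params
        n = graph.n_atoms
        if graph.atom_features.shape[1] != ATOM_FEATURE_DIM:
            raise ValueError("atom features must be 82-d (node projection)")
        h = linear(Tensor(graph.atom_features),
                   p["node_proj_w"], p["node_proj_b"]).leaky_relu()
        edges, edge_feats = graph.directed_edges()
        has_edges = len(edges) > 0
        if has_edges:
            target = edges[:, 0]
            source = edges[:, 1]
            e = Tensor(edge_feats)
        for t in range(self.config.layers):
            if has_edges:
                hj = gather_rows(h, source)
                msg = concat([hj, e], axis=1) @ p[f"layer{t}_Wu"]
                msg = msg.leaky_relu()
                agg = segment_sum(msg, target, n)
            else:
                agg = Tensor(np.zeros((n, self.config.h3)))
            h = concat([h, agg], axis=1) @ p[f"layer{t}_WC"]
        return DrugEncoding(embeddings=h)
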