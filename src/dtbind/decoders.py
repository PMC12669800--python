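"""Task heads: binding occurrence, binding-site, and affinity decoders.

All three consume the shared encoder outputs.

* Occurrence: dual-pathway multi-head cross-attention (protein↔drug)
  with residual layer-norm, per-modality sigmoid gating between original
  and attended features, mean+max pooling, residual MLP refinement, a
  joint vector [z_p ∥ z_d ∥ z_p⊙z_d ∥ z_p−z_d], and a 4-layer classifier
  ending in a sigmoid. The pooled pathway makes the probability
  invariant to residue/atom ordering.
* Site: cross-attention (protein queries, drug keys/values) with a
  residual, then residue self-attention, sigmoid-gated fusion of the two
  streams, and a per-residue head ŷ_i = sigmoid(W_r z_i + MLP(z_i)).
* Affinity: typed graph convolution over the pocket-centered
  heterogeneous interface graph with per-neighborhood softmax attention
  on [neighbor ∥ edge] keys, sum pooling of residues and atoms,
  attention-weighted residue–atom pair aggregation, and a regression
  head on [g ∥ u_d ∥ u_p] producing a p-affinity.

The classifier squashes its single logit with a sigmoid — the two-class
softmax with a fixed zero reference — and the affinity pair weights are
softmax-normalized so the pair aggregate is a convex combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, concat, dropout, gather_rows, layer_norm,
                       segment_softmax, segment_sum, softmax)
from .complex_graph import HeteroComplexGraph
from .config import ModelConfig
from .encoders import DrugEncoding, Module, ProteinEncoding, linear

__all__ = ["OccurrenceDecoder", "SiteDecoder", "AffinityDecoder",
           "OccurrenceOutput", "SiteOutput", "AffinityOutput"]


@dataclass
class OccurrenceOutput:
    probability: Tensor   # scalar in [0, 1]
    joint: Tensor         # fused vector z of width 4·h4


@dataclass
class SiteOutput:
    probabilities: Tensor  # (N_p,) in [0, 1]


@dataclass
class AffinityOutput:
    paffinity: Tensor      # scalar, −log10 molar


def _mha(q: Tensor, k: Tensor, v: Tensor, heads: int, wo: Tensor) -> Tensor:
    """Standard scaled-dot-product multi-head attention + output proj."""
    nq, width = q.shape
    nk = k.shape[0]
    dh = width // heads
    qh = q.reshape(nq, heads, dh).transpose(1, 0, 2)
    kh = k.reshape(nk, heads, dh).transpose(1, 0, 2)
    vh = v.reshape(nk, heads, dh).transpose(1, 0, 2)
    scores = qh @ kh.transpose(0, 2, 1) * (1.0 / math.sqrt(dh))
    attn = softmax(scores, axis=-1)
    out = (attn @ vh).transpose(1, 0, 2).reshape(nq, width)
    return out @ wo


def _mlp2(x: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    return linear(linear(x, w1, b1).leaky_relu(), w2, b2)


class OccurrenceDecoder(Module):
    """Predicts the probability that the drug binds the protein at all."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        h4 = config.h4
        if h4 % config.heads != 0:
            raise ValueError("h4 must be divisible by the number of heads")
        self.param("proj_p_w", (config.h1, h4), rng)
        self.param("proj_d_w", (config.h3, h4), rng)
        for side in ("p", "d"):
            for name in ("WQ", "WK", "WV", "WO"):
                self.param(f"att_{side}_{name}", (h4, h4), rng)
            self.param(f"ln_{side}_g", (h4,), rng)
            self._params[f"ln_{side}_g"].data[:] = 1.0
            self.param(f"ln_{side}_b", (h4,), rng)
            self.param(f"gate_{side}_w", (2 * h4, h4), rng)
            self.param(f"res_{side}_w1", (h4, h4), rng)
            self.param(f"res_{side}_b1", (h4,), rng)
            self.param(f"res_{side}_w2", (h4, h4), rng)
            self.param(f"res_{side}_b2", (h4,), rng)
            self.param(f"res_{side}_skip", (h4, h4), rng)
        dims = [4 * h4, 2 * h4, h4, h4 // 2, 1]
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.param(f"clf_w{i}", (a, b), rng)
            self.param(f"clf_b{i}", (b,), rng)
            if b > 1:
                self.param(f"clf_ln{i}_g", (b,), rng)
                self._params[f"clf_ln{i}_g"].data[:] = 1.0
                self.param(f"clf_ln{i}_b", (b,), rng)

    def __call__(self, protein: ProteinEncoding, drug: DrugEncoding,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> OccurrenceOutput:
        if protein.embeddings.shape[0] == 0 or drug.embeddings.shape[0] == 0:
            raise ValueError("protein and drug encodings must be nonempty")
        p = self._params
        cfg = self.config
        hp = (protein.embeddings @ p["proj_p_w"]).leaky_relu()
        hd = (drug.embeddings @ p["proj_d_w"]).leaky_relu()

        att_p = _mha(hp @ p["att_p_WQ"], hd @ p["att_p_WK"],
                     hd @ p["att_p_WV"], cfg.heads, p["att_p_WO"])
        hp_att = layer_norm(hp + att_p, p["ln_p_g"], p["ln_p_b"])
        att_d = _mha(hd @ p["att_d_WQ"], hp @ p["att_d_WK"],
                     hp @ p["att_d_WV"], cfg.heads, p["att_d_WO"])
        hd_att = layer_norm(hd + att_d, p["ln_d_g"], p["ln_d_b"])

        gp = (concat([hp_att, hp], axis=1) @ p["gate_p_w"]).sigmoid()
        hpf = gp * hp_att + (1.0 - gp) * hp
        gd = (concat([hd_att, hd], axis=1) @ p["gate_d_w"]).sigmoid()
        hdf = gd * hd_att + (1.0 - gd) * hd

        zp = hpf.mean(axis=0) + hpf.max(axis=0)
        zd = hdf.mean(axis=0) + hdf.max(axis=0)
        zp = _mlp2(zp, p["res_p_w1"], p["res_p_b1"],
                   p["res_p_w2"], p["res_p_b2"]) + zp @ p["res_p_skip"]
        zd = _mlp2(zd, p["res_d_w1"], p["res_d_b1"],
                   p["res_d_w2"], p["res_d_b2"]) + zd @ p["res_d_skip"]

        z = concat([zp, zd, zp * zd, zp - zd], axis=0)
        x = z
        for i in range(4):
            x = linear(x, p[f"clf_w{i}"], p[f"clf_b{i}"])
            if i < 3:
                x = x.leaky_relu()
                x = layer_norm(x, p[f"clf_ln{i}_g"], p[f"clf_ln{i}_b"])
                x = dropout(x, self.config.dropout, rng, training)
        prob = x.reshape(()).sigmoid()
        return OccurrenceOutput(probability=prob, joint=z)


class SiteDecoder(Module):
    """Per-residue binding-site probabilities."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        h5 = config.h5
        if h5 % config.heads != 0:
            raise ValueError("h5 must be divisible by the number of heads")
        self.param("proj_p_w", (config.h1, h5), rng)
        self.param("proj_d_w", (config.h3, h5), rng)
        for name in ("WQp", "WKd", "WVd", "WOc"):
            self.param(f"cross_{name}", (h5, h5), rng)
        for name in ("WQ", "WK", "WV", "WO"):
            self.param(f"self_{name}", (h5, h5), rng)
        self.param("gate_w", (2 * h5, h5), rng)
        self.param("out_wr", (h5, 1), rng)
        self.param("out_w1", (h5, 2 * h5), rng)
        self.param("out_b1", (2 * h5,), rng)
        self.param("out_w2", (2 * h5, 1), rng)
        self.param("out_b2", (1,), rng)

    def __call__(self, protein: ProteinEncoding, drug: DrugEncoding,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> SiteOutput:
        if protein.embeddings.shape[0] == 0 or drug.embeddings.shape[0] == 0:
            raise ValueError("protein and drug encodings must be nonempty")
        p = self._params
        cfg = self.config
        hp = (protein.embeddings @ p["proj_p_w"]).leaky_relu()
        hd = (drug.embeddings @ p["proj_d_w"]).leaky_relu()

        hc = hp + _mha(hp @ p["cross_WQp"], hd @ p["cross_WKd"],
                       hd @ p["cross_WVd"], cfg.heads, p["cross_WOc"])
        hs = _mha(hc @ p["self_WQ"], hc @ p["self_WK"],
                  hc @ p["self_WV"], cfg.heads, p["self_WO"])
        g = (concat([hc, hs], axis=1) @ p["gate_w"]).sigmoid()
        z = g * hc + (1.0 - g) * hs
        logits = (z @ p["out_wr"]
                  + _mlp2(z, p["out_w1"], p["out_b1"],
                          p["out_w2"], p["out_b2"]))
        return SiteOutput(probabilities=logits.reshape(-1).sigmoid())


class AffinityDecoder(Module):
    """p-affinity regression over the heterogeneous interface graph."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        h6 = config.h6
        self.param("proj_p_w", (config.h1, h6), rng)
        self.param("proj_p_b", (h6,), rng)
        self.param("proj_d_w", (config.h3, h6), rng)
        self.param("proj_d_b", (h6,), rng)
        self.param("edge_p2d_w", (8, h6), rng)
        self.param("edge_d2p_w", (8, h6), rng)
        for t in range(config.layers):
            for side in ("p", "d"):
                self.param(f"layer{t}_W{side}", (h6, h6), rng)
                self.param(f"layer{t}_WQ{side}", (h6, h6), rng)
                self.param(f"layer{t}_WK{side}", (2 * h6, h6), rng)
                self.param(f"layer{t}_Wm{side}", (2 * h6, h6), rng)
        self.param("pair_Wv", (2 * h6, h6), rng)
        self.param("pair_Watt", (2 * h6, 1), rng)
        self.param("aff_w1", (3 * h6, 2 * h6), rng)
        self.param("aff_b1", (2 * h6,), rng)
        self.param("aff_w2", (2 * h6, 1), rng)
        self.param("aff_b2", (1,), rng)

    def __call__(self, pocket: ProteinEncoding, drug: DrugEncoding,
                 hetero: HeteroComplexGraph, training: bool = False,
                 rng: np.random.Generator | None = None) -> AffinityOutput:
        p = self._params
        cfg = self.config
        n_res, n_atom = hetero.n_residues, hetero.n_atoms
        if n_res == 0 or n_atom == 0:
            raise ValueError("pocket and drug must both be nonempty")
        if pocket.embeddings.shape[0] != n_res:
            raise ValueError("pocket encoding does not match hetero graph")
        if drug.embeddings.shape[0] != n_atom:
            raise ValueError("drug encoding does not match hetero graph")

        hp = linear(pocket.embeddings, p["proj_p_w"], p["proj_p_b"]).leaky_relu()
        hd = linear(drug.embeddings, p["proj_d_w"], p["proj_d_b"]).leaky_relu()
        e_p2d = Tensor(hetero.features_p2d) @ p["edge_p2d_w"]
        e_d2p = Tensor(hetero.features_d2p) @ p["edge_d2p_w"]

        # d→p rows are (atom j, residue i): residue i aggregates atoms
        res_tgt, res_src = hetero.edges_d2p[:, 1], hetero.edges_d2p[:, 0]
        # p→d rows are (residue i, atom j): atom j aggregates residues
        atom_src, atom_tgt = hetero.edges_p2d[:, 0], hetero.edges_p2d[:, 1]
        scale = 1.0 / math.sqrt(cfg.h6)

        for t in range(cfg.layers):
            msg_p = concat([gather_rows(hd, res_src), e_d2p], axis=1)
            s_p = ((gather_rows(hp, res_tgt) @ p[f"layer{t}_WQp"])
                   * (msg_p @ p[f"layer{t}_WKp"])).sum(axis=1) * scale
            a_p = segment_softmax(s_p, res_tgt, n_res)
            agg_p = segment_sum(a_p.reshape(-1, 1) * msg_p, res_tgt, n_res)

            msg_d = concat([gather_rows(hp, atom_src), e_p2d], axis=1)
            s_d = ((gather_rows(hd, atom_tgt) @ p[f"layer{t}_WQd"])
                   * (msg_d @ p[f"layer{t}_WKd"])).sum(axis=1) * scale
            a_d = segment_softmax(s_d, atom_tgt, n_atom)
            agg_d = segment_sum(a_d.reshape(-1, 1) * msg_d, atom_tgt, n_atom)

            hp = (hp @ p[f"layer{t}_Wp"] + agg_p @ p[f"layer{t}_Wmp"]).leaky_relu()
            hd = (hd @ p[f"layer{t}_Wd"] + agg_d @ p[f"layer{t}_Wmd"]).leaky_relu()

        u_p = hp.sum(axis=0)
        u_d = hd.sum(axis=0)

        if cfg.pairwise == "all":
            ii, jj = np.meshgrid(np.arange(n_res), np.arange(n_atom),
                                 indexing="ij")
            pair_i, pair_j = ii.ravel(), jj.ravel()
        else:
            pairs = np.unique(np.concatenate(
                [hetero.edges_p2d,
                 hetero.edges_d2p[:, ::-1]], axis=0), axis=0)
            pair_i, pair_j = pairs[:, 0], pairs[:, 1]
        pair_feat = concat([gather_rows(hp, pair_i),
                            gather_rows(hd, pair_j)], axis=1)
        scores = (pair_feat @ p["pair_Watt"]).reshape(-1)
        alpha = softmax(scores, axis=-1)
        g = (alpha.reshape(-1, 1) * (pair_feat @ p["pair_Wv"])).sum(axis=0)

        x = concat([g, u_d, u_p], axis=0)
        x = linear(x, p["aff_w1"], p["aff_b1"]).leaky_relu()
        x = dropout(x, cfg.dropout, rng, training)
        y = linear(x, p["aff_w2"], p["aff_b2"]).reshape(())
        return AffinityOutput(paffinity=y)
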