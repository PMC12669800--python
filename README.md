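# dtbind

Unified, geometry-aware prediction of drug–target molecular
recognition at three resolutions: **binding occurrence** (does this
drug bind this protein?), **binding site** (which residues form the
interface?), and **binding affinity** (how strongly, as a p-affinity
= −log₁₀ of a molar Ki/Kd/IC50). It is aimed at computational
chemists and method developers who want a fully inspectable,
CPU-trainable reference implementation of this family of models, with
every geometric and statistical property verified by tests.

## The model

A protein of N_p residues is a directed graph G_p: nodes carry a
1024-d per-residue sequence embedding (any `SequenceEmbedder`; a
deterministic stub ships with the package), edges connect residues
with Cα–Cα distance ≤ 12 Å, and each edge (i, j) carries the
rotation-invariant descriptor

    e_ij = [ x_ij, y_ij, z_ij, φ(d_ij), q_ij ] ∈ R⁸

— the partner's Cα in residue i's backbone frame, a Gaussian distance
encoding φ(d) = exp(−d²/2σ²) (σ = 1 Å), and the unit quaternion
between the two local frames. Each residue also carries a 10-d surface
vector: mean/Gaussian curvature, shape index and curvedness of its
patch of the molecular surface, plus its atom-type composition. A drug
is an atom-level graph with 82-d atom and 6-d bond one-hot features
(RDKit perception). For affinity, pocket residues and ligand atoms are
joined into a directed bipartite interface graph by k = 6 nearest
neighbors with the same frame-based 8-d edge features.

A λ-blended attention encoder (λ·node-similarity +
(1−λ)·edge-similarity, λ = 0.5, T = 3 layers) embeds residues; a
3-layer message-passing network embeds atoms. Three heads decode the
shared embeddings: dual cross-attention with gating and mean+max
pooling for occurrence; cross- plus self-attention with gated fusion
for per-residue site probabilities trained with focal loss
(γ = 2, α = 0.75 on the rare binding class); typed graph convolution
over the interface graph with attention-weighted residue–atom pair
aggregation for affinity. All tensor math runs on a small gradient-
checked reverse-mode autodiff engine over NumPy; no GPU is needed.

## Worked example

`examples/predict_affinity.py` builds eight synthetic helix–ligand
complexes whose p-affinities follow a planted rule (4.0 + 0.3 ×
contact-count + noise), trains the affinity head on their interface
graphs, and prints:

```
train metrics: {'rmse': 0.001, 'mae': 0.001, 'pearson': 1.0, 'spearman': 1.0}

pair  contacts  planted  predicted
   0         3    4.846      4.846
   1         1    4.336      4.339
   2         4    5.284      5.285
   3         2    4.572      4.573
   4         5    5.648      5.649
   ...
```

Each row is one complex: the number of residues in contact with the
ligand, the planted p-affinity, and the model's prediction — the model
has recovered the planted linear affinity rule from the interface
graphs. The other examples cover featurization
(`featurize_protein.py`), occurrence (`predict_occurrence.py` —
aromatic ligands are the planted binders and score ≈ 0.99 vs ≈ 0.005)
and site localization (`predict_sites.py` — the top-ranked residues
are exactly the planted 5 Å contact residues).

A thin CLI wraps the same library:

```
dtbind fixtures --out fix/ --seed 1          # synthetic PDBs/SDFs/labels
dtbind train --task site --pairs fix/pairs.tsv --out runs/
dtbind predict --task site --pairs fix/pairs.tsv \
       --checkpoint runs/site.ckpt.npz --out preds.tsv
dtbind config --dump                         # every default
```

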