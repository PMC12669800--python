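# Methods

`dtbind` models drug–target molecular recognition at three resolutions
— does a drug bind a protein at all (occurrence), which residues form
the interface (site), and how strongly the pair binds (affinity) — over
one shared, geometry-aware representation of the two molecules. This
note records the model, its assumptions, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## Molecular representations

**Protein.** A protein (or pocket) of N_p residues becomes a directed
graph. Nodes carry a 1024-d per-residue sequence embedding supplied by
a pluggable `SequenceEmbedder`; the package ships a deterministic hash
stub (below), and a pretrained protein language model can be plugged in
unchanged. Edges connect all residue pairs with Cα–Cα distance ≤ 12 Å
(both directions). Each residue gets a right-handed orthonormal local
frame anchored on its backbone: x̂ along Cα→C, ŷ the Gram–Schmidt
orthogonalization of Cα→N, ẑ = x̂ × ŷ; residues with missing or
collinear backbone atoms fall back to a frame built from the chain
direction, completed against a global axis. Each directed edge (i, j)
carries an 8-d descriptor

    e_ij = [ x_ij, y_ij, z_ij, φ(d_ij), q_ij ]

where (x, y, z) is residue j's Cα expressed in frame i, φ(d) =
exp(−d²/2σ²) with σ = 1 Å, and q_ij is the unit quaternion of the
relative rotation between the two frames, computed from basis inner
products R[a,b] = axis_a(i)·axis_b(j) so it is exactly invariant under
any global rigid motion; the double-cover sign is fixed by w ≥ 0.

**Surface.** Each residue additionally carries a 10-d surface vector:
four curvature descriptors (mean curvature H, Gaussian curvature K,
shape index, curvedness) averaged over the surface vertices assigned to
the residue, then the mean atom-type one-hot (C, H, O, N, S, other)
over the residue's atoms. The surface is the marching-cubes isosurface
of the probe-inflated (1.4 Å) union of van-der-Waals balls on a 1 Å
grid, smoothed with 10 Taubin iterations; curvatures come from a local
quadric fit over each vertex's 3-ring neighborhood, with the sign
convention that a convex sphere of radius r has H = 1/r and shape
index +1. The wider 3-ring support and the smoothing were chosen
because 2-ring fits on the raw voxel isosurface left 7–15 % re-meshing
noise under rotation; with them the per-residue descriptors agree
within ~3–5 % across poses, and the analytic sphere test (single atom:
H = 1/r, K = 1/r² within 20 %) still passes. Buried residues with no
assigned vertex get a zero geometric block, as does any structure whose
mesh cannot be built.

**Drug.** A molecule of N_d heavy atoms (hydrogens implicit) becomes an
undirected graph with 82-d atom and 6-d bond features. The 82
dimensions are concatenated blocks — atom type over 44 elements +
other (45), degree 0–10 (11), explicit valence (11), implicit valence
(11), aromaticity (2), and formal-charge sign flags (2) — declared once
in `drug_featurizer` so the partition can be swapped without code
changes. Bond features are a bond-order one-hot {single, double,
triple, aromatic} plus conjugation and ring-membership flags, all
perceived by RDKit.

**Complex.** For affinity the pocket (from a selection file, or all
residues with a heavy atom within 10 Å of the ligand) and the posed
ligand form a directed bipartite graph: each residue connects to its
k = 6 nearest drug atoms and each atom to its 6 nearest residue Cαs,
ties broken toward the lower index. Interface frames are anchored on
the partner: a residue frame points ẑ at its nearest drug atom with the
x̂ẑ plane set by the preceding residue's Cα (the succeeding one for the
first residue); an atom frame points ẑ at its nearest Cα with the x̂ẑ
plane set by its nearest neighboring atom. Edge features reuse the
[local coordinates, φ(d), quaternion] family, so they are invariant to
global rigid motion of the complex but respond to any relative motion
of ligand versus protein.

## Encoders

The protein encoder runs T = 3 rounds of attention-weighted message
passing. Node features are projected to width h1 (LeakyReLU), surface
vectors to h2, and the raw 8-d edge features are lifted linearly to h1
(the printed update would otherwise multiply an h1×h1 matrix into an
8-vector; the lift mirrors the node projection). The attention on edge
(i, j) blends two similarities, each softmax-normalized over node i's
in-neighborhood:

    α_ij = λ · softmax_j((W_Q h_j)·(W_K h_i)/√h1)
         + (1−λ) · softmax_j((W_Q^e e_ij)·(W_K^e e_ij)/√h1),  λ = 0.5

Messages m_ij = α_ij (W_v h_j + W_e e_ij) are summed and applied with a
residual: h_i ← LeakyReLU(W_out(h_i + Σ m)) + h_i. Setting λ = 1 or 0
reduces exactly to pure node- or edge-similarity attention (asserted in
tests). After the last layer the node state is concatenated with the
projected surface features and fused by a two-layer MLP
(h1+h2 → h1 → h1).

The drug encoder is a 3-layer message-passing network on the bond
graph: m_ij = LeakyReLU(W_u [h_j ∥ e_ij]), h_i ← W_C [h_i ∥ Σ m].

## Task heads

**Occurrence.** Both encodings are projected to h4 and exchanged
through dual multi-head cross-attention (4 scaled-dot-product heads,
concatenated and linearly projected) with residual layer-norm; each
modality then gates between its attended and original features,
g = σ([attended ∥ original]·W). Mean + max pooling over residues and
atoms gives modality vectors, refined by residual MLPs, joined as
z = [z_p ∥ z_d ∥ z_p⊙z_d ∥ z_p−z_d], and classified by a 4-layer MLP
(4h4 → 2h4 → h4 → h4/2 → 1) with layer normalization and dropout. The
single logit is squashed by a sigmoid — the two-class softmax with a
fixed zero reference. Pooling makes the probability invariant to
residue/atom ordering.

**Site.** Protein queries attend over drug keys/values (residual), a
residue self-attention follows, and a sigmoid gate fuses the two
streams; the per-residue probability is sigmoid(W_r z_i + MLP(z_i))
with MLP widths h5 → 2h5 → 1 (the fused residue embedding is the only
per-residue tensor in scope, so both terms read it). All stages are
equivariant to residue relabeling.

**Affinity.** Pocket and atom embeddings are projected to h6 and
refined by T = 3 typed graph-convolution layers on the interface
graph: node i attends over its cross-type neighbors with per-
neighborhood softmax scores (W_Q h_i)·(W_K [h_j ∥ e_ij])/√h6, and the
aggregated [neighbor ∥ edge] message is projected back to h6 by W_m
before the LeakyReLU update (the printed update adds tensors of
different widths; W_m reconciles them). Sum pooling gives u_p and u_d
— deliberately size-sensitive — and a softmax-normalized pairwise
attention over the hetero-graph's residue–atom pairs (configurable to
all pairs) builds a complex vector g; the regression head maps
[g ∥ u_d ∥ u_p] through 3h6 → 2h6 → 1 to a p-affinity. Before training,
the head's output bias is set to the mean training target so the first
epochs refine structure rather than traverse a constant offset.

Affinities pool Ki, Kd and IC50 measurements on the p-affinity scale
p = −log10(value / 1 M).

## Losses, metrics, training

Occurrence trains with binary cross-entropy, affinity with mean squared
error on p-affinity, and site with the focal loss
−α_t (1−p_t)^γ log p_t, γ = 2, α = 0.75 on the positive class. α > 0.5
up-weights the binding class, which is the rare one at residue level —
the curated complex corpus this package models contains ~134.9 k
binding versus ~6.49 M nonbinding residues, a 1:48 imbalance — so
pointing α at the majority class would defeat the loss's purpose.
Metrics are the field's standard set (MCC, F1, accuracy, specificity,
AUROC, AUPRC for classification; RMSE, MAE, Pearson, Spearman for
regression), computed through scikit-learn/SciPy and cross-checked in
tests against a brute-force pairwise-rank AUROC. Datasets split
7:1:2 by seeded permutation with rounding; training uses Adam at
lr 1e-3 (1e-4 converges for the classification heads but leaves the
affinity head short of the desk-scale recovery bar within 300 epochs),
per-sample steps, best-validation checkpointing, and early stopping
with patience 20 when a validation set is given. A global seed fans out
to initialization, shuffling, and dropout streams via `SeedSequence`.

All tensor arithmetic runs on a small in-package reverse-mode autodiff
engine over float64 NumPy arrays (`dtbind.autodiff`); every primitive
is gradient-checked against central finite differences, and fixed
seeds give bit-identical outputs on one platform.

## Synthetic fixtures: what they emulate

The generator plants recoverable statistical structure in data with
realistic shapes; it does not emulate binding physics. A toy protein is
an ideal α-helix (1.5 Å rise, 100° twist, 2.3 Å radius) with N/Cα/C
backbone atoms and a random 19-letter sequence (cysteine reserved,
below). A ligand from a fixed SMILES pool (5–20 atoms, half aromatic)
gets a seeded ETKDG conformer and is rigidly posed 2.5–5.5 Å off a
random helix face; that range makes the planted contact counts vary
over ~1–7 so the affinity rule has usable variance. Planted truths:

* **site** — residues with any atom within r_bind = 5 Å of any drug
  heavy atom. Site residues are marked with a cysteine SG atom (a
  distinctive chemical microenvironment, as real sites have), and four
  times as many isolated distractor residues receive the same marking
  away from the ligand, so chemistry alone cannot saturate the task and
  spatial contiguity matters. Labels are re-evaluated on the final
  structure.
* **affinity** — 4.0 + 0.3 × (contact count) + N(0, 0.1) p-affinity
  units; recoverable by regression on contact counts with R² > 0.9.
* **occurrence** — a pair binds iff its ligand is aromatic, learnable
  from the drug graph alone.

The stub sequence embedder hashes (letter, position) into 1024 values
in [−1, 1], weighted 0.8 toward a letter-identity component — like a
real language-model embedding it is dominated by residue identity with
positional variation, which is what lets any sequence-derived signal
transfer to held-out proteins. The imbalanced-site generator poses a
ligand on a long helix and trims to a contiguous window of
(ratio + 1) × contacts residues, giving an exact 1:48 residue class
ratio.

Passing the synthetic benchmarks therefore shows that the architecture
is wired correctly (invariances, equivariances, oracle equivalence),
that it can recover planted signals of each task's type at desk scale,
and nothing about accuracy on real proteins, which would require the
external corpora and a pretrained embedder.

## Verification problem sizes

The verification suite (`dtbind.verification`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 20 random
rigid transforms for the invariance checks; 8 complexes × 300 epochs at
hidden width 64 for the learnability runs; and for the focal-vs-BCE
comparison a fixed canonical dataset of 8 training and 16 held-out
1:48-imbalanced complexes, 40 epochs at width 32 without dropout, with
5 paired training seeds per loss. Widths are not pinned by the
architecture and were chosen so a full pass stays within minutes on one
CPU core; the package default is 128 throughout. The focal-vs-BCE
margin at this scale is small relative to run-to-run training noise, so
that comparison is the one verification result with a genuinely
stochastic outcome.

## Known limitations

* The local-frame construction and the surface pipeline are principled
  standard constructions (backbone Gram–Schmidt; union-of-balls +
  quadric-fit curvature); other choices exist and would change feature
  values but not the invariance guarantees.
* The shipped embedder is a hash stub: outputs have the right shape and
  determinism but no biology. Sequence-level transfer claims require a
  real protein language model behind the `SequenceEmbedder` interface.
* φ(d) underflows to exactly 0 beyond ~38 Å; pocket-centered graphs
  keep distances far below this.
* Multi-chain proteins are embedded per chain and concatenated in
  residue order; inter-chain context enters only through the geometric
  edges. Altloc handling keeps the highest-occupancy conformer ('A' on
  ties); only one model of multi-model files is read.
* Training is CPU-bound, full-batch-free and desk-scale; there is no
  GPU path, no hyperparameter search, and no uncertainty
  quantification.
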