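# Methods

## Problem and model

The package predicts drug–target binding affinity (DTA): given a small
molecule (SMILES) and a protein (sequence plus Cα coordinates), estimate a
continuous affinity label — pKd, a KIBA composite score, or a pIC50-derived
value — or, with the sigmoid head, an activity probability. The architecture
couples two graph encoders through a multimodal fusion head:

1. **Molecular graph.** Heavy atoms are nodes carrying provider-supplied
   embeddings (512-D for the reference atom embedder). Every covalent bond
   contributes two directed edges with a 6-D feature
   `[single, double, triple, aromatic, conjugated, π-environment]`.
   The first four bits are an exclusive bond-type one-hot; the π-environment
   flag is 1 when both endpoint atoms are sp²- or sp-hybridised. How a
   single "hybridization" dimension should be binarised is genuinely open;
   this bond-level flag was chosen because it is a single chemically
   meaningful bit that marks π-capable (aromatic/pharmacophoric) bond
   environments.
2. **Protein contact graph.** Residues are nodes carrying provider-supplied
   embeddings (2560-D reference). An edge joins residues *i ≠ j* whenever
   their Cα distance *d(i,j)* ≤ 8 Å (inclusive at the boundary), weighted
   1/d in Å⁻¹. The weight enters the attention score as a 1-D edge feature
   rather than scaling messages, so near residues are *prioritised* but do
   not linearly dampen information flow.
3. **Graph encoders.** Three GATv2 layers per side. For an edge *j → i*
   the attention score is
   `aᵀ LeakyReLU(W¹[hᵢ ∥ hⱼ ∥ e_ij] + b¹) / √d_k`
   with d_k the concatenated dimension, normalised by a softmax over each
   node's in-neighbourhood (self-loops added so isolated residues keep
   their state). An `as_printed_linear` score mode drops the LeakyReLU and
   the attention vector, leaving the plain linear form `(w¹ᵀ[hᵢ ∥ hⱼ ∥ e_ij]
   + b¹)/√d_k`; both modes are implemented and tested because the canonical
   GATv2 form is what makes attention *dynamic* while the linear form is
   the equation as printed in most compact write-ups. Messages are
   `h'ᵢ = σ(Σⱼ α_ij W² hⱼ)` with σ = ELU by default (ReLU available).
   Heads (4 by default) concatenate on layers 1–2 and average on layer 3;
   readout is a mean pool over nodes.
4. **Ablation variants.** `wo_MG`/`wo_PG` replace a graph encoder with the
   column mean of the provider's node embeddings (the embedder's
   sequence-level feature); `wo_MG_PG` replaces both; `wo_AM` swaps GATv2
   for symmetric-normalised GCN (no attention); `wo_DAM` swaps it for
   original GAT (static attention: the neighbour ranking cannot depend on
   the query node).
5. **Fusion and prediction.** The two graph-level vectors are projected to
   a shared width (d_model = 384), treated as a two-token sequence, mixed
   by 8-head scaled-dot-product self-attention, projected back, added
   residually and concatenated — 3072-D at reference widths. Self-attention
   over a single concatenated vector would be a softmax over one element,
   so the two-token scheme is the non-degenerate reading; a bypass flag
   recovers the plain concatenation. Prediction runs through fully
   connected layers 3072 → 1280 → 320 → 1 with batch normalisation
   (`(x−μ_B)/√(σ_B²+ε)·γ+β`, ε = 1e-5, running-stat momentum 0.1) and ReLU
   after the first two, then a linear (regression) or sigmoid
   (classification) output.

All tensors run on a compact in-repo reverse-mode autodiff engine over
NumPy float64 (`dualgraph_dta.autodiff`), gradient-checked against central
finite differences. Training is single-threaded and bitwise reproducible
for a fixed seed. Edge aggregation uses a sorted-segment `reduceat` fast
path that is tested to agree with the generic scatter-add ops exactly.

## Label conventions

`pkd_transform` follows the DeepDTA convention: Kd arrives in nM and
pKd = −log₁₀(Kd·10⁻⁹); Davis placeholder entries (Kd = 10 000 nM for
non-binders, pKd = 5.0) are kept. The KIBA filter retains records whose
target has ≥ 10 measurements; the symmetric per-drug rule is an option.
Cross-validation splits are record-level random (the benchmark protocol),
with grouped splitting deliberately out of scope.

rm² is the Roy & Roy external-validation metric
rm² = r²(1 − √|r² − r0²|), with r0² the through-origin coefficient of
determination of y on ŷ (slope k = Σyŷ/Σŷ²); the symmetric averaged variant
is available. Note that a pure positive rescaling of the predictions is
through-origin-perfect and leaves rm² = 1; the metric penalises additive
offsets and genuine scatter. The concordance index counts label-discordant
pairs ordered correctly, prediction ties at ½ (Gönen–Heller). Classification
metrics (ACC, AUC, BA, MCC, F1) use threshold 0.5; AUC is rank-based.

## Training protocol

Adam (lr 3e-3 default), mini-batches of 128, MSE loss (BCE for the sigmoid
head), early stopping on validation loss with patience 15, best-validation
checkpoint restored. Regression targets are standardised on the training
partition and predictions mapped back, so the output head does not have to
learn the label offset. Each distinct molecule/protein graph is encoded
once per forward pass and indexed per pair. 5-fold cross-validation holds
out each fold in turn and donates 10 % of the complement for early
stopping. Y-scrambling permutes the labels of the *entire* dataset (train,
validation and test alike) for each seed in 1..10 and reruns the identical
protocol. Hyperparameter search is a config-level concern; the `hpo_hook`
accepts a budget and search space but refuses to run trials.

## Synthetic benchmark

The generator produces a fully offline study substrate:

* **Molecules** are assembled from joinable SMILES fragments (aromatic
  rings plus aliphatic/unsaturated units); molecule *i* targets the
  (i mod 10)-th aromatic-fraction decile so aromatic content spans [0, 1]
  evenly.
* **Proteins** draw a per-protein hydrophobic-fraction target uniform in
  [0.1, 0.7] before sampling residues. Without this bias the hydrophobic
  fraction of a random sequence concentrates near its expectation
  (SD ≈ 0.06 at length 60) and the protein side would carry almost no
  signal variance. Lengths default to 40–120 residues.
* **Geometry** comes in three modes with exact 3.8 Å consecutive Cα
  spacing: a collinear ideal chain; an α-helix with 1.5 Å rise and
  100°/residue whose radius (≈ 2.28 Å) is solved from the spacing
  constraint; and a fixed-step self-avoiding random walk (minimum pairwise
  distance 3.0 Å, bounded retries). The random walk is the default because
  it yields contact graphs with irregular, protein-like degree variation.
* **Labels** follow a planted signal
  `raw = AromFrac + HydFrac + AromFrac·HydFrac + ε`, ε ~ N(0, 0.1²),
  affinely calibrated to a pKd-like range via `label = 4 + 2·raw`. The
  signal needs both modalities plus an interaction, so removing either
  graph branch measurably hurts; the label scale means default
  hyperparameters transfer to real pKd data.
* **Mock embedding providers** hash local chemical identity (atom:
  element/degree/aromaticity/charge; residue: identity with ±1 context)
  through SHA-256 into seeded unit-variance Gaussian vectors. Identical
  chemistry therefore always maps to identical features — the learning
  task is well-posed without pretrained weights — and distinct identities
  get near-orthogonal vectors.

What the synthetic substrate does *not* emulate: real binding physics,
conformational flexibility, 3-D pockets, assay noise structure, or the
label correlations of public benchmarks. Passing the validation suite
demonstrates that the architecture, training loop and evaluation machinery
are correct and that the model recovers a planted multimodal signal; it
does not certify benchmark-level accuracy, which requires the real
pretrained embedders and external datasets accessed through the provider
contracts.

## Problem sizes and numerical choices

Validation experiments run at reduced widths — 16-D atom and 32-D residue
embeddings, 16-D hidden layers, d_model 16, FCLs 48 → 32 → 16 → 1, n = 500
pairs (60 drugs × 25 proteins), 40 epochs — chosen so the full suite
(5-fold CV, four ablation variants × 5 seeds, 11 Y-scrambling runs)
completes on a single CPU core in well under an hour while leaving wide
margins on every directional comparison. The reference-width architecture
(512/2560-D, 3072 → 1280 → 320 → 1) is constructed and shape-checked in
the tests but not trained at that size.

Degenerate inputs are errors, not silent defaults: empty graphs, single-row
training batches (undefined batch variance), all-equal labels for CI,
zero-variance inputs for rm², single-class labels for AUC, non-positive Kd,
non-finite coordinates or fused features. Attention softmaxes subtract the
per-segment maximum before exponentiation; batch-norm eval mode uses
unbiased running variance; prediction ties in CI count ½; the contact-graph
cutoff is inclusive at exactly 8 Å.

## Known limitations

* No GPU path; reference-width *training* is out of reach of the NumPy
  engine (it is intended for the reduced configuration and for unit-scale
  checks of the reference shapes).
* Single-chain proteins only; no multi-chain complexes.
* The dictionary-lookup separation (GATv2 ≪ GAT/GCN in fit error) is a
  property of single attention layers on a synthetic family, not a claim
  about end-to-end benchmark gaps.
* `as_printed_linear` mode keeps √d_k scaling and softmax but, being
  query-independent inside the score, behaves like a static-attention
  variant; it exists for comparability, not as the recommended setting.
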