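# Methods

This note documents the models, the protocol, the synthetic data, and the
numerical choices the package makes, in the order a user meets them.

## Molecular graph representation

A molecule is a heavy-atom graph. Nodes carry a 46-slot feature vector built
from eight blocks, in fixed order: atom symbol (12 one-hot categories — C,
N, O, S, F, Si, P, Cl, Br, I, H, other), degree 0–6 (7), hybridization
sp/sp²/sp³/sp³d/sp³d² (5), implicit valence 0–6 (7), formal charge −1/0/+1
(3), membership in rings of size 3–8 (6), an aromaticity flag (1 integer
slot), and explicit-hydrogen count 0–4 (5). Edges are stored in directed COO
form with both directions of every chemical bond and no self-loops
(self-information enters through the layer update rules instead).

Choices where the representation is genuinely open:

- **Ring-size block is multi-hot.** An atom shared by a fused 5- and 6-ring
  sets both slots. Strict one-hot is ill-defined for fused-ring atoms; the
  other seven blocks remain exactly one-hot.
- **Hydrogens.** The graph is heavy-atom only; hydrogens appear through the
  explicit-H count feature. "H" stays in the symbol list for inputs that
  spell out hydrogen atoms.
- **Valence means implicit valence** (the implicit-H capacity RDKit
  reports), matching the feature's name in the schema.
- **Out-of-range categories.** In the default tolerant mode, ordinal values
  outside their block (degree/valence > 6, explicit-H > 4, |charge| > 1) are
  clamped to the nearest listed category, unlisted symbols fall into
  "other", and unlisted hybridizations (e.g. unhybridized halide ions) map
  to sp³. Strict mode raises instead. Tolerant keeps screening pipelines
  running on unusual inputs; strict is for dataset auditing.

## Layer operators

All four operators are pure functions of the node-feature matrix and the
edge list, with 64-bit arithmetic throughout.

- **GIN** — `h'_v = MLP((1+ε)·h_v + Σ_{u∈N(v)} h_u)`. The MLP is two affine
  layers with one ReLU between and hidden width equal to output width; ε is
  a trainable scalar initialized at 0. Isolated nodes aggregate a zero sum.
- **GAT** — scores `e_ij = LeakyReLU(a·[Wh_i ‖ Wh_j])` (negative slope 0.2),
  softmax-normalized over each target's neighborhood, output
  `σ(Σ_j α_ij W h_j)` with σ = ReLU. Self-loops are added before attention
  so every neighborhood is non-empty; a single attention head is the
  default. The softmax is max-shifted per target node for numerical
  stability (the shift is a constant per segment and does not affect the
  gradient).
- **ARMA** — the graph-convolutional-skip recursion
  `X̄^(t+1) = σ(L̃ X̄^(t) W^(t) + X V^(t))` with σ = ReLU, run for T steps in
  each of K parallel stacks and averaged. `L̃ = I − L_sym =
  D^{-1/2} A D^{-1/2}` is built from the graph without self-loops; isolated
  nodes receive a zero propagation term and keep the skip term. Defaults
  K = 1, T = 1; weights are per-step (shared weights can be emulated by
  passing the same parameter object).
- **SGC** — `S^K X W` with `S = D̃^{-1/2}(A+I)D̃^{-1/2}`. No softmax is
  applied: the task is regression and the fully connected head follows.
  Propagation depth defaults to K = 2, the depth the operator's reference
  construction uses; it is configurable (`sgc_k`).
- **Batch normalization** — per channel over all node rows of the minibatch:
  subtract the minibatch mean, divide by `sqrt(population variance + ε)`
  (ε = 1e-5), scale by γ and shift by β. Running statistics (momentum 0.1)
  are kept during training and used in evaluation mode, so a molecule's
  prediction does not depend on its batch companions at inference.

## Composite regressors

GIAN = GIN block → BN → ARMA block; GIAT = GIN block → BN → GAT block;
SGCA = SGC block → BN → ARMA block. Single-operator baselines (GIN, GAT,
ARMA, SGC) share the same head for comparison. Each architecture uses one
layer of each kind at hidden width 100. After the graph blocks, node
embeddings are sum-pooled per molecule (mean pooling is available; sum is
the default because it preserves count information, which matters for
activity models driven by substructure counts) and passed to the fixed head
100→200→300→200→1 with ReLU between the first three layers and no
activation on the last. Dropout acts on the ARMA block output (rate 0.35)
and the GAT block output (rate 0.06), in training mode only. Batch
normalization sits only between the two graph blocks, not inside the head.

## Training protocol

Mean-squared-error loss, Adam at learning rate 0.001, minibatches of 32
whole molecules, at most 1000 epochs. After every epoch the model is
evaluated on a validation set; if validation RMSE has not improved (strict
decrease by more than 1e-6) for 60 consecutive epochs, training stops and
the best-epoch parameter state is restored. During final fits the
validation set is a held-out 10% of the training partition; during
cross-validation the held-out fold plays that role. Labels are internally
standardized to the training set's mean and standard deviation — the
fitted affine transform is stored on the model and inverted at prediction
time, so every reported metric is on the pIC50 scale. Without this the
optimizer spends most of its budget learning the label offset (~4–8 pIC50
units) before any structure signal, and generalization suffers badly at
this learning rate.

Randomness is explicit: the model seed drives parameter initialization; the
train seed spawns two child streams (minibatch shuffling, dropout masks) via
`numpy.random.SeedSequence`. Identical seeds reproduce training histories
and predictions bit-for-bit on one platform.

Model selection uses 10-fold cross-validation: shuffled near-equal folds,
each validated exactly once, candidates compared on mean validation RMSE.

There is no GPU path; the autodiff engine is NumPy-only. On one CPU core a
200-molecule training run converges in seconds, and the full reference-scale
protocol (532 compounds, 3 seeds, 3 architectures) in tens of minutes.

## Descriptor QSAR pipeline

Fixed order: variance filter → standardize → Lasso selection → model fit,
with every transform fitted on training data only. The variance filter
keeps descriptors whose raw (pre-standardization) variance exceeds 0.01.
Standardization maps each kept descriptor to mean 0, variance 1. Lasso
selection fits an L1-penalized linear model; the penalty comes from an
internal 5-fold cross-validation over a logarithmic grid (1e-4…10), taking
the largest penalty within one standard error of the best mean CV error
(the one-standard-error rule) — the plain CV minimum systematically keeps
near-zero nuisance coefficients. Descriptors with exactly zero coefficient
are dropped. PCA projections (2–3 components with explained-variance
fractions) are a diagnostic for inspecting descriptor-space structure and
are not part of the modeling path.

The baselines use scikit-learn estimators at fixed hyperparameters: random
forest with 225 trees, all features considered at each split,
`min_samples_split=2`, `random_state=2`; support-vector regression with RBF
kernel, `tol=0.0017`, `epsilon=0.1`. The SVR's recorded `random_state` (55)
has no effect under the deterministic solver and is logged for fidelity
only. Computing the descriptors themselves is out of scope — the module
ingests any numeric descriptor CSV (rows with missing values are dropped
and logged).

## Consensus vote scoring

For each criterion column (docking score, each model's predicted pIC50) over
N candidates, let k = ceil(N/2). Every candidate whose score ties or beats
the k-th best receives one point; boundary ties are promoted together, so
the voted count can exceed k only through ties. A 0/1 multi-target flag —
an input, derived upstream from docking interaction networks — is added to
the row sum. The rule is translation-invariant and direction-symmetric
(negating scores and flipping `higher_is_better` changes nothing); all
bundled criteria are higher-is-better. For even N with ties exactly at the
boundary the promote-ties convention is the one consistent with the bundled
ten-candidate table, which exhibits a two-way tie at the cut.

## Synthetic data generator

The fixtures module emulates a small-molecule activity dataset without any
download. Molecules are generated from a fragment grammar: substituents
from a curated list (alkyl, ether, amine, halogen, nitrile, carboxylate,
ammonium, silyl, phosphine, …) grafted onto scaffold templates covering
ring sizes 3–8, aromatic heterocycles, a fused bicyclic, and open chains.
Every emitted string is RDKit-canonicalized and deduplicated, so validity
needs no repair pass. A fixed coverage library guarantees that ring sizes
3–8, the schema heteroatoms, and charges −1/0/+1 all appear regardless of
the random draw.

Labels follow `pIC50 = 4.0 + 0.4·(#N + #O) + 0.05·(#aromatic atoms) −
0.1·(#rings) + N(0, σ²)`. The defaults put labels in a realistic 4–6.5
pIC50 band with structure-driven spread of roughly half a log unit. The
standard test conditions are 200 molecules at σ = 0.2.

What this emulates — and what it does not: labels are an additive function
of substructure counts, which sum pooling can represent almost directly.
Passing the learnability tests therefore shows the pipeline can extract a
structure-determined signal at realistic noise, not that it matches
measured-inhibitor benchmarks; real structure–activity landscapes are
nonlinear, activity-cliffed, and assay-noisy in ways this generator does
not imitate. Conclusions about real datasets come only from running the
integration script on real data.

The descriptor-table generator emits the activity model's own structural
counts plus independent standard-normal decoy columns, giving the Lasso
recovery tests a known ground truth.

## Known limitations

- No edge features, 3D conformers, or stereochemistry descriptors; bond
  type never enters the representation.
- Single-head GAT by default; multi-head output averaging only.
- The NumPy training loop is single-threaded; wall-clock scales linearly
  with dataset size and epochs.
- The bundled screening table is an example input for the consensus ranker;
  docking scores and multi-target flags are always upstream inputs, never
  computed here.
- Checkpoints are npz archives tied to this package's parameter layout;
  they are versioned but not portable to other frameworks.
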