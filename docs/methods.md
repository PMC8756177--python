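# Methods

## Model

`gexgan` models the conditional distribution P(X = x | R = r, Q = q) of a
gene-expression profile x ∈ Rⁿ given k numeric covariates r and c
categorical covariates q. Two multilayer perceptrons play the WGAN-GP
game:

* **Generator** G_θ(z, r, q) = MLP(z ‖ r ‖ e^G): input is the
  concatenation of a latent vector z ~ N(0, I_u), the standardized numeric
  covariates, and the concatenated categorical embeddings
  e^G = ‖_j W_j^G q̄_j. Hidden layers use ReLU; the output layer is linear,
  so generated expression is unrestricted in range.
* **Critic** D_ω(x̄, r, q) = MLP(x̄ ‖ r ‖ e^D): same conditioning but an
  *independent* set of embedding tables, output a single unbounded realism
  scalar.

Losses per minibatch of size k (covariates of generated samples are always
the covariates of the paired real samples, i.e. sampled from the data
distribution):

* generator: −(1/k) Σ D_ω(x̂_i, r_i, q_i)
* critic: (1/k) Σ [D_ω(x̂_i) − D_ω(x_i)] + (λ/k) Σ (‖∇_{x̃_i} D_ω(x̃_i)‖₂ − 1)²,
  with x̃_i = α_i x_i + (1 − α_i) x̂_i, α_i ~ U(0, 1) fresh per batch
  element. The gradient is taken with respect to the interpolated
  expression only, never the covariates.

### Numpy implementation and the second-order term

Both players are plain numpy MLPs with hand-written backpropagation. The
gradient penalty needs the derivative of an input-gradient with respect to
the weights. For ReLU networks the input-gradient is piecewise linear in
the weights with the activation masks locally constant (ReLU curvature is
zero almost everywhere), so the second-order sweep reuses the first sweep's
backward deltas and accumulates exact penalty gradients; biases receive no
penalty gradient, and embeddings receive none either (they enter the
penalty only through masks). This matches what reverse-mode autodiff
computes for the same architecture; the test suite verifies both the
input-gradient and every penalty weight-gradient against central finite
differences (relative error < 1e-6 at h = 1e-5).

## Tunable parameters

| parameter | default | notes |
| --- | --- | --- |
| noise_dim u | 32 | latent dimensionality; prior N(0, I) (the standard WGAN-GP choice) |
| hidden_sizes | (128, 128) | two hidden layers; 128 units suit a bacterial-scale gene set, 256 a human-scale one; the bundled studies use (64, 64) at their 50-gene scale |
| embedding dims d_j | ⌊√v_j⌋ + 1 | per categorical covariate, overridable; a binary covariate gets 2 dims, a 15-level one 4 |
| learning_rate | 5e-4 | RMSProp, decay ρ = 0.9, ε = 1e-8 |
| gp_weight λ | 10 | gradient-penalty coefficient |
| batch_size k | 32 | |
| n_critic | 5 | critic updates per generator update |
| patience | 30 | epochs without validation improvement before stopping |
| validation_fraction | 0.1 | held-out split used only for the validation score |

Numeric covariates are standardized inside `fit` (mean/scale stored and
reused at sampling time). Expression is used at the scale supplied; the
intended workflow standardizes each gene to mean 0, sd 1 first
(`standard_score`), and the CLI does this by default.

### Validation score and early stopping

The validation score is S_dist between the held-out real split and a
generated set conditioned on that split's covariates, computed each epoch;
the returned model is the best-validation checkpoint, not the last. The
score is a natural choice because it is the same statistic the realism
evaluation optimizes for, but it is *unconditional*: it measures gene-gene
geometry pooled over covariates. At the bundled 50-gene study scale it
saturates within a few tens of epochs while covariate-conditional structure
(a planted disease shift) is still being learned, so the packaged scaled
study trains its full 300-epoch budget (patience = max_epochs) rather than
letting the saturated score halt training; the early-stopping machinery
itself is exercised by dedicated tests. On larger problems, where the
validation score keeps improving for much longer, the default patience of
30 behaves as intended.

## Synthetic data generator

The fixture model is a linear-Gaussian structural equation model (SEM),
*not* a kinetic simulator: its purpose is dependence structure that is
known in closed form, so metrics and the GAN can be validated exactly.

* **Network**: a two-level hierarchy — one master regulator feeding
  ~n/5 TFs (edge weights ±U(0.4, 0.9)), each TF regulating an equal share
  of the remaining genes (weights ±U(0.7, 1.3)). The shared root makes
  between-regulon correlations graded rather than uniformly ≈ 0, which is
  what real master-regulator hierarchies look like and what makes the gene
  dendrogram well determined: with isolated regulons all cross-regulon
  distances are ≈ 1 and the dendrogram of even a real replicate is
  noise-ordered, so dendrogram comparisons would measure nothing.
* **Equations**: parentless genes ~ N(shift, 1); each regulated gene is the
  weighted sum of its parents plus covariate shifts plus N(0, 0.5²) noise,
  evaluated in topological order.
* **Covariates**: age ~ N(50, 15) with a 0.01 slope on two genes, and a
  binary condition (p = 0.5) adding +3 (raw scale) to designated target
  genes in disease samples. After per-gene standardization this planted
  shift is ≈ 1.7 standard deviations, and *that* empirical standardized
  difference is the ground truth against which recovery is judged — the raw
  +3 has no meaning on the standardized scale the model is trained on.
* **Null baseline**: i.i.d. U(0, 1) matrices.

What the fixture does **not** emulate: heavy-tailed and count-valued
expression, nonlinear (saturating) regulation, combinatorial TF logic,
batch effects, measurement dropout. Passing tests therefore demonstrate
that the machinery is correct and that the GAN can learn linear-Gaussian
conditional structure at desk scale — not that it reproduces every property
of a particular RNA-seq compendium.

## Realism metrics: numerical choices

* Pearson dissimilarity is 1 − r (signed), not 1 − |r|: anticorrelated
  regulation is structure worth preserving, and the signed form maps
  perfect anticorrelation to the maximal distance 2.
* γ(A, B) is the Pearson correlation of the strict upper triangles; it is
  undefined (error) when a triangle is constant. Note γ is invariant to
  affine maps of either matrix — a candidate whose correlations are all
  shrunk by one common factor scores as well as the original. This is by
  design (the score targets *relative* geometry) but means uniform
  attenuation is invisible to S_dist.
* Dendrograms use scipy agglomerative clustering; linkage defaults to
  complete (average and single are available), and the dendrogram distance
  is the cophenetic merge height, which is ultrametric by construction.
* S_TG–TG averages the per-target cosine similarities within each regulon
  before the regulon-size-weighted average over TFs. A raw inner sum would
  exceed 1 for any TF with more than one target, making the score's scale
  depend on regulon sizes; the mean keeps every score in [−1, 1] and equal
  to 1 at identity.
* TFs absent from the expression matrix, or with fewer than 1 (TF–TG) / 2
  (TG–TG) usable targets, are excluded, and the weight normalization uses
  only included TFs.
* Zero-variance genes standardize to all-zero columns (warning, or error in
  strict mode) and take correlation 0 — distance 1 — to every other gene;
  this keeps the gene index aligned with the GRN rather than silently
  dropping columns.
* k-means cluster matching runs 10 seeded restarts per dataset and matches
  each real cluster to the synthetic cluster sharing most genes, ties to
  the lower index. Train-synthetic/test-real classification uses a 2×64
  ReLU MLP classifier, macro one-vs-rest AUC and macro F1 averaged over 5
  seeded runs by default.

## Counterfactual signatures

A counterfactual pair clamps (z, r, q) and toggles one categorical value;
per run a fresh z is drawn and, by default, the non-toggled covariates are
resampled from an empirical covariate table (clamping them instead is a
flag), so the signature marginalizes over the population while holding the
toggled factor as the only difference within each pair. The default 1000
runs give per-gene standard errors ~30× smaller than a single pair. Genes
are ranked by |mean Δ| with the signed mean reported; ties break
lexicographically so rankings are stable.

## Reproducibility

Every stochastic component takes an explicit seed and is a pure function of
(arguments, seed); training is exactly reproducible, and checkpoints
round-trip bit-exactly through a single `.npz` archive with an embedded
schema manifest (gene order, covariate vocabularies, architecture). CLI
subcommands write a manifest with the resolved configuration, seeds and
input checksums.

## Problem sizes of the bundled studies

The packaged experiments run at desk scale, chosen so the whole suite
completes in well under a minute of training: 50 genes × 2000 training /
2000 test samples for the fidelity-ordering and counterfactual studies
(2×64 hidden units, 300 epochs), 200 genes × 500 samples × 20 replicates
for the null baselines, and 15–30 gene fixtures for unit tests.

## Known limitations

* The generator is an MLP over a fixed gene panel; it does not scale to
  full transcriptomes without wider layers, and gene identity is positional
  (no transfer across panels).
* Wasserstein training on very small sample counts (hundreds) can
  mode-average; the realism scores will show it, but no warning is raised.
* S_dend compares a single dendrogram per dataset; for weakly structured
  data its value is noisy even between real replicates.
* The counterfactual ranking is causal only within the fitted model: it
  inherits every bias of the training data and of the fit, and is a
  hypothesis-generating tool, not evidence of biological causation.
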