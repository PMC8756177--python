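# gexgan

Conditional adversarial simulation of bulk gene-expression profiles, with a
realism-metric suite and a counterfactual differential-expression ranking
tool.

## The problem

Benchmarking transcriptomics methods — above all algorithms that reverse-
engineer gene regulatory networks (GRNs) — needs synthetic expression data,
but kinetic simulators built on Michaelis–Menten/Hill equations are known to
preserve the correlation structure of real expression data poorly. `gexgan`
takes the data-driven route: it learns the expression manifold directly from
a training dataset with a **conditional Wasserstein GAN with gradient
penalty (WGAN-GP)** and can then sample realistic profiles for arbitrary
combinations of sample covariates (age, sex, tissue, disease condition, …).

The generator maps a noise vector **z** ~ N(0, I) plus covariates to an
expression vector,

x̂ = G_θ(z, r, q) = MLP(z ‖ r ‖ e^G),

where **r** are numeric covariates and each categorical covariate q_j is
looked up in a learned embedding table, e_j = W_j q̄_j (q̄_j one-hot), with
d_j = ⌊√v_j⌋ + 1 embedding dimensions for a vocabulary of size v_j. The
critic D_ω(x̄, r, q) = MLP(x̄ ‖ r ‖ e^D) scores realism with its own
embeddings. Training solves

min_θ max_ω  E[D_ω(x, r, q)] − E[D_ω(x̂, r, q)] − λ·E[(‖∇_x̃ D_ω(x̃, r, q)‖₂ − 1)²],

with x̃ drawn uniformly on segments between real and generated samples
(λ = 10), using RMSProp (learning rate 5·10⁻⁴) and early stopping on a
validation realism score (patience 30 epochs). Both players are plain numpy
MLPs; all gradients, including the second-order gradient-penalty term, are
computed analytically and are verified against finite differences in the
test suite.

Realism of a candidate dataset **Z** against a reference **X** is scored
through gene-gene geometry, using γ(A, B) = Pearson correlation of the
strict upper triangles of two distance matrices:

* **S_dist** = γ(D^X, D^Z), where D_{ij} = 1 − corr(gene i, gene j);
* **S_dend** = γ(C(D^X), C(D^Z)), C = cophenetic matrix of the
  agglomerative dendrogram (complete linkage by default);
* **S_TF–TG** — regulon-size-weighted cosine similarity of TF→target
  distance vectors, given a known GRN;
* **S_TG–TG** — the same for within-regulon target–target distance vectors.

Finally, because a generated sample is fully determined by (z, r, q),
clamping everything and toggling one categorical covariate (e.g. condition
normal→disease) yields **counterfactual pairs**; averaging x̂_b − x̂_a over
many draws gives a per-gene differential-expression signature that is causal
*within the model*, and genes are ranked by its magnitude.

No external dataset is required: `gexgan.simulate` generates GRNs,
covariates and expression from a linear-Gaussian structural equation model
with planted covariate effects, so every claim is testable against known
ground truth.

## Worked example

Train on a 50-gene hierarchical SEM dataset (2000 samples) with an age
covariate and a binary condition covariate that shifts one target gene, then
evaluate on 2000 held-out samples:

```python
import numpy as np
from gexgan import (sem_fixture, standard_score, ExpressionWGAN,
                    realism_report, differential_signature, rank_genes)
from gexgan.containers import ExpressionMatrix

spec, covs, X, affected = sem_fixture(n_genes=50, m=4000, seed=11)
Xs = standard_score(X)
tr, te = np.arange(2000), np.arange(2000, 4000)
sub = lambda E, r: ExpressionMatrix(E.values[r], E.gene_ids,
                                    [E.sample_ids[i] for i in r])
X_train, X_test = sub(Xs, tr), sub(Xs, te)
c_train, c_test = covs.subset(tr), covs.subset(te)

model = ExpressionWGAN(hidden_sizes=(64, 64), max_epochs=300, patience=300,
                       random_state=101)
model.fit(X_train, c_train)

synthetic = model.sample(c_test, seed=77)       # one profile per test row
report = realism_report(X_test, synthetic, net=spec.grn)

sig = differential_signature(model, "condition", "normal", "disease",
                             c_train, n_runs=1000, seed=500)
print(rank_genes(sig, top=3).to_string(index=False))
```

Output (training takes ~10 s on one CPU core):

```
best validation S_dist: 0.9901 (epoch 134)
S_dist=0.9912  S_dend=0.9964  S_TF-TG=0.9993  S_TG-TG=0.9993
 rank gene  mean_delta  abs_delta   stderr
    1 G001    1.760332   1.760332 0.012952
    2 G021    0.260682   0.260682 0.010814
    3 G022   -0.216154   0.216154 0.008144
```

All four realism scores are near their maximum of 1: the generated data
reproduce the gene-gene distance matrix, the dendrogram, and the regulon
geometry of the held-out real data (uniform-random data scores ≈ 0 on the
first two). The counterfactual ranking puts `G001` — the gene whose
expression the simulator shifts in disease samples — first, and the
recovered mean difference (1.76, in per-gene standard-deviation units)
matches the shift actually present in the standardized training data
(≈ 1.7).

The same workflow is available from the shell:

```sh
gexgan simulate --n-genes 50 --n-samples 4000 --seed 11 --out-dir data/
gexgan train --expression data/expression.tsv --covariates data/covariates.tsv \
             --numeric age --categorical condition --hidden 64,64 --out model.npz
gexgan generate --checkpoint model.npz --covariates data/covariates.tsv \
                --seed 77 --out synthetic.tsv
gexgan evaluate --reference data/expression.tsv --candidate synthetic.tsv \
                --grn data/grn.tsv --out report.json
gexgan rank --checkpoint model.npz --covariates data/covariates.tsv \
            --toggle condition --from normal --to disease --out ranking.tsv
```

Every subcommand writes a JSON manifest (configuration, seeds, input
checksums) next to its output, so runs are reproducible bit for bit.

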