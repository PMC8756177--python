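"""Conditional WGAN-GP for bulk gene-expression profiles.

The generator maps ``noise || numeric covariates || categorical embeddings``
to an expression vector; the critic maps ``expression || numeric covariates
|| categorical embeddings`` to an unbounded realism scalar.  Each player
owns an independent set of per-covariate embedding tables.  Training
minimises the WGAN objective with a gradient penalty enforcing an
approximately 1-Lipschitz critic, using RMSProp and early stopping on a
validation realism score.
"""

from __future__ import annotations

import copy
import io
import json
import math
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .containers import CovariateTable, ExpressionMatrix

__all__ = [
    "ExpressionWGAN",
    "embedding_dim",
    "embed_categorical",
    "interpolate",
]


def embedding_dim(v_j: int) -> int:
    """Default embedding dimensionality for a vocabulary of size ``v_j``.

    Uses the square-root rule of thumb ``floor(sqrt(v_j)) + 1`` (so a
    2-level covariate gets 2 dimensions, a 15-level one gets 4).
    """
    if v_j < 1:
        raise ValueError(f"vocabulary size must be >= 1, got {v_j}")
    return int(math.isqrt(int(v_j))) + 1


def embed_categorical(q, tables) -> np.ndarray:
    """Concatenated embedding lookup.

    ``q`` holds one 0-based category index per covariate; ``tables[j]`` is a
    ``d_j x v_j`` matrix whose columns are the category vectors (the lookup
    is the one-hot matrix product ``W_j @ onehot(q_j)``, i.e. column
    selection).  Returns the length ``sum_j d_j`` concatenation.
    """
    q = np.atleast_1d(np.asarray(q, dtype=int))
    if len(q) != len(tables):
        raise ValueError(f"{len(q)} indices for {len(tables)} embedding tables")
    parts = []
    for j, (idx, W) in enumerate(zip(q, tables)):
        W = np.asarray(W, dtype=float)
        if not (0 <= idx < W.shape[1]):
            raise IndexError(
                f"covariate {j}: index {idx} outside vocabulary of size "
                f"{W.shape[1]}"
            )
        parts.append(W[:, idx])
    return np.concatenate(parts) if parts else np.empty(0)


def interpolate(x: np.ndarray, x_hat: np.ndarray, alpha) -> np.ndarray:
    """Componentwise convex combination ``alpha*x + (1-alpha)*x_hat``.

    ``alpha`` may be a scalar or one value per row (batch element).
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0.0) or np.any(alpha > 1.0):
        raise ValueError("interpolation coefficients must lie in [0, 1]")
    if alpha.ndim == 1 and x.ndim == 2:
        alpha = alpha[:, None]
    return alpha * x + (1.0 - alpha) * x_hat


class _Player:
    """One adversary: embedding tables (stored v_j x d_j, rows = categories)
    plus an MLP."""

    def __init__(self, emb: list[np.ndarray], Ws, bs):
        self.emb = emb
        self.Ws = Ws
        self.bs = bs

    @classmethod
    def create(cls, vocab_sizes, emb_dims, layer_sizes, rng):
        emb = [
            rng.normal(0.0, 0.1, size=(v, d))
            for v, d in zip(vocab_sizes, emb_dims)
        ]
        Ws, bs = _nn.init_mlp(layer_sizes, rng)
        return cls(emb, Ws, bs)

    def flat_params(self) -> list[np.ndarray]:
        return self.emb + self.Ws + self.bs

    def embed_rows(self, Q: np.ndarray) -> np.ndarray:
        """Batch embedding lookup: Q (batch, c) -> (batch, sum d_j)."""
        if not self.emb:
            return np.empty((Q.shape[0], 0))
        return np.concatenate(
            [E[Q[:, j]] for j, E in enumerate(self.emb)], axis=1
        )

    def scatter_embedding_grads(self, Q, d_emb_slice):
        """Accumulate input-gradient slices back into embedding tables."""
        grads = [np.zeros_like(E) for E in self.emb]
        off = 0
        for j, E in enumerate(self.emb):
            d = E.shape[1]
            np.add.at(grads[j], Q[:, j], d_emb_slice[:, off : off + d])
            off += d
        return grads


class ExpressionWGAN(BaseEstimator):
    """Conditional Wasserstein GAN with gradient penalty for expression data.

    Parameters
    ----------
    noise_dim : int
        Dimensionality ``u`` of the latent noise vector, drawn from a
        standard normal prior.
    hidden_sizes : tuple of int
        Hidden-layer widths shared by generator and critic (two layers of
        128 suit a bacterial-scale gene set; 256 a human-scale one).
    learning_rate : float
        RMSProp learning rate (default 0.0005).
    gp_weight : float
        Gradient-penalty coefficient lambda (default 10).
    batch_size : int
        Minibatch size ``k``.
    n_critic : int
        Critic updates per generator update.
    patience : int
        Early stopping: epochs without validation improvement before
        training halts (default 30).
    max_epochs : int
        Hard cap on epochs.
    validation_fraction : float
        Fraction of samples held out; the validation score is the distance-
        matrix realism score between the held-out data and samples generated
        under the held-out covariates.
    embedding_dims : dict or None
        Optional per-covariate override of the default embedding rule.
    rmsprop_rho, rmsprop_eps : float
        RMSProp decay and stabiliser.
    random_state : int or None
        Seed for initialisation, splitting, batching and noise.

    Attributes
    ----------
    gene_ids_ : list of str
        Gene order the model generates in.
    generator_, critic_ : _Player
        Fitted parameters (best-validation checkpoint).
    history_ : list of dict
        Per-epoch generator loss, critic loss and validation score.
    best_epoch_, best_score_ : early-stopping bookkeeping.
    """

    def __init__(
        self,
        noise_dim: int = 32,
        hidden_sizes: tuple = (128, 128),
        learning_rate: float = 5e-4,
        gp_weight: float = 10.0,
        batch_size: int = 32,
        n_critic: int = 5,
        patience: int = 30,
        max_epochs: int = 300,
        validation_fraction: float = 0.1,
        embedding_dims: dict | None = None,
        rmsprop_rho: float = 0.9,
        rmsprop_eps: float = 1e-8,
        random_state: int | None = None,
    ):
        self.noise_dim = noise_dim
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.gp_weight = gp_weight
        self.batch_size = batch_size
        self.n_critic = n_critic
        self.patience = patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.embedding_dims = embedding_dims
        self.rmsprop_rho = rmsprop_rho
        self.rmsprop_eps = rmsprop_eps
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    # conditioning helpers

    def _check_schema(self, covs: CovariateTable) -> None:
        if (
            list(covs.numeric_names) != self.numeric_names_
            or list(covs.categorical_names) != self.categorical_names_
            or covs.vocab_sizes() != self.vocab_sizes_
        ):
            raise ValueError(
                "covariate schema does not match the training schema "
                f"(expected numeric {self.numeric_names_}, categorical "
                f"{self.categorical_names_} with vocabulary sizes "
                f"{self.vocab_sizes_})"
            )

    def _standardize_numeric(self, R: np.ndarray) -> np.ndarray:
        if R.shape[1] == 0:
            return R
        return (R - self.numeric_mean_) / self.numeric_scale_

    def _gen_input(self, Z, R_std, Q) -> np.ndarray:
        return np.concatenate(
            [Z, R_std, self.generator_.embed_rows(Q)], axis=1
        )

    def _critic_input(self, Xb, R_std, Q) -> np.ndarray:
        return np.concatenate(
            [Xb, R_std, self.critic_.embed_rows(Q)], axis=1
        )

    def generator_forward(self, Z, R, Q) -> np.ndarray:
        """Raw generator pass (numeric covariates already on original scale)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        R = np.atleast_2d(np.asarray(R, dtype=float))
        Q = np.atleast_2d(np.asarray(Q, dtype=int))
        if Z.shape[1] != self.noise_dim:
            raise ValueError(
                f"noise width {Z.shape[1]} != noise_dim {self.noise_dim}"
            )
        if R.shape[1] != len(self.numeric_names_):
            raise ValueError("numeric covariate width mismatch")
        if Q.shape[1] != len(self.categorical_names_):
            raise ValueError("categorical covariate width mismatch")
        V = self._gen_input(Z, self._standardize_numeric(R), Q)
        out, _ = _nn.mlp_forward(self.generator_.Ws, self.generator_.bs, V)
        return out

    def critic_forward(self, Xb, R, Q) -> np.ndarray:
        """Critic realism scores for a batch, one unbounded scalar per row."""
        Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
        R = np.atleast_2d(np.asarray(R, dtype=float))
        Q = np.atleast_2d(np.asarray(Q, dtype=int))
        if Xb.shape[1] != self.n_genes_:
            raise ValueError(
                f"expression width {Xb.shape[1]} != n_genes {self.n_genes_}"
            )
        V = self._critic_input(Xb, self._standardize_numeric(R), Q)
        out, _ = _nn.mlp_forward(self.critic_.Ws, self.critic_.bs, V)
        return out[:, 0]

    # ------------------------------------------------------------------ #
    # losses (batch covariates already standardized internally)

    def _critic_scores(self, Xb, R_std, Q, player=None):
        player = player or self.critic_
        V = self._critic_input(Xb, R_std, Q)
        out, cache = _nn.mlp_forward(player.Ws, player.bs, V)
        return out[:, 0], cache

    def gradient_penalty(self, X_real, X_fake, R, Q, lam=None, alphas=None,
                         rng=None):
        """lambda * mean_i (||grad_x D(x~_i, r_i, q_i)||_2 - 1)^2.

        One fresh U(0,1) coefficient per batch element unless ``alphas`` is
        given; the gradient is taken with respect to the interpolated
        expression only, never the covariates.
        """
        lam = self.gp_weight if lam is None else lam
        if lam < 0:
            raise ValueError("gradient-penalty weight must be >= 0")
        X_real = np.atleast_2d(np.asarray(X_real, dtype=float))
        X_fake = np.atleast_2d(np.asarray(X_fake, dtype=float))
        k = X_real.shape[0]
        if k == 0:
            raise ValueError("empty batch")
        if alphas is None:
            rng = rng or np.random.default_rng()
            alphas = rng.random(k)
        X_tilde = interpolate(X_real, X_fake, alphas)
        R_std = self._standardize_numeric(
            np.atleast_2d(np.asarray(R, dtype=float))
        )
        Q = np.atleast_2d(np.asarray(Q, dtype=int))
        V = self._critic_input(X_tilde, R_std, Q)
        _, cache = _nn.mlp_forward(self.critic_.Ws, self.critic_.bs, V)
        _, deltas = _nn.input_gradient(self.critic_.Ws, self.critic_.bs, cache)
        penalty, _ = _nn.gradient_penalty_terms(
            self.critic_.Ws, cache, deltas, self.n_genes_, lam, k
        )
        return penalty

    def critic_loss(self, X_real, X_fake, R, Q, lam=None, alphas=None, rng=None):
        """mean D(fake) - mean D(real) + gradient penalty."""
        if np.atleast_2d(np.asarray(X_real)).shape[0] == 0:
            raise ValueError("empty batch")
        d_fake = self.critic_forward(X_fake, R, Q)
        d_real = self.critic_forward(X_real, R, Q)
        gp = self.gradient_penalty(X_real, X_fake, R, Q, lam=lam,
                                   alphas=alphas, rng=rng)
        return float(d_fake.mean() - d_real.mean() + gp)

    def generator_loss(self, X_fake, R, Q):
        """-mean D(fake): the generator maximises the critic's score."""
        X_fake = np.atleast_2d(np.asarray(X_fake, dtype=float))
        if X_fake.shape[0] == 0:
            raise ValueError("empty batch")
        return float(-self.critic_forward(X_fake, R, Q).mean())

    # ------------------------------------------------------------------ #
    # training

    def fit(self, X: ExpressionMatrix, covs: CovariateTable):
        """Train on an expression matrix with paired per-sample covariates.

        Expression is used at the scale supplied (standardize upstream for
        the usual workflow).  Returns ``self`` with the best-validation
        parameters installed.
        """
        if covs.n_samples != X.n_samples:
            raise ValueError(
                f"{covs.n_samples} covariate rows for {X.n_samples} samples"
            )
        if self.patience < 1 or self.batch_size < 1 or self.gp_weight < 0:
            raise ValueError("invalid training configuration")
        seed_seq = np.random.SeedSequence(self.random_state)
        rng_init, rng_split, rng_batch, rng_val = [
            np.random.default_rng(s) for s in seed_seq.spawn(4)
        ]

        self.gene_ids_ = list(X.gene_ids)
        self.n_genes_ = X.n_genes
        self.numeric_names_ = list(covs.numeric_names)
        self.categorical_names_ = list(covs.categorical_names)
        self.vocabularies_ = {
            k: list(v) for k, v in covs.vocabularies.items()
        }
        self.vocab_sizes_ = covs.vocab_sizes()
        override = self.embedding_dims or {}
        self.embedding_dims_ = [
            int(override.get(name, embedding_dim(v)))
            for name, v in zip(self.categorical_names_, self.vocab_sizes_)
        ]
        if covs.n_numeric:
            self.numeric_mean_ = covs.numeric.mean(axis=0)
            scale = covs.numeric.std(axis=0, ddof=0)
            self.numeric_scale_ = np.where(scale == 0.0, 1.0, scale)
        else:
            self.numeric_mean_ = np.empty(0)
            self.numeric_scale_ = np.empty(0)

        n = self.n_genes_
        k_num = covs.n_numeric
        d_total = sum(self.embedding_dims_)
        hidden = list(self.hidden_sizes)
        self.generator_ = _Player.create(
            self.vocab_sizes_, self.embedding_dims_,
            [self.noise_dim + k_num + d_total] + hidden + [n], rng_init,
        )
        self.critic_ = _Player.create(
            self.vocab_sizes_, self.embedding_dims_,
            [n + k_num + d_total] + hidden + [1], rng_init,
        )

        m = X.n_samples
        n_val = int(round(self.validation_fraction * m))
        if n_val < self.batch_size:
            raise ValueError(
                f"validation split of {n_val} samples is smaller than one "
                f"batch ({self.batch_size}); lower batch_size or raise "
                "validation_fraction"
            )
        perm = rng_split.permutation(m)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        X_all = X.values
        R_std_all = self._standardize_numeric(covs.numeric)
        Q_all = covs.categorical
        X_val = X_all[val_idx]
        R_val, Q_val = R_std_all[val_idx], Q_all[val_idx]

        opt_g = _nn.RMSProp(self.generator_.flat_params(),
                            self.learning_rate, self.rmsprop_rho,
                            self.rmsprop_eps)
        opt_d = _nn.RMSProp(self.critic_.flat_params(),
                            self.learning_rate, self.rmsprop_rho,
                            self.rmsprop_eps)

        self.history_ = []
        best_score, best_epoch = -np.inf, -1
        best_params = None
        wait = 0
        for epoch in range(self.max_epochs):
            order = rng_batch.permutation(len(train_idx))
            g_losses, d_losses = [], []
            n_batches = len(order) // self.batch_size
            for b in range(n_batches):
                idx = train_idx[order[b * self.batch_size:(b + 1) * self.batch_size]]
                Xb = X_all[idx]
                Rb, Qb = R_std_all[idx], Q_all[idx]
                d_losses.append(self._critic_step(Xb, Rb, Qb, opt_d, rng_batch))
                if (b + 1) % self.n_critic == 0:
                    g_losses.append(self._generator_step(Rb, Qb, opt_g, rng_batch))
            score = self._validation_score(X_val, R_val, Q_val, rng_val)
            self.history_.append({
                "epoch": epoch,
                "generator_loss": float(np.mean(g_losses)) if g_losses else np.nan,
                "critic_loss": float(np.mean(d_losses)) if d_losses else np.nan,
                "validation_score": score,
            })
            if score > best_score:
                best_score, best_epoch = score, epoch
                best_params = (
                    copy.deepcopy(self.generator_),
                    copy.deepcopy(self.critic_),
                )
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        self.generator_, self.critic_ = best_params
        self.best_epoch_ = best_epoch
        self.best_score_ = best_score
        self.n_iter_ = len(self.history_)
        return self

    def _critic_step(self, Xb, R_std, Qb, opt, rng) -> float:
        k = Xb.shape[0]
        n = self.n_genes_
        Z = rng.standard_normal((k, self.noise_dim))
        Vg = self._gen_input(Z, R_std, Qb)
        X_fake, _ = _nn.mlp_forward(self.generator_.Ws, self.generator_.bs, Vg)

        pl = self.critic_
        # main Wasserstein terms
        d_fake, cache_f = self._critic_scores(X_fake, R_std, Qb)
        dW_f, db_f, deltas_f = _nn.mlp_backward(
            pl.Ws, pl.bs, cache_f, np.full((k, 1), 1.0 / k)
        )
        d_real, cache_r = self._critic_scores(Xb, R_std, Qb)
        dW_r, db_r, deltas_r = _nn.mlp_backward(
            pl.Ws, pl.bs, cache_r, np.full((k, 1), -1.0 / k)
        )
        # gradient penalty at interpolates
        alphas = rng.random(k)
        X_tilde = interpolate(Xb, X_fake, alphas)
        V_t = self._critic_input(X_tilde, R_std, Qb)
        _, cache_t = _nn.mlp_forward(pl.Ws, pl.bs, V_t)
        _, deltas_t = _nn.input_gradient(pl.Ws, pl.bs, cache_t)
        penalty, dW_gp = _nn.gradient_penalty_terms(
            pl.Ws, cache_t, deltas_t, n, self.gp_weight, k
        )

        emb_width = V_t.shape[1] - n - R_std.shape[1]
        d_emb = (
            deltas_f[0][:, n + R_std.shape[1]:]
            + deltas_r[0][:, n + R_std.shape[1]:]
        ) if emb_width else np.empty((k, 0))
        emb_grads = pl.scatter_embedding_grads(Qb, d_emb)
        w_grads = [a + b + c for a, b, c in zip(dW_f, dW_r, dW_gp)]
        b_grads = [a + b for a, b in zip(db_f, db_r)]
        opt.step(emb_grads + w_grads + b_grads)
        return float(d_fake.mean() - d_real.mean() + penalty)

    def _generator_step(self, R_std, Qb, opt, rng) -> float:
        k = R_std.shape[0]
        n = self.n_genes_
        Z = rng.standard_normal((k, self.noise_dim))
        gp = self.generator_
        Vg = self._gen_input(Z, R_std, Qb)
        X_fake, cache_g = _nn.mlp_forward(gp.Ws, gp.bs, Vg)
        d_fake, cache_d = self._critic_scores(X_fake, R_std, Qb)
        # dL/dx_hat for L = -mean D(x_hat)
        _, _, deltas_d = _nn.mlp_backward(
            self.critic_.Ws, self.critic_.bs, cache_d,
            np.full((k, 1), -1.0 / k),
        )
        d_xhat = deltas_d[0][:, :n]
        dW_g, db_g, deltas_g = _nn.mlp_backward(gp.Ws, gp.bs, cache_g, d_xhat)
        d_emb = deltas_g[0][:, self.noise_dim + R_std.shape[1]:]
        emb_grads = gp.scatter_embedding_grads(Qb, d_emb)
        opt.step(emb_grads + dW_g + db_g)
        return float(-d_fake.mean())

    def _validation_score(self, X_val, R_val_std, Q_val, rng) -> float:
        from .metrics import pearson_dissimilarity_values, gamma_values

        Z = rng.standard_normal((X_val.shape[0], self.noise_dim))
        V = self._gen_input(Z, R_val_std, Q_val)
        X_gen, _ = _nn.mlp_forward(self.generator_.Ws, self.generator_.bs, V)
        try:
            return float(gamma_values(
                pearson_dissimilarity_values(X_val),
                pearson_dissimilarity_values(X_gen),
            ))
        except ValueError:
            return -np.inf  # degenerate generated data scores worst

    # ------------------------------------------------------------------ #
    # sampling & counterfactual access

    def sample(self, covs: CovariateTable, seed: int | None = None
               ) -> ExpressionMatrix:
        """Generate one expression profile per covariate row."""
        self._check_fitted()
        self._check_schema(covs)
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((covs.n_samples, self.noise_dim))
        values = self.generator_forward(Z, covs.numeric, covs.categorical)
        ids = covs.sample_ids or [f"gen{i + 1}" for i in range(covs.n_samples)]
        return ExpressionMatrix(values, list(self.gene_ids_), list(ids))

    def score(self, X: ExpressionMatrix, covs: CovariateTable,
              seed: int | None = 0) -> float:
        """Distance-matrix realism score of generated data against ``X``."""
        from .metrics import s_dist

        return s_dist(X, self.sample(covs, seed=seed))

    def _check_fitted(self) -> None:
        if not hasattr(self, "generator_"):
            raise RuntimeError("model is not fitted")

    # ------------------------------------------------------------------ #
    # persistence

    def save(self, path) -> None:
        """Write weights plus a schema manifest to a single .npz archive."""
        self._check_fitted()
        manifest = {
            "params": self.get_params(deep=False),
            "gene_ids": self.gene_ids_,
            "numeric_names": self.numeric_names_,
            "categorical_names": self.categorical_names_,
            "vocabularies": self.vocabularies_,
            "embedding_dims": self.embedding_dims_,
            "best_epoch": int(self.best_epoch_),
            "best_score": float(self.best_score_),
        }
        arrays = {
            "numeric_mean": self.numeric_mean_,
            "numeric_scale": self.numeric_scale_,
        }
        for tag, player in (("G", self.generator_), ("D", self.critic_)):
            for j, E in enumerate(player.emb):
                arrays[f"{tag}_emb{j}"] = E
            for l, (W, b) in enumerate(zip(player.Ws, player.bs)):
                arrays[f"{tag}_W{l}"] = W
                arrays[f"{tag}_b{l}"] = b
        manifest["n_layers"] = len(self.generator_.Ws)
        buf = io.BytesIO()
        np.savez(buf, manifest=np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8), **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path) -> "ExpressionWGAN":
        with np.load(path) as data:
            manifest = json.loads(bytes(data["manifest"]).decode())
            model = cls(**{
                k: (tuple(v) if k == "hidden_sizes" and isinstance(v, list)
                    else v)
                for k, v in manifest["params"].items()
            })
            model.gene_ids_ = manifest["gene_ids"]
            model.n_genes_ = len(model.gene_ids_)
            model.numeric_names_ = manifest["numeric_names"]
            model.categorical_names_ = manifest["categorical_names"]
            model.vocabularies_ = manifest["vocabularies"]
            model.vocab_sizes_ = [
                len(model.vocabularies_[c]) for c in model.categorical_names_
            ]
            model.embedding_dims_ = manifest["embedding_dims"]
            model.best_epoch_ = manifest["best_epoch"]
            model.best_score_ = manifest["best_score"]
            model.history_ = []
            model.n_iter_ = 0
            model.numeric_mean_ = data["numeric_mean"]
            model.numeric_scale_ = data["numeric_scale"]
            n_layers = manifest["n_layers"]
            players = {}
            for tag in ("G", "D"):
                emb = [
                    data[f"{tag}_emb{j}"]
                    for j in range(len(model.categorical_names_))
                ]
                Ws = [data[f"{tag}_W{l}"] for l in range(n_layers)]
                bs = [data[f"{tag}_b{l}"] for l in range(n_layers)]
                players[tag] = _Player(emb, Ws, bs)
            model.generator_ = players["G"]
            model.critic_ = players["D"]
        return model
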