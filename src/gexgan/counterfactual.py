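"""Counterfactual differential-expression signatures.

A fitted conditional generator determines a sample's expression entirely
from its latent noise and covariates.  Clamping the noise and all covariates
while toggling a single categorical covariate (e.g. condition
normal -> disease) yields a *counterfactual pair*: two profiles for the same
synthetic individual that differ only in the toggled factor.  Averaging the
paired differences over many draws gives a differential-expression
signature that is causal *within the model*: every other determinant of
expression is held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CovariateTable
from .gan import ExpressionWGAN

__all__ = [
    "DifferentialSignature",
    "paired_counterfactual",
    "differential_signature",
    "rank_genes",
]


@dataclass
class DifferentialSignature:
    """Per-gene mean counterfactual expression difference (b minus a)."""

    gene_ids: list[str]
    mean_delta: np.ndarray
    stderr: np.ndarray
    n_runs: int
    toggled_covariate: str
    value_a: str
    value_b: str
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_delta = np.asarray(self.mean_delta, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if len(self.gene_ids) != len(self.mean_delta):
            raise ValueError("mean_delta length must match gene count")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def _covariate_indices(model: ExpressionWGAN, toggle: str,
                       value_a: str, value_b: str) -> tuple[int, int, int]:
    if toggle not in model.categorical_names_:
        raise KeyError(
            f"{toggle!r} is not a categorical covariate of the model "
            f"(has {model.categorical_names_})"
        )
    j = model.categorical_names_.index(toggle)
    vocab = model.vocabularies_[toggle]
    for v in (value_a, value_b):
        if v not in vocab:
            raise KeyError(f"value {v!r} not in vocabulary {vocab} of {toggle!r}")
    if value_a == value_b:
        raise ValueError("the two toggled values must differ")
    return j, vocab.index(value_a), vocab.index(value_b)


def paired_counterfactual(
    model: ExpressionWGAN,
    z: np.ndarray,
    r: np.ndarray,
    q: np.ndarray,
    toggle: str,
    value_a: str,
    value_b: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a counterfactual pair sharing (z, r, q) except one toggle.

    Returns ``(x_a, x_b)``; any difference between them is attributable
    solely to the toggled covariate.
    """
    model._check_fitted()
    j, ia, ib = _covariate_indices(model, toggle, value_a, value_b)
    q = np.asarray(q, dtype=int).copy()
    q_a, q_b = q.copy(), q.copy()
    q_a[..., j] = ia
    q_b[..., j] = ib
    x_a = model.generator_forward(z, r, q_a)
    x_b = model.generator_forward(z, r, q_b)
    return np.squeeze(x_a), np.squeeze(x_b)


def differential_signature(
    model: ExpressionWGAN,
    toggle: str,
    value_a: str,
    value_b: str,
    covariates: CovariateTable,
    context: dict | None = None,
    n_runs: int = 1000,
    seed: int | None = 0,
    resample_unclamped: bool = True,
) -> DifferentialSignature:
    """Average counterfactual differences over many latent draws.

    Per run a fresh latent vector is drawn and, unless
    ``resample_unclamped=False``, the non-toggled covariates are resampled
    from rows of the supplied empirical ``covariates`` table; covariates
    named in ``context`` are clamped to fixed values throughout (categorical
    values given as labels, numeric as floats).
    """
    model._check_fitted()
    model._check_schema(covariates)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    j, ia, ib = _covariate_indices(model, toggle, value_a, value_b)
    context = dict(context or {})
    rng = np.random.default_rng(seed)

    m = covariates.n_samples
    if resample_unclamped:
        rows = rng.integers(0, m, size=n_runs)
    else:
        rows = np.full(n_runs, int(rng.integers(0, m)))
    R = covariates.numeric[rows].copy()
    Q = covariates.categorical[rows].copy()
    for name, value in context.items():
        if name in covariates.numeric_names:
            R[:, covariates.numeric_names.index(name)] = float(value)
        elif name in covariates.categorical_names:
            cj = covariates.categorical_names.index(name)
            vocab = covariates.vocabularies[name]
            if str(value) not in vocab:
                raise KeyError(
                    f"context value {value!r} not in vocabulary of {name!r}"
                )
            Q[:, cj] = vocab.index(str(value))
        else:
            raise KeyError(f"unknown context covariate {name!r}")

    Z = rng.standard_normal((n_runs, model.noise_dim))
    Q_a, Q_b = Q.copy(), Q.copy()
    Q_a[:, j] = ia
    Q_b[:, j] = ib
    x_a = model.generator_forward(Z, R, Q_a)
    x_b = model.generator_forward(Z, R, Q_b)
    delta = x_b - x_a
    mean = delta.mean(axis=0)
    if n_runs > 1:
        stderr = delta.std(axis=0, ddof=1) / np.sqrt(n_runs)
    else:
        stderr = np.full(delta.shape[1], np.nan)
    return DifferentialSignature(
        gene_ids=list(model.gene_ids_),
        mean_delta=mean,
        stderr=stderr,
        n_runs=n_runs,
        toggled_covariate=toggle,
        value_a=value_a,
        value_b=value_b,
        context={
            "clamped": context,
            "resample_unclamped": resample_unclamped,
        },
    )


def rank_genes(sig: DifferentialSignature, top: int | None = None
               ) -> pd.DataFrame:
    """Rank genes by the magnitude of their mean counterfactual difference.

    Ties in |mean delta| break lexicographically on gene id; the signed mean
    and its standard error are reported alongside.
    """
    n = len(sig.gene_ids)
    if top is None:
        top = n
    if top > n:
        raise ValueError(f"top={top} exceeds the {n} genes")
    order = sorted(
        range(n), key=lambda i: (-abs(sig.mean_delta[i]), sig.gene_ids[i])
    )[:top]
    return pd.DataFrame({
        "rank": np.arange(1, top + 1),
        "gene": [sig.gene_ids[i] for i in order],
        "mean_delta": sig.mean_delta[order],
        "abs_delta": np.abs(sig.mean_delta[order]),
        "stderr": sig.stderr[order],
    })
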