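import numpy as np
import pytest

from gexgan import (
    CovariateTable,
    ExpressionMatrix,
    ExpressionWGAN,
    sem_fixture,
    standard_score,
)


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        rng.normal(size=(40, 8)),
        [f"g{j}" for j in range(8)],
        [f"s{i}" for i in range(40)],
    )


@pytest.fixture
def sem_small():
    """A 20-gene SEM dataset with its spec, covariates and affected genes."""
    spec, covs, X, affected = sem_fixture(n_genes=20, m=400, seed=3)
    return spec, covs, standard_score(X), affected


@pytest.fixture(scope="session")
def tiny_gan():
    """A quickly-trained small model for unit tests of sampling,
    persistence and counterfactuals (not for realism claims)."""
    spec, covs, X, affected = sem_fixture(n_genes=15, m=400, seed=5)
    Xs = standard_score(X)
    model = ExpressionWGAN(
        hidden_sizes=(16, 16),
        batch_size=16,
        max_epochs=15,
        patience=15,
        noise_dim=8,
        random_state=0,
    )
    model.fit(Xs, covs)
    return {
        "model": model,
        "spec": spec,
        "covs": covs,
        "X": Xs,
        "affected": affected,
    }


def subset_expression(X: ExpressionMatrix, rows) -> ExpressionMatrix:
    rows = np.asarray(rows)
    return ExpressionMatrix(
        X.values[rows], list(X.gene_ids), [X.sample_ids[i] for i in rows]
    )


@pytest.fixture(scope="session")
def trained_study():
    """The scaled conditional study: a WGAN-GP trained on the hierarchical
    SEM fixture (50 genes, 2000 training samples, 2x64 hidden units), with
    an independent 2000-sample test split.

    The distance-matrix validation score saturates early at this scale while
    the conditional effect is still being learned, so the study trains its
    full epoch budget; early-stopping behaviour is exercised elsewhere.
    """
    spec, covs, X, affected = sem_fixture(n_genes=50, m=4000, seed=11)
    Xs = standard_score(X)
    tr, te = np.arange(2000), np.arange(2000, 4000)
    Xtr, Xte = subset_expression(Xs, tr), subset_expression(Xs, te)
    ctr, cte = covs.subset(tr), covs.subset(te)
    model = ExpressionWGAN(
        hidden_sizes=(64, 64),
        max_epochs=300,
        patience=300,
        random_state=101,
    )
    model.fit(Xtr, ctr)
    gene = affected[0]
    j = Xs.gene_ids.index(gene)
    cond = np.asarray(ctr.labels("condition"))
    delta_true = float(
        Xtr.values[cond == "disease", j].mean()
        - Xtr.values[cond == "normal", j].mean()
    )
    return {
        "model": model,
        "spec": spec,
        "X_train": Xtr,
        "X_test": Xte,
        "covs_train": ctr,
        "covs_test": cte,
        "affected": affected,
        "delta_true": delta_true,
    }


@pytest.fixture
def toy_covariates() -> CovariateTable:
    return CovariateTable(
        numeric=np.array([[30.0], [40.0], [50.0], [60.0]]),
        numeric_names=["age"],
        categorical=np.array([[0, 0], [1, 0], [0, 1], [1, 1]]),
        categorical_names=["sex", "condition"],
        vocabularies={
            "sex": ["female", "male"],
            "condition": ["normal", "disease"],
        },
        sample_ids=["s1", "s2", "s3", "s4"],
    )
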