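"""Realism metrics for synthetic expression data.

A candidate dataset Z is compared to a reference dataset X through the
geometry of its gene-gene relationships:

* ``s_dist`` — correlation (gamma) of the two Pearson-dissimilarity
  matrices: do pairwise gene distances agree?
* ``s_dend`` — gamma of the cophenetic matrices of the two dendrograms
  obtained by agglomerative clustering: do the *cluster structures* agree?
* ``s_tf_tg`` — GRN-aware: cosine similarity of TF-to-target distance
  vectors, weighted by regulon size.
* ``s_tg_tg`` — GRN-aware: cosine similarity of within-regulon
  target-target distance vectors, weighted by regulon size.

All scores live in [-1, 1] and equal 1 when Z == X.  Also provided:
k-means cluster matching between datasets and train-synthetic/test-real
classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.neural_network import MLPClassifier

from .containers import ExpressionMatrix, RegulatoryNetwork

__all__ = [
    "DistanceMatrix",
    "RealismReport",
    "pearson_dissimilarity_matrix",
    "gamma",
    "s_dist",
    "dendrogram_distance_matrix",
    "s_dend",
    "cosine_similarity",
    "tf_tg_vector",
    "s_tf_tg",
    "s_tg_tg",
    "realism_report",
    "cluster_match",
    "tstr_classification",
]

LINKAGES = ("complete", "average", "single")


@dataclass
class DistanceMatrix:
    """A symmetric gene-gene distance matrix with gene identifiers."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.gene_ids) != n:
            raise ValueError("gene id count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix has non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("distance matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def entry(self, gene_a: str, gene_b: str) -> float:
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        return float(self.values[idx[gene_a], idx[gene_b]])


# --------------------------------------------------------------------- #
# value-level helpers (ndarray in / ndarray out), reused in the GAN's
# validation loop where container overhead matters

def pearson_dissimilarity_values(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between all column pairs; zero diagonal.

    Columns with zero variance get correlation 0 (distance 1) against
    everything, with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples per gene")
    centered = values - values.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    flat = norms == 0.0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s): correlations set to 0",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(flat, 1.0, norms)
    corr = (centered / safe).T @ (centered / safe)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def gamma_values(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of the strict upper triangles of A and B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("gamma needs two square matrices of the same size")
    iu = np.triu_indices(A.shape[0], k=1)
    a, b = A[iu], B[iu]
    for name, v in (("first", a), ("second", b)):
        if np.std(v) == 0.0:
            raise ValueError(
                f"gamma undefined: the {name} matrix has a constant "
                "upper triangle"
            )
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    return float(np.clip((a * b).mean(), -1.0, 1.0))


# --------------------------------------------------------------------- #
# container-level API

def pearson_dissimilarity_matrix(X: ExpressionMatrix) -> DistanceMatrix:
    """Gene-gene Pearson dissimilarity (1 - r) of an expression matrix."""
    return DistanceMatrix(
        pearson_dissimilarity_values(X.values), list(X.gene_ids)
    )


def gamma(A: DistanceMatrix, B: DistanceMatrix) -> float:
    """Correlation of two distance matrices over their upper triangles."""
    if A.gene_ids != B.gene_ids:
        raise ValueError("distance matrices must share gene order")
    return gamma_values(A.values, B.values)


def _align(X: ExpressionMatrix, Z: ExpressionMatrix) -> ExpressionMatrix:
    """Reorder Z's genes to X's order; gene-set mismatch is an error."""
    sx, sz = set(X.gene_ids), set(Z.gene_ids)
    if sx != sz:
        diff = sorted(sx.symmetric_difference(sz))
        raise ValueError(f"gene sets differ; symmetric difference: {diff}")
    return Z.reorder_genes(X.gene_ids)


def s_dist(X: ExpressionMatrix, Z: ExpressionMatrix) -> float:
    """Distance-matrix realism score: gamma of the dissimilarity matrices."""
    Z = _align(X, Z)
    return gamma_values(
        pearson_dissimilarity_values(X.values),
        pearson_dissimilarity_values(Z.values),
    )


def dendrogram_distance_matrix(
    D: DistanceMatrix, linkage: str = "complete"
) -> DistanceMatrix:
    """Cophenetic distances of the agglomerative dendrogram built on ``D``.

    Entry (i, j) is the merge height of the smallest cluster containing both
    genes; the result is ultrametric.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if D.n < 2:
        raise ValueError("dendrogram needs at least 2 genes")
    merge = scipy_linkage(squareform(D.values, checks=False), method=linkage)
    coph = squareform(cophenet(merge))
    return DistanceMatrix(coph, list(D.gene_ids))


def s_dend(
    X: ExpressionMatrix, Z: ExpressionMatrix, linkage: str = "complete"
) -> float:
    """Dendrogram realism score: gamma of the two cophenetic matrices."""
    Z = _align(X, Z)
    cx = dendrogram_distance_matrix(
        DistanceMatrix(pearson_dissimilarity_values(X.values), list(X.gene_ids)),
        linkage,
    )
    cz = dendrogram_distance_matrix(
        DistanceMatrix(pearson_dissimilarity_values(Z.values), list(Z.gene_ids)),
        linkage,
    )
    return gamma_values(cx.values, cz.values)


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ValueError("cosine similarity needs two equal-length vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def tf_tg_vector(
    D: DistanceMatrix, tf: str, net: RegulatoryNetwork
) -> np.ndarray:
    """Distances from a TF to each of its targets, targets in lexicographic
    order."""
    if tf not in net.tf_set:
        raise KeyError(f"{tf!r} is not a TF of the network")
    idx = {g: j for j, g in enumerate(D.gene_ids)}
    targets = sorted(net.targets(tf))
    missing = [g for g in [tf] + targets if g not in idx]
    if missing:
        raise KeyError(f"genes absent from the distance matrix: {missing}")
    f = idx[tf]
    return D.values[f, [idx[g] for g in targets]].copy()


def _eligible_tfs(
    net: RegulatoryNetwork, gene_ids: set[str], min_targets: int
) -> list[tuple[str, list[str]]]:
    out = []
    for tf in sorted(net.tf_set):
        if tf not in gene_ids:
            continue
        targets = sorted(t for t in net.targets(tf) if t in gene_ids)
        if len(targets) >= min_targets:
            out.append((tf, targets))
    return out


def s_tf_tg(
    X: ExpressionMatrix, Z: ExpressionMatrix, net: RegulatoryNetwork
) -> float:
    """Regulon-size-weighted cosine similarity of TF-target distance vectors.

    TFs missing from the data, or with no measured target, are excluded
    (and excluded from the weight normalisation).
    """
    Z = _align(X, Z)
    dx = pearson_dissimilarity_values(X.values)
    dz = pearson_dissimilarity_values(Z.values)
    idx = {g: j for j, g in enumerate(X.gene_ids)}
    eligible = _eligible_tfs(net, set(X.gene_ids), min_targets=1)
    if not eligible:
        raise ValueError("no TF with measurable targets in both datasets")
    num = den = 0.0
    for tf, targets in eligible:
        f = idx[tf]
        cols = [idx[g] for g in targets]
        w = float(len(targets))
        num += w * cosine_similarity(dx[f, cols], dz[f, cols])
        den += w
    return float(np.clip(num / den, -1.0, 1.0))


def s_tg_tg(
    X: ExpressionMatrix, Z: ExpressionMatrix, net: RegulatoryNetwork
) -> float:
    """Regulon-size-weighted score of within-regulon target geometry.

    For each TF f and each target g, compare the vector of distances from g
    to the other targets of f between the two datasets; average the cosine
    similarities over g (keeping the score in [-1, 1]), then weight TFs by
    regulon size.  Only TFs with at least two measured targets participate.
    """
    Z = _align(X, Z)
    dx = pearson_dissimilarity_values(X.values)
    dz = pearson_dissimilarity_values(Z.values)
    idx = {g: j for j, g in enumerate(X.gene_ids)}
    eligible = _eligible_tfs(net, set(X.gene_ids), min_targets=2)
    if not eligible:
        raise ValueError("no TF with >= 2 measurable targets")
    num = den = 0.0
    for _tf, targets in eligible:
        cols = [idx[g] for g in targets]
        w = float(len(targets))
        sims = []
        for gi, g in enumerate(cols):
            others = cols[:gi] + cols[gi + 1:]
            sims.append(cosine_similarity(dx[g, others], dz[g, others]))
        num += w * float(np.mean(sims))
        den += w
    return float(np.clip(num / den, -1.0, 1.0))


@dataclass
class RealismReport:
    """The four realism scores for one (reference, candidate) pair."""

    s_dist: float
    s_dend: float
    s_tf_tg: float | None = None
    s_tg_tg: float | None = None
    parameters: dict = field(default_factory=dict)

    COLUMNS = ("s_dist", "s_dend", "s_tf_tg", "s_tg_tg")

    def to_dict(self) -> dict:
        return {
            "s_dist": self.s_dist,
            "s_dend": self.s_dend,
            "s_tf_tg": self.s_tf_tg,
            "s_tg_tg": self.s_tg_tg,
            "parameters": dict(self.parameters),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RealismReport":
        d = json.loads(text)
        return cls(
            s_dist=d["s_dist"],
            s_dend=d["s_dend"],
            s_tf_tg=d.get("s_tf_tg"),
            s_tg_tg=d.get("s_tg_tg"),
            parameters=d.get("parameters", {}),
        )

    def to_tsv(self) -> str:
        header = "\t".join(self.COLUMNS)
        fmt = lambda v: "NA" if v is None else f"{v:.6f}"  # noqa: E731
        row = "\t".join(fmt(getattr(self, c)) for c in self.COLUMNS)
        return f"{header}\n{row}\n"


def realism_report(
    X: ExpressionMatrix,
    Z: ExpressionMatrix,
    net: RegulatoryNetwork | None = None,
    linkage: str = "complete",
) -> RealismReport:
    """Compute all applicable realism scores for a candidate dataset."""
    report = RealismReport(
        s_dist=s_dist(X, Z),
        s_dend=s_dend(X, Z, linkage=linkage),
        parameters={
            "distance": "pearson_dissimilarity",
            "linkage": linkage,
            "tf_weight": "regulon_size",
        },
    )
    if net is not None:
        report.s_tf_tg = s_tf_tg(X, Z, net)
        report.s_tg_tg = s_tg_tg(X, Z, net)
    return report


def cluster_match(
    X: ExpressionMatrix,
    Z: ExpressionMatrix,
    k: int = 10,
    seed: int | None = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Match k-means gene clusters between a real and a synthetic dataset.

    Genes are clustered by their expression profiles (each gene's feature
    vector is its column across samples), separately in each dataset; each
    real cluster is matched to the synthetic cluster sharing the most genes
    (ties to the lower synthetic cluster index).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.n_genes:
        raise ValueError(f"k={k} exceeds the {X.n_genes} genes")
    Z = _align(X, Z)
    km_x = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km_z = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    lab_x = km_x.fit_predict(X.values.T)
    lab_z = km_z.fit_predict(Z.values.T)
    genes = np.asarray(X.gene_ids)
    rows = []
    for c in range(k):
        members = set(genes[lab_x == c])
        shared = np.array([
            len(members & set(genes[lab_z == cz])) for cz in range(k)
        ])
        best = int(np.argmax(shared))  # argmax takes the lowest index on ties
        rows.append({
            "real_cluster": c,
            "real_size": int((lab_x == c).sum()),
            "matched_synthetic_cluster": best,
            "matched_size": int((lab_z == best).sum()),
            "shared_genes": int(shared[best]),
        })
    return pd.DataFrame(rows)


def tstr_classification(
    Z_train: ExpressionMatrix,
    train_labels,
    X_test: ExpressionMatrix,
    test_labels,
    n_runs: int = 5,
    seed: int = 0,
    max_iter: int = 300,
) -> dict:
    """Train-synthetic / test-real classification.

    Fits a feed-forward classifier (two hidden layers of 64 ReLU units) on
    the synthetic data and evaluates on real data, reporting macro one-vs-
    rest AUC and macro F1 averaged over ``n_runs`` seeded runs.
    """
    Z_train = _align(X_test, Z_train)
    y_train = np.asarray(train_labels)
    y_test = np.asarray(test_labels)
    if len(y_train) != Z_train.n_samples or len(y_test) != X_test.n_samples:
        raise ValueError("label lengths must match the sample counts")
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if set(np.unique(y_test)) - set(classes):
        raise ValueError("test labels outside the training vocabulary")
    aucs, f1s = [], []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_runs):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        clf = MLPClassifier(
            hidden_layer_sizes=(64, 64),
            activation="relu",
            random_state=run_seed,
            max_iter=max_iter,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter
            clf.fit(Z_train.values, y_train)
        proba = clf.predict_proba(X_test.values)
        if len(classes) == 2:
            auc = roc_auc_score(y_test, proba[:, list(clf.classes_).index(classes[1])])
        else:
            auc = roc_auc_score(
                y_test, proba, multi_class="ovr", average="macro",
                labels=list(clf.classes_),
            )
        f1 = f1_score(y_test, clf.predict(X_test.values), average="macro")
        aucs.append(float(auc))
        f1s.append(float(f1))
    return {
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=1)) if n_runs > 1 else 0.0,
        "f1_mean": float(np.mean(f1s)),
        "f1_sd": float(np.std(f1s, ddof=1)) if n_runs > 1 else 0.0,
        "auc_runs": aucs,
        "f1_runs": f1s,
        "n_runs": n_runs,
    }
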