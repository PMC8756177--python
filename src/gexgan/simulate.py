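"""Synthetic ground-truth fixtures: random GRNs, covariates and SEM expression.

The expression simulator is a linear-Gaussian structural equation model
(SEM) over an acyclic TF->target network, with optional additive covariate
effects on designated genes.  It is deliberately *not* a kinetic simulator:
its purpose is to provide data whose dependence structure (pairwise
correlations, regulon geometry, planted condition effects) is known in
closed form, so that the generative model and the realism metrics can be
validated against analytic expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import CovariateTable, ExpressionMatrix, RegulatoryNetwork

__all__ = [
    "SemSpec",
    "CovariateEffect",
    "random_grn",
    "simulate_sem_expression",
    "random_uniform_expression",
    "make_covariates",
    "sem_fixture",
]


@dataclass
class CovariateEffect:
    """Additive effect of one covariate on one gene.

    For a numeric covariate the effect is a slope (``value * gene shift``);
    for a categorical covariate it is a shift applied when the sample's
    category index is ``category`` (0-based).
    """

    covariate: str
    gene: str
    effect: float
    category: int | None = None  # None => numeric slope


@dataclass
class SemSpec:
    """Specification of a linear-Gaussian SEM over a regulatory network.

    Each parentless gene is Normal(covariate terms, root_sd^2); each
    regulated gene is the weighted sum of its parents plus covariate terms
    plus Normal(0, noise_sd^2) noise, evaluated in topological order.
    """

    grn: RegulatoryNetwork
    edge_weights: dict[tuple[str, str], float]
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    root_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0 or self.root_sd <= 0:
            raise ValueError("noise_sd and root_sd must be positive")
        for e in self.grn.edges:
            if e not in self.edge_weights:
                raise ValueError(f"missing weight for edge {e}")
        for w in self.edge_weights.values():
            if not np.isfinite(w):
                raise ValueError("edge weights must be finite")

    def gene_order(self) -> list[str]:
        """Genes in a deterministic topological order (cycles raise)."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.grn.nodes))
        g.add_edges_from(sorted(self.grn.edges))
        try:
            return list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible:
            raise ValueError("SEM network contains a cycle") from None


def random_grn(
    n_tfs: int, n_targets: int, out_degree: int, seed: int
) -> RegulatoryNetwork:
    """Draw a random acyclic TF->target network.

    TFs are ``TF001..`` and targets ``G001..``; each TF regulates
    ``out_degree`` targets drawn without replacement, so every TF has at
    least one target and the result is bipartite, hence acyclic.
    """
    if n_tfs < 1 or n_targets < 1 or out_degree < 1:
        raise ValueError("n_tfs, n_targets and out_degree must be >= 1")
    if out_degree > n_targets:
        raise ValueError(
            f"out_degree {out_degree} exceeds the {n_targets} available targets"
        )
    rng = np.random.default_rng(seed)
    width = max(3, len(str(max(n_tfs, n_targets))))
    tfs = [f"TF{i + 1:0{width}d}" for i in range(n_tfs)]
    tgs = [f"G{i + 1:0{width}d}" for i in range(n_targets)]
    edges = set()
    for tf in tfs:
        chosen = rng.choice(n_targets, size=out_degree, replace=False)
        for j in chosen:
            edges.add((tf, tgs[j]))
    return RegulatoryNetwork(edges, gene_universe=set(tfs) | set(tgs))


def simulate_sem_expression(
    spec: SemSpec, covs: CovariateTable, m: int, seed: int
) -> ExpressionMatrix:
    """Sample ``m`` expression profiles from the SEM.

    Genes are evaluated in topological order; covariate effects are additive
    on their designated genes.  Deterministic given the seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if covs.n_samples != m:
        raise ValueError(
            f"covariate table has {covs.n_samples} rows, expected {m}"
        )
    rng = np.random.default_rng(seed)
    order = spec.gene_order()
    col = {g: j for j, g in enumerate(order)}
    parents: dict[str, list[str]] = {g: [] for g in order}
    for tf, tg in spec.grn.edges:
        parents[tg].append(tf)

    shift = np.zeros((m, len(order)))
    for eff in spec.covariate_effects:
        if eff.gene not in col:
            raise ValueError(f"covariate effect on unknown gene {eff.gene!r}")
        j = col[eff.gene]
        if eff.category is None:
            k = covs.numeric_names.index(eff.covariate)
            shift[:, j] += eff.effect * covs.numeric[:, k]
        else:
            k = covs.categorical_names.index(eff.covariate)
            shift[:, j] += eff.effect * (covs.categorical[:, k] == eff.category)

    values = np.empty((m, len(order)))
    for g in order:
        j = col[g]
        pa = sorted(parents[g])
        if not pa:
            values[:, j] = shift[:, j] + rng.normal(0.0, spec.root_sd, size=m)
        else:
            base = np.zeros(m)
            for p in pa:
                base += spec.edge_weights[(p, g)] * values[:, col[p]]
            values[:, j] = base + shift[:, j] + rng.normal(
                0.0, spec.noise_sd, size=m
            )
    sample_ids = covs.sample_ids or [f"s{i + 1}" for i in range(m)]
    return ExpressionMatrix(values, order, list(sample_ids))


def random_uniform_expression(m: int, n: int, seed: int) -> ExpressionMatrix:
    """I.i.d. U(0,1) expression — the realism metrics' null baseline."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.random((m, n))
    width = max(3, len(str(n)))
    return ExpressionMatrix(
        values,
        [f"G{j + 1:0{width}d}" for j in range(n)],
        [f"s{i + 1}" for i in range(m)],
    )


def make_covariates(
    m: int,
    numeric_specs: dict[str, tuple[float, float]],
    categorical_specs: dict[str, dict[str, float]],
    seed: int,
) -> CovariateTable:
    """Draw a covariate table.

    ``numeric_specs`` maps column name -> (mean, sd) of a normal draw;
    ``categorical_specs`` maps column name -> {label: probability}.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    num_names = list(numeric_specs)
    num = np.empty((m, len(num_names)))
    for j, name in enumerate(num_names):
        mean, sd = numeric_specs[name]
        if sd < 0:
            raise ValueError(f"negative sd for numeric covariate {name!r}")
        num[:, j] = rng.normal(mean, sd, size=m)
    cat_names = list(categorical_specs)
    cat = np.empty((m, len(cat_names)), dtype=int)
    vocabs: dict[str, list[str]] = {}
    for j, name in enumerate(cat_names):
        table = categorical_specs[name]
        labels = list(table)
        probs = np.array([table[k] for k in labels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"probabilities for {name!r} sum to {probs.sum()!r}, not 1"
            )
        cat[:, j] = rng.choice(len(labels), size=m, p=probs)
        vocabs[name] = labels
    return CovariateTable(
        numeric=num,
        numeric_names=num_names,
        categorical=cat,
        categorical_names=cat_names,
        vocabularies=vocabs,
        sample_ids=[f"s{i + 1}" for i in range(m)],
    )


def sem_fixture(
    n_genes: int = 50,
    m: int = 2000,
    seed: int = 0,
    condition_effect: float = 3.0,
    condition_genes: int = 1,
    noise_sd: float = 0.5,
):
    """Build the package's standard SEM study fixture.

    The network is a two-level regulatory hierarchy, mirroring the
    master-regulator organisation of real bacterial networks: one root TF
    regulates a layer of roughly ``n_genes/5`` TFs (weights of magnitude
    0.4-0.9, random sign), each of which regulates an equal share of the
    target genes (weights of magnitude 0.7-1.3, random sign).  The shared
    root makes between-regulon correlations graded rather than zero, so the
    gene dendrogram is well determined and the dendrogram realism score of
    an independent real replicate is close to 1.

    Covariates: an age-like numeric column (Normal(50, 15), with a small
    0.01 slope on two target genes) and a binary ``condition`` covariate
    (normal/disease, p = 0.5) adding ``condition_effect`` to the first
    ``condition_genes`` target genes in disease samples.

    Returns ``(spec, covs, X, affected_genes)``.
    """
    if n_genes < 12:
        raise ValueError("n_genes must be >= 12")
    n_tfs = max(2, (n_genes - 1) // 5)
    n_targets = n_genes - 1 - n_tfs
    if condition_genes + 2 > n_targets:
        raise ValueError("too many condition genes for this gene count")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_genes)))
    root = f"TF{0:0{width}d}"
    tfs = [f"TF{i + 1:0{width}d}" for i in range(n_tfs)]
    tgs = [f"G{i + 1:0{width}d}" for i in range(n_targets)]
    edges = {(root, tf) for tf in tfs}
    for i, g in enumerate(tgs):  # round-robin: every TF gets a regulon
        edges.add((tfs[i % n_tfs], g))
    grn = RegulatoryNetwork(edges, gene_universe={root} | set(tfs) | set(tgs))
    weights = {}
    for e in sorted(edges):
        mag = rng.uniform(0.4, 0.9) if e[0] == root else rng.uniform(0.7, 1.3)
        weights[e] = float(mag * rng.choice([-1.0, 1.0]))
    covs = make_covariates(
        m,
        numeric_specs={"age": (50.0, 15.0)},
        categorical_specs={"condition": {"normal": 0.5, "disease": 0.5}},
        seed=int(rng.integers(2**31)),
    )
    affected = tgs[:condition_genes]
    disease_idx = covs.vocabularies["condition"].index("disease")
    effects = [
        CovariateEffect("condition", g, condition_effect, category=disease_idx)
        for g in affected
    ]
    effects += [
        CovariateEffect("age", g, 0.01)
        for g in tgs[condition_genes : condition_genes + 2]
    ]
    spec = SemSpec(
        grn=grn,
        edge_weights=weights,
        covariate_effects=effects,
        noise_sd=noise_sd,
        root_sd=1.0,
    )
    X = simulate_sem_expression(spec, covs, m, seed=int(rng.integers(2**31)))
    return spec, covs, X, affected
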