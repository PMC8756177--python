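"""Preprocessing: per-gene standard scores and BFS subnetwork extraction."""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .containers import ExpressionMatrix, RegulatoryNetwork

__all__ = ["standard_score", "log2_plus_one", "bfs_subnetwork"]


def standard_score(X: ExpressionMatrix, strict: bool = False) -> ExpressionMatrix:
    """Scale each gene to mean 0 and standard deviation 1 across samples.

    Zero-variance genes become all-zero columns with a warning (so the gene
    index stays aligned with any paired regulatory network); with
    ``strict=True`` they raise instead.
    """
    if X.n_samples < 2:
        raise ValueError("standard score needs at least 2 samples per gene")
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=0)
    flat = sd == 0.0
    if np.any(flat):
        names = [g for g, z in zip(X.gene_ids, flat) if z]
        if strict:
            raise ValueError(f"zero-variance genes: {names}")
        warnings.warn(
            f"zero-variance genes standardized to zeros: {names}",
            UserWarning,
            stacklevel=2,
        )
    safe_sd = np.where(flat, 1.0, sd)
    values = (X.values - mu) / safe_sd
    values[:, flat] = 0.0
    return ExpressionMatrix(values, list(X.gene_ids), list(X.sample_ids))


def log2_plus_one(X: ExpressionMatrix) -> ExpressionMatrix:
    """Optional log2(x+1) transform for count-scale RNA-seq input."""
    if np.any(X.values < -1.0 + 1e-12):
        raise ValueError("log2(x+1) requires values > -1")
    return ExpressionMatrix(
        np.log2(X.values + 1.0), list(X.gene_ids), list(X.sample_ids)
    )


def bfs_subnetwork(net: RegulatoryNetwork, root: str) -> RegulatoryNetwork:
    """Extract the BFS tree rooted at ``root``, breaking loops.

    Breadth-first search over the directed network; an edge into an
    already-visited gene (a non-tree edge) is dropped, so the result is a
    tree spanning exactly the genes reachable from the root.  Neighbors are
    expanded in lexicographic order of gene id, which makes the traversal
    deterministic.
    """
    root = str(root)
    if root not in net.nodes:
        raise KeyError(f"root {root!r} not present in the network")
    g = nx.DiGraph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(sorted(net.edges))
    tree_edges = set(nx.bfs_edges(g, root, sort_neighbors=sorted))
    return RegulatoryNetwork(tree_edges, gene_universe={root})
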