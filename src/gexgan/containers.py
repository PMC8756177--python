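"""Core data containers: expression matrices, covariate tables, regulatory networks.

Orientation is fixed throughout the package: rows are samples, columns are
genes.  Categorical covariates are stored as 0-based integer codes with a
per-column vocabulary of string labels; files always carry labels, never
codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "CovariateTable", "RegulatoryNetwork"]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A samples-by-genes real-valued expression matrix.

    Parameters
    ----------
    values : (m, n) ndarray of float
        Expression values; must be finite.
    gene_ids : sequence of str
        Column identifiers, unique, length n.
    sample_ids : sequence of str
        Row identifiers, unique, length m.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        m, n = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} columns"
            )
        if len(self.sample_ids) != m:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {m} rows"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.gene_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=list(map(str, df.columns)),
            sample_ids=list(map(str, df.index)),
        )

    def gene_column(self, gene_id: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None
        return self.values[:, j]

    def reorder_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy with columns in the requested gene order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[:, cols], list(gene_ids), list(self.sample_ids)
        )


@dataclass
class CovariateTable:
    """Per-sample covariates: numeric columns and categorical columns.

    Categorical entries are 0-based indices into per-column vocabularies
    (ordered lists of string labels).
    """

    numeric: np.ndarray
    numeric_names: list[str]
    categorical: np.ndarray
    categorical_names: list[str]
    vocabularies: dict[str, list[str]] = field(default_factory=dict)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.numeric = np.asarray(self.numeric, dtype=float)
        self.categorical = np.asarray(self.categorical, dtype=int)
        if self.numeric.ndim != 2 or self.categorical.ndim != 2:
            raise ValueError("numeric and categorical must be 2-D")
        if self.numeric.shape[0] != self.categorical.shape[0]:
            raise ValueError("numeric/categorical row counts differ")
        if self.numeric.shape[1] != len(self.numeric_names):
            raise ValueError("numeric column-name count mismatch")
        if self.categorical.shape[1] != len(self.categorical_names):
            raise ValueError("categorical column-name count mismatch")
        for j, name in enumerate(self.categorical_names):
            vocab = self.vocabularies.get(name)
            if not vocab:
                raise ValueError(f"missing vocabulary for {name!r}")
            col = self.categorical[:, j]
            if col.size and (col.min() < 0 or col.max() >= len(vocab)):
                raise ValueError(
                    f"categorical index out of range for {name!r} "
                    f"(vocabulary size {len(vocab)})"
                )
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != self.n_samples:
                raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.numeric.shape[0]

    @property
    def n_numeric(self) -> int:
        return self.numeric.shape[1]

    @property
    def n_categorical(self) -> int:
        return self.categorical.shape[1]

    def vocab_sizes(self) -> list[int]:
        return [len(self.vocabularies[c]) for c in self.categorical_names]

    def labels(self, name: str) -> list[str]:
        """Decode one categorical column to its string labels."""
        j = self.categorical_names.index(name)
        vocab = self.vocabularies[name]
        return [vocab[i] for i in self.categorical[:, j]]

    def subset(self, rows) -> "CovariateTable":
        rows = np.asarray(rows)
        return CovariateTable(
            numeric=self.numeric[rows],
            numeric_names=list(self.numeric_names),
            categorical=self.categorical[rows],
            categorical_names=list(self.categorical_names),
            vocabularies={k: list(v) for k, v in self.vocabularies.items()},
            sample_ids=(
                [self.sample_ids[i] for i in rows]
                if self.sample_ids is not None
                else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, name in enumerate(self.numeric_names):
            data[name] = self.numeric[:, j]
        for name in self.categorical_names:
            data[name] = self.labels(name)
        idx = self.sample_ids
        if idx is None:
            idx = [f"s{i}" for i in range(self.n_samples)]
        return pd.DataFrame(data, index=idx)


@dataclass
class RegulatoryNetwork:
    """A directed TF -> target-gene edge set.

    ``targets(f)`` is the regulon G(f); ``tf_set`` is the set of regulators
    with at least one target.
    """

    edges: set[tuple[str, str]]
    gene_universe: set[str] | None = None

    def __post_init__(self) -> None:
        self.edges = {(str(a), str(b)) for a, b in self.edges}
        self._targets: dict[str, set[str]] = {}
        for tf, tg in sorted(self.edges):
            self._targets.setdefault(tf, set()).add(tg)

    @property
    def tf_set(self) -> set[str]:
        return set(self._targets)

    def targets(self, tf: str) -> set[str]:
        if tf not in self._targets:
            raise KeyError(f"unknown TF: {tf!r}")
        return set(self._targets[tf])

    @property
    def nodes(self) -> set[str]:
        out = {g for e in self.edges for g in e}
        if self.gene_universe:
            out |= set(self.gene_universe)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def self_loops(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b in self.edges if a == b}
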