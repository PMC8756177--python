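"""Readers and writers for the package's tab-separated file formats.

Expression TSV: header ``sample_id<TAB>gene1<TAB>...``, one row per sample.
Covariates TSV: header row; which columns are numeric vs categorical is
declared by the caller, never inferred.
GRN TSV: two tab-separated columns ``tf<TAB>target``; lines starting with
``#`` are comments.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CovariateTable, ExpressionMatrix, RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_grn",
    "write_grn",
]


def read_expression(path) -> ExpressionMatrix:
    """Read a samples-by-genes expression TSV.

    Raises
    ------
    ValueError
        On duplicate gene or sample ids (naming the duplicate) or on a
        non-numeric cell (naming its coordinates).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = pd.Series(header)[pd.Series(header).duplicated()]
    if len(dupes):  # pandas would silently rename these
        raise ValueError(
            f"duplicate gene id in {path.name}: {dupes.iloc[0]!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = list(map(str, df.columns))
    samples = list(map(str, df.index))
    for name, ids in (("gene", genes), ("sample", samples)):
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()]
        if len(dupes):
            raise ValueError(
                f"duplicate {name} id in {path.name}: {dupes.iloc[0]!r}"
            )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, s in enumerate(samples):
            for j, g in enumerate(genes):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at sample {s!r}, gene {g!r} "
                        f"in {path.name}: {df.iat[i, j]!r}"
                    ) from None
        raise
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite cell at sample {samples[i]!r}, gene {genes[j]!r}"
        )
    return ExpressionMatrix(values, genes, samples)


def write_expression(X: ExpressionMatrix, path, float_format: str = "%.12g") -> None:
    df = X.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def read_covariates(
    path,
    numeric: list[str],
    categorical: list[str],
    vocabularies: dict[str, list[str]] | None = None,
) -> CovariateTable:
    """Read a covariate TSV with a declared column schema.

    Vocabularies default to the sorted distinct labels present in the file;
    passing explicit vocabularies pins category order (needed to match a
    trained model's schema).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in list(numeric) + list(categorical) if c not in df.columns]
    if missing:
        raise ValueError(f"covariate columns missing from file: {missing}")
    num = np.empty((len(df), len(numeric)), dtype=float)
    for j, c in enumerate(numeric):
        num[:, j] = pd.to_numeric(df[c], errors="raise").to_numpy()
    vocabs: dict[str, list[str]] = {}
    cat = np.empty((len(df), len(categorical)), dtype=int)
    for j, c in enumerate(categorical):
        col = df[c].astype(str)
        vocab = (
            list(vocabularies[c])
            if vocabularies and c in vocabularies
            else sorted(col.unique())
        )
        lookup = {lab: i for i, lab in enumerate(vocab)}
        unknown = sorted(set(col) - set(lookup))
        if unknown:
            raise ValueError(
                f"labels outside vocabulary for {c!r}: {unknown}"
            )
        cat[:, j] = [lookup[x] for x in col]
        vocabs[c] = vocab
    return CovariateTable(
        numeric=num,
        numeric_names=list(numeric),
        categorical=cat,
        categorical_names=list(categorical),
        vocabularies=vocabs,
        sample_ids=list(map(str, df.index)),
    )


def write_covariates(covs: CovariateTable, path, float_format: str = "%.12g") -> None:
    df = covs.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def read_grn(path) -> RegulatoryNetwork:
    """Read a two-column TF->target edge list; duplicates collapse to one edge."""
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"malformed GRN row at {path.name}:{lineno}: "
                    f"expected at least 2 tab-separated columns"
                )
            edges.add((fields[0].strip(), fields[1].strip()))
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"GRN file {path.name} contains no edges")
    net = RegulatoryNetwork(edges)
    loops = net.self_loops()
    if loops:
        logger.warning("GRN %s contains self-loops: %s", path.name, sorted(loops))
    return net


def write_grn(net: RegulatoryNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# tf\ttarget\n")
        for tf, tg in sorted(net.edges):
            fh.write(f"{tf}\t{tg}\n")
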