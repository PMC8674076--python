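"""Reading/writing expression tables and the standard preprocessing steps.

Expression matrices travel as delimited text with genes in rows and samples
in columns (header row of sample IDs, first column of gene IDs).  The
preprocessing mirrors the usual protocol for high-dimensional, small-sample
expression data: PCA down to a workable dimension, then K-means on the
sample columns to initialize the cluster indicators.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .types import ExpressionMatrix, IndicatorSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_labels",
    "read_labels",
    "pca_reduce",
    "kmeans_init",
    "zscore_genes",
]


class MatrixParseError(ValueError):
    """A delimited expression table failed to parse; the message names the cell."""


def read_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Parse a genes × samples table, rejecting NA/non-numeric cells by name."""
    path = Path(path)
    try:
        header = pd.read_csv(path, sep=delimiter, header=None, nrows=1, dtype=str)
        sample_ids = header.iloc[0, 1:]  # pandas mangles duplicates on read
        if sample_ids.duplicated().any():
            dupes = sample_ids[sample_ids.duplicated()].unique().tolist()
            raise MatrixParseError(f"{path}: duplicate sample IDs {dupes}")
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at "
            f"gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
    )


def write_matrix(X: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def write_labels(sample_ids: list[str], labels, path) -> None:
    """Two-column TSV: sample_id <TAB> cluster (0-based)."""
    pd.DataFrame(
        {"sample_id": sample_ids, "cluster": np.asarray(labels, dtype=int)}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise MatrixParseError(f"{path}: expected two columns (sample_id, cluster)")
    return list(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(dtype=int)


def zscore_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scoring across samples (constant genes left centered)."""
    v = X.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ExpressionMatrix((v - mu) / sd, X.gene_ids, X.sample_ids)


def pca_reduce(X: ExpressionMatrix, d: int) -> ExpressionMatrix:
    """Project samples onto the top-d principal directions of gene space.

    Genes are centered (row means removed) and the n sample columns become
    d-dimensional coordinates; output features are named PC1..PCd.
    """
    if not 1 <= d <= min(X.n_genes, X.n_samples):
        raise ValueError(
            f"d must be in [1, {min(X.n_genes, X.n_samples)}], got {d}"
        )
    pca = PCA(n_components=d, svd_solver="full")
    Z = pca.fit_transform(X.values.T)  # samples as rows
    return ExpressionMatrix(
        values=Z.T,
        gene_ids=[f"PC{i + 1}" for i in range(d)],
        sample_ids=X.sample_ids,
    )


def kmeans_init(X: ExpressionMatrix, c: int, seed: int = 0) -> IndicatorSet:
    """Seeded K-means (k-means++ start, Lloyd iterations) on sample columns."""
    if c > X.n_samples:
        raise ValueError(f"c={c} exceeds the number of samples {X.n_samples}")
    if c == 1:
        return IndicatorSet(labels=np.zeros(X.n_samples, dtype=int), c=1)
    km = KMeans(n_clusters=c, init="k-means++", n_init=1, random_state=seed)
    return IndicatorSet(labels=km.fit_predict(X.values.T), c=c)
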