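"""Co-expression adjacency and dissimilarity.

The adjacency between two genes is the coefficient of determination,
``a_ij = corr(gene_i, gene_j)^2`` — the squared correlation with a fixed
soft-threshold exponent of 2, so no scale-free fitting step is needed and
every entry reads directly as "fraction of variance explained". The
dissimilarity is simply ``d_ij = 1 - a_ij``.

Squaring makes correlated and anti-correlated pairs equidistant; that is a
documented property of the measure, not an accident. A gene duplicated in
the matrix has d = 0 to its copy, which the overlap-based dissimilarity of
classic WGCNA does not guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, ValidationError

__all__ = ["AdjacencyMatrix", "DissimilarityMatrix", "compute_adjacency", "compute_dissimilarity"]

BETA = 2  # fixed exponent: adjacency is the coefficient of determination


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, in [0, 1], unit diagonal
    corr_method: str = "pearson"
    beta: int = BETA

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.gene_ids):
            raise ValidationError("adjacency shape does not match gene ids")
        if not np.isfinite(v).all():
            raise ValidationError("adjacency contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class DissimilarityMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, in [0, 1], zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def compute_adjacency(
    expr: ExpressionMatrix, corr_method: str = "pearson"
) -> AdjacencyMatrix:
    """Squared gene-gene correlation matrix.

    Parameters
    ----------
    expr:
        Expression matrix; correlations are computed on the values as given
        (callers log-transform first when appropriate).
    corr_method:
        ``pearson`` (default) or ``spearman`` (Pearson on ranks).
    """
    if expr.n_samples < 3:
        raise ValidationError("adjacency requires at least 3 samples")
    x = expr.values
    sd = x.std(axis=1)
    zero_var = np.asarray(sd == 0).nonzero()[0]
    if zero_var.size:
        names = [expr.gene_ids[i] for i in zero_var[:5]]
        raise ValidationError(f"zero-variance genes present: {names}")
    if corr_method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
    elif corr_method != "pearson":
        raise ValidationError(f"unknown corr_method {corr_method!r}")
    r = np.corrcoef(x)
    a = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0  # enforce exact symmetry against fp drift
    return AdjacencyMatrix(gene_ids=expr.gene_ids, values=a, corr_method=corr_method)


def compute_dissimilarity(adj: AdjacencyMatrix) -> DissimilarityMatrix:
    """d_ij = 1 - a_ij, with an exactly zero diagonal."""
    d = 1.0 - adj.values
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DissimilarityMatrix(gene_ids=list(adj.gene_ids), values=d)
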