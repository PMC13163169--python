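"""Expression-matrix container and file I/O.

The whole pipeline works on a genes x samples matrix of TPM-scale values.
A thin wrapper around :class:`pandas.DataFrame` records whether values are
in linear (TPM) or log space, because the two halves of the method disagree
on purpose: normalization factors are averages of linear expression, while
correlations are computed on log2(x+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

__all__ = ["ExpressionMatrix", "load_expression", "write_expression"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with explicit value space.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with sample ids as columns. Values must
        be finite; in ``linear`` space they must also be non-negative.
    space:
        ``"linear"`` for TPM-scale values, ``"log"`` after a log transform.
    """

    data: pd.DataFrame
    space: str = "linear"

    def __post_init__(self) -> None:
        if self.space not in ("linear", "log"):
            raise ValidationError(f"space must be 'linear' or 'log', got {self.space!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains NaN or infinite values")
        if self.space == "linear" and values.size and (values < 0).any():
            raise ValidationError("linear-space expression must be non-negative")
        if self.n_samples < 3:
            raise ValidationError(
                f"need at least 3 samples, got {self.n_samples}"
            )
        # canonical dtypes and labels
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "gene_id"

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to ``genes``, keeping the matrix's row order."""
        keep = set(genes)
        missing = keep - set(self.data.index)
        if missing:
            raise ValidationError(f"genes not in matrix: {sorted(missing)[:5]}")
        mask = self.data.index.isin(keep)
        return ExpressionMatrix(self.data.loc[mask].copy(), space=self.space)

    def log2p1(self) -> "ExpressionMatrix":
        """Return log2(x + 1)-transformed copy (no-op guard for log space)."""
        if self.space == "log":
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), space="log")


def _read_sidecar(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def load_expression(
    path: str | Path,
    format: str | None = None,
    transform: str = "none",
) -> ExpressionMatrix:
    """Load an expression matrix from TSV, CSV or MatrixMarket.

    TSV/CSV files carry gene ids in the first column and sample ids in the
    header. MatrixMarket input expects sidecar files ``<stem>.rows`` and
    ``<stem>.cols`` holding gene and sample ids, one per line.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``tsv``, ``csv`` or ``mtx``; inferred from the suffix when omitted.
    transform:
        ``none`` keeps linear space; ``log2p1`` applies log2(x+1) and marks
        the result as log space.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValidationError(f"cannot infer format from suffix of {path.name}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise ValidationError(f"malformed {format} file {path.name}: {exc}") from exc
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate gene ids in {path.name}: {dups[:5]}"
            )
    elif format == "mtx":
        raw = mmread(path)
        if hasattr(raw, "todense"):
            raw = raw.todense()
        mat = np.atleast_2d(np.asarray(raw, dtype=float))
        rows = _read_sidecar(path.with_suffix(".rows"))
        cols = _read_sidecar(path.with_suffix(".cols"))
        if mat.shape != (len(rows), len(cols)):
            raise ValidationError(
                f"mtx shape {mat.shape} does not match sidecars "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        df = pd.DataFrame(mat, index=rows, columns=cols)
        if df.index.duplicated().any():
            raise ValidationError(f"duplicate gene ids in {path.name} sidecar")
    else:
        raise ValidationError(f"unknown format {format!r}")

    expr = ExpressionMatrix(df, space="linear")
    if transform == "log2p1":
        return expr.log2p1()
    if transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    return expr


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as TSV/CSV (genes as rows) or MatrixMarket + sidecars."""
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        expr.data.to_csv(path, sep=sep, index_label="gene_id")
    elif format == "mtx":
        mmwrite(str(path), np.asarray(expr.values))
        path.with_suffix(".rows").write_text(
            "\n".join(expr.gene_ids) + "\n", encoding="utf-8"
        )
        path.with_suffix(".cols").write_text(
            "\n".join(expr.sample_ids) + "\n", encoding="utf-8"
        )
    else:
        raise ValidationError(f"unknown format {format!r}")
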