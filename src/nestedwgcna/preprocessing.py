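"""Gene filtering ahead of network inference.

Two filters are applied before any correlation is computed:

* a biotype filter that keeps protein-coding genes when an annotation is
  supplied (skipped with a warning otherwise), and
* an information filter on the per-gene *misclassification error*,
  ``ME = 1 - (modal value count) / N``: a gene whose most frequent value
  covers most samples carries almost no information, and under bootstrap
  resampling (which retains ~63.2% unique samples) such genes are unstable.
  Genes with ME below ``1/e`` are dropped by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "GeneFilterReport",
    "misclassification_error",
    "filter_genes",
    "multi_dataset_filter",
    "load_annotation",
    "DEFAULT_ME_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_ME_THRESHOLD = 1.0 / np.e


@dataclass
class GeneFilterReport:
    """Which genes were dropped by which filter, and why."""

    misclassification_error: pd.Series
    dropped_noncoding: set[str] = field(default_factory=set)
    dropped_low_information: set[str] = field(default_factory=set)
    unannotated_kept: set[str] = field(default_factory=set)
    threshold: float = DEFAULT_ME_THRESHOLD

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_noncoding | self.dropped_low_information)


def misclassification_error(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene ME = 1 - modal-value frequency / N, on raw values.

    ME is 0 for a constant gene and at most ``1 - 1/N``; it depends only on
    the multiset of values, so any bijective relabeling leaves it unchanged.
    """
    n = expr.n_samples
    values = expr.values

    def _me(row: np.ndarray) -> float:
        _, counts = np.unique(row, return_counts=True)
        return 1.0 - counts.max() / n

    return pd.Series(
        [_me(values[i]) for i in range(values.shape[0])],
        index=expr.gene_ids,
        name="misclassification_error",
    )


def load_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, biotype) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "biotype"], dtype=str)
    return dict(zip(df["gene_id"], df["biotype"]))


def filter_genes(
    expr: ExpressionMatrix,
    annotation: dict[str, str] | None = None,
    me_threshold: float = DEFAULT_ME_THRESHOLD,
) -> tuple[ExpressionMatrix, GeneFilterReport]:
    """Apply the biotype and misclassification-error filters.

    Genes absent from ``annotation`` are kept and logged; when no annotation
    is given the coding filter is skipped entirely with a warning.
    """
    me = misclassification_error(expr)
    report = GeneFilterReport(misclassification_error=me, threshold=me_threshold)

    keep = pd.Series(True, index=expr.data.index)
    if annotation is None:
        logger.warning("no gene annotation supplied; skipping the coding-gene filter")
    else:
        for gene in expr.gene_ids:
            biotype = annotation.get(gene)
            if biotype is None:
                report.unannotated_kept.add(gene)
            elif biotype.lower() != "protein_coding":
                report.dropped_noncoding.add(gene)
                keep[gene] = False
        if report.unannotated_kept:
            logger.info(
                "%d genes lacked a biotype annotation and were kept",
                len(report.unannotated_kept),
            )

    low_info = me < me_threshold
    for gene in me.index[low_info & keep]:
        report.dropped_low_information.add(gene)
        keep[gene] = False

    if not keep.any():
        raise ValidationError(
            "all genes removed by filtering; consider lowering me_threshold"
        )
    filtered = ExpressionMatrix(expr.data.loc[keep].copy(), space=expr.space)
    return filtered, report


def multi_dataset_filter(
    exprs: list[ExpressionMatrix],
    me_threshold: float = DEFAULT_ME_THRESHOLD,
) -> list[str]:
    """Common gene set after applying the ME filter jointly across datasets.

    A gene is excluded if it fails the ME filter in *any* dataset; the
    returned list is the intersection of gene sets, in the first dataset's
    row order, minus those failures.
    """
    if len(exprs) < 2:
        raise ValidationError("multi_dataset_filter needs at least 2 datasets")
    common = set(exprs[0].gene_ids)
    for e in exprs[1:]:
        common &= set(e.gene_ids)
    if not common:
        raise ValidationError("datasets share no gene ids")
    failing: set[str] = set()
    for e in exprs:
        me = misclassification_error(e)
        failing |= set(me.index[me < me_threshold]) & common
    result = [g for g in exprs[0].gene_ids if g in common and g not in failing]
    if not result:
        raise ValidationError(
            "no genes survive the joint filter; consider lowering me_threshold"
        )
    return result
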