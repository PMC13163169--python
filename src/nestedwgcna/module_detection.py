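"""Coarse-grained module (CGM) detection.

Genes are embedded from the dissimilarity matrix with UMAP (treating the
matrix as precomputed pairwise distances) and clustered with HDBSCAN in the
embedding. Density clustering degrades badly above ~100 dimensions, which
is why the embedding step exists at all; its dimensionality scales with the
dataset as ``round(log2(N) + 1)`` where N is the number of samples.

The only free hyperparameter is ``min_cluster_size``; everything else is
derived from it:

* ``n_neighbors = 2 * min_cluster_size`` — wide enough neighborhoods to keep
  clusters connected and avoid fragmentation;
* ``min_samples = min_cluster_size // 2`` — the usual half-of-cluster-size
  convention for HDBSCAN's density estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import umap
from sklearn.cluster import HDBSCAN

from .matrix import ExpressionMatrix, ValidationError
from .network import DissimilarityMatrix, compute_adjacency, compute_dissimilarity

__all__ = [
    "ClusteringParams",
    "ModuleAssignment",
    "derive_params",
    "embed",
    "cluster",
    "detect_cgms",
    "DEFAULT_MIN_CLUSTER_SIZE",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLUSTER_SIZE = 50


@dataclass(frozen=True)
class ClusteringParams:
    """UMAP + HDBSCAN settings, all derived from ``min_cluster_size``."""

    min_cluster_size: int
    n_components: int
    n_neighbors: int
    min_samples: int
    random_seed: int

    def as_dict(self) -> dict:
        return {
            "min_cluster_size": self.min_cluster_size,
            "n_components": self.n_components,
            "n_neighbors": self.n_neighbors,
            "min_samples": self.min_samples,
            "random_seed": self.random_seed,
        }


@dataclass
class ModuleAssignment:
    """Per-gene module labels; -1 marks unassigned (noise) genes.

    Labels of real modules are contiguous integers from 0, ordered by
    decreasing module size for determinism.
    """

    gene_ids: list[str]
    labels: np.ndarray
    level: str = "CGM"  # or "FGM"
    parent_module: int | None = None
    params: ClusteringParams | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.gene_ids) != self.labels.shape[0]:
            raise ValidationError("labels length does not match gene ids")

    @property
    def n_modules(self) -> int:
        return int(np.sum(np.unique(self.labels) >= 0))

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(l) for l in np.unique(self.labels) if l >= 0)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == module]

    @property
    def noise_genes(self) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == -1]

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.gene_ids, name="label")

    def to_tsv(self, path) -> None:
        self.to_series().to_csv(path, sep="\t", index_label="gene_id")


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Make non-noise labels contiguous from 0, largest module first."""
    out = np.full(labels.shape, -1, dtype=int)
    uniq = [l for l in np.unique(labels) if l >= 0]
    sizes = {l: int(np.sum(labels == l)) for l in uniq}
    order = sorted(uniq, key=lambda l: (-sizes[l], l))
    for new, old in enumerate(order):
        out[labels == old] = new
    return out


def derive_params(
    n_samples: int, min_cluster_size: int, seed: int = 0
) -> ClusteringParams:
    """Derive embedding/clustering settings from the sample count.

    ``n_components = round(log2(N) + 1)`` with a floor of 2; N is the number
    of RNA-Seq samples, reflecting that intrinsic dimensionality grows with
    dataset size.
    """
    if n_samples < 4:
        raise ValidationError("need at least 4 samples to derive parameters")
    if min_cluster_size < 2:
        raise ValidationError("min_cluster_size must be >= 2")
    n_components = max(2, round(np.log2(n_samples) + 1))
    return ClusteringParams(
        min_cluster_size=min_cluster_size,
        n_components=int(n_components),
        n_neighbors=2 * min_cluster_size,
        min_samples=max(1, min_cluster_size // 2),
        random_seed=int(seed),
    )


def embed(dissim: DissimilarityMatrix, params: ClusteringParams) -> np.ndarray:
    """UMAP embedding of genes from precomputed dissimilarities.

    Deterministic for a fixed ``random_seed`` (UMAP runs single-threaded
    when seeded).
    """
    n_genes = len(dissim.gene_ids)
    if n_genes <= params.n_neighbors:
        raise ValidationError(
            f"{n_genes} genes but n_neighbors={params.n_neighbors}; "
            "use a smaller min_cluster_size"
        )
    reducer = umap.UMAP(
        n_components=params.n_components,
        n_neighbors=params.n_neighbors,
        metric="precomputed",
        random_state=params.random_seed,
    )
    return np.asarray(reducer.fit_transform(dissim.values), dtype=float)


def cluster(
    embedding: np.ndarray,
    params: ClusteringParams,
    gene_ids: list[str] | None = None,
    level: str = "CGM",
) -> ModuleAssignment:
    """HDBSCAN on the embedding with Euclidean distances.

    Finding no cluster at all is a legitimate outcome (all genes noise); it
    produces a warning, not an error.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] < 2 * params.min_cluster_size:
        raise ValidationError(
            "fewer than 2 * min_cluster_size points to cluster"
        )
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(embedding.shape[0])]
    model = HDBSCAN(
        min_cluster_size=params.min_cluster_size,
        min_samples=params.min_samples,
        metric="euclidean",
        copy=True,
    )
    labels = model.fit_predict(embedding)
    if (labels >= 0).sum() == 0:
        logger.warning("HDBSCAN found no clusters; all genes labeled noise")
    return ModuleAssignment(
        gene_ids=list(gene_ids),
        labels=_relabel(labels),
        level=level,
        params=params,
    )


def detect_cgms(
    expr: ExpressionMatrix,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    seed: int = 0,
    corr_method: str = "pearson",
) -> ModuleAssignment:
    """Full first-round pipeline: adjacency -> dissimilarity -> UMAP -> HDBSCAN.

    Correlations are computed on log2(x+1) values when the input is in
    linear space.
    """
    work = expr.log2p1() if expr.space == "linear" else expr
    adj = compute_adjacency(work, corr_method=corr_method)
    dissim = compute_dissimilarity(adj)
    params = derive_params(expr.n_samples, min_cluster_size, seed)
    logger.info("derived params: %s", params.as_dict())
    emb = embed(dissim, params)
    return cluster(emb, params, gene_ids=expr.gene_ids, level="CGM")
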