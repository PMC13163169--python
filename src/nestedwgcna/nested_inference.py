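"""Core-signal normalization and fine-grained module (FGM) inference.

A coarse module is dominated by one shared signal — the activity of the
cell type or process it represents. Genes inside the module stay correlated
mostly *because* of that signal, which hides any finer sub-structure from a
second round of clustering. The remedy is to divide the signal out:

1. compute the module core's *eigengene* (first principal component of the
   core genes across samples);
2. select the normalization gene set (INGS): genes whose Spearman
   correlation with the eigengene exceeds ``rho_threshold`` (0.9);
3. first normalization: divide each gene in each sample by that sample's
   mean expression of the INGS genes — except that an INGS gene is divided
   by the mean of the *remaining* INGS genes, avoiding self-normalization;
4. keep INGS genes whose coefficient of variation shrank (CV-after /
   CV-before < ``cv_ratio_threshold``, 0.8) as the final INGS;
5. second normalization of the original matrix with the final INGS factors,
   same self-exclusion rule.

Clustering the normalized module genes then reveals compact fine-grained
modules — gene sets that stay correlated with the core signal removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, ValidationError
from .module_detection import ModuleAssignment, cluster, derive_params, embed
from .network import compute_adjacency, compute_dissimilarity

__all__ = [
    "NormalizationResult",
    "FGMSet",
    "compute_eigengene",
    "immfocus_normalize",
    "infer_fgms",
    "DEFAULT_RHO_THRESHOLD",
    "DEFAULT_CV_RATIO_THRESHOLD",
    "DEFAULT_FGM_MIN_CLUSTER_SIZE",
]

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.9
DEFAULT_CV_RATIO_THRESHOLD = 0.8
DEFAULT_FGM_MIN_CLUSTER_SIZE = 15
EPS = 1e-9  # guards normalization denominators near zero


@dataclass
class NormalizationResult:
    eigengene: pd.Series  # per-sample core signal
    ings_initial: set[str]
    ings_final: set[str]
    f_ings: pd.Series  # per-sample final normalization factor
    cv_ratio: pd.Series  # per initial-INGS gene
    normalized_expr: ExpressionMatrix


@dataclass
class FGMSet:
    parent_cgm: int | None
    assignment: ModuleAssignment
    normalization: NormalizationResult | None = None

    @property
    def fgm_genes(self) -> dict[int, list[str]]:
        return {m: self.assignment.module_genes(m) for m in self.assignment.module_ids}

    @property
    def n_fgms(self) -> int:
        return self.assignment.n_modules


def _spearman_vs_vector(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of ``rows`` with the vector ``v``."""
    rr = np.apply_along_axis(rankdata, 1, rows)
    rv = rankdata(v)
    rr = rr - rr.mean(axis=1, keepdims=True)
    rv = rv - rv.mean()
    denom = np.sqrt((rr**2).sum(axis=1) * (rv**2).sum())
    denom[denom == 0] = np.nan
    out = (rr @ rv) / denom
    return np.nan_to_num(out, nan=0.0)


def compute_eigengene(expr: ExpressionMatrix, core_genes: set[str] | list[str]) -> pd.Series:
    """First principal component of the core genes, as per-sample scores.

    Each core gene is standardized across samples (on log2(x+1) values when
    the matrix is linear); the eigengene is the leading right singular
    vector, sign-oriented to correlate positively with mean core expression.
    """
    core = sorted(set(core_genes))
    if len(core) < 2:
        raise ValidationError("eigengene needs at least 2 core genes")
    sub = expr.log2p1().subset_genes(core)
    x = sub.values
    sd = x.std(axis=1)
    if (sd == 0).all():
        raise ValidationError("core submatrix has no variance")
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    # leading right singular vector = PC1 sample scores of the gene-standardized matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_core = x.mean(axis=0)
    if np.corrcoef(eig, mean_core)[0, 1] < 0:
        eig = -eig
    return pd.Series(eig, index=expr.sample_ids, name="eigengene")


def _normalize_once(
    data: pd.DataFrame, ings: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide every gene by the per-sample mean of ``ings``, with the
    self-exclusion rule for INGS members. Returns (normalized, factors)."""
    ings_mat = data.loc[ings]
    total = ings_mat.sum(axis=0)
    k = len(ings)
    f = total / k
    if (f <= 0).any():
        bad = f.index[f <= 0].tolist()
        raise ValidationError(
            f"non-positive normalization factor for samples {bad[:5]}; "
            "input must be linear-space expression"
        )
    out = data.div(f + EPS, axis=1)
    if k > 1:
        # leave-one-out factors for INGS genes: mean of the remaining members
        loo = (total.values[None, :] - ings_mat.values) / (k - 1)
        out.loc[ings] = ings_mat.values / (loo + EPS)
    return out, f


def immfocus_normalize(
    expr: ExpressionMatrix,
    core_genes: set[str] | list[str],
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    cv_ratio_threshold: float = DEFAULT_CV_RATIO_THRESHOLD,
) -> NormalizationResult:
    """Two-pass normalization of a module on its core signal.

    ``expr`` must be in linear space: the factors are plain averages of
    expression. See the module docstring for the five steps.
    """
    if expr.space != "linear":
        raise ValidationError("normalization requires linear-space expression")
    core = sorted(set(core_genes))
    if not core:
        raise ValidationError("core gene set is empty")
    eig = compute_eigengene(expr, core) if len(core) >= 2 else None
    if eig is None:
        raise ValidationError("core gene set too small for an eigengene")

    rho = _spearman_vs_vector(expr.values, eig.values)
    ings_initial = [g for g, r in zip(expr.gene_ids, rho) if r > rho_threshold]
    if not ings_initial:
        raise ValidationError(
            f"no gene exceeds Spearman rho > {rho_threshold} with the eigengene; "
            "lower rho_threshold"
        )

    first_pass, _ = _normalize_once(expr.data, ings_initial)

    def _cv(df: pd.DataFrame) -> pd.Series:
        m = df.mean(axis=1)
        return df.std(axis=1) / (m.abs() + EPS)

    cv_before = _cv(expr.data.loc[ings_initial])
    cv_after = _cv(first_pass.loc[ings_initial])
    cv_ratio = cv_after / (cv_before + EPS)
    ings_final = [g for g in ings_initial if cv_ratio[g] < cv_ratio_threshold]
    if not ings_final:
        logger.warning(
            "no INGS gene passed the CV-ratio filter; falling back to the initial INGS"
        )
        ings_final = list(ings_initial)

    second_pass, f_final = _normalize_once(expr.data, ings_final)

    return NormalizationResult(
        eigengene=eig,
        ings_initial=set(ings_initial),
        ings_final=set(ings_final),
        f_ings=f_final.rename("f_ings"),
        cv_ratio=cv_ratio.rename("cv_ratio"),
        normalized_expr=ExpressionMatrix(second_pass, space="linear"),
    )


def infer_fgms(
    expr: ExpressionMatrix,
    cgm_genes: set[str] | list[str],
    core_genes: set[str] | list[str],
    fgm_min_cluster_size: int = DEFAULT_FGM_MIN_CLUSTER_SIZE,
    seed: int = 0,
    parent_cgm: int | None = None,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    cv_ratio_threshold: float = DEFAULT_CV_RATIO_THRESHOLD,
    corr_method: str = "pearson",
    normalize: bool = True,
) -> FGMSet:
    """Second-round network inference inside one CGM.

    Restrict to the CGM's genes, normalize on the core, log-transform, and
    rerun the embed-and-cluster pipeline at ``fgm_min_cluster_size``.
    ``normalize=False`` skips the core normalization (ablation mode: the
    shared core signal then typically masks all sub-structure).
    """
    cgm = set(cgm_genes)
    core = set(core_genes)
    if not core <= cgm:
        raise ValidationError("core genes must be a subset of the CGM genes")
    sub = expr.subset_genes(cgm)
    n_genes = sub.n_genes
    params = derive_params(expr.n_samples, fgm_min_cluster_size, seed)
    if n_genes <= params.n_neighbors or n_genes < 2 * fgm_min_cluster_size:
        logger.warning(
            "CGM of %d genes too small for fgm_min_cluster_size=%d; returning empty FGM set",
            n_genes,
            fgm_min_cluster_size,
        )
        empty = ModuleAssignment(
            gene_ids=sorted(cgm),
            labels=np.full(len(cgm), -1),
            level="FGM",
            parent_module=parent_cgm,
        )
        return FGMSet(parent_cgm=parent_cgm, assignment=empty)

    norm: NormalizationResult | None = None
    if normalize:
        norm = immfocus_normalize(
            sub, core, rho_threshold=rho_threshold, cv_ratio_threshold=cv_ratio_threshold
        )
        work = norm.normalized_expr.log2p1()
    else:
        work = sub.log2p1()

    adj = compute_adjacency(work, corr_method=corr_method)
    dissim = compute_dissimilarity(adj)
    emb = embed(dissim, params)
    assignment = cluster(emb, params, gene_ids=work.gene_ids, level="FGM")
    assignment.parent_module = parent_cgm
    return FGMSet(parent_cgm=parent_cgm, assignment=assignment, normalization=norm)
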