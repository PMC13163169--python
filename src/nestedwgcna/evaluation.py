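"""Module evaluation: stability, transcriptional coherence, sample scores.

Stability is quantified by comparing module assignments across bootstrap
pseudosamples (or across independent datasets) with three standard
partition-agreement indices: Adjusted Rand Index, Adjusted Mutual
Information and the V-measure. A bootstrap pseudosample draws n samples
with replacement, so it covers 1 - 1/e (~63.2%) of the original samples on
average.

Transcriptional coherence is the *knowledge score*: the odds ratio relating
"gene pair shares a module" (co-expressed pair, CP) to "gene pair shares at
least one transcription-factor regulator" (knowledge pair, KP), counted
over all N(N-1)/2 pairs of TF-annotated, module-assigned genes:

    score = (|CP&KP| * |~CP&~KP|) / (|~CP&KP| * |CP&~KP|)

with significance from Fisher's exact test on the 2x2 table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    v_measure_score,
)

from .matrix import ExpressionMatrix, ValidationError
from .module_detection import DEFAULT_MIN_CLUSTER_SIZE, ModuleAssignment, detect_cgms

__all__ = [
    "StabilityReport",
    "KnowledgeScore",
    "ModuleScore",
    "compare_clusterings",
    "bootstrap_stability",
    "knowledge_score",
    "score_module",
    "dichotomize_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    pairwise: pd.DataFrame  # columns: ari, ami, v_measure, one row per replicate pair
    n_replicates: int
    mode: str  # "bootstrap" | "cross_dataset"
    unique_sample_fractions: list[float] = field(default_factory=list)
    failed_replicates: int = 0

    @property
    def means(self) -> pd.Series:
        return self.pairwise.mean()

    @property
    def stds(self) -> pd.Series:
        return self.pairwise.std(ddof=1)

    @property
    def cv(self) -> pd.Series:
        return self.stds / self.means.abs()

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_replicates": self.n_replicates,
            "n_pairs": int(len(self.pairwise)),
            "mean": self.means.to_dict(),
            "std": self.stds.to_dict(),
            "cv": self.cv.to_dict(),
            "unique_sample_fractions": self.unique_sample_fractions,
            "failed_replicates": self.failed_replicates,
        }


@dataclass
class KnowledgeScore:
    counts: tuple[int, int, int, int]  # (CP&KP, ~CP&KP, CP&~KP, ~CP&~KP)
    score: float
    p_value: float
    n_tf_annotated_genes: int
    infinite: bool = False

    def to_dict(self) -> dict:
        a, b, c, d = self.counts
        return {
            "cp_kp": a,
            "not_cp_kp": b,
            "cp_not_kp": c,
            "not_cp_not_kp": d,
            "score": self.score,
            "p_value": self.p_value,
            "n_tf_annotated_genes": self.n_tf_annotated_genes,
            "infinite": self.infinite,
        }


@dataclass
class ModuleScore:
    module_id: str
    raw: pd.Series  # per-sample mean z-scored log expression
    normalized: pd.Series | None = None  # raw(module) - raw(core), or ratio
    mode: str = "difference"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"raw": self.raw})
        if self.normalized is not None:
            df["normalized"] = self.normalized
        return df


def compare_clusterings(
    a: ModuleAssignment, b: ModuleAssignment
) -> tuple[float, float, float]:
    """(ARI, AMI, V-measure) between two assignments over their shared genes.

    Noise (-1) is treated as a cluster of its own; the comparison is
    invariant to label permutation and symmetric in its arguments.
    """
    common = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not common:
        raise ValidationError("assignments share no genes")
    if len(common) != len(a.gene_ids) or len(common) != len(b.gene_ids):
        logger.info(
            "comparing on %d shared genes (of %d / %d)",
            len(common), len(a.gene_ids), len(b.gene_ids),
        )
    sa = a.to_series().loc[common].to_numpy()
    sb = b.to_series().loc[common].to_numpy()
    return (
        float(adjusted_rand_score(sa, sb)),
        float(adjusted_mutual_info_score(sa, sb)),
        float(v_measure_score(sa, sb)),
    )


def draw_bootstrap_columns(
    sample_ids: list[str], rng: np.random.Generator
) -> tuple[list[str], float]:
    """Draw n sample columns with replacement; also return the unique fraction."""
    n = len(sample_ids)
    idx = rng.integers(0, n, size=n)
    unique_fraction = len(np.unique(idx)) / n
    return [sample_ids[i] for i in idx], unique_fraction


def bootstrap_stability(
    expr: ExpressionMatrix,
    B: int = 10,
    seed: int = 0,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    corr_method: str = "pearson",
) -> StabilityReport:
    """Stability of CGM detection under bootstrap resampling of samples.

    Each of the B pseudosamples redraws the sample columns with replacement
    (covering ~63.2% unique samples) and reruns CGM detection on the same
    gene set; all replicate pairs are compared with ARI/AMI/V.
    """
    if B < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    assignments: list[ModuleAssignment] = []
    fractions: list[float] = []
    failed = 0
    for b in range(B):
        cols, frac = draw_bootstrap_columns(expr.sample_ids, rng)
        fractions.append(frac)
        # duplicate draws are kept: a bootstrap weights samples by multiplicity
        data = expr.data.loc[:, cols]
        data.columns = [f"bs{b}_{i}" for i in range(len(cols))]
        try:
            boot = ExpressionMatrix(data, space=expr.space)
            rep_seed = int(rng.integers(0, 2**31 - 1))
            assignments.append(
                detect_cgms(boot, min_cluster_size=min_cluster_size,
                            seed=rep_seed, corr_method=corr_method)
            )
        except Exception as exc:  # pragma: no cover - defensive
            failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if len(assignments) < 2:
        raise ValidationError("fewer than 2 bootstrap replicates succeeded")
    rows = []
    for i, j in combinations(range(len(assignments)), 2):
        ari, ami, v = compare_clusterings(assignments[i], assignments[j])
        rows.append({"ari": ari, "ami": ami, "v_measure": v})
    return StabilityReport(
        pairwise=pd.DataFrame(rows),
        n_replicates=len(assignments),
        mode="bootstrap",
        unique_sample_fractions=fractions,
        failed_replicates=failed,
    )


def cross_dataset_stability(
    a: ModuleAssignment, b: ModuleAssignment
) -> StabilityReport:
    """Compare two assignments from independent datasets on their shared genes."""
    ari, ami, v = compare_clusterings(a, b)
    return StabilityReport(
        pairwise=pd.DataFrame([{"ari": ari, "ami": ami, "v_measure": v}]),
        n_replicates=2,
        mode="cross_dataset",
    )


def knowledge_score(
    modules: ModuleAssignment,
    tf_targets: dict[str, set[str]],
    alternative: str = "greater",
) -> KnowledgeScore:
    """Odds ratio of co-module membership against shared TF regulation.

    The universe is restricted to genes that (i) carry at least one TF
    annotation and (ii) are assigned to a real module (noise excluded).
    """
    annotated = set()
    for targets in tf_targets.values():
        annotated |= set(targets)
    universe = [
        g for g, l in zip(modules.gene_ids, modules.labels)
        if l >= 0 and g in annotated
    ]
    n = len(universe)
    if n < 2:
        raise ValidationError("fewer than 2 TF-annotated genes in real modules")

    labels = modules.to_series().loc[universe].to_numpy()
    tf_names = sorted(tf_targets)
    gene_idx = {g: i for i, g in enumerate(universe)}
    member = np.zeros((n, len(tf_names)), dtype=bool)
    for j, tf in enumerate(tf_names):
        for g in tf_targets[tf]:
            if g in gene_idx:
                member[gene_idx[g], j] = True

    same_module = labels[:, None] == labels[None, :]
    shares_tf = member @ member.T > 0
    iu = np.triu_indices(n, k=1)
    cp = same_module[iu]
    kp = shares_tf[iu]
    a = int(np.sum(cp & kp))
    b = int(np.sum(~cp & kp))
    c = int(np.sum(cp & ~kp))
    d = int(np.sum(~cp & ~kp))
    assert a + b + c + d == n * (n - 1) // 2

    infinite = b * c == 0
    score = float("inf") if infinite else (a * d) / (b * c)
    table = [[a, c], [b, d]]  # rows: KP yes/no, cols: CP yes/no
    _, p = fisher_exact(table, alternative=alternative)
    if infinite:
        logger.warning("knowledge score denominator is zero; reporting +inf")
    return KnowledgeScore(
        counts=(a, b, c, d),
        score=score,
        p_value=float(p),
        n_tf_annotated_genes=n,
        infinite=infinite,
    )


def score_module(
    expr: ExpressionMatrix,
    module_genes: set[str] | list[str],
    core_genes: set[str] | list[str] | None = None,
    module_id: str = "module",
    mode: str = "difference",
) -> ModuleScore:
    """Per-sample module signature score.

    raw = mean over module genes of the z-scored (across samples) log2(x+1)
    expression. With ``core_genes`` given, the normalized score is
    raw(module) - raw(core) by default — the sub-process activity relative
    to the whole process — or raw(module) / raw(core) in ``ratio`` mode.
    """
    genes = sorted(set(module_genes))
    if not genes:
        raise ValidationError("cannot score an empty module")

    def _raw(gene_set: list[str]) -> pd.Series:
        sub = expr.log2p1().subset_genes(gene_set)
        x = sub.values
        sd = x.std(axis=1)
        sd[sd == 0] = 1.0  # constant genes contribute a flat zero z-score
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        return pd.Series(z.mean(axis=0), index=expr.sample_ids)

    raw = _raw(genes)
    normalized = None
    if core_genes is not None:
        core_raw = _raw(sorted(set(core_genes)))
        if mode == "difference":
            normalized = raw - core_raw
        elif mode == "ratio":
            normalized = raw / core_raw.replace(0, np.nan)
        else:
            raise ValidationError(f"unknown score mode {mode!r}")
    return ModuleScore(module_id=module_id, raw=raw, normalized=normalized, mode=mode)


def dichotomize_scores(scores: pd.Series) -> pd.Series:
    """Median split into 'high'/'low'; values at the median count as low."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 samples to dichotomize")
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="group"
    )
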