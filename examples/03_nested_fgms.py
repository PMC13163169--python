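"""Unmask fine-grained modules by normalizing a module on its core signal.

The nested scenario plants one coarse module whose periphery hides three
compact sub-blocks (each mixing induced and repressed targets of its
sub-process) behind a strong shared signal. Dividing each gene by the
per-sample mean of the core-tracking gene set (INGS) removes that signal;
re-clustering then recovers the sub-blocks, while re-clustering without
the normalization does not.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import nestedwgcna as nw
from nestedwgcna.nested_inference import _spearman_vs_vector

ds = nw.generate(nw.scenario("nested", seed=0))
cgm_genes = ds.truth_cgm.module_genes(0)
core = ds.truth_core[0]
truth = ds.truth_fgm[0].to_series()
planted = truth.values >= 0

fgm = nw.infer_fgms(ds.expr, cgm_genes, core, fgm_min_cluster_size=15, seed=0)
ablation = nw.infer_fgms(
    ds.expr, cgm_genes, core, fgm_min_cluster_size=15, seed=0, normalize=False
)

res = fgm.normalization
print(f"INGS: {len(res.ings_initial)} genes pass Spearman rho > 0.9, "
      f"{len(res.ings_final)} kept after the CV-ratio filter")

noncore = [g for g in cgm_genes if g not in core]
sub = ds.expr.subset_genes(cgm_genes)
pre = _spearman_vs_vector(sub.subset_genes(noncore).values, res.eigengene.values)
post = _spearman_vs_vector(
    res.normalized_expr.subset_genes(noncore).values, res.eigengene.values
)
print(f"mean |rho| of non-core genes vs core eigengene: "
      f"{np.abs(pre).mean():.2f} before -> {np.abs(post).mean():.2f} after normalization")


def planted_ari(assignment):
    return adjusted_rand_score(
        truth[planted], assignment.to_series().loc[truth.index[planted]]
    )


print(f"with core normalization:    {fgm.n_fgms} FGMs, "
      f"ARI vs planted sub-blocks {planted_ari(fgm.assignment):.2f}")
print(f"without normalization:      {ablation.n_fgms} clusters, "
      f"ARI vs planted sub-blocks {planted_ari(ablation.assignment):.2f}")
print(
    "# the shared core signal masks the sub-blocks (their anti-regulated halves\n"
    "# end up farther apart than unrelated genes); removing it reveals them"
)
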