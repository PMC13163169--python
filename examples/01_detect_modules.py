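"""Detect coarse-grained co-expression modules on simulated bulk RNA-Seq.

Generates the four-module study scenario (4 planted modules of 300 genes,
50 housekeeping genes, 500 noise genes, 150 samples), runs the first-round
pipeline (squared-correlation adjacency -> 1-a dissimilarity -> UMAP ->
HDBSCAN) and compares the result with the planted structure.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import nestedwgcna as nw

ds = nw.generate(nw.scenario("default", seed=0))
print(f"simulated {ds.expr.n_genes} genes x {ds.expr.n_samples} samples")

detected = nw.detect_cgms(ds.expr, min_cluster_size=50, seed=0)
sizes = {m: len(detected.module_genes(m)) for m in detected.module_ids}
print(f"detected {detected.n_modules} modules, sizes {sizes}")
print(f"{len(detected.noise_genes)} genes left unassigned (noise)")

truth = ds.truth_cgm.to_series()
planted = truth.values >= 0
ari = adjusted_rand_score(
    truth[planted], detected.to_series().loc[truth.index[planted]]
)
print(f"ARI against the planted modules (planted genes only): {ari:.3f}")
print(
    "# ARI 1.0 means every planted module was recovered exactly; the extra\n"
    "# detected module collects the mutually correlated housekeeping genes\n"
    "# plus some residual noise genes."
)
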