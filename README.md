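# nestedwgcna

Two-stage (nested) weighted gene co-expression network analysis for bulk
RNA-Seq. The package is aimed at transcriptomics researchers who want to go
beyond the broad gene modules that a single clustering pass produces — large
clusters tracking major cell types or processes — and resolve the compact,
self-standing gene programs hidden inside them (cell subsets, subprocesses),
for example as candidate biomarkers of treatment response.

## The method

**First round — coarse-grained modules (CGMs).** From a genes × samples
expression matrix (TPM scale; correlations are computed on log2(x+1)),
the adjacency between genes *i* and *j* is the coefficient of determination

    a_ij = cor(x_i, x_j)^2

i.e. the classic WGCNA soft threshold with the exponent fixed at β = 2, so no
scale-free fitting is needed and each entry reads as "fraction of variance
explained". The dissimilarity is simply `d_ij = 1 − a_ij`; unlike the
topological-overlap/Szymkiewicz–Simpson dissimilarity it gives duplicated
genes a distance of exactly zero and does not let broadly connected
housekeeping genes masquerade as module members. Genes are embedded with
UMAP (treating `d` as precomputed distances, `n_components ≈ log2(N)+1`
with *N* the sample count, `n_neighbors = 2·min_cluster_size`) and clustered
with HDBSCAN (`min_samples = min_cluster_size/2`); `min_cluster_size` is the
only free parameter.

**Core extraction.** Each module's *core* is the maximum weighted k-core of
its complete co-expression subgraph (edge weights `a_ij`): nodes are peeled
in order of minimum weighted degree, the core number `c(u)` is the largest
*k* for which *u* survives in the *k*-core, and the core is the node set at
graph degeneracy — the densest, most mutually correlated subset.

**Second round — fine-grained modules (FGMs).** Module genes are normalized
on the core signal: the core's eigengene (first principal component across
samples) selects the INGS — genes with Spearman ρ > 0.9 to the eigengene;
each gene in each sample is divided by that sample's mean INGS expression
(INGS members are divided by the mean of the *remaining* members); INGS
genes whose coefficient of variation shrank (ratio < 0.8) form the final
INGS used for a second normalization pass. Re-running the network inference
on the normalized module then yields compact FGMs — gene sets that stay
correlated once the dominant shared signal is gone.

**Evaluation.** Bootstrap and cross-dataset stability (ARI / AMI /
V-measure), a TF-coregulation *knowledge score* (the odds ratio
`(|CP∩KP|·|¬CP∩¬KP|)/(|¬CP∩KP|·|CP∩¬KP|)` over all pairs of TF-annotated
module genes, with Fisher's exact test), and per-sample module scores
(mean z-scored log expression, optionally net of the parent core) with a
median high/low split.

A fully tested synthetic-data generator plants hierarchical structure
(module factors, nested sub-factors with induced and repressed targets,
housekeeping genes, noise) so every stage can be validated without any
external download.

## Worked example

`examples/03_nested_fgms.py` plants one coarse module whose periphery hides
three sub-blocks behind a strong shared signal, then runs FGM inference with
and without the core normalization:

```text
INGS: 226 genes pass Spearman rho > 0.9, 226 kept after the CV-ratio filter
mean |rho| of non-core genes vs core eigengene: 0.89 before -> 0.06 after normalization
with core normalization:    5 FGMs, ARI vs planted sub-blocks 1.00
without normalization:      2 clusters, ARI vs planted sub-blocks 0.28
```

Reading: before normalization every module gene tracks the core eigengene
(mean |ρ| 0.89), and re-clustering recovers nothing useful (ARI 0.28) —
the sub-blocks are masked, since each one mixes induced and repressed
targets whose correlation through the shared signal pulls them apart.
After dividing out the core signal the residual correlations are nearly
zero against the eigengene (0.06) but intact within sub-blocks, and all
three planted blocks are recovered exactly (ARI 1.00). The other example
scripts cover first-round detection (`01`), weighted k-core extraction
(`02`) and the evaluation utilities (`04`).

The same pipeline is scriptable from the shell:

```bash
nestedwgcna simulate --scenario default --seed 0 --out expr.tsv
nestedwgcna run --input expr.tsv --min-cluster-size 50 --seed 0 --outdir out/
nestedwgcna kscore --modules out/modules.gmt --tf-targets tf.gmt --out ks.json
```

`out/modules.gmt` holds one gene set per module (`CGM_k`), its core
(`CGM_k_core`) and each fine-grained module (`CGM_k_FGM_j`);
`run_metadata.json` records every parameter, derived value and seed.

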