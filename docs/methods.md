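# Methods

## Model and assumptions

The package treats bulk expression as a superposition of latent sample-level
signals. A coarse-grained module (CGM) is a set of genes dominated by one
such signal — the abundance of a cell type or the activity of a major
process; fine-grained modules (FGMs) are gene sets that remain mutually
correlated once that dominant signal is removed. Three assumptions follow:

1. Pairwise association is adequately captured by squared correlation
   (`a = cor²`, Pearson by default on log2(x+1) values). Squaring makes
   induced and repressed targets of the same signal equally similar — a
   deliberate property, since a regulon contains both.
2. Density-based clustering of a low-dimensional embedding of `d = 1 − a`
   finds modules; genes that belong to no dense region stay unassigned
   (label −1) rather than being forced into a module.
3. Normalization factors are meaningful only in linear (TPM-scale) space:
   the per-sample INGS mean is an average of expression values, so the
   normalization stage refuses log-space input, while every correlation
   step log-transforms first. This split is enforced by the
   `ExpressionMatrix.space` tag.

`d = 1 − cor²` is symmetric, non-negative and zero exactly for perfectly
(anti-)correlated genes, but it is not a metric — three vectors with
pairwise correlations cos30°, cos30°, cos60° violate the triangle
inequality. Nothing downstream relies on metric axioms (UMAP accepts
arbitrary precomputed dissimilarities).

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `min_cluster_size` (CGM) | 50 | the one user-facing knob; smallest believable module. Real CGMs span ~100–1000 genes, so 50 is a conservative floor |
| `fgm_min_cluster_size` | 15 | FGMs are compact (tens of genes); must sit below the smallest interesting sub-program |
| `n_components` | round(log2(N)+1), min 2 | embedding dimensionality grows slowly with sample count N; fixed 2–3D loses structure, high D defeats density clustering |
| `n_neighbors` | 2·min_cluster_size | neighborhoods wide enough to keep clusters connected without smoothing real boundaries |
| `min_samples` | min_cluster_size // 2, min 1 | HDBSCAN density-estimate convention |
| `beta` | 2 (fixed) | adjacency = coefficient of determination; no scale-free fitting |
| `rho_threshold` | 0.9 | Spearman gate selecting the INGS: genes that track the core eigengene almost deterministically |
| `cv_ratio_threshold` | 0.8 | an INGS gene whose coefficient of variation did not shrink by ≥20% after the first pass was not really driven by the core signal |
| `me_threshold` | 1/e ≈ 0.368 | misclassification error `1 − modal-frequency/N`; genes below it are nearly constant and unstable under bootstrap (a pseudosample covers 1 − 1/e of samples) |
| normalization pseudocount | 1e−9 | guards division by near-zero INGS means |
| core-number tolerance | 1e−9 | real-valued weighted degrees; degeneracy comparisons and nestedness checks use this slack |

## Numerical and design choices

- **Correlation space.** Adjacency is computed on log2(x+1) of linear
  input by default (variance stabilization, standard co-expression
  practice); Spearman is available by flag and is rank-equivalent in both
  spaces.
- **Weighted k-core.** Peeling with a lazy binary heap; ties in the current
  minimum weighted degree are broken by lexicographic gene id, making the
  decomposition deterministic and node-order independent. Edge weights for
  core extraction are the adjacency values on the complete module subgraph
  — no edge thresholding.
- **Eigengene.** First right singular vector of the gene-standardized
  (z-scored per gene) log-expression of the core, sign-oriented to
  correlate positively with mean core expression, so "high eigengene"
  always means "core genes up".
- **Self-exclusion in normalization.** An INGS gene is divided by the mean
  of the *other* INGS members (leave-one-out), so a gene never normalizes
  itself; non-INGS genes are divided by the full INGS mean.
- **Labels.** Module labels are re-indexed 0,1,2,… by decreasing size;
  −1 always means unassigned. All comparisons use permutation-invariant
  indices (ARI/AMI/V) with −1 treated as its own cluster.
- **Determinism.** UMAP runs single-threaded under a fixed `random_state`;
  with the seeded generator, two runs of the full pipeline produce
  byte-identical GMT output (verified in the acceptance checks).
- **Module scores.** Raw score = per-sample mean of z-scored log2(x+1)
  expression over module genes. The core-normalized score is the
  *difference* raw(module) − raw(core) rather than a ratio: it is
  scale-free, defined when the core score is 0, and monotone in the same
  contrast; a ratio mode exists by flag. Fisher's exact test for the
  knowledge score is one-sided (greater) by default, matching the
  enrichment direction of the odds ratio; two-sided by flag.
- **Degenerate inputs.** Zero-variance genes are rejected by name at
  adjacency time; an empty INGS raises with advice to lower the threshold;
  a module too small for FGM inference yields an all-noise FGM set with a
  warning; in the full pipeline a module failing its normalization gate
  logs a warning and contributes no FGMs instead of aborting the run.

## The synthetic-data generator

`synthetic_data` draws a Gaussian factor model in the log domain:
per-sample standard-normal module factors `F_c`, sub-factors `S_cj`
(independent of `F_c` by default; a `subfactor_core_corr` option couples
them for robustness runs), per-gene loadings, i.i.d. Gaussian noise
(optionally with per-gene sd jitter), then `expression = 100 · 2^(log
signal)` — strictly positive, TPM-like. Closed forms make the generator
self-verifiable: two genes sharing only a loading-λ factor correlate
λ²/(λ²+σ²) in the log domain, and the acceptance checks confirm the
empirical value within ±0.05 at 500 samples.

Scenario presets define the study conditions:

- **default** — 150 samples; 4 modules × 300 genes (40% core at loading
  0.9, periphery 0.6, three 40-gene sub-blocks at 0.6), 50 housekeeping
  genes loading 0.3 on *every* module factor, 500 noise genes, noise sd 1.
- **nested** — one module (core/periphery loadings 1.0, noise sd 0.4)
  whose periphery hides three 22-gene sub-blocks at loading 0.5 with 45%
  *repressed* (negative-loading) targets. The loadings put core genes above
  the Spearman-0.9 INGS gate (model correlation 1/√1.16 ≈ 0.93) and
  periphery genes in the 0.7–0.9 band below it. The signed sub-blocks are
  what makes the ablation informative: through the shared core signal, an
  induced and a repressed target of the same sub-process are *less*
  correlated than unrelated genes, so before normalization each block's
  two halves fall below the detectable cluster size and recovery fails;
  after normalization the sign-blind `cor²` similarity sees each block
  whole. In a sign-uniform factor model, by contrast, removing a shared
  factor leaves within/between-block neighbor orderings essentially
  unchanged and re-clustering succeeds with or without normalization —
  the masking phenomenon genuinely requires mixed-sign regulation (or
  some other ordering-corrupting structure), which real regulons have.
- **core_periphery** — one module with a high-loading core sub-block, for
  core-extraction checks (the maximum core recovers ≥90% of the planted
  core at ~37% of the module size, consistent with cores being 30–70% of
  their module).
- **noise_only** and **null_cgm** — negative controls for detection and
  FGM inference.

What the generator does *not* emulate: library-size and batch effects,
count noise (it is log-Gaussian, not negative-binomial), dropout, and
heavy-tailed expression baselines. Passing tests therefore demonstrate the
machinery — recovery, unmasking, determinism, exactness of the
decomposition — under the assumed factor structure, not performance on
real cohorts with technical artifacts.

## Known limitations

- **UMAP blob artifact.** Mutually uncorrelated genes (all nearly
  equidistant) can be embedded into compact blobs that HDBSCAN reports as
  clusters: in the default scenario a few dozen of the 500 noise genes are
  absorbed into modules or form small spurious clusters, and in the null
  scenario the de-correlated genes yield 1–2 artifact "FGMs" with no
  internal co-expression (within-cluster mean |r| < 0.3 — the test-suite
  coherence check distinguishes them from real sub-modules). Whole-universe
  agreement scores are diluted accordingly: planted-gene ARI is 1.0 where
  the all-gene ARI is ~0.7–0.8, and bootstrap replicate agreement on the
  default scenario runs ~0.66 for the same reason.
- **Housekeeping genes** form a genuine (weak) cluster of their own under
  the default conditions — they are mutually correlated through every
  module factor. They are correctly kept out of module cores, which is the
  failure mode the squared-correlation dissimilarity is designed to avoid.
- The INGS gate (ρ > 0.9) is demanding: on data where no gene tracks the
  core eigengene that tightly, normalization refuses with an explicit
  error rather than silently normalizing on a poor factor.
- Problem sizes in the test and acceptance suites (≈300–1750 genes,
  60–150 samples, 5 seeds) are chosen to exercise every code path at
  desk scale; the implementation itself is dense double-precision and is
  comfortable to ~25k genes.
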