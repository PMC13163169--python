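"""Eigengene, core-signal normalization, and FGM inference."""

import numpy as np
import pytest

import nestedwgcna as nw
from nestedwgcna.matrix import ValidationError
from nestedwgcna.nested_inference import _spearman_vs_vector

from conftest import make_expr, nested_dataset, nested_fgm, restricted_ari


def _corr(a, b):
    return float(np.corrcoef(np.asarray(a), np.asarray(b))[0, 1])


class TestEigengene:
    def test_rank_one_case(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = make_expr([10 * v, 2 * v, 5 * v], space="log")
        eig = nw.compute_eigengene(expr, {"g0", "g1", "g2"})
        assert abs(_corr(eig, v)) == pytest.approx(1.0, abs=1e-9)
        assert _corr(eig, v) > 0  # oriented along mean core expression

    def test_noisy_common_signal(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=80)
        rows = [v + 0.1 * rng.normal(size=80) for _ in range(20)]
        expr = make_expr(rows, space="log")
        eig = nw.compute_eigengene(expr, set(expr.gene_ids))
        assert _corr(eig, v) > 0.99

    def test_orientation_stable_under_loading_sign_flip(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50)
        rows = [v + 0.05 * rng.normal(size=50) for _ in range(6)]
        expr = make_expr(rows, space="log")
        flipped = make_expr([-r for r in rows], space="log")
        e1 = nw.compute_eigengene(expr, set(expr.gene_ids))
        e2 = nw.compute_eigengene(flipped, set(flipped.gene_ids))
        # orientation follows each matrix's own mean profile
        assert _corr(e1, v) > 0.99
        assert _corr(e2, -v) > 0.99

    def test_rank_zero_error(self):
        expr = make_expr([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], space="log")
        with pytest.raises(ValidationError):
            nw.compute_eigengene(expr, {"g0", "g1"})


class TestImmfocusNormalize:
    def test_single_factor_cancels_exactly(self):
        """Pure rank-one data: normalization flattens every gene."""
        factor = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        loadings = np.array([2.0, 5.0, 1.0, 3.0])
        expr = make_expr(np.outer(loadings, factor))
        res = nw.immfocus_normalize(expr, {"g0", "g1"})
        out = res.normalized_expr.values
        np.testing.assert_allclose(out, out[:, [0]] * np.ones_like(out), rtol=1e-6)

    def test_ings_nesting_and_positive_factors(self):
        ds = nested_dataset(0)
        _, fgm = nested_fgm(0, True)
        res = fgm.normalization
        assert res.ings_final <= res.ings_initial
        assert (res.f_ings > 0).all()
        assert set(res.cv_ratio.index) == res.ings_initial

    def test_impossible_threshold_errors(self):
        rng = np.random.default_rng(3)
        expr = make_expr(np.abs(rng.normal(5, 1, size=(10, 20))))
        with pytest.raises(ValidationError, match="rho_threshold"):
            nw.immfocus_normalize(expr, set(expr.gene_ids[:4]), rho_threshold=1.0)

    def test_requires_linear_space(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(5, 10)), space="log")
        with pytest.raises(ValidationError, match="linear"):
            nw.immfocus_normalize(expr, set(expr.gene_ids[:2]))

    def test_scale_invariance(self):
        ds = nested_dataset(0)
        sub = ds.expr.subset_genes(ds.truth_cgm.module_genes(0))
        r1 = nw.immfocus_normalize(sub, ds.truth_core[0])
        scaled = make_expr(sub.values * 7.0, gene_ids=sub.gene_ids, sample_ids=sub.sample_ids)
        r2 = nw.immfocus_normalize(scaled, ds.truth_core[0])
        np.testing.assert_allclose(
            r1.normalized_expr.values, r2.normalized_expr.values, rtol=1e-9
        )

    def test_decorrelates_periphery_from_core_eigengene(self):
        """The shared core signal is removed: non-core genes drop from
        strong to near-zero correlation with the core eigengene."""
        ds = nested_dataset(0)
        cgm = ds.truth_cgm.module_genes(0)
        sub = ds.expr.subset_genes(cgm)
        res = nw.immfocus_normalize(sub, ds.truth_core[0])
        noncore = [g for g in cgm if g not in ds.truth_core[0]]
        pre = _spearman_vs_vector(
            sub.subset_genes(noncore).values, res.eigengene.values
        )
        post = _spearman_vs_vector(
            res.normalized_expr.subset_genes(noncore).values, res.eigengene.values
        )
        assert np.abs(pre).mean() > 0.7
        assert np.abs(post).mean() < 0.3


class TestInferFgms:
    def test_recovers_planted_subblocks(self):
        ds, fgm = nested_fgm(0, True)
        truth = ds.truth_fgm[0].to_series()
        ari = restricted_ari(truth, fgm.assignment.to_series())
        assert ari >= 0.8

    def test_ablation_without_normalization_masks_subblocks(self):
        """Omitting the core normalization leaves the shared signal in
        place; the signed sub-block halves fracture and recovery fails."""
        ds, raw = nested_fgm(0, False)
        truth = ds.truth_fgm[0].to_series()
        ari = restricted_ari(truth, raw.assignment.to_series())
        assert ari <= 0.4

    def test_fgm_genes_partition_parent(self):
        ds, fgm = nested_fgm(0, True)
        cgm = set(ds.truth_cgm.module_genes(0))
        seen: set[str] = set()
        for genes in fgm.fgm_genes.values():
            assert set(genes) <= cgm
            assert not (set(genes) & seen)
            seen |= set(genes)
        assert set(fgm.assignment.gene_ids) == cgm

    def test_null_scenario_finds_no_coherent_submodule(self):
        """Without planted sub-factors, any clusters in the normalized
        space are embedding artifacts with no internal co-expression."""
        ds = nw.generate(nw.scenario("null_cgm", seed=0))
        cgm = ds.truth_cgm.module_genes(0)
        fgm = nw.infer_fgms(ds.expr, cgm, ds.truth_core[0], seed=0)
        norm_log = fgm.normalization.normalized_expr.log2p1()
        for genes in fgm.fgm_genes.values():
            r = np.corrcoef(norm_log.subset_genes(genes).values)
            mean_abs = np.abs(r[np.triu_indices_from(r, k=1)]).mean()
            assert mean_abs < 0.3

        # the nested scenario's recovered blocks, by contrast, are coherent
        _, nested = nested_fgm(0, True)
        truth_blocks = nested_dataset(0).truth_fgm[0]
        norm_log = nested.normalization.normalized_expr.log2p1()
        coherences = []
        for j in truth_blocks.module_ids:
            r = np.corrcoef(norm_log.subset_genes(truth_blocks.module_genes(j)).values)
            coherences.append(np.abs(r[np.triu_indices_from(r, k=1)]).mean())
        assert min(coherences) > 0.3

    def test_too_small_cgm_yields_empty_fgmset(self, caplog):
        ds = nested_dataset(0)
        tiny = ds.truth_cgm.module_genes(0)[:20]
        fgm = nw.infer_fgms(ds.expr, tiny, set(tiny[:5]), fgm_min_cluster_size=15, seed=0)
        assert fgm.n_fgms == 0
        assert set(fgm.assignment.labels) == {-1}

    def test_core_must_be_subset(self):
        ds = nested_dataset(0)
        with pytest.raises(ValidationError, match="subset"):
            nw.infer_fgms(ds.expr, ds.truth_cgm.module_genes(0)[:50], {"NOT_A_GENE"})
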