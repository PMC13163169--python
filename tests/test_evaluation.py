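"""Stability metrics, knowledge score, and per-sample module scores."""

from math import comb

import numpy as np
import pandas as pd
import pytest

import nestedwgcna as nw
from nestedwgcna.evaluation import draw_bootstrap_columns
from nestedwgcna.matrix import ValidationError

from conftest import FAST_TWO_CGM, fast_dataset, make_expr, restricted_ari


def assignment(gene_ids, labels):
    return nw.ModuleAssignment(gene_ids=list(gene_ids), labels=np.asarray(labels))


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p as an exact hypergeometric tail sum."""
    n = a + b + c + d
    kp, cp = a + b, a + c
    total = comb(n, cp)
    return sum(
        comb(kp, x) * comb(n - kp, cp - x)
        for x in range(a, min(kp, cp) + 1)
    ) / total


def brute_force_knowledge_counts(labels: dict, tf_map: dict):
    """Count CP/KP pair categories by direct enumeration."""
    genes = sorted(labels)
    tf_of = {g: {t for t, targets in tf_map.items() if g in targets} for g in genes}
    a = b = c = d = 0
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            cp = labels[gi] == labels[gj]
            kp = bool(tf_of[gi] & tf_of[gj])
            if cp and kp:
                a += 1
            elif kp:
                b += 1
            elif cp:
                c += 1
            else:
                d += 1
    return a, b, c, d


class TestCompareClusterings:
    def test_identical_and_permuted(self):
        genes = [f"g{i}" for i in range(30)]
        a = assignment(genes, [i % 3 for i in range(30)])
        b = assignment(genes, [(i % 3 + 1) % 3 for i in range(30)])
        assert nw.compare_clusterings(a, a) == (1.0, 1.0, 1.0)
        ari, ami, v = nw.compare_clusterings(a, b)
        assert (ari, ami, v) == (1.0, 1.0, 1.0)

    def test_trivial_partition_has_zero_ari(self):
        genes = [f"g{i}" for i in range(1000)]
        one = assignment(genes, [0] * 1000)
        ten = assignment(genes, [i // 100 for i in range(1000)])
        ari, _, _ = nw.compare_clusterings(one, ten)
        assert ari == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_intersection(self):
        a = assignment([f"g{i}" for i in range(20)], [i % 2 for i in range(20)])
        b = assignment([f"g{i}" for i in range(10, 30)], [i % 4 for i in range(20)])
        assert nw.compare_clusterings(a, b) == nw.compare_clusterings(b, a)
        with pytest.raises(ValidationError):
            nw.compare_clusterings(a, assignment(["x"], [0]))


class TestBootstrap:
    def test_unique_fraction_near_632(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(500)]
        fracs = [draw_bootstrap_columns(ids, rng)[1] for _ in range(50)]
        assert np.mean(fracs) == pytest.approx(1 - 1 / np.e, abs=0.01)

    def test_two_replicates_one_pair(self):
        ds = fast_dataset(0)
        rep = nw.bootstrap_stability(ds.expr, B=2, seed=0, min_cluster_size=30)
        assert rep.n_replicates == 2
        assert len(rep.pairwise) == 1
        assert {"ari", "ami", "v_measure"} <= set(rep.pairwise.columns)

    def test_planted_structure_is_stable(self):
        """Replicate detections agree on the planted module genes."""
        ds = fast_dataset(0)
        rng = np.random.default_rng(1)
        truth = ds.truth_cgm.to_series()
        dets = []
        for b in range(3):
            cols, _ = draw_bootstrap_columns(ds.expr.sample_ids, rng)
            data = ds.expr.data.loc[:, cols]
            data.columns = [f"b{b}_{i}" for i in range(len(cols))]
            boot = nw.ExpressionMatrix(data, space="linear")
            dets.append(nw.detect_cgms(boot, min_cluster_size=30, seed=b))
        aris = [
            restricted_ari(truth, d.to_series())
            for d in dets
        ]
        assert np.mean(aris) >= 0.8


class TestKnowledgeScore:
    def _fixture(self):
        # two coherent modules, each regulated by its own TF, plus overlap
        labels = {f"g{i}": (0 if i < 6 else 1) for i in range(12)}
        tf_map = {
            "TF_A": {"g0", "g1", "g2", "g3"},
            "TF_B": {"g6", "g7", "g8", "g9"},
            "TF_C": {"g4", "g5", "g10", "g11", "g0"},
        }
        return labels, tf_map

    def test_counts_and_score_match_enumeration_oracle(self):
        labels, tf_map = self._fixture()
        modules = assignment(labels.keys(), list(labels.values()))
        ks = nw.knowledge_score(modules, tf_map)
        a, b, c, d = brute_force_knowledge_counts(labels, tf_map)
        assert ks.counts == (a, b, c, d)
        n = len(labels)
        assert sum(ks.counts) == n * (n - 1) // 2
        assert ks.score == pytest.approx((a * d) / (b * c))

    def test_fisher_p_matches_hypergeometric_oracle(self):
        labels, tf_map = self._fixture()
        modules = assignment(labels.keys(), list(labels.values()))
        ks = nw.knowledge_score(modules, tf_map)
        assert ks.p_value == pytest.approx(hypergeom_tail_p(*ks.counts), abs=1e-9)

    def test_noise_genes_excluded_from_universe(self):
        genes = [f"g{i}" for i in range(8)]
        modules = assignment(genes, [0, 0, 1, 1, -1, -1, -1, -1])
        tf_map = {"TF": set(genes)}
        ks = nw.knowledge_score(modules, tf_map)
        assert ks.n_tf_annotated_genes == 4
        assert sum(ks.counts) == 6

    def test_zero_denominator_reports_inf(self):
        genes = [f"g{i}" for i in range(4)]
        modules = assignment(genes, [0, 0, 1, 1])
        tf_map = {"TF_A": {"g0", "g1"}, "TF_B": {"g2", "g3"}}
        ks = nw.knowledge_score(modules, tf_map)
        assert ks.infinite and ks.score == float("inf")

    def test_random_labels_concentrate_at_one(self):
        """Independent modules and TF annotations give an odds ratio ~1."""
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        tf_map = {
            f"TF{t}": set(rng.choice(genes, size=12, replace=False))
            for t in range(8)
        }
        scores = []
        for _ in range(200):
            labels = rng.integers(0, 5, size=50)
            ks = nw.knowledge_score(assignment(genes, labels), tf_map)
            if np.isfinite(ks.score):
                scores.append(ks.score)
        assert 0.8 <= np.mean(scores) <= 1.25


class TestModuleScore:
    def test_module_equal_to_core_scores_zero(self):
        rng = np.random.default_rng(0)
        expr = make_expr(np.abs(rng.normal(4, 1, size=(6, 20))))
        genes = set(expr.gene_ids[:4])
        ms = nw.score_module(expr, genes, core_genes=genes)
        np.testing.assert_allclose(ms.normalized.values, 0.0, atol=1e-12)

    def test_single_gene_raw_is_its_zscore(self):
        rng = np.random.default_rng(1)
        expr = make_expr(np.abs(rng.normal(4, 1, size=(3, 15))))
        ms = nw.score_module(expr, {"g1"})
        x = np.log2(expr.values[1] + 1)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(ms.raw.values, z, atol=1e-12)

    def test_affine_invariance_in_log_space(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(5, 12))
        a = make_expr(values, space="log")
        b = make_expr(values * 2.5 + 3.0, space="log")
        s1 = nw.score_module(a, set(a.gene_ids))
        s2 = nw.score_module(b, set(b.gene_ids))
        np.testing.assert_allclose(s1.raw.values, s2.raw.values, atol=1e-9)

    def test_subprocess_gain_raises_normalized_score(self):
        """Doubling sub-process activity at fixed core activity raises the
        core-normalized score of the sub-module."""
        rng = np.random.default_rng(3)
        n = 40
        F = rng.normal(size=n)
        S = rng.normal(size=n)
        S[:10] += 2.0  # samples with boosted sub-process
        core_rows = [2 ** (F + 0.2 * rng.normal(size=n)) for _ in range(10)]
        sub_rows = [2 ** (F + 0.8 * S + 0.2 * rng.normal(size=n)) for _ in range(10)]
        expr = make_expr(100 * np.vstack([core_rows, sub_rows]))
        core = set(expr.gene_ids[:10])
        sub = set(expr.gene_ids[10:])
        ms = nw.score_module(expr, sub, core_genes=core)
        assert ms.normalized.values[:10].mean() > ms.normalized.values[10:].mean()

    def test_empty_module_error(self):
        rng = np.random.default_rng(0)
        expr = make_expr(np.abs(rng.normal(4, 1, size=(3, 10))))
        with pytest.raises(ValidationError):
            nw.score_module(expr, set())


class TestDichotomize:
    def test_even_split(self):
        s = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        groups = nw.dichotomize_scores(s)
        assert (groups == "high").sum() == 5
        assert (groups == "low").sum() == 5

    def test_ties_go_low(self):
        s = pd.Series([2.0, 2.0, 2.0, 2.0])
        assert set(nw.dichotomize_scores(s)) == {"low"}

    def test_outlier_does_not_shift_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 1000.0])
        groups = nw.dichotomize_scores(s)
        assert groups.tolist() == ["low", "low", "low", "high", "high"]
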