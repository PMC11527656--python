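import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrsuite.gsea import (
    ExpressionMatrix,
    RankedList,
    GeneSetResult,
    moderated_t,
    rank_genes,
    enrichment_score,
    gsea_permutation,
    filter_significant,
    read_gmt,
    write_gmt,
    _es_from_positions,
)
from mrsuite.synth import ExprSimConfig, simulate_expression


def brute_force_es(gene_ids, stats_vals, gene_set, p=1.0):
    """Position-by-position running-sum reference implementation."""
    gene_set = set(gene_set)
    n = len(gene_ids)
    hits = [g in gene_set for g in gene_ids]
    nh = sum(hits)
    denom = sum(abs(s) ** p for g, s, h in zip(gene_ids, stats_vals, hits) if h)
    best, run = 0.0, 0.0
    for g, s, h in zip(gene_ids, stats_vals, hits):
        if h:
            run += (abs(s) ** p / denom) if denom > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestModeratedT:
    def test_equal_variances_reduce_to_ordinary_t(self):
        """When every gene has the same sample variance the shrinkage
        target is that variance, so moderated t == two-sample t."""
        rng = np.random.default_rng(1)
        g, n = 200, 3
        base = rng.normal(0, 1, (g, 2 * n))
        # force all pooled variances equal by rescaling each gene
        case, ctrl = base[:, :n], base[:, n:]
        pooled = ((case.var(axis=1, ddof=1) + ctrl.var(axis=1, ddof=1)) / 2)
        vals = base / np.sqrt(pooled)[:, None]
        mat = ExpressionMatrix([f"g{i}" for i in range(g)],
                               [f"s{i}" for i in range(2 * n)], vals,
                               ["case"] * n + ["control"] * n)
        res = moderated_t(mat)
        t_ord, _ = stats.ttest_ind(vals[:, :n], vals[:, n:], axis=1)
        np.testing.assert_allclose(res["t"], t_ord, atol=1e-8)

    def test_equal_group_means_give_null_stats(self):
        rng = np.random.default_rng(2)
        vals = np.tile(rng.normal(5, 1, (50, 1)), (1, 6))
        vals += rng.normal(0, 1e-6, vals.shape)
        mat = ExpressionMatrix([f"g{i}" for i in range(50)],
                               [f"s{i}" for i in range(6)], vals,
                               ["case"] * 3 + ["control"] * 3)
        res = moderated_t(mat)
        assert np.abs(res["log2fc"]).max() < 1e-5

    def test_planted_signal_rises_to_top(self):
        planted = {"UP": ([f"G{i+1:05d}" for i in range(50)], 2.0)}
        mat, _ = simulate_expression(
            ExprSimConfig(n_genes=1000, planted_sets=planted, seed=3))
        res = moderated_t(mat)
        top100 = set(res["t"].abs().nlargest(100).index)
        hits = len(top100 & set(planted["UP"][0]))
        assert hits >= 45

    def test_zero_variance_gene_flagged_not_fatal(self):
        vals = np.random.default_rng(0).normal(0, 1, (10, 6))
        vals[0] = 3.0  # identical in every sample
        mat = ExpressionMatrix([f"g{i}" for i in range(10)],
                               [f"s{i}" for i in range(6)], vals,
                               ["case"] * 3 + ["control"] * 3)
        res = moderated_t(mat)
        assert "g0" in res.attrs["flagged_zero_variance"]
        assert np.isfinite(res.loc["g0", "t"])


class TestRanking:
    def test_descending_order(self):
        df = pd.DataFrame({"t": [1.0, 3.0, 2.0], "log2fc": [0, 0, 0]},
                          index=pd.Index(["a", "b", "c"], name="gene"))
        r = rank_genes(df)
        assert r.gene_ids == ["b", "c", "a"]

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame({"t": [1.0, 1.0, 1.0], "log2fc": [0, 0, 0]},
                          index=pd.Index(["c", "a", "b"], name="gene"))
        assert rank_genes(df).gene_ids == ["a", "b", "c"]

    def test_negation_reverses_modulo_ties(self):
        rng = np.random.default_rng(4)
        t = rng.normal(0, 1, 20)
        df = pd.DataFrame({"t": t, "log2fc": t},
                          index=pd.Index([f"g{i}" for i in range(20)],
                                         name="gene"))
        df2 = df.copy()
        df2["t"] = -df2["t"]
        assert rank_genes(df).gene_ids == rank_genes(df2).gene_ids[::-1]


class TestEnrichmentScore:
    def test_perfectly_separated_top_set(self):
        r = RankedList([f"g{i}" for i in range(10)],
                       np.linspace(5, 0.5, 10))
        es, run = enrichment_score(r, {"g0", "g1"})
        assert es == pytest.approx(1.0)
        assert run[-1] == pytest.approx(0.0, abs=1e-9)

    def test_bottom_set_matches_brute_force(self):
        r = RankedList([f"g{i}" for i in range(10)],
                       np.linspace(5, 0.5, 10))
        es, _ = enrichment_score(r, {"g8", "g9"})
        ref = brute_force_es(r.gene_ids, r.stats, {"g8", "g9"})
        assert es < 0
        assert es == pytest.approx(ref, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        r1 = RankedList([f"g{i}" for i in range(30)],
                        np.sort(rng.normal(0, 1, 30))[::-1])
        r2 = RankedList(r1.gene_ids, 7.3 * r1.stats)
        s = {"g3", "g7", "g11", "g20"}
        assert enrichment_score(r1, s)[0] == pytest.approx(
            enrichment_score(r2, s)[0], abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        statv = np.sort(rng.normal(0, 2, n))[::-1]
        r = RankedList([f"g{i}" for i in range(n)], statv)
        k = int(rng.integers(1, n // 2))
        s = set(rng.choice(r.gene_ids, k, replace=False))
        es, run = enrichment_score(r, s)
        assert es == pytest.approx(brute_force_es(r.gene_ids, statv, s),
                                   abs=1e-12)
        assert -1 - 1e-9 <= es <= 1 + 1e-9
        assert abs(run[-1]) < 1e-9

    def test_batch_position_scorer_agrees_with_loop(self):
        """The vectorized permutation scorer equals the full running sum."""
        rng = np.random.default_rng(6)
        n = 40
        statv = np.sort(rng.normal(0, 2, n))[::-1]
        r = RankedList([f"g{i}" for i in range(n)], statv)
        wt = np.abs(statv)
        for _ in range(20):
            k = int(rng.integers(2, 15))
            pos = np.sort(rng.choice(n, k, replace=False))
            batch = _es_from_positions(pos[None, :], wt, n)[0]
            direct, _ = enrichment_score(r, {r.gene_ids[i] for i in pos})
            assert batch == pytest.approx(direct, abs=1e-12)

    def test_degenerate_sets_fatal(self):
        r = RankedList(["a", "b"], np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            enrichment_score(r, set())
        with pytest.raises(ValueError):
            enrichment_score(r, {"a", "b"})


class TestPermutation:
    def ranked(self, seed=7, n=300):
        rng = np.random.default_rng(seed)
        return RankedList([f"g{i}" for i in range(n)],
                          np.sort(rng.normal(0, 1, n))[::-1])

    def test_min_p_respects_add_one_floor(self):
        """The add-one rule bounds p below by 1/(n_same_sign + 1), which
        can never undercut 1/(n_perm + 1)."""
        r = self.ranked()
        sets = {"TOP": r.gene_ids[:20]}
        res = gsea_permutation(r, sets, n_perm=999, seed=1, min_size=5)
        assert 1 / 1000 <= res[0].pvalue <= 0.01

    def test_deterministic_and_set_order_invariant(self):
        r = self.ranked()
        sets = {"A": r.gene_ids[:15], "B": r.gene_ids[50:70]}
        a = gsea_permutation(r, sets, n_perm=200, seed=3, min_size=5)
        b = gsea_permutation(r, dict(reversed(list(sets.items()))),
                             n_perm=200, seed=3, min_size=5)
        assert [(x.set_name, x.es, x.pvalue) for x in a] == [
            (x.set_name, x.es, x.pvalue) for x in b]

    def test_null_pvalues_approximately_uniform(self):
        """A non-enriched random set on signal-free data rejects at
        roughly the nominal 5% rate."""
        from mrsuite.evaluation import gsea_null_calibration

        rate = gsea_null_calibration(99, n_rep=100, n_perm=200)
        assert 0.02 <= rate <= 0.09

    def test_size_bounds_respected(self):
        r = self.ranked()
        sets = {"TINY": r.gene_ids[:3], "OK": r.gene_ids[:30]}
        res = gsea_permutation(r, sets, n_perm=200, seed=5, min_size=10)
        assert [x.set_name for x in res] == ["OK"]


def test_filter_significant_boundaries():
    def gs(p, q):
        return GeneSetResult("s", -0.4, -1.5, p, q, 30)

    assert filter_significant([gs(0.005, 0.019)])  # kept
    assert not filter_significant([gs(0.04, 0.30)])  # q fails
    assert not filter_significant([gs(0.05, 0.10)])  # boundary is strict


def test_gmt_round_trip(tmp_path):
    sets = {"S1": ["a", "b", "c"], "S2": ["d", "e"]}
    p = tmp_path / "x.gmt"
    write_gmt(sets, p)
    assert read_gmt(p) == sets
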