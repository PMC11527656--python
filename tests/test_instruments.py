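import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrsuite.instruments import (
    LdMatrix,
    select_by_pvalue,
    greedy_clump,
    drop_duplicates,
    f_statistic,
    filter_by_f,
)

from conftest import make_gwas


def ld_from(ids, pairs):
    """Dense LdMatrix from {frozenset pair: r2}; everything else 0."""
    n = len(ids)
    r2 = np.eye(n)
    idx = {s: i for i, s in enumerate(ids)}
    for (a, b), v in pairs.items():
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
    return LdMatrix(snp_ids=list(ids), r2=r2)


class TestPvalueFilter:
    def test_threshold_is_inclusive(self):
        t = make_gwas(["a", "b", "c"], [0.1] * 3, [0.01] * 3,
                      pval=[1e-7, 4e-6, 1e-5])
        out = select_by_pvalue(t, 5e-6)
        assert list(out.df["snp"]) == ["a", "b"]

    def test_vacuous_threshold_keeps_all(self):
        t = make_gwas(["a", "b"], [0.1, 0.2], [0.01, 0.01], pval=[0.5, 0.99])
        assert len(select_by_pvalue(t, 1.0)) == 2

    def test_matches_enumeration_on_uniform_pvalues(self, rng):
        p = rng.uniform(0, 1, 500)
        t = make_gwas([f"s{i}" for i in range(500)], np.full(500, 0.1),
                      np.full(500, 0.01), pval=p)
        out = select_by_pvalue(t, 0.05)
        assert len(out) == int(np.sum(p <= 0.05))
        assert list(out.df["snp"]) == [f"s{i}" for i in np.flatnonzero(p <= 0.05)]


class TestClumping:
    def test_hand_executed_greedy(self):
        t = make_gwas(["A", "B", "C"], [0.1] * 3, [0.01] * 3,
                      pval=[1e-8, 1e-7, 1e-6], pos=[1, 2, 3])
        ld = ld_from(["A", "B", "C"], {("A", "B"): 0.5})
        out = greedy_clump(t, ld, r2_max=0.001, window_kb=10_000)
        assert list(out.df["snp"]) == ["A", "C"]

    def test_unlinked_all_retained(self):
        t = make_gwas(["A", "B", "C"], [0.1] * 3, [0.01] * 3,
                      pval=[1e-8, 1e-7, 1e-6])
        out = greedy_clump(t, None, r2_max=0.001, window_kb=10_000)
        assert len(out) == 3

    def test_window_applies_within_chromosome_only(self):
        t = make_gwas(["A", "B"], [0.1, 0.1], [0.01, 0.01],
                      pval=[1e-8, 1e-7], chrom=["1", "2"], pos=[100, 200])
        ld = ld_from(["A", "B"], {("A", "B"): 0.9})
        assert len(greedy_clump(t, ld, 0.001, 10_000)) == 2

    def test_output_sorted_by_p_and_idempotent(self, rng):
        n = 30
        t = make_gwas([f"s{i}" for i in range(n)], np.full(n, 0.1),
                      np.full(n, 0.01), pval=rng.uniform(0, 1e-4, n),
                      pos=rng.integers(1, 5_000_000, n))
        r2 = rng.uniform(0, 1, (n, n))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix([f"s{i}" for i in range(n)], r2)
        out = greedy_clump(t, ld, r2_max=0.3, window_kb=1_000)
        assert list(out.df["pval"]) == sorted(out.df["pval"])
        again = greedy_clump(out, ld, r2_max=0.3, window_kb=1_000)
        assert list(again.df["snp"]) == list(out.df["snp"])
        # independent-set property: no retained pair is both close and linked
        kept = list(out.df["snp"])
        pos = dict(zip(out.df["snp"], out.df["pos"]))
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                linked = ld.lookup(a, b) >= 0.3
                close = abs(pos[a] - pos[b]) <= 1_000 * 1000
                assert not (linked and close)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_exhaustive_reference_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        ids = [f"s{i}" for i in range(n)]
        pvals = rng.uniform(0, 1e-3, n)
        pos = rng.integers(1, 2_000_000, n)
        r2 = rng.uniform(0, 1, (n, n))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        t = make_gwas(ids, np.full(n, 0.1), np.full(n, 0.01),
                      pval=pvals, pos=pos)
        ld = LdMatrix(ids, r2)
        out = greedy_clump(t, ld, r2_max=0.4, window_kb=500)

        # reference: repeatedly remove neighbours of the current best p
        remaining = sorted(range(n), key=lambda i: (pvals[i], ids[i]))
        kept = []
        while remaining:
            best = remaining.pop(0)
            kept.append(ids[best])
            remaining = [
                j
                for j in remaining
                if not (abs(int(pos[j]) - int(pos[best])) <= 500 * 1000
                        and r2[j, best] >= 0.4)
            ]
        assert list(out.df["snp"]) == kept


class TestDuplicatesAndF:
    def test_duplicate_keeps_smallest_p(self):
        t = make_gwas(["rs1", "rs1"], [0.1, 0.1], [0.01, 0.01],
                      pval=[1e-6, 1e-7])
        out = drop_duplicates(t)
        assert len(out) == 1
        assert out.df.loc[0, "pval"] == 1e-7

    def test_no_duplicates_is_identity(self):
        t = make_gwas(["a", "b"], [0.1, 0.2], [0.01, 0.01])
        assert list(drop_duplicates(t).df["snp"]) == ["a", "b"]

    def test_planted_duplicates_removed(self, rng):
        ids = [f"s{i}" for i in range(90)] + [f"s{i}" for i in range(10)]
        t = make_gwas(ids, rng.normal(0, 0.1, 100), np.full(100, 0.01))
        assert len(drop_duplicates(t)) == 90

    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.05, 4.0), (0.0, 0.3, 0.0), (-0.2, 0.02, 100.0)],
    )
    def test_f_statistic_formula(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_f_statistic_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    def test_f_filter_boundary_inclusive(self):
        # F values 4, 10, 100
        t = make_gwas(["a", "b", "c"], [0.2, 0.2, 0.2],
                      [0.1, 0.2 / np.sqrt(10), 0.02])
        inst = filter_by_f(t, min_f=10)
        assert list(inst.table.df["snp"]) == ["b", "c"]
        assert inst.selection_log["removed_weak"] == 1

    def test_f_filter_matches_enumeration(self, rng):
        n = 200
        beta = rng.normal(0, 0.1, n)
        se = rng.uniform(0.005, 0.1, n)
        t = make_gwas([f"s{i}" for i in range(n)], beta, se)
        inst = filter_by_f(t, min_f=10)
        assert len(inst) == int(np.sum(beta**2 / se**2 >= 10))
        # idempotent
        assert len(filter_by_f(inst.table, min_f=10)) == len(inst)
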