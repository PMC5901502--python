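"""Permutation null construction, empirical p-values, percentile report."""

import itertools

import numpy as np
import pandas as pd
import pytest

from transpoly.errors import InputError
from transpoly.features import MatchedPool
from transpoly.permutation import (
    build_null,
    count_set_statistic,
    null_percentiles,
    percentile_table,
    permutation_test,
    sample_null_set,
)


def _tallies(counts: dict) -> pd.DataFrame:
    df = pd.DataFrame({"gene": list(counts), "trans_snps": list(counts.values())})
    return df.set_index("gene")


def _pool(candidates: dict) -> MatchedPool:
    return MatchedPool("test", candidates)


class TestCountStatistic:
    def test_sum_and_mean(self):
        stat = count_set_statistic(["g1", "g2"], _tallies({"g1": 1, "g2": 3}), "trans_snps")
        assert stat.count == 4 and stat.mean_per_gene == 2.0

    def test_all_zero(self):
        stat = count_set_statistic(["g1", "g2"], _tallies({"g1": 0, "g2": 0}), "trans_snps")
        assert stat.count == 0 and stat.mean_per_gene == 0.0

    def test_missing_genes_count_zero(self):
        stat = count_set_statistic(["g1", "gX"], _tallies({"g1": 2}), "trans_snps")
        assert stat.count == 2 and stat.n_genes == 2

    def test_matches_independent_recount_on_random_fixture(self):
        rng = np.random.default_rng(11)
        counts = {f"g{i}": int(rng.poisson(2)) for i in range(20)}
        genes = [f"g{i}" for i in range(0, 20, 2)]
        stat = count_set_statistic(genes, _tallies(counts), "trans_snps")
        assert stat.count == sum(counts[g] for g in genes)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            count_set_statistic([], _tallies({"g1": 1}), "trans_snps")


class TestNullSampling:
    def test_single_candidate_replicate_is_deterministic(self):
        pool = _pool({"t1": ["a"], "t2": ["b"]})
        rng = np.random.default_rng(0)
        genes, reused = sample_null_set(pool, rng)
        assert genes == ["a", "b"] and reused == 0

    def test_shared_single_candidate_forces_reuse(self):
        pool = _pool({"t1": ["a"], "t2": ["a"]})
        genes, reused = sample_null_set(pool, np.random.default_rng(0))
        assert genes == ["a", "a"] and reused == 1

    def test_within_replicate_draws_avoid_duplicates_when_possible(self):
        pool = _pool({"t1": ["a", "b"], "t2": ["a", "b"]})
        for seed in range(20):
            genes, reused = sample_null_set(pool, np.random.default_rng(seed))
            assert sorted(genes) == ["a", "b"] and reused == 0

    def test_three_by_two_sets_appear_uniformly(self):
        pool = _pool({"t1": ["a", "b"], "t2": ["c", "d"], "t3": ["e", "f"]})
        rng = np.random.default_rng(123)
        n = 8000
        seen = {}
        for _ in range(n):
            genes, _ = sample_null_set(pool, rng)
            seen[tuple(genes)] = seen.get(tuple(genes), 0) + 1
        assert len(seen) == 8
        se = np.sqrt((1 / 8) * (7 / 8) / n)
        for combo in itertools.product("ab", "cd", "ef"):
            freq = seen[combo] / n
            assert abs(freq - 1 / 8) <= 3 * se


class TestPermutationTest:
    TALLIES = _tallies({"a": 1, "b": 0, "c": 2, "d": 1, "e": 0, "f": 3, "t1": 3, "t2": 2, "t3": 2})
    POOL = MatchedPool("test", {"t1": ["a", "b"], "t2": ["c", "d"], "t3": ["e", "f"]})

    def test_extreme_observation_gets_minimum_p(self):
        res = permutation_test(self.TALLIES, self.POOL, "trans_snps", n_perm=999, seed=0)
        # observed 7 exceeds the largest possible null count (1+2+3=6)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_dominated_observation_gets_p_one(self):
        tallies = _tallies({"a": 5, "b": 5, "c": 5, "d": 5, "e": 5, "f": 5,
                            "t1": 0, "t2": 0, "t3": 0})
        res = permutation_test(tallies, self.POOL, "trans_snps", n_perm=200, seed=0)
        assert res.p_value == 1.0

    def test_p_agrees_with_exhaustive_enumeration(self):
        counts = {"a": 1, "b": 0, "c": 2, "d": 1, "e": 0, "f": 3}
        observed = 5
        tallies = _tallies({**counts, "t1": 2, "t2": 2, "t3": 1})
        exact_ge = [
            counts[x] + counts[y] + counts[z] >= observed
            for x, y, z in itertools.product("ab", "cd", "ef")
        ]
        exact_p = sum(exact_ge) / 8
        n_perm = 8000
        res = permutation_test(tallies, self.POOL, "trans_snps", n_perm=n_perm, seed=42)
        mc_se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert abs(res.p_value - exact_p) <= 3 * mc_se + 1 / (n_perm + 1)

    def test_seeded_run_is_bit_reproducible(self):
        a = permutation_test(self.TALLIES, self.POOL, "trans_snps", n_perm=300, seed=9)
        b = permutation_test(self.TALLIES, self.POOL, "trans_snps", n_perm=300, seed=9)
        assert np.array_equal(a.null.counts, b.null.counts)
        assert a.p_value == b.p_value

    def test_p_invariant_under_control_relabeling(self):
        pool2 = MatchedPool("test", {"t1": ["b", "a"], "t2": ["d", "c"], "t3": ["f", "e"]})
        tallies = _tallies({"a": 1, "b": 1, "c": 2, "d": 2, "e": 0, "f": 0,
                            "t1": 2, "t2": 2, "t3": 1})
        r1 = permutation_test(tallies, self.POOL, "trans_snps", n_perm=2000, seed=5)
        r2 = permutation_test(tallies, pool2, "trans_snps", n_perm=2000, seed=5)
        # candidates within each target have identical tallies, so the null
        # count distribution is unchanged by the relabeling
        assert r1.p_value == r2.p_value


class TestPercentiles:
    def test_constant_null_gives_constant_rows(self):
        pool = _pool({"t1": ["a"], "t2": ["b"]})
        null = build_null(pool, _tallies({"a": 2, "b": 2}), "trans_snps", n_perm=50, seed=0)
        pct = null_percentiles(null)
        assert all(v == pytest.approx(2.0) for v in pct.values())

    def test_type7_interpolation_closed_form(self):
        pool = _pool({"t": ["x"]})
        null = build_null(pool, _tallies({"x": 0}), "trans_snps", n_perm=100, seed=0)
        null.counts = np.arange(1, 101)  # inject 1..100
        null.n_genes = 1
        pct = null_percentiles(null)
        # type-7: q_p = 1 + p*(n-1) on the sorted values 1..100
        assert pct[5] == pytest.approx(5.95)
        assert pct[100] == pytest.approx(100.0)
        assert list(pct.values()) == sorted(pct.values())

    def test_table_has_20_rows_and_one_column_per_kind(self):
        tallies = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "all_polymorphisms": [3, 4],
                "trans_snps": [1, 2],
                "trans_snps_nonsyn": [0, 1],
            }
        ).set_index("gene")
        pool = _pool({"t1": ["a", "b"]})
        nulls = {
            kind: build_null(pool, tallies, kind, n_perm=40, seed=0)
            for kind in ("all_polymorphisms", "trans_snps_nonsyn", "trans_snps")
        }
        table = percentile_table(nulls)
        assert list(table["percentile"]) == list(range(5, 101, 5))
        assert list(table.columns) == [
            "percentile", "all_polymorphisms", "trans_snps_nonsyn", "trans_snps",
        ]
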