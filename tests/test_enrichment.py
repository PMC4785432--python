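import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlink import (
    TargetDB,
    anticorrelated_set,
    correlate_covariates,
    correlate_pairs,
    hypergeom_enrichment,
    rank_enrichment,
    select_enriched,
)


def _enumerate_hypergeom(N, K, n, k):
    """Upper-tail p by exhaustively enumerating all C(N, n) draws."""
    population = list(range(N))
    successes = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def _enumerate_ranksum(x, y):
    """One-sided (x smaller) rank-sum p by enumerating all rank assignments."""
    pooled = sorted(x + y)
    obs = sum(pooled.index(v) + 1 for v in x)
    m = len(x)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), m):
        total += 1
        if sum(combo) <= obs:
            count += 1
    return count / total


class TestCorrelatePairs:
    def _mats(self, rng, n=10):
        mir = pd.DataFrame(rng.normal(size=(2, n)), index=["m1", "m2"])
        gene = pd.DataFrame(
            {0: -mir.loc["m1"], 1: mir.loc["m1"], 2: rng.normal(size=n)}
        ).T
        gene.index = ["g_neg", "g_pos", "g_rand"]
        gene.columns = mir.columns
        return mir, gene

    def test_exact_anticorrelation(self, rng):
        mir, gene = self._mats(rng)
        tab = correlate_pairs(mir, gene, ["m1"], ["g_neg", "g_pos"]).set_index("gene")
        assert tab.loc["g_neg", "r"] == pytest.approx(-1.0)
        assert tab.loc["g_pos", "r"] == pytest.approx(1.0)

    def test_null_rejection_rate_matches_t_critical_value(self, rng):
        # with 28 samples, |r| > 0.374 should occur in ~5% of independent pairs
        n = 28
        mir = pd.DataFrame(rng.normal(size=(40, n)), index=[f"m{i}" for i in range(40)])
        gene = pd.DataFrame(rng.normal(size=(100, n)), index=[f"g{i}" for i in range(100)])
        gene.columns = mir.columns
        tab = correlate_pairs(mir, gene, list(mir.index), list(gene.index))
        crit = stats.t.ppf(0.975, n - 2) / math.sqrt(n - 2 + stats.t.ppf(0.975, n - 2) ** 2)
        rate = (tab["r"].abs() > crit).mean()
        assert rate == pytest.approx(0.05, abs=0.015)
        # and the p-value column must agree with the r threshold
        assert ((tab["p"] < 0.05) == (tab["r"].abs() > crit)).all()

    def test_degenerate_feature_flagged(self, rng):
        mir = pd.DataFrame([[1.0] * 6], index=["flat"])
        gene = pd.DataFrame([list(rng.normal(size=6))], index=["g"], columns=mir.columns)
        tab = correlate_pairs(mir, gene, ["flat"], ["g"])
        assert tab["degenerate"].iloc[0]
        assert tab["r"].iloc[0] == 0.0

    def test_requires_shared_columns(self, rng):
        mir = pd.DataFrame(rng.normal(size=(1, 4)), index=["m"], columns=list("abcd"))
        gene = pd.DataFrame(rng.normal(size=(1, 4)), index=["g"], columns=list("abce"))
        with pytest.raises(ValueError):
            correlate_pairs(mir, gene, ["m"], ["g"])


class TestAnticorrelatedSet:
    @pytest.mark.parametrize(
        "r,p,expected",
        [(-0.6, 0.01, True), (-0.5, 0.01, False), (-0.9, 0.2, False), (0.6, 0.01, False)],
    )
    def test_threshold_rules(self, r, p, expected):
        tab = pd.DataFrame({"mirna": ["m"], "gene": ["g"], "r": [r], "p": [p]})
        got = anticorrelated_set(tab, "m", {"g"})
        assert (got == {"g"}) is expected

    def test_rejects_positive_threshold(self):
        tab = pd.DataFrame({"mirna": [], "gene": [], "r": [], "p": []})
        with pytest.raises(ValueError):
            anticorrelated_set(tab, "m", set(), r_max=0.5)


class TestHypergeomEnrichment:
    def test_exact_small_case(self):
        # N=10, K=5, n=4, k=4: only C(5,4)*C(5,0) = 5 of the 210 draws qualify
        p = hypergeom_enrichment(set(range(5)), set(range(4)), 10)
        assert p == pytest.approx(5 / 210)

    def test_zero_overlap_gives_one(self):
        assert hypergeom_enrichment({"a"}, {"b"}, 10) == pytest.approx(1.0)

    def test_empty_draw_gives_one(self):
        assert hypergeom_enrichment({"a"}, set(), 10) == pytest.approx(1.0)

    def test_empty_targets_skipped(self):
        assert hypergeom_enrichment(set(), {"a"}, 10) is None

    def test_matches_enumeration_on_small_grid(self):
        for N in [5, 8]:
            for K in [2, 3]:
                for n in [2, 4]:
                    for k in range(max(0, n - (N - K)), min(K, n) + 1):
                        targets = set(range(K))
                        anticorr = set(range(k)) | set(range(K, K + n - k))
                        got = hypergeom_enrichment(targets, anticorr, N)
                        assert got == pytest.approx(_enumerate_hypergeom(N, K, n, k))

    def test_monotone_in_added_true_target(self):
        # adding a gene that is both target and anticorrelated can only
        # strengthen (never weaken) the enrichment
        universe = 50
        anticorr = set(range(10))
        targets = set(range(3)) | {30, 31}
        p0 = hypergeom_enrichment(targets, anticorr, universe)
        p1 = hypergeom_enrichment(targets | {5}, anticorr, universe)
        assert p1 <= p0


class TestRankEnrichment:
    def test_two_smallest_of_five(self):
        pv = pd.Series({"a": 0.01, "b": 0.02, "c": 0.5, "d": 0.6, "e": 0.7})
        assert rank_enrichment({"a", "b"}, pv) == pytest.approx(0.1)  # 1 / C(5,2)

    def test_single_smallest_of_three(self):
        pv = pd.Series({"a": 0.1, "b": 0.5, "c": 0.9})
        assert rank_enrichment({"a"}, pv) == pytest.approx(1 / 3)

    def test_opposite_tail_gives_one(self):
        pv = pd.Series({"a": 0.8, "b": 0.9, "c": 0.1, "d": 0.2, "e": 0.3})
        assert rank_enrichment({"a", "b"}, pv) == pytest.approx(1.0)

    def test_matches_full_rank_enumeration(self, rng):
        vals = rng.uniform(size=9)
        ids = [f"g{i}" for i in range(9)]
        pv = pd.Series(vals, index=ids)
        targets = {"g0", "g3", "g7"}
        got = rank_enrichment(targets, pv)
        x = [pv[g] for g in sorted(targets)]
        y = [pv[g] for g in ids if g not in targets]
        assert got == pytest.approx(_enumerate_ranksum(x, y))

    def test_exact_and_approximate_agree_at_switchover(self, rng):
        vals = rng.uniform(size=120)
        pv = pd.Series(vals, index=[f"g{i}" for i in range(120)])
        targets = {f"g{i}" for i in range(10)}
        exact = rank_enrichment(targets, pv, exact_max=10)
        approx = rank_enrichment(targets, pv, exact_max=0)
        assert abs(exact - approx) < 0.01

    def test_targets_cover_universe_error(self):
        pv = pd.Series({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError):
            rank_enrichment({"a", "b"}, pv)


class TestSelectEnriched:
    def _corr(self, rows):
        return pd.DataFrame(rows, columns=["mirna", "gene", "r", "p"])

    def test_significant_without_anticorr_target_excluded(self):
        # significant by the rank test but no target below r < -0.5: dropped
        tdb = TargetDB({"m1": {"g1"}}, background_size=100)
        corr = self._corr([("m1", "g1", -0.2, 0.01)])
        res = select_enriched({"m1": 0.001}, {"m1": 0.001}, corr, {"g1"}, tdb)
        assert res.enriched_mirnas == []
        assert res.table.loc["m1", "n_anticorr_targets"] == 0

    def test_all_null_pvalues_select_nothing(self):
        tdb = TargetDB({"m1": {"g1"}, "m2": {"g2"}}, background_size=100)
        corr = self._corr([("m1", "g1", -0.9, 0.001), ("m2", "g2", -0.9, 0.001)])
        res = select_enriched({"m1": 1.0, "m2": 1.0}, {"m1": 1.0, "m2": 1.0},
                              corr, {"g1", "g2"}, tdb)
        assert res.enriched_mirnas == []

    def test_enriched_requires_either_test(self):
        tdb = TargetDB({"m1": {"g1"}, "m2": {"g2"}}, background_size=100)
        corr = self._corr([("m1", "g1", -0.9, 0.001), ("m2", "g2", -0.9, 0.001)])
        res = select_enriched({"m1": 1e-6, "m2": 1.0}, {"m1": 1.0, "m2": 1.0},
                              corr, {"g1", "g2"}, tdb)
        assert res.enriched_mirnas == ["m1"]
        assert res.anticorr_union == {"g1"}


class TestCorrelateCovariates:
    def test_monotone_and_exact_relations(self, rng):
        deltas = pd.DataFrame(
            rng.normal(size=(1, 6)), index=["m"], columns=[f"s{i}" for i in range(6)]
        )
        cov = pd.DataFrame(
            {
                "exp_delta": np.exp(deltas.loc["m"]),
                "neg_delta": -deltas.loc["m"],
            },
            index=deltas.columns,
        )
        tab = correlate_covariates(deltas, cov).set_index("variable")
        assert tab.loc["exp_delta", "spearman_rho"] == pytest.approx(1.0)
        assert tab.loc["neg_delta", "pearson_r"] == pytest.approx(-1.0)

    def test_constant_covariate_degenerate(self, rng):
        deltas = pd.DataFrame(rng.normal(size=(1, 5)), index=["m"],
                              columns=[f"s{i}" for i in range(5)])
        cov = pd.DataFrame({"flat": np.ones(5)}, index=deltas.columns)
        tab = correlate_covariates(deltas, cov)
        assert tab["degenerate"].iloc[0]

    def test_null_rejection_rate(self):
        r = np.random.default_rng(7)
        n_sig = 0
        n_tot = 0
        deltas = pd.DataFrame(r.normal(size=(50, 20)),
                              index=[f"m{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(20)])
        cov = pd.DataFrame(r.normal(size=(20, 10)), index=deltas.columns,
                           columns=[f"v{i}" for i in range(10)])
        tab = correlate_covariates(deltas, cov)
        rate = (tab["pearson_p"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.025)
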