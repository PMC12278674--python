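"""Set enrichment (hypergeometric ORA, rank-based LSEA) and the
redox-lipid correlation integration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ptmflux import enrich
from ptmflux.diff_stats import DiffResults
from ptmflux.io import FilterConfig, SetCollection


# ---------------------------------------------------------------------------
# hypergeometric ORA
# ---------------------------------------------------------------------------

def brute_force_ora(universe_n, set_k, selected, members):
    """Oracle: exact tail by enumerating every n-subset of the universe."""
    universe = list(range(universe_n))
    k_obs = len(set(selected) & set(members))
    n = len(selected)
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(set(subset) & set(members)) >= k_obs:
            hits += 1
    return hits / total


class TestORA:
    def test_worked_example(self):
        """N=20, K=5, n=5, k=3: P(X >= 3) = 1126/15504."""
        universe = {f"g{i}" for i in range(20)}
        members = {f"g{i}" for i in range(5)}
        selected = {"g0", "g1", "g2", "g10", "g11"}
        res = enrich.ora_hypergeometric(selected, members, universe)
        assert res.overlap_k == 3 and res.set_size_K == 5
        assert res.p == pytest.approx(1126 / 15504, rel=1e-12)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 4, 5), (12, 6, 3)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        universe = set(range(N))
        members = set(range(K))
        rng = np.random.default_rng(N * 100 + K * 10 + n)
        for _ in range(5):
            selected = set(rng.choice(N, size=n, replace=False).tolist())
            res = enrich.ora_hypergeometric({str(s) for s in selected},
                                            {str(m) for m in members},
                                            {str(u) for u in universe})
            oracle = brute_force_ora(N, K, selected, members)
            assert res.p == pytest.approx(oracle, rel=1e-12)

    def test_degenerate_cases(self):
        universe = {f"g{i}" for i in range(10)}
        members = {"g0", "g1"}
        # zero overlap -> p = P(X >= 0) = 1
        res = enrich.ora_hypergeometric({"g5", "g6"}, members, universe)
        assert res.overlap_k == 0 and res.p == 1.0
        # selection = set = universe -> k = K = n = N -> p = 1
        res = enrich.ora_hypergeometric(universe, universe, universe)
        assert res.p == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            enrich.ora_hypergeometric(set(), {"a"}, {"a"})
        with pytest.raises(ValueError):
            enrich.ora_hypergeometric({"z"}, {"a"}, {"a"})

    def test_collection_reporting_rule(self):
        """Reported enrichments satisfy adj_p <= 0.05 AND q <= 0.2 jointly."""
        universe = {f"g{i}" for i in range(40)}
        sets = {f"s{j}": ("", frozenset({f"g{i}" for i in range(j, j + 5)}))
                for j in range(0, 35, 5)}
        sets["hit"] = ("", frozenset({f"g{i}" for i in range(8)}))
        selected = {f"g{i}" for i in range(8)}
        df = enrich.enrich_collection(selected, SetCollection(sets), universe)
        hit = df[df["set_name"] == "hit"].iloc[0]
        assert hit["overlap_k"] == 8
        assert bool(hit["reported"]) == (hit["adj_p"] <= 0.05 and hit["q"] <= 0.2)
        assert df["p"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# rank-based set test
# ---------------------------------------------------------------------------

class TestRankSetTest:
    def test_top_block_exact_p(self):
        """6 features, set = top 3 by score: one-sided 1/C(6,3) = 0.05,
        two-sided 0.10, direction up."""
        scores = {f"f{i}": float(10 - i) for i in range(6)}
        res = enrich.rank_set_test(scores, {"f0", "f1", "f2"})
        assert res.p == pytest.approx(0.10, rel=1e-9)
        assert res.direction == "up"
        res_dn = enrich.rank_set_test(scores, {"f3", "f4", "f5"})
        assert res_dn.p == pytest.approx(0.10, rel=1e-9)
        assert res_dn.direction == "down"

    def test_all_tied_gives_p_one(self):
        scores = {f"f{i}": 1.0 for i in range(8)}
        assert enrich.rank_set_test(scores, {"f0", "f1"}).p == 1.0

    def test_exact_matches_permutation_oracle(self):
        """Exact branch equals brute-force enumeration over member placements."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=10)
        scores = {f"f{i}": v for i, v in enumerate(vals)}
        members = {"f0", "f3", "f4"}
        res = enrich.rank_set_test(scores, members)
        # oracle: two-sided rank-sum by full enumeration of C(10,3) subsets
        from scipy.stats import rankdata
        ranks = rankdata(vals)
        obs = ranks[[0, 3, 4]].sum()
        m = 3
        mean = m * (len(vals) + 1) / 2
        stats_all = [sum(ranks[list(c)]) for c in itertools.combinations(range(10), m)]
        extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats_all)
        oracle = extreme / len(stats_all)
        assert res.p == pytest.approx(oracle, rel=1e-9)

    def test_exact_and_normal_branches_agree_near_boundary(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=12)
        scores = pd.Series(vals, index=[f"f{i}" for i in range(12)])
        members = {"f0", "f1", "f2", "f7"}
        exact = enrich.rank_set_test(scores, members).p
        from scipy.stats import mannwhitneyu
        in_set = scores.index.isin(members)
        approx = mannwhitneyu(scores[in_set], scores[~in_set],
                              alternative="two-sided", method="asymptotic",
                              use_continuity=True).pvalue
        assert abs(exact - approx) < 0.01

    def test_lsea_flags_top_set(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(0, 0.2, 60), index=[f"L{i}" for i in range(60)])
        scores.iloc[:12] += 3.0
        sets = {"up_set": ("", frozenset(scores.index[:12])),
                "null_set": ("", frozenset(scores.index[30:45]))}
        df = enrich.lsea(scores, SetCollection(sets))
        top = df.iloc[0]
        assert top["set_name"] == "up_set" and top["direction"] == "up"
        assert bool(top["reported"])


# ---------------------------------------------------------------------------
# condition means / correlation / selection
# ---------------------------------------------------------------------------

class TestConditionMeans:
    def test_mean_and_missing_skip(self, make_matrix):
        vals = [np.nan] * 12
        vals[0], vals[6] = 1.0, 3.0   # high_24h bridges in both plexes
        vals[2] = 5.0                 # high_48h single replicate
        m = make_matrix({"f": vals})
        cm = enrich.condition_means(m)
        assert cm.loc["f", "high_24h"] == 2.0
        assert cm.loc["f", "high_48h"] == 5.0  # single replicate passthrough


def _means_frame(rows, conds=6):
    cols = [f"c{i}" for i in range(conds)]
    return pd.DataFrame(rows, columns=cols)


class TestCorrelation:
    def test_affine_and_negative(self):
        tg = np.array([1.0, 2, 3, 4, 5, 6])
        sites = _means_frame({"s_pos": 2 * tg + 1, "s_neg": -tg}.values())
        sites.index = ["s_pos", "s_neg"]
        lipids = _means_frame([tg])
        lipids.index = ["TG"]
        res = enrich.correlate_sites_lipids(sites, lipids)
        piv = res.pivot()
        assert piv.loc["s_pos", "TG"] == pytest.approx(1.0)
        assert piv.loc["s_neg", "TG"] == pytest.approx(-1.0)

    def test_zero_variance_site_omitted(self):
        sites = pd.DataFrame([[1.0] * 6, [1, 2, 3, 4, 5, 6.0]],
                             index=["flat", "ok"], columns=[f"c{i}" for i in range(6)])
        lipids = pd.DataFrame([[1, 2, 3, 4, 5, 6.0]], index=["TG"],
                              columns=[f"c{i}" for i in range(6)])
        res = enrich.correlate_sites_lipids(sites, lipids)
        assert res.omitted == ["flat"]
        assert set(res.rows["site"]) == {"ok"}

    def test_random_pairs_center_on_zero(self):
        rng = np.random.default_rng(6)
        sites = pd.DataFrame(rng.normal(size=(2000, 6)),
                             columns=[f"c{i}" for i in range(6)])
        sites.index = [f"s{i}" for i in range(2000)]
        lipids = pd.DataFrame(rng.normal(size=(5, 6)), index=list("ABCDE"),
                              columns=[f"c{i}" for i in range(6)])
        res = enrich.correlate_sites_lipids(sites, lipids)
        assert abs(res.rows["pearson_r"].mean()) < 0.05

    def test_requires_three_conditions(self):
        sites = pd.DataFrame([[1.0, 2.0]], index=["s"], columns=["c0", "c1"])
        with pytest.raises(ValueError, match=">= 3"):
            enrich.correlate_sites_lipids(sites, sites)


def _diff_results(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "contrast", "log2FC", "t",
                                     "df", "p", "adj_p", "n_a", "n_b"])
    return DiffResults(df)


class TestSelection:
    def _corr(self, rows):
        df = pd.DataFrame(rows, columns=["site", "target", "pearson_r", "n_conditions"])
        return enrich.CorrelationResult(rows=df, omitted=[])

    def test_conjunction_rule(self):
        corr = self._corr([("s1", "TG", 0.9, 6), ("s1", "DG", 0.85, 6),
                           ("s2", "TG", 0.9, 6), ("s2", "DG", 0.5, 6)])
        diff = _diff_results([("s1", "Nitrogen", 1.0, 5.0, 10, 0.001, 0.01, 18, 0),
                              ("s2", "Nitrogen", 1.0, 5.0, 10, 0.001, 0.01, 18, 0)])
        assert enrich.select_correlated_sites(corr, diff) == {"s1"}
        # disjunction mode admits s2 as well
        assert enrich.select_correlated_sites(corr, diff, mode="any") == {"s1", "s2"}

    def test_fold_change_threshold(self):
        corr = self._corr([("s1", "TG", 0.9, 6), ("s1", "DG", 0.85, 6)])
        weak = _diff_results([("s1", "Nitrogen", 0.5, 2.0, 10, 0.01, 0.02, 18, 0)])
        assert enrich.select_correlated_sites(corr, weak) == set()
        boundary = _diff_results([("s1", "Nitrogen", 0.8, 2.0, 10, 0.01, 0.02, 18, 0)])
        assert enrich.select_correlated_sites(corr, boundary) == {"s1"}  # >= inclusive

    def test_r_threshold_is_strict(self):
        corr = self._corr([("s1", "TG", 0.80, 6), ("s1", "DG", 0.9, 6)])
        diff = _diff_results([("s1", "Nitrogen", 1.0, 5.0, 10, 0.001, 0.01, 18, 0)])
        assert enrich.select_correlated_sites(corr, diff) == set()  # r > 0.80, strict


class TestInputFilters:
    def test_kegg_thresholds_inclusive(self):
        rows = [("in_both", "c", 1.2, 3, 10, 0.001, 0.04, 3, 3),
                ("weak_fc", "c", 0.9, 3, 10, 0.001, 0.04, 3, 3),
                ("boundary", "c", 1.0, 3, 10, 0.001, 0.04, 3, 3),
                ("weak_p", "c", 2.0, 3, 10, 0.2, 0.3, 3, 3)]
        diff = _diff_results(rows)
        assert enrich.kegg_input_filter(diff) == {"in_both", "boundary"}

    def test_msea_uses_lfc_4(self):
        rows = [("big", "c", 4.5, 3, 10, 0.001, 0.01, 3, 3),
                ("mid", "c", 2.0, 3, 10, 0.001, 0.01, 3, 3)]
        assert enrich.msea_input_filter(_diff_results(rows)) == {"big"}


class TestStoreyQ:
    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=2000)
        q = enrich.storey_qvalues(p)
        assert np.all((q >= 0) & (q <= 1))
        # with pi0 ~ 1, q ~ BH adjusted p
        from ptmflux.diff_stats import bh_adjust
        assert np.allclose(q, bh_adjust(p) * min(1.0, (p > 0.5).sum() / (0.5 * p.size)),
                           atol=0.02)

    def test_qvalues_monotone_in_p(self):
        p = np.array([0.001, 0.01, 0.2, 0.8, 0.9])
        q = enrich.storey_qvalues(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
        assert np.all(q <= 1.0)
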