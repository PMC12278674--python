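"""Differential statistics: replicate filtering, the empirical-Bayes
variance prior, moderated and ordinary two-group tests, the factorial
nitrogen x time model, and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ptmflux import diff_stats
from ptmflux.diff_stats import ModerationPrior


# ---------------------------------------------------------------------------
# replicate filter
# ---------------------------------------------------------------------------

class TestFilterMinReps:
    def test_rules(self):
        nan = np.nan
        m = _two_group_matrix({
            "one_rep": (np.array([1.0, nan, nan]), np.array([nan, nan, nan])),
            "one_each": (np.array([1.0, nan, nan]), np.array([2.0, nan, nan])),
            "two_in_A_only": (np.array([1.0, 2.0, nan]), np.array([nan, nan, nan])),
            "full": (np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])),
        }, None)
        out = diff_stats.filter_min_reps(m, k=2)
        assert "one_rep" not in out.data.index
        assert "one_each" not in out.data.index
        assert "two_in_A_only" in out.data.index  # >=2 reps in one condition suffices
        assert "full" in out.data.index
        # k=1 is the identity on fully observed data
        assert diff_stats.filter_min_reps(m, k=1).data.shape[0] == 4

    def test_bridge_tech_reps_count_once(self, make_matrix):
        # mini design: high_24h appears as one bridge channel in each plex,
        # but both are the same biological sample
        vals = [np.nan] * 12
        vals[0] = 1.0   # plex1 bridge high_24h_r1
        vals[6] = 2.0   # plex2 bridge high_24h_r1
        m = make_matrix({"f": vals})
        assert len(diff_stats.filter_min_reps(m, k=2).data) == 0
        assert len(diff_stats.filter_min_reps(m, k=1).data) == 1

    def test_k_must_be_positive(self, make_matrix):
        with pytest.raises(ValueError):
            diff_stats.filter_min_reps(make_matrix({"f": [1.0] * 12}), k=0)


# ---------------------------------------------------------------------------
# variance prior
# ---------------------------------------------------------------------------

class TestEstimatePrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = diff_stats.estimate_prior([(0.25, 4.0)] * 50)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="zero"):
            diff_stats.estimate_prior([(0.0, 4.0)] * 20)

    def test_too_few_features_error(self):
        with pytest.raises(ValueError, match=">= 10"):
            diff_stats.estimate_prior([(0.1, 4.0)] * 5)

    def test_recovers_known_d0(self):
        """s^2 drawn from the scaled inverse-chi-square hierarchy with
        d0 = 4: the trigamma-inversion estimate lands within 20%."""
        rng = np.random.default_rng(0)
        d0, s0, df = 4.0, 0.05, 4
        n = 5000
        sigma_sq = d0 * s0 / rng.chisquare(d0, n)
        s_sq = sigma_sq * rng.chisquare(df, n) / df
        prior = diff_stats.estimate_prior(s_sq=s_sq, df=np.full(n, float(df)))
        assert abs(prior.d0 - d0) / d0 < 0.2
        assert abs(prior.s0_sq - s0) / s0 < 0.2

    def test_squeeze_limits(self):
        inf_prior = ModerationPrior(d0=np.inf, s0_sq=0.3)
        assert np.allclose(inf_prior.squeeze(np.array([0.1, 9.0]), np.array([4.0, 4.0])), 0.3)
        zero_prior = ModerationPrior(d0=0.0, s0_sq=0.3)
        assert np.allclose(zero_prior.squeeze(np.array([0.1, 9.0]), np.array([4.0, 4.0])),
                           [0.1, 9.0])


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def _two_group_matrix(a_vals, b_vals):
    """3v3 matrix at a single timepoint (48 h) in one plex."""
    from ptmflux.containers import AbundanceMatrix
    n = len(next(iter(a_vals.values()))[0])
    labels = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    cols = pd.MultiIndex.from_product([["p1"], labels])
    meta = pd.DataFrame(index=cols, data={
        "sample_id": [f"low_48h_r{i+1}" for i in range(n)] + [f"high_48h_r{i+1}" for i in range(n)],
        "nitrogen": ["low"] * n + ["high"] * n,
        "timepoint_h": [48] * 2 * n,
        "replicate": list(range(1, n + 1)) * 2,
        "assay": "global", "channel_class": "sample", "batch": "p1",
        "condition": ["low_48h"] * n + ["high_48h"] * n,
    })
    data = pd.DataFrame({f: np.concatenate([a, b]) for f, (a, b) in a_vals.items()}).T
    data.columns = cols
    return AbundanceMatrix(data=data, channels=meta, scale="log2")


class TestModeratedTwoGroup:
    def test_textbook_student_t(self):
        """A=(0,1,2) vs B=(3,4,5): log2FC -3, t = -3.674, df 4, p = 0.0214."""
        m = _two_group_matrix({"f": (np.array([0.0, 1, 2]), np.array([3.0, 4, 5]))}, None)
        res = diff_stats.moderated_two_group(m, "low_48h", "high_48h", prior=None)
        row = res.table.iloc[0]
        assert row["log2FC"] == pytest.approx(-3.0)
        assert row["t"] == pytest.approx(-3.674, abs=1e-3)
        assert row["df"] == 4
        assert row["p"] == pytest.approx(0.02139, abs=1e-4)
        assert row["n_a"] == 3 and row["n_b"] == 3

    def test_infinite_d0_reduces_to_known_form(self):
        m = _two_group_matrix({"f": (np.array([0.0, 1, 2]), np.array([3.0, 4, 5]))}, None)
        prior = ModerationPrior(d0=np.inf, s0_sq=0.5)
        res = diff_stats.moderated_two_group(m, "low_48h", "high_48h", prior)
        expected_t = -3.0 / np.sqrt(0.5 * (2.0 / 3.0))
        assert res.table["t"].iloc[0] == pytest.approx(expected_t, rel=1e-12)
        # normal reference distribution at infinite df
        assert res.table["p"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(abs(expected_t)), rel=1e-9)

    def test_d0_zero_equals_ordinary(self):
        rng = np.random.default_rng(1)
        feats = {f"f{i}": (rng.normal(0, 1, 3), rng.normal(0.5, 1, 3)) for i in range(20)}
        m = _two_group_matrix(feats, None)
        plain = diff_stats.moderated_two_group(m, "low_48h", "high_48h", None)
        zero = diff_stats.moderated_two_group(m, "low_48h", "high_48h",
                                              ModerationPrior(d0=0.0, s0_sq=1.0))
        assert np.allclose(plain.table["t"], zero.table["t"], atol=1e-10)
        assert np.allclose(plain.table["p"], zero.table["p"], atol=1e-10)

    def test_identical_groups(self):
        m = _two_group_matrix({"f": (np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))}, None)
        res = diff_stats.moderated_two_group(m, "low_48h", "high_48h", None)
        assert res.table["log2FC"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == 1.0

    def test_small_groups_skipped(self):
        m = _two_group_matrix({"f": (np.array([1.0, np.nan, np.nan]),
                                     np.array([2.0, 3.0, 4.0]))}, None)
        res = diff_stats.moderated_two_group(m, "low_48h", "high_48h", None)
        assert len(res.table) == 0 and res.skipped == ["f"]

    def test_model_class_summary(self):
        rng = np.random.default_rng(2)
        feats = {f"f{i}": (rng.normal(1, 0.3, 3), rng.normal(0, 0.3, 3)) for i in range(30)}
        m = _two_group_matrix(feats, None)
        res = diff_stats.ModeratedTTest(m, "low_48h", "high_48h").fit()
        assert res.prior is not None
        text = res.summary()
        assert "features tested : 30" in text
        up, down = res.counts(adj_p_max=0.05)
        assert up > 0 and down == 0


# ---------------------------------------------------------------------------
# factorial model
# ---------------------------------------------------------------------------

def _grid_matrix(feature_fn, n_features=1, sd=0.0, seed=0, conditions=None):
    """Full 2x3 grid, 3 replicates, one plex."""
    from ptmflux.containers import AbundanceMatrix
    conds = conditions or [(n, t) for t in (24, 48, 72) for n in ("high", "low")]
    labels, meta_rows = [], []
    for n, t in conds:
        for r in (1, 2, 3):
            labels.append(f"{n}_{t}_{r}")
            meta_rows.append(dict(sample_id=f"{n}_{t}h_r{r}", nitrogen=n, timepoint_h=t,
                                  replicate=r, assay="global", channel_class="sample",
                                  batch="p1", condition=f"{n}_{t}h"))
    cols = pd.MultiIndex.from_product([["p1"], labels])
    meta = pd.DataFrame(meta_rows, index=cols)
    rng = np.random.default_rng(seed)
    rows = {}
    for i in range(n_features):
        vals = [feature_fn(1.0 if n == "low" else 0.0, t - 24.0) + rng.normal(0, sd)
                for n, t in conds for _ in (1, 2, 3)]
        rows[f"f{i}"] = vals
    data = pd.DataFrame(rows).T
    data.columns = cols
    return AbundanceMatrix(data=data, channels=meta, scale="log2")


class TestFactorial:
    def test_exact_recovery_on_linear_truth(self):
        b0, bn, bt, bnt = 5.0, 1.25, 0.03, -0.01
        m = _grid_matrix(lambda N, T: b0 + bn * N + bt * T + bnt * N * T)
        res = diff_stats.fit_factorial(m, prior=None)
        by = res.table.set_index("contrast")["log2FC"]
        assert by["Nitrogen"] == pytest.approx(bn, abs=1e-10)
        assert by["Time"] == pytest.approx(bt, abs=1e-10)
        assert by["Nitrogen:Time"] == pytest.approx(bnt, abs=1e-10)

    def test_zero_interaction_noise_free_convention(self):
        m = _grid_matrix(lambda N, T: 2.0 + 1.0 * N + 0.05 * T)
        res = diff_stats.fit_factorial(m, prior=None)
        row = res.table[res.table["contrast"] == "Nitrogen:Time"].iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0
        nit = res.table[res.table["contrast"] == "Nitrogen"].iloc[0]
        assert np.isinf(nit["t"]) and nit["p"] < 1e-300

    def test_rank_deficient_design_reports_aliased(self):
        m = _grid_matrix(lambda N, T: 1.0 + N,
                         conditions=[("high", 24), ("low", 24)])
        with pytest.raises(ValueError, match="aliased.*Time"):
            diff_stats.fit_factorial(m, prior=None)

    def test_matches_statsmodels_ols(self):
        """Vectorized per-feature OLS agrees with statsmodels on noisy data
        with missing entries."""
        import statsmodels.api as sm

        m = _grid_matrix(lambda N, T: 1.0 + 0.8 * N + 0.02 * T + 0.01 * N * T,
                         n_features=5, sd=0.3, seed=3)
        m.data.iloc[0, 0] = np.nan
        m.data.iloc[2, 7] = np.nan
        res = diff_stats.fit_factorial(m, prior=None)
        nitro = m.channels["nitrogen"].eq("low").astype(float).to_numpy()
        hours = m.channels["timepoint_h"].astype(float).to_numpy() - 24.0
        X = np.column_stack([np.ones_like(hours), nitro, hours, nitro * hours])
        for i, feat in enumerate(m.data.index):
            y = m.data.iloc[i].to_numpy(dtype=float)
            obs = ~np.isnan(y)
            fit = sm.OLS(y[obs], X[obs]).fit()
            mine = res.table[res.table["feature_id"] == feat].set_index("contrast")
            for j, name in enumerate(["Nitrogen", "Time", "Nitrogen:Time"], start=1):
                assert mine.loc[name, "log2FC"] == pytest.approx(fit.params[j], rel=1e-8)
                assert mine.loc[name, "t"] == pytest.approx(fit.tvalues[j], rel=1e-6)
                assert mine.loc[name, "p"] == pytest.approx(fit.pvalues[j], rel=1e-6)

    def test_effect_recovery_under_noise(self):
        """beta_N = 1, sigma = 0.25, n = 3 per cell: the mean estimate over
        1,000 features is within +-0.1 of truth."""
        m = _grid_matrix(lambda N, T: 3.0 + 1.0 * N, n_features=1000, sd=0.25, seed=4)
        res = diff_stats.fit_factorial(m, prior=None)
        nit = res.table[res.table["contrast"] == "Nitrogen"]["log2FC"]
        assert abs(nit.mean() - 1.0) < 0.1

    def test_categorical_time_coding(self):
        m = _grid_matrix(lambda N, T: 1.0 + N + 0.5 * (T == 24.0) * 0)
        res = diff_stats.fit_factorial(m, prior=None, time_coding="categorical")
        assert {"Nitrogen", "Time48", "Time72", "Nitrogen:Time48",
                "Nitrogen:Time72"} <= set(res.table["contrast"])


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(diff_stats.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert diff_stats.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_stay_equal(self):
        assert np.allclose(diff_stats.bh_adjust([0.2] * 7), 0.2)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [-0.1]):
            with pytest.raises(ValueError):
                diff_stats.bh_adjust(bad)

    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=60))
    def test_monotone_and_dominates_p(self, ps):
        adj = diff_stats.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)
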