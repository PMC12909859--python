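"""Inferential chain vs brute-force / closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, strategies as st

import dyadsync as ds
from dyadsync.stats import CohortTable, bh_adjust


def make_cohort(theta, alpha=None, ages=None, sexes=None,
                conditions=("FP1", "SF1", "FP2", "SF2", "RU")):
    """CohortTable from per-band dyads x conditions arrays."""
    theta = np.asarray(theta, float)
    n = theta.shape[0]
    rows = []
    bands = {"theta": theta}
    if alpha is not None:
        bands["alpha"] = np.asarray(alpha, float)
    for b, arr in bands.items():
        for d in range(n):
            for j, c in enumerate(conditions[:arr.shape[1]]):
                if not np.isnan(arr[d, j]):
                    rows.append({"dyad": f"d{d:02d}", "band": b,
                                 "condition": c, "global_wpli": arr[d, j]})
    meta = pd.DataFrame({
        "dyad": [f"d{d:02d}" for d in range(n)],
        "infant_age_months": ages if ages is not None
        else np.linspace(6, 12, n),
        "infant_sex": sexes if sexes is not None
        else ["F", "M"] * (n // 2) + ["F"] * (n % 2),
    })
    return CohortTable(pd.DataFrame(rows), meta,
                       conditions=tuple(conditions))


# ---------------------------------------------------------------------------
# independent oracles

def friedman_by_hand(X):
    """Rank sums within blocks, no tie correction (used on tie-free data)."""
    n, k = X.shape
    ranks = np.array([sps.rankdata(row) for row in X])
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (R ** 2).sum() - 3 * n * (k + 1)
    p = sps.chi2.sf(chi2, k - 1)
    return chi2, p


def bh_by_hand(pvals):
    """Step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def signed_rank_enumeration(d):
    """All 2^n sign patterns on the ranks of |d|; two-sided doubling."""
    ranks = sps.rankdata(np.abs(d))
    wpos = ranks[d > 0].sum()
    n = len(d)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.asarray(dist, float)
    lo = np.mean(dist <= wpos + 1e-9)
    hi = np.mean(dist >= wpos - 1e-9)
    return min(wpos, ranks.sum() - wpos), min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------

class TestOutliers:
    def test_far_value_flagged(self):
        # the outlier inflates the column SD it is judged against, so it
        # must be gross relative to the clean spread (masking effect)
        col = np.full((20, 5), 0.4)
        col += np.random.default_rng(0).normal(0, 0.01, col.shape)
        col[3, 1] = 0.4 + 10 * 0.01
        t = make_cohort(col)
        flags = ds.detect_outliers(t, "theta")
        assert flags.loc["d03", "SF1"]
        assert flags.to_numpy().sum() == 1

    def test_tight_column_unflagged(self):
        col = 0.4 + np.random.default_rng(1).uniform(-0.005, 0.005, (10, 5))
        flags = ds.detect_outliers(make_cohort(col), "theta")
        assert not flags.to_numpy().any()

    def test_rule_none_is_identity(self):
        col = np.random.default_rng(2).normal(0.4, 0.1, (8, 5))
        col[0, 0] = 5.0
        flags = ds.detect_outliers(make_cohort(col), "theta", rule="none")
        assert not flags.to_numpy().any()

    def test_too_few_dyads_rejected(self):
        with pytest.raises(ValueError, match="5 dyads"):
            ds.detect_outliers(make_cohort(np.ones((4, 5))), "theta")


class TestFriedman:
    def test_all_ties_degenerate(self):
        t = make_cohort(np.full((6, 5), 0.4))
        res = ds.friedman_conditions(t, "theta")
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_matches_rank_by_hand_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0.4, 0.05, (4, 3))
        t = make_cohort(X, conditions=("FP1", "SF1", "RU"))
        res = ds.friedman_conditions(t, "theta")
        chi2, p = friedman_by_hand(X)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_raw == pytest.approx(p)
        assert res.df == "2"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0.4, 0.05, (8, 5))
        r1 = ds.friedman_conditions(make_cohort(X), "theta")
        r2 = ds.friedman_conditions(make_cohort(np.exp(3 * X)), "theta")
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_incomplete_dyads_dropped_listwise(self):
        X = np.random.default_rng(5).normal(0.4, 0.05, (8, 5))
        X[2, 1] = np.nan
        res = ds.friedman_conditions(make_cohort(X), "theta")
        assert res.n == 7
        assert "dropped" in res.note

    def test_imputation_keeps_all_dyads(self):
        X = np.random.default_rng(5).normal(0.4, 0.05, (8, 5))
        X[2, 1] = np.nan
        res = ds.friedman_conditions(make_cohort(X), "theta",
                                     missing="impute")
        assert res.n == 8

    def test_type_one_error_calibrated(self):
        """Under exchangeable null data the Friedman test rejects at about
        the nominal 5% level (500 simulated cohorts)."""
        rng = np.random.default_rng(6)
        rej = 0
        for _ in range(500):
            X = rng.normal(0.4, 0.03, (33, 5))
            chi2, p = friedman_by_hand(X)
            res = ds.friedman_conditions(make_cohort(X), "theta")
            assert res.p_raw == pytest.approx(p)
            rej += res.p_raw < 0.05
        assert 0.02 <= rej / 500 <= 0.08


class TestWilcoxon:
    def test_toy_pair_matches_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 3, 4, 5, 7])
        X = np.column_stack([x, y, y + 1, y + 2, y + 3])
        t = make_cohort(X)
        res = ds.pairwise_wilcoxon_fdr(t, "theta")
        r01 = next(r for r in res if r.comparison == "theta: FP1 vs SF1")
        w, p = signed_rank_enumeration(x - y)
        assert r01.statistic == pytest.approx(w)
        assert r01.p_raw == pytest.approx(p)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.3, 1, 10)
            w, p = signed_rank_enumeration(x - y)
            ref = sps.wilcoxon(x, y, method="exact")
            assert w == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_identical_columns_all_fdr_one(self):
        t = make_cohort(np.tile(np.linspace(0.3, 0.5, 8)[:, None], (1, 5)))
        res = ds.pairwise_wilcoxon_fdr(t, "theta")
        assert len(res) == 10
        assert all(r.p_fdr == 1.0 for r in res)
        assert all("degenerate" in r.note for r in res)

    def test_ten_comparisons_one_family(self):
        rng = np.random.default_rng(8)
        t = make_cohort(rng.normal(0.4, 0.05, (12, 5)))
        res = ds.pairwise_wilcoxon_fdr(t, "theta")
        assert len(res) == 10
        q = bh_by_hand([r.p_raw for r in res])
        for r, qi in zip(res, q):
            assert r.p_fdr == pytest.approx(qi)
            assert r.p_fdr >= r.p_raw


class TestBenjaminiHochberg:
    def test_hand_case_uniform_grid(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        assert np.allclose(bh_adjust(p), 0.05)

    @given(st.integers(0, 10 ** 6))
    def test_matches_brute_force_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 40))
        assert np.allclose(bh_adjust(p), bh_by_hand(p))

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCovariates:
    def test_identical_groups_null(self):
        X = np.tile(np.linspace(0.3, 0.5, 10)[:, None], (1, 5))
        t = make_cohort(X, sexes=["F", "M"] * 5,
                        ages=np.full(10, 9.0))
        res = ds.covariate_checks(t)
        welch = [r for r in res if r.test_name == "welch_t_sex"]
        # F and M dyads interleave the same value grid -> near-zero t
        assert all(abs(r.statistic) < 1.2 for r in welch)

    def test_perfect_age_correlation(self):
        ages = np.linspace(6, 12, 10)
        X = np.tile(ages[:, None] / 30.0, (1, 5))
        t = make_cohort(X, ages=ages)
        res = [r for r in ds.covariate_checks(t)
               if r.test_name == "pearson_age"]
        assert all(r.statistic == pytest.approx(1.0) for r in res)

    def test_welch_df_matches_satterthwaite(self):
        rng = np.random.default_rng(10)
        g1 = rng.normal(0.4, 0.02, 6)
        g2 = rng.normal(0.45, 0.08, 8)
        X = np.tile(np.concatenate([g1, g2])[:, None], (1, 5))
        t = make_cohort(X, sexes=["F"] * 6 + ["M"] * 8)
        r = next(r for r in ds.covariate_checks(t)
                 if r.test_name == "welch_t_sex")
        v1, v2 = g1.var(ddof=1) / 6, g2.var(ddof=1) / 8
        df = (v1 + v2) ** 2 / (v1 ** 2 / 5 + v2 ** 2 / 7)
        assert float(r.df) == pytest.approx(df, abs=0.01)

    def test_single_sex_group_rejected(self):
        X = np.random.default_rng(11).normal(0.4, 0.05, (6, 5))
        t = make_cohort(X, sexes=["F"] * 5 + ["M"])
        with pytest.raises(ValueError, match="sex group"):
            ds.covariate_checks(t)


class TestRmAncova:
    def test_identical_profiles_f_zero(self):
        t = make_cohort(np.tile(np.linspace(0.3, 0.5, 8)[:, None], (1, 5)))
        res = ds.rm_anova_sensitivity(t, "theta")
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_condition_effect_detected(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0.42, 0.01, (20, 5))
        X[:, [1, 3]] -= 0.04       # still-face drop
        res = ds.rm_anova_sensitivity(make_cohort(X), "theta")
        assert res.statistic > 10
        assert res.p_raw < 0.001

    def test_missing_dyad_dropped_listwise(self):
        rng = np.random.default_rng(13)
        X = rng.normal(0.4, 0.02, (10, 5))
        X[4, 2] = np.nan
        res = ds.rm_anova_sensitivity(make_cohort(X), "theta")
        assert res.n == 9

    def test_power_at_default_effect(self):
        """At the still-face effect the pipeline's generator produces
        (global wPLI drop ~0.02 against within-dyad noise ~0.01), the
        parametric sensitivity F is significant in >= 90% of 100 cohorts
        at n = 33."""
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            base = rng.normal(0.41, 0.02, (33, 1))
            X = base + rng.normal(0, 0.01, (33, 5))
            X[:, [1, 3]] -= 0.02
            res = ds.rm_anova_sensitivity(make_cohort(X), "theta")
            hits += res.p_raw < 0.05
        assert hits >= 90


class TestWideConverter:
    def test_deposited_layout_round_trip(self):
        """A synthetic stand-in for the deposited per-dyad table: one row
        per dyad, ten band_condition columns."""
        rng = np.random.default_rng(14)
        n = 33
        df = pd.DataFrame({"dyad": [f"s{i}" for i in range(n)],
                           "infant_age_months": rng.uniform(6, 12, n),
                           "infant_sex": rng.choice(["F", "M"], n)})
        for b in ("theta", "alpha"):
            for c in ("FP1", "SF1", "FP2", "SF2", "RU"):
                df[f"{b}_{c}"] = rng.normal(0.4, 0.03, n)
        t = CohortTable.from_wide(df)
        assert set(t.bands()) == {"theta", "alpha"}
        w = t.wide("alpha")
        assert w.shape == (n, 5)
        assert w.loc["s3", "SF2"] == pytest.approx(df.loc[3, "alpha_SF2"])
        # the full chain runs on the converted table
        out = ds.run_stats(t)
        assert (out.test_name == "friedman").sum() == 2


def test_run_stats_shapes(small_config):
    rng = np.random.default_rng(15)
    X = rng.normal(0.42, 0.02, (12, 5))
    X[:, [1, 3]] -= 0.03
    A = rng.normal(0.36, 0.02, (12, 5))
    t = make_cohort(X, alpha=A)
    out = ds.run_stats(t)
    assert (out.test_name == "wilcoxon").sum() == 20
    assert (out.test_name == "rm_ancova").sum() == 2
    assert ((out.p_fdr + 1e-12) >= out.p_raw).all()
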