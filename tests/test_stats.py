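import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gesturelat.stats import (
    StatError,
    ancova,
    benjamini_hochberg,
    jzs_bayes_factor,
    mann_whitney_u,
    mixed_anova_2x2,
    one_sample_t,
    outlier_policy,
    paired_t,
    spearman,
)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_bruteforce(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 7.0, 6.5])
        # mid-ranks by hand
        def midrank(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                r[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return r
        rx, ry = midrank(x), midrank(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).statistic == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            res = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_matches_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = spearman(x, y, exact=True)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            hits += abs(r) >= obs - 1e-12
            total += 1
        assert res.p == pytest.approx(hits / total)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y)
        trans = spearman(np.exp(x), y**3)
        assert trans.statistic == pytest.approx(base.statistic, rel=1e-12)
        assert trans.p == pytest.approx(base.p, rel=1e-12)

    def test_constant_input_flagged(self):
        with pytest.raises(StatError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.options["u_second"] == 4.0

    def test_identical_tied_samples(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5  # n1*n2/2 with the half-tie convention

    def test_u_sum_invariant(self, rng):
        for _ in range(10):
            a = rng.choice(np.arange(10.0), size=6)
            b = rng.choice(np.arange(10.0), size=8)
            res = mann_whitney_u(a, b)
            assert res.options["u_first"] + res.options["u_second"] == len(a) * len(b)

    def test_exact_p_matches_scipy(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 8)))
            b = rng.normal(size=int(rng.integers(3, 8)))
            res = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, method="exact")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_tied_data_uses_corrected_normal_approximation(self, rng):
        a = rng.integers(0, 4, size=12).astype(float)
        b = rng.integers(0, 4, size=10).astype(float)
        res = mann_whitney_u(a, b)
        assert res.options["p_method"].startswith("normal")
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=6)
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert r1.statistic == r2.statistic
        assert r1.p == r2.p

    def test_exact_refused_for_large_or_tied(self):
        with pytest.raises(StatError, match="exact"):
            mann_whitney_u([1.0, 1.0, 2.0], [1.0, 3.0], exact=True)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatError):
            mann_whitney_u([], [1.0])


class TestTTests:
    def test_zero_variance_at_null_is_zero(self):
        res = one_sample_t([1.0, 1.0, 1.0], mu0=1.0)
        assert res.statistic == 0.0
        assert res.options.get("zero_variance") is True

    def test_zero_variance_off_null_rejected(self):
        with pytest.raises(StatError, match="variance"):
            one_sample_t([1.0, 1.0, 1.0], mu0=0.0)

    def test_constant_paired_difference_flagged(self):
        with pytest.raises(StatError, match="variance"):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_formula(self, rng):
        for _ in range(10):
            x = rng.normal(0.3, 1.0, size=int(rng.integers(5, 30)))
            res = one_sample_t(x, mu0=0.1)
            ref = sps.ttest_1samp(x, 0.1)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_paired_equals_one_sample_on_differences(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert paired_t(a, b).statistic == pytest.approx(
            one_sample_t(a - b).statistic, rel=1e-12
        )


class TestJzsBayesFactor:
    def test_null_t_favours_null(self):
        assert jzs_bayes_factor(0.0, 15) < 1.0

    def test_large_t_favours_alternative(self):
        assert jzs_bayes_factor(5.0, 20) > 10.0

    def test_matches_pingouin_grid(self):
        pingouin = pytest.importorskip("pingouin")
        for t in (0.088, 1.0, 2.23, 3.5):
            for n in (10, 15, 25):
                ours = jzs_bayes_factor(t, n)
                ref = float(pingouin.bayesfactor_ttest(t, n))
                assert ours == pytest.approx(ref, rel=1e-4)

    def test_prior_scale_recorded_and_matters(self):
        wide = jzs_bayes_factor(2.0, 20, r_scale=1.0)
        narrow = jzs_bayes_factor(2.0, 20, r_scale=0.5)
        assert wide != narrow


class TestMixedAnova:
    def test_identical_values_all_zero_f(self):
        g = np.array(["a"] * 4 + ["b"] * 4)
        ones = np.ones(8)
        res = mixed_anova_2x2(ones, ones, g)
        assert all(r.statistic == 0.0 for r in res.values())

    def test_constructed_crossover_interaction(self):
        # group a: arm1 - arm2 = +1; group b: -1; group means equal
        y1 = np.array([1.5, 2.5, 3.5, 0.5, 1.5, 2.5])
        y2 = np.array([0.5, 1.5, 2.5, 1.5, 2.5, 3.5])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = mixed_anova_2x2(y1, y2, g)
        assert res["interaction"].statistic > 0
        assert res["group"].statistic == pytest.approx(0.0, abs=1e-20)

    def test_matches_ttest_decomposition(self, rng):
        y1 = rng.normal(size=20)
        y2 = rng.normal(size=20)
        g = np.array(["a"] * 10 + ["b"] * 10)
        res = mixed_anova_2x2(y1, y2, g)
        s, d = (y1 + y2) / 2.0, y1 - y2
        t_group = sps.ttest_ind(s[:10], s[10:]).statistic
        t_inter = sps.ttest_ind(d[:10], d[10:]).statistic
        assert res["group"].statistic == pytest.approx(t_group**2, rel=1e-10)
        assert res["interaction"].statistic == pytest.approx(t_inter**2, rel=1e-10)

    def test_matches_pingouin(self, rng):
        # balanced design: the unbalanced case is covered by the t^2
        # decomposition oracle (unweighted-means / Type III convention)
        pingouin = pytest.importorskip("pingouin")
        y1 = rng.normal(size=18)
        y2 = rng.normal(0.4, 1.0, size=18)
        g = np.array(["a"] * 9 + ["b"] * 9)
        res = mixed_anova_2x2(y1, y2, g)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(18), 2),
                "group": np.tile(g, 2),
                "arm": np.repeat(["l1", "l2"], 18),
                "y": np.concatenate([y1, y2]),
            }
        )
        ref = pingouin.mixed_anova(
            long, dv="y", within="arm", subject="subject", between="group"
        ).set_index("Source")
        assert res["group"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res["within"].statistic == pytest.approx(ref.loc["arm", "F"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_missing_cell_rejected(self):
        with pytest.raises(StatError):
            mixed_anova_2x2([1, np.nan, 2, 3], [1, 2, 3, 4], np.array(["a", "a", "b", "b"]))


def _ancova_frame(rng, n=24, slope=1.0, noise=1.0):
    cov = rng.normal(size=n)
    cause = rng.permutation(np.array(["congenital", "acquired"] * (n // 2)))
    ptype = rng.permutation(np.array(["passive", "active"] * (n // 2)))
    y = slope * cov + noise * rng.normal(size=n)
    return pd.DataFrame({"y": y, "cov": cov, "cause": cause, "ptype": ptype})


class TestAncova:
    def test_orthogonal_covariate_zero_f(self, rng):
        df = _ancova_frame(rng, slope=0.0)
        # make the covariate exactly orthogonal to y and the factor coding
        D = np.column_stack(
            [
                np.ones(len(df)),
                (df["cause"] == "congenital").astype(float),
                (df["ptype"] == "passive").astype(float),
                df["y"],
            ]
        )
        raw = rng.normal(size=len(df))
        df["cov"] = raw - D @ np.linalg.lstsq(D, raw, rcond=None)[0]
        res = ancova(df, "y", ["cause", "ptype"], "cov")
        assert res["cov"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_strong_covariate_detected(self, rng):
        df = _ancova_frame(rng, slope=1.0, noise=0.3)
        res = ancova(df, "y", ["cause", "ptype"], "cov")
        assert res["cov"].p < 0.01
        assert res["cov"].df[1] == len(df) - 4

    def test_matches_nested_model_rss_comparison(self, rng):
        df = _ancova_frame(rng, slope=0.6)
        res = ancova(df, "y", ["cause", "ptype"], "cov")
        # independent route: Type III F per term from nested OLS fits (sum coding)
        c1 = np.where(df["cause"] == "congenital", 1.0, -1.0)
        c2 = np.where(df["ptype"] == "passive", 1.0, -1.0)
        full = np.column_stack([np.ones(len(df)), c1, c2, df["cov"]])
        y = df["y"].to_numpy()

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        rss_full = rss(full)
        dfe = len(df) - full.shape[1]
        for col, term in ((1, "cause"), (2, "ptype"), (3, "cov")):
            reduced = np.delete(full, col, axis=1)
            f = (rss(reduced) - rss_full) / (rss_full / dfe)
            assert res[term].statistic == pytest.approx(f, rel=1e-8)

    def test_empty_level_rejected(self, rng):
        df = _ancova_frame(rng)
        df["cause"] = "congenital"
        with pytest.raises(StatError, match="level"):
            ancova(df, "y", ["cause", "ptype"], "cov")


class TestOutlierPolicy:
    def test_single_gross_outlier_flagged(self):
        flags = outlier_policy([0.0, 0.0, 0.0, 0.0, 10.0])
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_no_flags(self):
        assert not outlier_policy([2.0] * 6).any()

    def test_gaussian_flag_rate_below_one_percent(self):
        rng = np.random.default_rng(7)
        rates = [outlier_policy(rng.normal(size=200)).mean() for _ in range(50)]
        assert np.mean(rates) < 0.01

    def test_minimum_sample_size(self):
        with pytest.raises(StatError):
            outlier_policy([1.0, 2.0])


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=20)
        ours = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
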