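import numpy as np
import pandas as pd
import pytest
import scipy.stats

from chromastress.discomfort_stats import (
    exclude_invariant_observers,
    fit_discomfort_lmm,
    fit_level_lmm,
    ks_two_sample,
    likelihood_ratio_test,
    spearman_bootstrap,
    spearman_difference_test,
    tukey_level_contrasts,
)
from chromastress.synthetic_data import ObserverModel, simulate_ratings


def make_table(n_obs=10, n_img=12, beta=0.4, seed=0, **model_kwargs):
    rng = np.random.default_rng(seed)
    metrics = rng.uniform(0.002, 0.02, n_img)
    model = ObserverModel(beta=beta, **model_kwargs)
    return simulate_ratings(metrics, model, n_observers=n_obs, seed=seed + 1)


class TestExclusion:
    def test_constant_rater_excluded(self):
        t = pd.DataFrame(
            {
                "observer_id": ["a"] * 3 + ["b"] * 3,
                "image_id": ["i1", "i2", "i3"] * 2,
                "rating": [3, 3, 3, 1, 4, 2],
            }
        )
        kept, excluded = exclude_invariant_observers(t)
        assert excluded == ["a"]
        assert set(kept["observer_id"]) == {"b"}

    def test_varying_raters_kept(self):
        t = make_table()
        kept, excluded = exclude_invariant_observers(t)
        assert excluded == []
        assert len(kept) == len(t)


class TestLmmFit:
    def test_noiseless_identical_observers_equal_ols(self):
        # zero variance components: the LMM slope must match pooled OLS
        rng = np.random.default_rng(3)
        metrics = rng.uniform(0.002, 0.02, 10)
        z = (metrics - metrics.mean()) / metrics.std(ddof=1)
        rows = []
        for o in range(5):
            for i in range(10):
                rows.append((f"o{o}", f"i{i}", 3.0 + 0.5 * z[i], metrics[i]))
        t = pd.DataFrame(
            rows, columns=["observer_id", "image_id", "rating", "metric"]
        )
        fit = fit_discomfort_lmm(t, ["metric"])
        assert fit.fe_params["metric"] == pytest.approx(0.5, abs=1e-6)

    def test_aic_bic_identities(self):
        fit = fit_discomfort_lmm(make_table(), ["metric"])
        assert fit.aic == pytest.approx(
            2 * fit.n_params - 2 * fit.loglik, abs=1e-9
        )
        n = len(make_table())
        assert fit.bic == pytest.approx(
            np.log(n) * fit.n_params - 2 * fit.loglik, abs=1e-9
        )

    def test_raw_scale_slope_consistent_with_standardized(self):
        t = make_table(seed=5)
        fit = fit_discomfort_lmm(t, ["metric"])
        sd = t.drop_duplicates("image_id")["metric"].std(ddof=1)
        assert fit.fe_raw["metric"] == pytest.approx(
            fit.fe_params["metric"] / sd
        )

    def test_too_few_groups_rejected(self):
        t = make_table(n_obs=1)
        with pytest.raises(ValueError):
            fit_discomfort_lmm(t, ["metric"])


class TestLrt:
    def test_identical_models_give_zero(self):
        fit = fit_discomfort_lmm(make_table(), ["metric"])
        null = fit_discomfort_lmm(make_table(), [], random_slopes=False)
        res = likelihood_ratio_test(null, fit)
        same = likelihood_ratio_test(
            null, fit_discomfort_lmm(make_table(), ["metric"])
        )
        assert res.chi2 == pytest.approx(same.chi2, abs=1e-8)

    def test_df_three_for_one_covariate_with_random_slope(self):
        t = make_table(seed=7)
        null = fit_discomfort_lmm(t, [], random_slopes=False)
        full = fit_discomfort_lmm(t, ["metric"], random_slopes=True)
        res = likelihood_ratio_test(null, full)
        assert res.df == 3

    def test_invariant_to_covariate_rescaling(self):
        t = make_table(seed=11)
        t2 = t.copy()
        t2["metric"] = t2["metric"] * 1000 + 5
        chi = []
        for tab in (t, t2):
            null = fit_discomfort_lmm(tab, [], random_slopes=False)
            full = fit_discomfort_lmm(tab, ["metric"])
            chi.append(likelihood_ratio_test(null, full).chi2)
        assert chi[0] == pytest.approx(chi[1], abs=1e-5)

    def test_reversed_nesting_rejected(self):
        t = make_table()
        null = fit_discomfort_lmm(t, [], random_slopes=False)
        full = fit_discomfort_lmm(t, ["metric"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, null)


class TestTukey:
    def _level_table(self, means, n_obs=12, n_triples=8, sd=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for o in range(n_obs):
            a_o = rng.normal(0, 0.3)
            for tr in range(n_triples):
                for lvl, mu in means.items():
                    rows.append(
                        (
                            f"o{o}", f"t{tr}_{lvl}", lvl, f"t{tr}",
                            mu + a_o + rng.normal(0, sd),
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["observer_id", "image_id", "level", "triple", "rating"],
        )

    def test_identical_groups_all_nonsignificant(self):
        t = self._level_table({"low": 2.0, "medium": 2.0, "high": 2.0})
        fit = fit_level_lmm(t)
        out = tukey_level_contrasts(fit)
        assert len(out) == 3
        assert (out["p_adj"] > 0.2).all()

    def test_low_vs_others_pattern(self):
        t = self._level_table({"low": 1.6, "medium": 2.0, "high": 2.02})
        fit = fit_level_lmm(t)
        out = tukey_level_contrasts(fit).set_index("contrast")
        # low differs from medium and high; medium vs high does not
        lo_med = out.loc[[c for c in out.index if "low" in c and "medium" in c][0]]
        med_hi = out.loc[[c for c in out.index if "medium" in c and "high" in c][0]]
        assert lo_med["p_adj"] < 0.05
        assert med_hi["p_adj"] > 0.2

    def test_adjusted_p_not_below_unadjusted_z_test(self):
        t = self._level_table({"low": 1.8, "medium": 2.1, "high": 2.3})
        fit = fit_level_lmm(t)
        out = tukey_level_contrasts(fit)
        for _, row in out.iterrows():
            unadj = 2 * scipy.stats.norm.sf(abs(row["z"]))
            assert row["p_adj"] >= unadj - 1e-9


class TestSpearman:
    def test_perfectly_increasing_is_one(self):
        rho, lo, hi = spearman_bootstrap([1, 2, 3, 4, 5], [2, 4, 6, 8, 10],
                                         B=200, seed=0)
        assert rho == 1.0

    def test_perfectly_decreasing_is_minus_one(self):
        rho, _, _ = spearman_bootstrap([1, 2, 3, 4, 5], [5, 4, 3, 2, 1],
                                       B=200, seed=0)
        assert rho == -1.0

    def test_hand_rank_examples(self):
        # sum of squared rank differences 4 -> 1 - 24/120 = 0.8
        rho, _, _ = spearman_bootstrap(
            [1, 2, 3, 4, 5], [1, 3, 2, 5, 4], B=200, seed=0
        )
        assert rho == pytest.approx(0.8)
        # sum of squared rank differences 6 -> 1 - 36/120 = 0.7
        rho, _, _ = spearman_bootstrap(
            [1, 2, 3, 4, 5], [1, 2, 4, 5, 3], B=200, seed=0
        )
        assert rho == pytest.approx(0.7)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        rho, _, _ = spearman_bootstrap(x, y, B=200, seed=0)
        assert rho == pytest.approx(scipy.stats.spearmanr(x, y).statistic)

    def test_ci_contains_point_estimate(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rho, lo, hi = spearman_bootstrap(x, y, B=2000, seed=3)
        assert lo <= rho <= hi

    def test_all_ties_undefined(self):
        rho, lo, hi = spearman_bootstrap([1, 1, 1, 1], [1, 2, 3, 4],
                                         B=200, seed=0)
        assert np.isnan(rho)


class TestSpearmanDifference:
    def test_identical_targets_p_one(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert spearman_difference_test(x, y, y, B=500, seed=0) == 1.0

    def test_detects_real_difference(self, rng):
        x = np.linspace(0, 1, 50)
        y1 = x + rng.normal(0, 0.1, 50)
        y2 = rng.normal(0, 1, 50)
        p = spearman_difference_test(x, y1, y2, B=1000, seed=1)
        assert p < 0.05


class TestKs:
    def test_identical_samples_d_zero(self):
        D, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert D == 0.0

    def test_fully_separated_d_one(self):
        D, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert D == 1.0

    def test_interleaved_example_is_one_third(self):
        D, _ = ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
        assert D == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])
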