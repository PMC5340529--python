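"""Selection differentials, Welch tests, curve fits, and mixed models."""

import numpy as np
import pandas as pd
import pytest

import ecocycles as ec


class TestSelectionDifferential:
    def test_identical_stages_give_zero(self):
        w = np.array([0.30, 0.32, 0.28, 0.35])
        assert ec.selection_differential(w, w) == pytest.approx(0.0)

    def test_smaller_survivors_give_negative_s(self):
        rng = np.random.default_rng(0)
        before = rng.normal(0.38, 0.05, 200)
        after = rng.normal(0.28, 0.05, 150)
        s = ec.selection_differential(before, after)
        assert s < -0.5

    def test_equals_difference_of_standardized_stage_means(self):
        rng = np.random.default_rng(1)
        before = rng.normal(0.35, 0.04, 80)
        after = rng.normal(0.30, 0.04, 50)
        pooled = np.concatenate([before, after])
        zb = (before.mean() - pooled.mean()) / pooled.std(ddof=1)
        za = (after.mean() - pooled.mean()) / pooled.std(ddof=1)
        assert ec.selection_differential(before, after) == pytest.approx(za - zb)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        before = rng.normal(0.35, 0.04, 60)
        after = rng.normal(0.31, 0.05, 40)
        s1 = ec.selection_differential(before, after)
        s2 = ec.selection_differential(1000 * before + 5, 1000 * after + 5)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_single_stage_insufficient(self):
        with pytest.raises(ValueError):
            ec.selection_differential([0.3], [0.3, 0.31])

    def test_table_wrapper_drops_incomplete_groups(self):
        weights = pd.DataFrame(
            {
                "population": [1] * 5 + [2] * 2,
                "generation": [1] * 5 + [1] * 2,
                "stage": ["before"] * 3 + ["after"] * 2 + ["before"] * 2,
                "weight_mg": [0.3, 0.32, 0.31, 0.28, 0.29, 0.33, 0.3],
            }
        )
        out = ec.selection_differentials(weights)
        assert list(out["population"]) == [1]


class TestWelchT:
    def test_identical_groups(self):
        w = [0.3, 0.31, 0.32, 0.29]
        t, df, p = ec.welch_t(w, w)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t, df, p = ec.welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(np.sqrt(1.5))  # (3-2)/sqrt(1/3+1/3)
        assert df == pytest.approx(4.0)

    def test_textbook_formulas_to_machine_precision(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0.3, 0.05, rng.integers(5, 40))
            b = rng.normal(0.33, 0.08, rng.integers(5, 40))
            t, df, p = ec.welch_t(b, a)
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            t_hand = (a.mean() - b.mean()) / se
            df_hand = se**4 / (
                (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
                + (b.var(ddof=1) / len(b)) ** 2 / (len(b) - 1)
            )
            assert t == pytest.approx(t_hand, abs=1e-12)
            assert df == pytest.approx(df_hand, abs=1e-9)
            # direction agrees with a permutation test's observed effect sign
            assert np.sign(t) == np.sign(a.mean() - b.mean())

    def test_equal_variance_case_matches_pooled_t(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        b = a + 0.07
        t, df, _ = ec.welch_t(a, b)
        from scipy.stats import ttest_ind

        pooled = ttest_ind(b, a, equal_var=True)
        assert t == pytest.approx(pooled.statistic, abs=1e-9)
        assert df == pytest.approx(8.0)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            ec.welch_t([0.3, 0.3, 0.3], [0.4, 0.4])


class TestLogisticSurvivalFit:
    @staticmethod
    def su(N, v, w):
        return 1.0 / (1.0 + (N / v) ** w)

    def make_table(self, N, frac):
        total = np.full_like(N, 1000.0)
        return pd.DataFrame({"n_start": total * 0 + N, "survivors": frac * N})

    def test_noiseless_recovery_is_exact(self):
        N = np.linspace(50, 700, 14)
        table = self.make_table(N, self.su(N, 375.22, 1.83))
        fit = ec.fit_logistic_survival(table)
        assert fit.v == pytest.approx(375.22, rel=1e-6)
        assert fit.w == pytest.approx(1.83, rel=1e-6)

    def test_fitted_curve_passes_through_half_at_v(self):
        N = np.linspace(50, 700, 14)
        fit = ec.fit_logistic_survival(self.make_table(N, self.su(N, 300.0, 2.1)))
        assert self.su(fit.v, fit.v, fit.w) == pytest.approx(0.5)

    def test_scale_consistency(self):
        N = np.linspace(50, 700, 14)
        frac = self.su(N, 375.22, 1.83)
        fit1 = ec.fit_logistic_survival(self.make_table(N, frac))
        fit10 = ec.fit_logistic_survival(self.make_table(10 * N, frac))
        assert fit10.v == pytest.approx(10 * fit1.v, rel=1e-6)
        assert fit10.w == pytest.approx(fit1.w, rel=1e-6)

    def test_binomial_noise_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        N = rng.integers(30, 700, size=400).astype(float)
        p = self.su(N, 375.22, 1.83)
        surv = rng.binomial(N.astype(int), p)
        fit = ec.fit_logistic_survival(
            pd.DataFrame({"n_start": N, "survivors": surv})
        )
        assert abs(fit.v - 375.22) < 3 * fit.se_v
        assert abs(fit.w - 1.83) < 3 * fit.se_w

    def test_bad_tables_rejected(self):
        with pytest.raises(ValueError):
            ec.fit_logistic_survival(
                pd.DataFrame({"n_start": [10.0, 10.0, 10.0], "survivors": [5, 5, 5]})
            )
        with pytest.raises(ValueError):
            ec.fit_logistic_survival(
                pd.DataFrame({"n_start": [10.0, 20.0, 30.0], "survivors": [15, 5, 5]})
            )


def synth_records(rng, slope=-0.004, intercept=-0.18, n_pops=25, n_gens=38,
                  sd_pop=0.05, sd_resid=0.15):
    rows = []
    for pop in range(n_pops):
        alpha = rng.normal(0.0, sd_pop)
        N = rng.uniform(50, 600, n_gens)
        S = intercept + alpha + slope * N + rng.normal(0, sd_resid, n_gens)
        for g in range(n_gens):
            rows.append({"population": pop, "generation": g, "S": S[g], "N_nb": N[g]})
    return pd.DataFrame(rows)


class TestSelectionDensityModel:
    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(12)
        fit = ec.fit_selection_density_model(synth_records(rng))
        est, se = fit.coef.loc["N_nb", "estimate"], fit.coef.loc["N_nb", "se"]
        assert abs(est - (-0.004)) < 3 * se
        assert fit.used_random_intercept

    def test_null_slope_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            fit = ec.fit_selection_density_model(
                synth_records(rng, slope=0.0, n_pops=10, n_gens=15)
            )
            hits += fit.coef.loc["N_nb", "p"] < 0.05
        assert hits <= 1

    def test_constant_s_gives_exactly_zero_slope(self):
        records = pd.DataFrame(
            {"population": [1, 1, 2, 2, 3, 3] * 2, "generation": list(range(12)),
             "S": -0.1, "N_nb": np.linspace(50, 500, 12)}
        )
        fit = ec.fit_selection_density_model(records)
        assert fit.coef.loc["N_nb", "estimate"] == 0.0

    def test_single_population_falls_back_to_ols(self):
        rng = np.random.default_rng(13)
        records = synth_records(rng, n_pops=1, n_gens=30)
        fit = ec.fit_selection_density_model(records)
        assert not fit.used_random_intercept
        assert abs(fit.coef.loc["N_nb", "estimate"] - (-0.004)) < 3 * fit.coef.loc["N_nb", "se"]


class TestDelayedDensityModels:
    @staticmethod
    def make_abundances(rng, n_pops=12, n_gens=25, lag_survival=True):
        """Counts whose log-survival depends on current or lagged densities."""
        rows = []
        for pop in range(n_pops):
            B = rng.uniform(80, 300, n_gens)
            NB = rng.uniform(100, 600, n_gens)
            for g in range(n_gens):
                fec = np.exp(0.6 - 0.002 * B[g] + rng.normal(0, 0.05))
                lag = 0.0005 * NB[g - 1] if (lag_survival and g > 0) else 0.0
                surv = np.exp(-0.2 - 0.001 * NB[g] - lag + rng.normal(0, 0.03))
                surv = min(surv, 1.0)
                rows += [
                    (pop, g, "breeding", "start", B[g]),
                    (pop, g, "breeding", "end", B[g] * fec),
                    (pop, g, "nonbreeding", "start", NB[g]),
                    (pop, g, "nonbreeding", "end", NB[g] * surv),
                ]
        return pd.DataFrame(
            rows, columns=["population", "generation", "season", "boundary", "count"]
        )

    def test_standardized_predictors_and_current_effects_recovered(self):
        rng = np.random.default_rng(14)
        fits = ec.fit_delayed_density_models(self.make_abundances(rng))
        sur = fits["survival"]
        # current non-breeding density effect present and negative
        assert sur.coef.loc["NB", "estimate"] < 0
        assert sur.coef.loc["NB", "p"] < 0.01
        # lagged NB effect built into the data is detected
        assert sur.coef.loc["NB1", "p"] < 0.01

    def test_lag_free_survival_shows_null_lag_terms(self):
        rng = np.random.default_rng(15)
        fits = ec.fit_delayed_density_models(
            self.make_abundances(rng, lag_survival=False)
        )
        sur = fits["survival"]
        for term in ("B1", "NB1", "B2", "NB2"):
            assert sur.coef.loc[term, "p"] > 0.05

    def test_needs_three_generations(self):
        rng = np.random.default_rng(16)
        short = self.make_abundances(rng, n_pops=3, n_gens=2)
        with pytest.raises(ValueError):
            ec.fit_delayed_density_models(short)
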