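import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pathplan import layout as lay
from pathplan import models as m
from pathplan.simulate import SimParams, simulate_judgment, univariate_intercept


def design_features():
    """Obstacle-condition features over the full design (21 cells)."""
    table = lay.feature_table(lay.full_design())
    return table[table["condition"] != 1].reset_index(drop=True)


def tile_design(values, n, rng=None):
    reps = -(-n // len(values))
    return np.tile(np.asarray(values, dtype=float), reps)[:n]


def gen_choices(x, intercept, slope, rng):
    return (rng.random(len(x)) < expit(intercept + slope * x)).astype(int)


class TestUnivariate:
    def test_null_slope_within_3se(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        y = rng.integers(0, 2, size=10_000)
        fit = m.fit_univariate(x, y)
        assert abs(fit.coef) < 3 * fit.se

    def test_amr_coefficient_recovery(self):
        # generating slope 4.67 over the middle-target AMR design values
        rng = np.random.default_rng(2)
        amr = tile_design(design_features().query("target_offset_cm == 0")["amr"], 10_000)
        y = gen_choices(amr, univariate_intercept(4.67, 1.0, 0.90), 4.67, rng)
        fit = m.fit_univariate(amr, y)
        assert abs(fit.coef - 4.67) < 3 * fit.se

    def test_separation_flagged(self):
        fit = m.fit_univariate([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert fit.separated
        assert np.isinf(fit.coef) and fit.coef > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.fit_univariate([1.0, 2.0], [1, 1])

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            m.fit_univariate([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])


class TestMultivariate:
    def gen(self, n, betas, interactions=(0.0, 0.0), intercept=0.5, seed=3):
        rng = np.random.default_rng(seed)
        feats = design_features()[["delta_theta", "delta_d", "amr"]]
        rows = rng.integers(0, len(feats), size=n)
        X = feats.to_numpy()[rows]
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        eta = intercept + Z @ np.asarray(betas)
        eta += interactions[0] * Z[:, 0] * Z[:, 1] + interactions[1] * Z[:, 0] * Z[:, 2]
        y = (rng.random(n) < expit(eta)).astype(int)
        return pd.DataFrame(X, columns=["delta_theta", "delta_d", "amr"]), y

    def test_zero_interactions_shrunk(self):
        X, y = self.gen(4000, [-0.8, -0.5, 0.6])
        fit = m.fit_multivariate(X, y, penalty_C=0.05)
        assert fit.coefficients["delta_theta:delta_d"] == 0.0
        assert fit.coefficients["delta_theta:amr"] == 0.0

    def test_main_effect_recovery(self):
        # printed-CI-width tolerance around the generating standardized effect
        X, y = self.gen(10_000, [-0.17, -0.06, -0.22], seed=4)
        fit = m.fit_multivariate(X, y, include_interactions=False, penalty_C=1.0)
        assert abs(fit.coefficients["delta_theta"] - (-0.17)) < 0.06

    def test_duplicate_column_zeroed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < expit(1.2 * x)).astype(int)
        X = pd.DataFrame({"delta_theta": x, "delta_d": x, "amr": rng.normal(size=2000)})
        fit = m.fit_multivariate(X, y, include_interactions=False, penalty_C=0.1)
        pair = (fit.coefficients["delta_theta"], fit.coefficients["delta_d"])
        assert min(abs(pair[0]), abs(pair[1])) == 0.0

    def test_partition_invariant_to_rescaling(self):
        X, y = self.gen(5000, [-0.4, -0.3, 0.5], seed=6)
        fit1 = m.fit_multivariate(X, y, include_interactions=False, penalty_C=1.0)
        X2 = X.assign(amr=X["amr"] * 100.0, delta_d=X["delta_d"] / 7.0)
        fit2 = m.fit_multivariate(X2, y, include_interactions=False, penalty_C=1.0)
        for key in ("delta_theta", "delta_d", "amr"):
            assert fit1.partition_shares[key] == pytest.approx(
                fit2.partition_shares[key], abs=1e-6
            )


class TestBootstrap:
    def test_null_p_values_centered(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(20):
            x = rng.normal(size=200)
            y = rng.integers(0, 2, size=200)
            out = m.bootstrap_effects(x, y, n_surrogates=200, rng=rng)
            ps.append(out["x0"]["p_value"])
        assert 0.25 < np.median(ps) < 0.75

    def test_strong_effect_p_below_resolution(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10_000)
        y = (rng.random(10_000) < expit(5.0 * x)).astype(int)
        out = m.bootstrap_effects(x, y, n_surrogates=500, rng=rng)
        assert out["x0"]["p_value"] == 0.0

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=500)
        y = (rng.random(500) < expit(0.8 * x)).astype(int)
        out = m.bootstrap_effects(x, y, n_surrogates=300, rng=rng)
        lo, hi = out["x0"]["ci"]
        assert lo < out["x0"]["observed"] < hi

    def test_same_seed_identical(self):
        x = np.random.default_rng(10).normal(size=300)
        y = (np.random.default_rng(11).random(300) < expit(x)).astype(int)
        a = m.bootstrap_effects(x, y, n_surrogates=150, rng=np.random.default_rng(0))
        b = m.bootstrap_effects(x, y, n_surrogates=150, rng=np.random.default_rng(0))
        assert a["x0"]["ci"] == b["x0"]["ci"]
        assert a["x0"]["p_value"] == b["x0"]["p_value"]

    def test_too_few_surrogates_refused(self):
        with pytest.raises(ValueError):
            m.bootstrap_effects([0.0, 1.0], [0, 1], n_surrogates=50)

    def test_batched_fit_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        x = rng.normal(size=400)
        y = (rng.random(400) < expit(0.3 + 0.9 * x)).astype(int)
        X = np.column_stack([np.ones(400), x])
        ours = m.batched_logit_fit(X, y[None, :])[0]
        ref = sm.Logit(y, X).fit(disp=0).params
        np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestPartition:
    def test_equal_effects(self):
        shares = m.effect_partition({"a": 0.2, "b": -0.2, "c": 0.2})
        assert all(v == pytest.approx(100 / 3) for v in shares.values())

    def test_zero_effect_share(self):
        shares = m.effect_partition({"a": 0.0, "b": 0.3, "c": 0.3})
        assert shares["a"] == 0.0
        assert shares["b"] + shares["c"] == pytest.approx(100.0)

    def test_arithmetic_example(self):
        shares = m.effect_partition({"a": 0.30, "b": 0.10, "c": 0.10})
        assert (shares["a"], shares["b"], shares["c"]) == (60.0, 20.0, 20.0)

    def test_sum_is_100(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            effects = dict(zip("abc", rng.normal(size=3)))
            assert sum(m.effect_partition(effects).values()) == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.effect_partition({"a": 0.0, "b": 0.0})


class TestLoocv:
    def test_separable_is_100(self):
        x = np.r_[np.linspace(-3, -1, 20), np.linspace(1, 3, 20)]
        y = (x > 0).astype(int)
        mean, sd = m.loocv_accuracy(x, y)
        assert mean == 100.0 and sd == 0.0

    def test_noise_near_50(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=400)
        y = rng.integers(0, 2, size=400)
        mean, _ = m.loocv_accuracy(x, y)
        assert abs(mean - 50.0) < 10.0

    def test_deterministic(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=100)
        y = (rng.random(100) < expit(x)).astype(int)
        assert m.loocv_accuracy(x, y) == m.loocv_accuracy(x, y)

    def test_participant_unit(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=120)
        y = (rng.random(120) < expit(2 * x)).astype(int)
        units = np.repeat(np.arange(12), 10)
        mean, sd = m.loocv_accuracy(x, y, unit_ids=units)
        assert 50.0 < mean <= 100.0

    def test_too_few_units(self):
        with pytest.raises(ValueError):
            m.loocv_accuracy([1.0], [1])


class TestJudgmentThreshold:
    def test_symmetric_ratings_threshold_zero(self):
        offsets = np.arange(-35, 36, 5.0)
        ratings = pd.DataFrame(
            {"offset_cm": offsets, "rating": 10.0 * expit(0.3 * offsets)}
        )
        curve = m.judgment_threshold(ratings)
        assert curve.threshold == pytest.approx(0.0, abs=1e-6)
        assert not curve.extrapolated
        assert curve.monotone_rho == pytest.approx(1.0)

    def test_recovers_minus_15(self):
        params = SimParams()
        table = simulate_judgment(
            np.arange(-35, 36, 5.0), params, np.random.default_rng(17)
        )
        curve = m.judgment_threshold(table)
        assert curve.threshold == pytest.approx(-15.0, abs=2.0)

    def test_all_max_ratings_flagged_extrapolated(self):
        offsets = np.arange(-35, 36, 5.0)
        ratings = pd.DataFrame({"offset_cm": offsets, "rating": 10.0})
        curve = m.judgment_threshold(ratings)
        assert curve.extrapolated

    def test_too_few_offsets_rejected(self):
        ratings = pd.DataFrame({"offset_cm": [0, 5, 10], "rating": [4, 5, 6]})
        with pytest.raises(ValueError):
            m.judgment_threshold(ratings)


class TestAmgrModels:
    def test_univariate_coefficient_recovery(self):
        rng = np.random.default_rng(18)
        amgr = rng.uniform(-1, 1, 10_000)
        y = (rng.random(10_000) < expit(1.94 * amgr)).astype(int)
        amr = rng.uniform(0.4, 2.2, 10_000)
        fits = fits_ = m.fit_amgr_models(amgr, amr, y)
        uni = fits["univariate"]
        assert abs(uni.coef - 1.94) < 3 * uni.se

    def test_bivariate_both_positive(self):
        rng = np.random.default_rng(19)
        amgr = rng.uniform(-1, 1, 5000)
        amr = rng.uniform(0.4, 2.2, 5000)
        eta = 1.4 * amgr + 2.0 * (amr - 1.0)
        y = (rng.random(5000) < expit(eta)).astype(int)
        fits = m.fit_amgr_models(amgr, amr, y)
        assert fits["bivariate"]["amgr"]["coef"] > 0
        assert fits["bivariate"]["amr"]["coef"] > 0

    def test_nan_amgr_refused(self):
        with pytest.raises(ValueError):
            m.fit_amgr_models([0.2, np.nan], [1.0, 1.0], [0, 1])

    def test_constant_amgr_rejected(self):
        with pytest.raises(ValueError):
            m.fit_amgr_models([0.5] * 10, [1.0] * 10, [0, 1] * 5)


class TestChoiceProbabilityTable:
    def make_df(self, rng, n=300):
        return pd.DataFrame(
            {
                "delta_d": rng.normal(size=n),
                "target_offset_cm": rng.choice([-30.0, 0.0, 30.0], size=n),
                "choice": rng.integers(0, 2, size=n),
            }
        )

    def test_all_right_gives_ones(self):
        rng = np.random.default_rng(20)
        df = self.make_df(rng).assign(choice=1)
        table = m.choice_probability_table(df, "delta_d", bins=4)
        assert (table["p_right"] == 1.0).all()

    def test_single_trial_bin_wide_ci(self):
        df = pd.DataFrame(
            {"delta_d": [0.0], "target_offset_cm": [0.0], "choice": [1]}
        )
        table = m.choice_probability_table(df, "delta_d", bins=[-1, 1])
        assert table["ci_high"].iloc[0] - table["ci_low"].iloc[0] > 0.7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.choice_probability_table(pd.DataFrame(), "delta_d")


class TestStartFootCorrelation:
    def test_identical_indicators(self):
        r, _ = m.start_foot_choice_correlation(
            ["right", "left", "right", "left"], ["right", "left", "right", "left"]
        )
        assert r == pytest.approx(1.0)

    def test_constant_flagged_nan(self):
        r, p = m.start_foot_choice_correlation(["right"] * 5, ["right", "left"] * 2 + ["right"])
        assert np.isnan(r) and np.isnan(p)
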