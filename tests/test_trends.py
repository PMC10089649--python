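"""Box-Cox transforms, breakpoint regression, cohort variance, trend sim."""

import numpy as np
import pytest

from domainloss.trends import (BoxCoxParams, boxcox, cohort_variability,
                               fit_boxcox, fit_breakpoint, inverse_boxcox,
                               rates_from_fit, simulate_trend)


class TestBoxCox:
    def test_identity_up_to_shift(self):
        p = BoxCoxParams(1.0, 0.0)
        x = np.array([0.5, 1.0, 4.0])
        assert boxcox(x, p) == pytest.approx(x - 1)

    def test_log_limit(self):
        x = np.array([0.3, 1.7, 9.0])
        near_zero = boxcox(x, BoxCoxParams(1e-8, 0.0))
        assert near_zero == pytest.approx(np.log(x), abs=1e-6)
        assert boxcox(x, BoxCoxParams(0.0, 0.0)) == pytest.approx(np.log(x))

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = BoxCoxParams(float(rng.uniform(-1, 1.5)),
                             float(rng.uniform(0, 0.5)))
            x = rng.lognormal(0, 1, 50)
            assert inverse_boxcox(boxcox(x, p), p) == pytest.approx(x, abs=1e-10)

    def test_domain_violation_names_values(self):
        with pytest.raises(ValueError, match="domain"):
            boxcox(np.array([1.0, -2.0]), BoxCoxParams(0.5, 0.0))

    def test_fit_lognormal_power_near_zero(self):
        x = np.random.default_rng(1).lognormal(0, 1, 5000)
        p = fit_boxcox(x)
        assert abs(p.lambda1) < 0.1

    def test_fit_normal_power_near_one(self):
        x = np.random.default_rng(2).normal(10, 1, 5000)
        p = fit_boxcox(x, variant="one_param")
        assert p.lambda1 == pytest.approx(1.0, abs=0.25)

    def test_fit_handles_exact_zeros_via_shift(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.lognormal(-7, 1.5, 2000), np.zeros(200)])
        p = fit_boxcox(x)
        assert p.lambda2 > 0  # shift must open the domain at 0
        y = boxcox(x, p)
        assert np.all(np.isfinite(y))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            fit_boxcox(np.full(100, 3.0))


class TestBreakpoint:
    def test_noiseless_v_recovered_exactly(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 500)
        y = -2.0 * x + 5.86 * np.maximum(0, x - 0.4)
        fit = fit_breakpoint(y, x)
        assert fit.psi == pytest.approx(0.4, abs=1e-3)
        assert fit.slope_left == pytest.approx(-2.0, abs=1e-6)
        assert fit.slope_right == pytest.approx(3.86, abs=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 1000)
        y = -1.0 * x + 3.0 * np.maximum(0, x - 0.5) + rng.normal(0, 0.5, 1000)
        fit = fit_breakpoint(y, x)
        assert fit.ci_low <= fit.psi <= fit.ci_high

    def test_reduces_to_ols_on_linear_data(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 800)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.3, 800)
        fit = fit_breakpoint(y, x)
        # hinge adds nothing: both slopes near the OLS slope
        b = np.polyfit(x, y, 1)[0]
        assert fit.slope_left == pytest.approx(b, abs=0.25)
        assert fit.p_vs_linear > 0.05

    def test_flat_comparisons_detect_both_arms(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 2000)
        y = -1.0 * x + 3.0 * np.maximum(0, x - 0.5) + rng.normal(0, 0.4, 2000)
        fit = fit_breakpoint(y, x)
        assert fit.p_vs_linear < 1e-6
        assert fit.p_vs_flat_left < 1e-6
        assert fit.p_vs_flat_right < 1e-6

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_breakpoint(np.arange(30.0), np.full(30, 2.0))


class TestCohortVariability:
    def test_identical_sds_flat(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 200)
        cohorts = {age: base.copy() for age in (100.0, 300.0, 500.0, 700.0)}
        out = cohort_variability(cohorts)
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_sd_perfect_fit(self):
        rng = np.random.default_rng(9)
        cohorts = {age: rng.normal(0, 0.001 * age, 5000)
                   for age in (100.0, 300.0, 500.0)}
        out = cohort_variability(cohorts)
        assert out["r2"] > 0.99
        assert out["slope"] == pytest.approx(0.001, rel=0.1)

    def test_singleton_cohort_dropped(self, caplog):
        rng = np.random.default_rng(10)
        cohorts = {a: rng.normal(0, 1, 50) for a in (1.0, 2.0, 3.0)}
        cohorts[4.0] = np.array([1.0])
        with caplog.at_level("WARNING"):
            out = cohort_variability(cohorts)
        assert len(out["table"]) == 3
        assert any("dropped" in r.message for r in caplog.records)


class TestSimulateTrend:
    @staticmethod
    def v_rate_map(tr):
        tr = np.asarray(tr)
        return np.exp(np.log(7e-4) + np.where(tr < 0.18, -2.0 * (tr - 0.18),
                                              3.86 * (tr - 0.18)))

    def test_constant_rates_leave_mean_unchanged(self):
        rng = np.random.default_rng(11)
        young = rng.beta(4, 6, 2000)
        sim = simulate_trend(young, lambda t: np.full(len(t), 1e-3),
                             n=5000, horizon=2000, seed=1)
        cp = sim.checkpoints
        assert cp["mean"].iloc[-1] == pytest.approx(cp["mean"].iloc[0], abs=0.02)

    def test_horizon_zero_keeps_everyone(self):
        young = np.random.default_rng(12).beta(4, 6, 500)
        sim = simulate_trend(young, lambda t: np.full(len(t), 1e-3),
                             n=1000, horizon=0.0, checkpoints=[0.0], seed=2)
        assert sim.checkpoints["n_survivors"].iloc[0] == 1000
        assert sim.checkpoints["mean"].iloc[0] == pytest.approx(
            sim.traits.mean())

    def test_survivor_count_non_increasing(self):
        young = np.random.default_rng(13).beta(4, 6, 1000)
        sim = simulate_trend(young, self.v_rate_map, n=3000, horizon=3000,
                             seed=3)
        counts = sim.checkpoints["n_survivors"].to_numpy()
        assert np.all(np.diff(counts) <= 0)

    def test_matches_reweighting_oracle(self):
        """Survivor trait distribution equals the initial distribution
        importance-reweighted by exp(-rate * T)."""
        young = np.random.default_rng(14).beta(4, 6, 2000)
        sim = simulate_trend(young, self.v_rate_map, n=5000, horizon=2000,
                             seed=4)
        w_all = np.exp(-sim.loss_rates * 1000.0)
        oracle_mean = float(np.sum(sim.traits * w_all) / np.sum(w_all))
        cp = sim.checkpoints
        got = float(cp.loc[cp["time"] == 1000.0, "mean"].iloc[0])
        n_surv = int(cp.loc[cp["time"] == 1000.0, "n_survivors"].iloc[0])
        mc_err = 3 * sim.traits.std() / np.sqrt(n_surv)
        assert abs(got - oracle_mean) < mc_err

    def test_rates_from_fit_floors_predictions(self):
        from domainloss.trends import BreakpointFit
        fit = BreakpointFit(psi=0.18, ci_low=0.1, ci_high=0.3,
                            slope_left=-2.0, slope_right=3.86,
                            intercept=np.log(7e-4), adj_r2=0.03,
                            p_vs_linear=0.0, p_vs_flat_left=0.0,
                            p_vs_flat_right=0.0, sse=1.0, n=100)
        # intercept is the value AT x=0; with the log transform the
        # back-transformed rates must stay positive everywhere
        rate = rates_from_fit(fit, BoxCoxParams(0.0, 0.0))
        out = rate(np.linspace(0, 1, 50))
        assert np.all(out >= 1e-6)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_trend(np.array([]), self.v_rate_map, seed=0)
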