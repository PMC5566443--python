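"""Power-law / exponential / lognormal fitting: closed forms, the KS
lower-bound scan against a brute-force oracle, and bootstrap behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from callscale import (
    compare_models,
    estimate_alpha,
    fit_exponential,
    fit_lognormal,
    fit_powerlaw,
    gof_pvalue,
    ks_distance,
    powerlaw_ccdf,
    sample_powerlaw_intervals,
)


def brute_force_scan(data):
    """Independent oracle: exhaustive lower-bound scan via scipy.stats.kstest.

    Shares no code with the implementation: candidate bounds, tail MLE and
    the KS supremum are all recomputed from first principles.
    """
    data = np.sort(np.asarray(data, dtype=float))
    data = data[data > 0]
    best = None
    for x in np.unique(data)[:-1]:
        tail = data[data >= x]
        alpha = 1.0 + tail.size / np.log(tail / x).sum()
        d = stats.kstest(tail, lambda v: 1.0 - (v / x) ** (1.0 - alpha)).statistic
        if best is None or d < best[2]:
            best = (alpha, x, d)
    return best


class TestPowerlawCcdf:
    def test_boundary_and_closed_form_values(self):
        assert powerlaw_ccdf(5.0, 2.7, 5.0) == 1.0
        assert powerlaw_ccdf(2.0, 3.0, 1.0) == pytest.approx(0.25)
        assert powerlaw_ccdf(10.0, 2.0, 1.0) == pytest.approx(0.1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            powerlaw_ccdf(0.5, 2.5, 1.0)
        with pytest.raises(ValueError):
            powerlaw_ccdf(2.0, 0.9, 1.0)

    @given(
        alpha=st.floats(1.05, 6.0),
        tau_min=st.floats(0.01, 50.0),
        factor=st.floats(1.0, 1e4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_decreasing_from_one(self, alpha, tau_min, factor):
        taus = tau_min * np.array([1.0, factor, factor * 1.5])
        vals = powerlaw_ccdf(taus, alpha, tau_min)
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) <= 1e-15)

    def test_moments_finite_mean_divergent_variance_for_alpha_in_2_3(self):
        # E[T] = tau_min*(a-1)/(a-2) finite iff a>2; E[T^2] finite iff a>3:
        # verify against numerical integrals of the density on a huge range
        from scipy.integrate import quad

        a, tmin = 2.5, 1.0
        pdf = lambda t: (a - 1) / tmin * (t / tmin) ** (-a)
        mean, _ = quad(lambda t: t * pdf(t), tmin, np.inf)
        assert mean == pytest.approx(tmin * (a - 1) / (a - 2), rel=1e-8)
        m2_partial = [quad(lambda t: t * t * pdf(t), tmin, u)[0] for u in (1e3, 1e6)]
        assert m2_partial[1] > 10 * m2_partial[0]  # second moment diverges


class TestEstimateAlpha:
    def test_corrected_estimator_unit_log_term(self):
        tau_min = 2.0
        tau = np.array([np.e * (tau_min - 0.5)])
        assert estimate_alpha(tau, tau_min, "paper-eq4") == pytest.approx(2.0)

    def test_continuous_closed_form(self):
        taus = np.full(7, np.e * 3.0)
        assert estimate_alpha(taus, 3.0, "continuous") == pytest.approx(2.0)

    def test_continuous_mle_recovers_generating_exponent(self):
        taus = sample_powerlaw_intervals(10000, 2.5, 1.0, seed=1)
        alpha = estimate_alpha(taus, 1.0, "continuous")
        assert 2.45 <= alpha <= 2.55

    def test_discrete_zeta_mle_on_integer_data(self):
        # scipy's zipf IS the zeta power law on k >= 1: an independent sampler
        taus = stats.zipf.rvs(2.5, size=20000, random_state=9).astype(float)
        alpha = estimate_alpha(taus, 1.0, "discrete")
        assert 2.45 <= alpha <= 2.55

    def test_corrected_estimator_requires_bound_above_half(self):
        with pytest.raises(ValueError, match="1/2"):
            estimate_alpha(np.array([1.0, 2.0]), 0.4, "paper-eq4")

    def test_tail_violation_rejected(self):
        with pytest.raises(ValueError):
            estimate_alpha(np.array([0.5, 2.0]), 1.0, "continuous")


class TestKsDistance:
    def test_quantile_placed_points_attain_half_step_floor(self):
        # points placed at mid-step model quantiles: the supremum is exactly
        # half an empirical step, the smallest D any m-point sample allows
        m, alpha, tau_min = 100, 2.5, 1.0
        levels = (2 * m - 2 * np.arange(m) - 1) / (2 * m)  # (emp_hi+emp_lo)/2
        tail = tau_min * levels ** (-1.0 / (alpha - 1.0))
        model = lambda v: (np.asarray(v) / tau_min) ** (1.0 - alpha)
        assert ks_distance(tail, model, tau_min) == pytest.approx(1 / (2 * m))

    def test_two_point_supremum_includes_lower_step_limit(self):
        # tail {1, 2} vs CCDF (tau)^-2: the gap just below tau=2 (empirical
        # 0.5 vs model ~1) dominates the at-point gap |0.5 - 0.25|
        model = lambda v: np.asarray(v, dtype=float) ** -2.0
        assert ks_distance(np.array([1.0, 2.0]), model, 1.0) == pytest.approx(0.5)

    def test_agrees_with_scipy_kstest(self):
        taus = sample_powerlaw_intervals(500, 2.3, 1.5, seed=21)
        alpha = estimate_alpha(taus, 1.5)
        d_mine = ks_distance(taus, lambda v: (np.asarray(v) / 1.5) ** (1 - alpha), 1.5)
        d_scipy = stats.kstest(taus, lambda v: 1 - (v / 1.5) ** (1 - alpha)).statistic
        assert d_mine == pytest.approx(d_scipy, rel=1e-12)

    def test_bound_above_data_rejected(self):
        with pytest.raises(ValueError):
            ks_distance(np.array([1.0, 2.0]), lambda v: v, 3.0)


class TestFitPowerlaw:
    def test_contaminated_sample_recovers_bound_and_exponent(self):
        rng = np.random.default_rng(7)
        data = np.concatenate(
            [
                sample_powerlaw_intervals(7000, 2.5, 1.0, seed=7),
                rng.uniform(0.2, 1.0, 3000),
            ]
        )
        fit = fit_powerlaw(data)
        assert 0.8 <= fit.tau_min <= 1.5
        assert 2.35 <= fit.alpha <= 2.65

    def test_scan_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for seed in range(5):
            data = np.concatenate(
                [
                    sample_powerlaw_intervals(400, 2.4, 1.0, seed=seed),
                    rng.uniform(0.3, 1.0, 150),
                ]
            )
            fit = fit_powerlaw(data)
            alpha, tau_min, d = brute_force_scan(data)
            assert fit.tau_min == tau_min
            assert fit.alpha == pytest.approx(alpha, rel=1e-12)
            assert fit.ks_distance == pytest.approx(d, rel=1e-9)

    def test_scan_matches_oracle_with_ties_and_zeros(self):
        data = np.array([0.0, 0.4, 0.4, 1.0, 1.0, 1.0, 2.0, 3.5, 3.5, 8.0, 30.0])
        fit = fit_powerlaw(data)
        alpha, tau_min, d = brute_force_scan(data)
        assert (fit.alpha, fit.tau_min) == (pytest.approx(alpha), tau_min)
        assert fit.ks_distance == pytest.approx(d, rel=1e-9)

    def test_small_tail_carries_reliability_warning(self):
        taus = sample_powerlaw_intervals(40, 2.5, 1.0, seed=2)
        fit = fit_powerlaw(taus, tau_min_grid=[float(taus.min())])
        assert fit.n_tail == 40
        assert any("unreliable" in w for w in fit.warnings)

    def test_single_candidate_equals_direct_mle(self):
        taus = sample_powerlaw_intervals(500, 2.2, 2.0, seed=3)
        bound = float(taus.min())
        fit = fit_powerlaw(taus, tau_min_grid=[bound])
        assert fit.tau_min == bound
        assert fit.alpha == pytest.approx(estimate_alpha(taus, bound), rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_powerlaw(np.array([1.0]))
        with pytest.raises(ValueError, match="identical"):
            fit_powerlaw(np.full(10, 3.0))

    def test_estimator_bias_shrinks_with_n(self):
        # RMSE of the continuous MLE tracks (alpha-1)/sqrt(n)
        for n, seeds in ((100, 30), (1000, 30)):
            errs = [
                estimate_alpha(sample_powerlaw_intervals(n, 2.5, 1.0, seed=s), 1.0) - 2.5
                for s in range(seeds)
            ]
            rmse = float(np.sqrt(np.mean(np.square(errs))))
            assert rmse < 1.5 * 1.5 / np.sqrt(n)


class TestGofPvalue:
    def test_reproducible_under_fixed_seed(self):
        data = sample_powerlaw_intervals(300, 2.5, 1.0, seed=5)
        fit = fit_powerlaw(data)
        p1 = gof_pvalue(fit, data, n_boot=50, seed=11)
        p2 = gof_pvalue(fit, data, n_boot=50, seed=11)
        assert p1 == p2

    def test_single_replicate_p_is_binary(self):
        data = sample_powerlaw_intervals(200, 2.5, 1.0, seed=6)
        fit = fit_powerlaw(data)
        assert gof_pvalue(fit, data, n_boot=1, seed=0) in (0.0, 1.0)

    def test_invalid_boot_count_rejected(self):
        data = sample_powerlaw_intervals(50, 2.5, 1.0, seed=6)
        fit = fit_powerlaw(data)
        with pytest.raises(ValueError):
            gof_pvalue(fit, data, n_boot=0)

    def test_null_pvalue_not_degenerate_at_zero(self):
        # under the null the test may be conservative but must not reject
        # systematically
        ps = []
        for seed in range(10):
            data = sample_powerlaw_intervals(200, 2.5, 1.0, seed=100 + seed)
            fit = fit_powerlaw(data)
            ps.append(gof_pvalue(fit, data, n_boot=60, seed=seed))
        assert np.median(ps) > 0.2


class TestExponentialFit:
    def test_mle_is_sample_mean_exactly(self):
        fit = fit_exponential(np.array([1.0, 3.0]))
        assert fit.mu == 2.0
        rng = np.random.default_rng(0)
        data = rng.exponential(3.0, 5000)
        assert fit_exponential(data).mu == pytest.approx(data.mean(), rel=1e-15)

    def test_recovers_scale_and_passes_ks_on_own_data(self):
        ok = 0
        for seed in range(20):
            data = np.random.default_rng(seed).exponential(3.0, 5000)
            fit = fit_exponential(data)
            ok += (2.88 <= fit.mu <= 3.12) and fit.ks_pvalue > 0.01
        assert ok >= 19

    def test_rejects_powerlaw_data(self):
        ok = 0
        for seed in range(20):
            data = sample_powerlaw_intervals(5000, 2.5, 1.0, seed=seed)
            ok += fit_exponential(data).ks_pvalue < 0.001
        assert ok >= 19

    def test_degenerate_mean_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.zeros(5))


class TestLognormalFit:
    def test_log_moment_closed_form(self):
        data = np.array([np.e, np.e, np.e**3, np.e**3])
        fit = fit_lognormal(data)
        assert fit.mu_log == pytest.approx(2.0)
        assert fit.sigma_log == pytest.approx(1.0)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal(np.full(10, 2.0))

    def test_parameter_recovery_at_n5000(self):
        rng = np.random.default_rng(4)
        data = rng.lognormal(1.0, 0.5, 5000)
        fit = fit_lognormal(data)
        assert 0.98 <= fit.mu_log <= 1.02
        assert 0.49 <= fit.sigma_log <= 0.51

    def test_zeros_excluded_and_counted(self):
        data = np.array([0.0, 0.0, 1.0, np.e, np.e**2])
        fit = fit_lognormal(data)
        assert fit.n_excluded_zeros == 2
        assert fit.mu_log == pytest.approx(1.0)


class TestCompareModels:
    def test_powerlaw_preferred_on_powerlaw_data(self):
        wins = 0
        for seed in range(10):
            data = sample_powerlaw_intervals(800, 2.5, 1.0, seed=200 + seed)
            cmp_ = compare_models(data, n_boot=50, seed=seed)
            wins += cmp_.preferred == "power-law"
        assert wins >= 9

    def test_exponential_model_accepted_on_own_data(self):
        ok = 0
        for seed in range(10):
            data = np.random.default_rng(300 + seed).exponential(3.0, 800)
            cmp_ = compare_models(data, n_boot=50, seed=seed)
            ok += cmp_.verdicts["exponential"]
        assert ok >= 9

    def test_verdicts_follow_stored_pvalues_and_level(self):
        data = sample_powerlaw_intervals(400, 2.5, 1.0, seed=17)
        cmp_ = compare_models(data, n_boot=50, seed=1, level=0.01)
        assert cmp_.verdicts["power-law"] == (cmp_.powerlaw.gof_pvalue > 0.01)
        assert cmp_.verdicts["exponential"] == (cmp_.exponential.ks_pvalue > 0.01)
        assert cmp_.verdicts["lognormal"] == (cmp_.lognormal.ks_pvalue > 0.01)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_models(np.array([1.0]))
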