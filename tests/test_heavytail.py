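"""Heavy-tail fitting: CCDF, log-normal back-transform, power-law tail, KS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crackfrac.heavytail import (
    AreaSample,
    critical_D,
    empirical_ccdf,
    fit_lognormal,
    fit_powerlaw_tail,
    fit_sample,
    ks_statistic,
    lognormal_interval_mass,
    reports_to_frame,
    summarize_groups,
)

positive_samples = st.lists(
    st.floats(min_value=1e-3, max_value=1e3, allow_nan=False), min_size=2, max_size=60
).map(np.array)


def ccdf_oracle(values):
    """O(n^2) double loop: G(x) = #{v >= x} / n at each distinct x."""
    xs = np.unique(values)
    return xs, np.array([(values >= x).sum() / len(values) for x in xs])


def ks_oracle(values, cdf, xmin=None):
    v = np.sort(values)
    if xmin is not None:
        v = v[v >= xmin]
    m = len(v)
    best = 0.0
    for i, x in enumerate(v):
        best = max(best, abs(cdf(x) - (i + 1) / m), abs(cdf(x) - i / m))
    return best


def powerlaw_fit_oracle(values, min_tail_size=10):
    """Brute-force xmin scan with per-candidate MLE and KS distance."""
    v = np.sort(values)
    best = None
    for xmin in np.unique(v):
        tail = v[v >= xmin]
        m = len(tail)
        if m < min_tail_size:
            continue
        s = np.sum(np.log(tail / xmin))
        if s <= 0:
            continue
        alpha = 1 + m / s
        D = ks_oracle(tail, lambda x: 1 - (x / xmin) ** (1 - alpha))
        if best is None or D < best[0]:
            best = (D, xmin, alpha)
    return best


class TestEmpiricalCCDF:
    def test_small_examples(self):
        c = empirical_ccdf(AreaSample(np.array([1.0, 2.0, 3.0])))
        assert np.allclose(c.gs, [1.0, 2 / 3, 1 / 3])
        c1 = empirical_ccdf(AreaSample(np.array([5.0])))
        assert c1.xs.tolist() == [5.0] and c1.gs.tolist() == [1.0]

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            AreaSample(np.array([1.0, -2.0]))

    @given(positive_samples)
    @settings(max_examples=50, deadline=None)
    def test_matches_double_loop_oracle(self, values):
        c = empirical_ccdf(AreaSample(values))
        xs, gs = ccdf_oracle(values)
        assert np.array_equal(c.xs, xs)
        assert np.allclose(c.gs, gs)
        # non-increasing, starts at 1
        assert c.gs[0] == 1.0
        assert np.all(np.diff(c.gs) <= 0)


class TestLogNormalFit:
    def test_hand_example(self):
        fit = fit_lognormal(AreaSample(np.exp(np.array([-1.0, 1.0]))))
        assert fit.mu == pytest.approx(0.0)
        assert fit.sigma == pytest.approx(1.0)  # divide-by-n MLE
        assert fit.mu_star == pytest.approx(1.0)
        assert fit.sigma_star == pytest.approx(np.e)

    def test_degenerate_sample(self):
        fit = fit_lognormal(AreaSample(np.ones(3)))
        assert fit.degenerate
        assert fit.mu_star == pytest.approx(1.0)
        assert fit.sigma_star == 1.0
        assert np.isnan(fit.ks_D)

    def test_mu_star_is_geometric_mean(self, rng):
        values = rng.lognormal(-1.0, 1.2, size=200)
        fit = fit_lognormal(AreaSample(values))
        assert fit.mu_star == pytest.approx(
            float(np.exp(np.mean(np.log(values)))), rel=1e-14)

    @given(positive_samples, st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=40, deadline=None)
    def test_scale_equivariance(self, values, s):
        """Scaling the sample scales mu* and leaves sigma* unchanged."""
        base = fit_lognormal(AreaSample(values))
        scaled = fit_lognormal(AreaSample(values * s))
        assert scaled.mu_star == pytest.approx(base.mu_star * s, rel=1e-9)
        assert scaled.sigma_star == pytest.approx(base.sigma_star, rel=1e-9)

    def test_permutation_invariance(self, rng):
        values = rng.lognormal(0.0, 1.0, size=50)
        a = fit_lognormal(AreaSample(values))
        b = fit_lognormal(AreaSample(rng.permutation(values)))
        assert (a.mu_star, a.sigma_star, a.ks_D) == (b.mu_star, b.sigma_star, b.ks_D)

    def test_parameter_recovery_at_study_scale(self):
        """n=1e4 draws at the crack-area scale recover mu within 3 SE."""
        from crackfrac.synthetic import gen_lognormal

        mu_star, sigma_star, n = 0.26, 3.3, 10_000
        values = gen_lognormal(mu_star, sigma_star, n, seed=42)
        fit = fit_lognormal(AreaSample(values))
        assert abs(fit.mu - np.log(mu_star)) <= 3 * np.log(sigma_star) / np.sqrt(n)
        assert fit.params_estimated  # caveat flag on the KS p-value


class TestKsStatistic:
    def test_single_point_half(self):
        assert ks_statistic(AreaSample(np.array([2.0])), lambda x: 0.5 * np.ones_like(x)) \
            == pytest.approx(0.5)

    def test_step_function_bound(self, rng):
        v = np.sort(rng.lognormal(0, 1, size=20))
        emp_cdf = lambda x: np.searchsorted(v, x, side="right") / len(v)
        assert ks_statistic(AreaSample(v), emp_cdf) <= 1 / len(v) + 1e-12

    def test_empty_tail_errors(self):
        with pytest.raises(ValueError, match="xmin"):
            ks_statistic(AreaSample(np.array([1.0, 2.0])), lambda x: x, xmin=5.0)

    @given(positive_samples)
    @settings(max_examples=40, deadline=None)
    def test_matches_scan_oracle(self, values):
        cdf = lambda x: 1 - np.exp(-np.asarray(x, dtype=float))
        xmin = float(np.median(values))
        got = ks_statistic(AreaSample(values), cdf, xmin=xmin)
        assert got == pytest.approx(ks_oracle(values, lambda x: 1 - np.exp(-x), xmin))


class TestPowerLawTail:
    def test_fixed_xmin_mle_hand_example(self):
        """{2,4,8} with all values in the tail: alpha = 1 + 3/(3 ln 2)."""
        fit = fit_powerlaw_tail(AreaSample(np.array([2.0, 4.0, 8.0])), min_tail_size=3)
        assert fit.xmin == 2.0
        assert fit.alpha == pytest.approx(1 + 1 / np.log(2), rel=1e-12)
        assert fit.c == pytest.approx((fit.alpha - 1) * fit.xmin ** (fit.alpha - 1))

    def test_alpha_recovery_on_pareto(self):
        from crackfrac.synthetic import gen_powerlaw

        alpha, xmin, n = 1.67, 0.25, 5000
        values = gen_powerlaw(xmin, alpha, n, seed=99)
        fit = fit_powerlaw_tail(AreaSample(values))
        assert abs(fit.alpha - alpha) <= 3 * (alpha - 1) / np.sqrt(fit.n_tail)
        assert fit.xmin <= np.quantile(values, 0.10)

    def test_alpha_gt_one_and_density_normalized(self, spliced_sample):
        from scipy.integrate import quad

        values, _ = spliced_sample
        fit = fit_powerlaw_tail(AreaSample(values))
        assert fit.alpha > 1
        mass, _ = quad(lambda x: fit.c * x**-fit.alpha, fit.xmin, np.inf)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError, match="min_tail_size"):
            fit_powerlaw_tail(AreaSample(np.arange(1.0, 6.0)))

    def test_matches_exhaustive_oracle(self, rng):
        from crackfrac.synthetic import gen_spliced

        for seed in (3, 17, 151):
            values, _ = gen_spliced(n=150, seed=seed)
            fit = fit_powerlaw_tail(AreaSample(values))
            D, xmin, alpha = powerlaw_fit_oracle(values)
            assert fit.xmin == pytest.approx(xmin)
            assert fit.alpha == pytest.approx(alpha)
            assert fit.D == pytest.approx(D)

    def test_tie_breaks_to_smaller_xmin(self):
        # duplicated sample: candidate set has exact duplicates, the scan
        # must keep the smallest winning xmin
        values = np.concatenate([np.array([1.0, 2.0, 4.0, 8.0, 16.0])] * 4)
        fit = fit_powerlaw_tail(AreaSample(values), min_tail_size=4)
        D, xmin, alpha = powerlaw_fit_oracle(values, min_tail_size=4)
        assert fit.xmin == xmin and fit.D == pytest.approx(D)


class TestCriticalD:
    def test_reference_values(self):
        assert critical_D(100) == pytest.approx(0.136)
        assert critical_D(400) == pytest.approx(0.068)

    def test_pass_fail_logic(self):
        from crackfrac.synthetic import gen_powerlaw

        values = gen_powerlaw(0.25, 1.67, 400, seed=5)
        fit = fit_powerlaw_tail(AreaSample(values))
        assert fit.passed == (fit.D < fit.D_crit)

    def test_decreases_with_n(self):
        assert critical_D(10_000) < critical_D(100) < critical_D(10)

    def test_unsupported_significance(self):
        with pytest.raises(ValueError, match="significance"):
            critical_D(100, significance=0.123)

    def test_exact_table_override(self):
        assert critical_D(5, exact_table={5: 0.565}) == 0.565


class TestIntervalMass:
    @pytest.mark.parametrize("k, expected", [(1, 0.68269), (2, 0.95450), (3, 0.99730)])
    def test_back_transform_rule(self, k, expected):
        """Mass between mu*/sigma*^k and mu*.sigma*^k is 2*Phi(k)-1."""
        assert lognormal_interval_mass(0.26, 3.3, k) == pytest.approx(expected, abs=5e-6)

    def test_k_zero_and_parameter_independence(self):
        assert lognormal_interval_mass(0.26, 3.3, 0) == 0.0
        for mu_star, sigma_star in [(0.1, 1.5), (10.0, 4.0), (0.3, 3.2)]:
            assert lognormal_interval_mass(mu_star, sigma_star, 1.7) == \
                lognormal_interval_mass(1.0, 2.0, 1.7)

    def test_matches_fitted_cdf_mass(self, spliced_sample):
        values, _ = spliced_sample
        fit = fit_lognormal(AreaSample(values))
        lo, hi = fit.interval(2)
        assert float(fit.cdf(hi) - fit.cdf(lo)) == pytest.approx(
            lognormal_interval_mass(fit.mu_star, fit.sigma_star, 2), abs=1e-12)


class TestGroupSummary:
    def _report(self, seed, group):
        from crackfrac.synthetic import gen_spliced

        values, _ = gen_spliced(n=200, seed=seed)
        return fit_sample(values, sample_id=f"s{seed}", group=group)

    def test_single_report_table_equals_report(self):
        r = self._report(1, "A")
        table = summarize_groups([r])
        assert table.loc["A", "alpha"] == pytest.approx(r.powerlaw.alpha)
        assert table.loc["A", "mu_star"] == pytest.approx(r.lognormal.mu_star)

    def test_identical_reports_mean_is_common_value(self):
        r = self._report(2, "B")
        table = summarize_groups([r, r])
        assert table.loc["B", "xmin"] == pytest.approx(r.powerlaw.xmin)
        assert table.attrs["n_samples"]["B"] == 2

    def test_schema(self):
        table = summarize_groups([self._report(3, "A"), self._report(4, "B")])
        assert list(table.columns) == ["xmin", "alpha", "D", "mu_star",
                                       "sigma_star", "total_area_mm2"]
        raw = reports_to_frame([self._report(3, "A")])
        assert {"sample_id", "group", "n"}.issubset(raw.columns)
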