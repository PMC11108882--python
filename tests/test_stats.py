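"""Correlation statistics: coefficients, p-values, Fisher-z CIs, OLS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special
from scipy import stats as sps

from gazebias import (
    SyntheticConfig,
    apply_inclusion,
    correlate_by_fixation,
    fisher_ci,
    generate_cohort,
    ols_slope,
    pearson_r,
    per_age_fixation_means,
    r_p_value,
    spearman_rho,
    trim_to_post_onset,
)
from gazebias.stats import DegenerateDesignError, ZeroVarianceError
from gazebias.synthetic import AXES

# Published per-fixation correlations of per-year mean gaze bias with age
# (n = 61 age years) and their printed 95% CIs, used as analytic checks of
# the Fisher-z interval.
PRINTED_CI_ROWS = [
    (0.41, (0.18, 0.60)),  # vertical, fixation 1
    (0.64, (0.46, 0.77)),  # vertical, fixation 2
    (0.79, (0.67, 0.87)),  # vertical, fixation 3
    (0.43, (0.20, 0.62)),  # horizontal, fixation 3
]


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_evaluated_product_moment(self):
        # xc=(-1.5,-.5,.5,1.5), yc=(-.5,-1.5,1.5,.5): Sxy=3, Sxx=Syy=5 -> 0.6
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert pearson_r(x, y) == pytest.approx(sps.pearsonr(x, y).statistic)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
        flip=st.booleans(),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, a, b, flip, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        scale = -a if flip else a
        r0 = pearson_r(x, y)
        r1 = pearson_r(scale * x + b, y)
        assert r1 == pytest.approx(-r0 if flip else r0, abs=1e-9)


class TestSpearman:
    def test_monotone_transforms_give_one(self):
        x = np.array([1.0, 3.0, 5.0, 10.0, 20.0])
        assert spearman_rho(x, np.exp(x / 10)) == pytest.approx(1.0)
        assert spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_rank_valued_inputs_equal_pearson(self):
        # values already coincide with their ranks
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert spearman_rho(x, y) == pytest.approx(pearson_r(x, y)) == pytest.approx(0.6)

    def test_agrees_with_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 5, size=20).astype(float)
            y = rng.integers(0, 5, size=20).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic
            )


class TestPValue:
    def test_zero_r_gives_one(self):
        assert r_p_value(0.0, 20) == pytest.approx(1.0)

    def test_monotone_decreasing_in_abs_r(self):
        ps = [r_p_value(r, 30) for r in np.linspace(0, 0.99, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_quadrature_oracle(self):
        # two-sided tail mass of the t density integrated numerically
        r, n = 0.5, 12
        df = n - 2
        t = r * math.sqrt(df) / math.sqrt(1 - r * r)

        def t_pdf(u):
            c = special.gamma((df + 1) / 2) / (
                math.sqrt(df * math.pi) * special.gamma(df / 2)
            )
            return c * (1 + u * u / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(t_pdf, t, np.inf)
        assert r_p_value(r, n) == pytest.approx(2 * tail, rel=1e-8)

    def test_exact_fit_convention(self):
        assert r_p_value(1.0, 10) == 0.0


class TestFisherCI:
    @pytest.mark.parametrize("r, expected", PRINTED_CI_ROWS)
    def test_reproduces_printed_intervals(self, r, expected):
        lo, hi = fisher_ci(r, 61)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_contains_point_estimate(self):
        for r in np.linspace(-0.95, 0.95, 21):
            lo, hi = fisher_ci(r, 30)
            assert -1 <= lo <= r <= hi <= 1

    def test_width_shrinks_with_n(self):
        widths = [np.diff(fisher_ci(0.3, n))[0] for n in (10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_degenerate_at_unit_r(self):
        assert fisher_ci(1.0, 20) == (1.0, 1.0)

    @pytest.mark.parametrize("rho", [0.0, 0.4, 0.8])
    def test_empirical_coverage(self, rho):
        # 10,000 bivariate-normal samples at n=61: coverage near 95%
        n, reps = 61, 10_000
        rng = np.random.default_rng(2024)
        x = rng.normal(size=(reps, n))
        y = rho * x + math.sqrt(1 - rho * rho) * rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = np.einsum("ij,ij->i", xc, yc) / np.sqrt(
            np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc)
        )
        half = sps.norm.ppf(0.975) / math.sqrt(n - 3)
        lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
        coverage = np.mean((lo <= rho) & (rho <= hi))
        assert 0.94 <= coverage <= 0.96


class TestOlsSlope:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ols_slope(x, 0.05 * x + 3.0)
        assert fit.slope == pytest.approx(0.05)
        assert fit.intercept == pytest.approx(3.0)

    def test_constant_y_gives_zero_slope(self):
        fit = ols_slope([1, 2, 3], [7, 7, 7])
        assert fit.slope == 0.0

    def test_six_point_hand_solution(self):
        # normal equations by hand: Sxy=35, Sxx=17.5 -> slope 2, intercept 1
        x = [0, 1, 2, 3, 4, 5]
        y = [1.0, 2.9, 5.1, 7.0, 9.1, 10.9]
        fit = ols_slope(x, y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_residuals_orthogonal_to_x(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        fit = ols_slope(x, y)
        resid = y - fit.slope * x - fit.intercept
        assert abs(resid @ x) < 1e-9

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDesignError):
            ols_slope([2, 2, 2], [1, 2, 3])


class TestCorrelateByFixation:
    @staticmethod
    def aggregate_from(cfg):
        cohort = [trim_to_post_onset(p) for p in generate_cohort(cfg)]
        included, _ = apply_inclusion(cohort)
        return per_age_fixation_means(included)

    def test_noise_free_linear_effect_gives_unit_r(self):
        beta = [0.01] * 9
        cfg = SyntheticConfig(
            counts_per_age=2,
            sigma_participant=0.0,
            sigma_fixation=0.0,
            frac_few_fixations=0.0,
            frac_pre_onset=0.0,
            age_slope={"horizontal": beta, "vertical": beta},
        )
        results = correlate_by_fixation(self.aggregate_from(cfg))
        assert len(results) == 18
        for res in results:
            assert res.r == pytest.approx(1.0)
            assert res.n == 61

    def test_constant_bias_surfaces_zero_variance(self):
        cfg = SyntheticConfig(
            counts_per_age=2,
            sigma_participant=0.0,
            sigma_fixation=0.0,
            frac_few_fixations=0.0,
            frac_pre_onset=0.0,
            age_slope={"horizontal": (0.0,) * 9, "vertical": (0.0,) * 9},
        )
        with pytest.raises(ZeroVarianceError, match="no association computable"):
            correlate_by_fixation(self.aggregate_from(cfg))

    def test_r_sign_matches_injected_slope_sign(self):
        # mixed-sign effect profile; moderate noise; sign stable over seeds
        beta_h = [0.03, -0.03, 0.03, -0.03, 0.03, -0.03, 0.03, -0.03, 0.03]
        beta_v = [-0.03, 0.03, -0.03, 0.03, -0.03, 0.03, -0.03, 0.03, -0.03]
        for seed in range(10):
            cfg = SyntheticConfig(
                counts_per_age=30,
                sigma_participant=1.5,
                sigma_fixation=1.0,
                frac_few_fixations=0.0,
                frac_pre_onset=0.0,
                age_slope={"horizontal": beta_h, "vertical": beta_v},
                seed=seed,
            )
            for res in correlate_by_fixation(self.aggregate_from(cfg)):
                beta = (beta_h if res.axis == "horizontal" else beta_v)[
                    res.fix_index - 1
                ]
                assert np.sign(res.r) == np.sign(beta)
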