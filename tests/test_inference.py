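"""t-tests, Bayes factors, correlation comparisons, regression, mediation."""

import numpy as np
import pytest
from scipy import stats

from physiosync import (BFConfig, ConfigError, bonferroni,
                        compare_dependent_correlations, jzs_bf10, mediate,
                        one_sample_t_from_raw, pearson, regression_control,
                        two_sample_t, two_sample_t_from_raw)


def moment_matched(mean, sd, n, rng):
    """Raw sample with exactly the requested mean and SD."""
    z = rng.normal(0, 1, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestTwoSampleT:
    def test_equal_means_give_zero(self):
        res = two_sample_t(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert res.t == pytest.approx(0.0) and res.cohens_d == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.bf10 < 1.0

    def test_summary_equals_moment_matched_raw(self, rng):
        x = moment_matched(3.75, 3.31, 24, rng)
        y = moment_matched(1.79, 2.57, 24, rng)
        a = two_sample_t(3.75, 3.31, 24, 1.79, 2.57, 24)
        b = two_sample_t_from_raw(x, y)
        assert a.t == pytest.approx(b.t, abs=1e-9)
        assert a.cohens_d == pytest.approx(b.cohens_d, abs=1e-9)
        assert a.df == b.df

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigError):
            two_sample_t(1.0, 0.0, 10, 0.0, 1.0, 10)
        with pytest.raises(ConfigError):
            two_sample_t(1.0, 1.0, 1, 0.0, 1.0, 10)

    def test_d_ci_brackets_d(self):
        res = two_sample_t(3.75, 3.31, 24, 1.79, 2.57, 24)
        assert res.d_ci_low < res.cohens_d < res.d_ci_high
        # noncentral-t inversion at this contrast: published-grade interval
        assert res.d_ci_low == pytest.approx(0.08, abs=0.01)
        assert res.d_ci_high == pytest.approx(1.24, abs=0.01)


class TestJZSBayesFactor:
    @staticmethod
    def grid_oracle(t, n1, n2=None, scale=0.707):
        """Independent fine-grid quadrature of the same marginal likelihood."""
        if n2 is None:
            n_eff, df = n1, n1 - 1
        else:
            n_eff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2
        center = t / np.sqrt(n_eff)
        d = np.linspace(center - 25, center + 25, 400001)
        f = stats.nct.pdf(t, df, d * np.sqrt(n_eff)) * stats.cauchy.pdf(d, 0, scale)
        return np.trapezoid(f, d) / stats.t.pdf(t, df)

    def test_null_t_favours_h0(self):
        bf = jzs_bf10(0.0, 24, kind="one_sample")
        assert bf < 1.0
        assert bf == pytest.approx(self.grid_oracle(0.0, 24), rel=1e-6)

    def test_large_t_overwhelms_h0(self):
        bf = jzs_bf10(8.0, 24, kind="one_sample")
        assert bf > 100.0
        assert bf == pytest.approx(self.grid_oracle(8.0, 24), rel=1e-6)

    def test_two_sample_matches_grid_and_pingouin(self):
        import pingouin

        bf = jzs_bf10(2.29, 24, 24)
        assert bf == pytest.approx(self.grid_oracle(2.29, 24, 24), rel=1e-6)
        assert bf == pytest.approx(float(pingouin.bayesfactor_ttest(2.29, 24, 24)),
                                   rel=1e-6)

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bf10(t, 24, 24) for t in np.linspace(0, 6, 13)]
        assert np.all(np.diff(bfs) > 0)

    def test_custom_prior_width(self):
        wide = jzs_bf10(0.0, 24, kind="one_sample", cfg=BFConfig(cauchy_scale=1.4))
        narrow = jzs_bf10(0.0, 24, kind="one_sample", cfg=BFConfig(cauchy_scale=0.707))
        assert wide < narrow  # wider prior penalised harder at t = 0


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_independent_samples_near_zero(self, rng):
        x = rng.normal(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert abs(pearson(x, y).r) < 0.1

    def test_four_point_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        cx, cy = x - x.mean(), y - y.mean()
        expected = np.dot(cx, cy) / np.sqrt(np.dot(cx, cx) * np.dot(cy, cy))
        assert pearson(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_fisher_ci_brackets_r(self, rng):
        x = rng.normal(0, 1, 23)
        y = 0.5 * x + rng.normal(0, 1, 23)
        res = pearson(x, y)
        assert res.ci_low < res.r < res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigError):
            pearson(np.ones(5), np.arange(5.0))


class TestDependentCorrelations:
    @staticmethod
    def oracle(r_jk, r_jh, r_kh, n):
        """Second, independent transcription of the published z formula,
        written through the unreduced Dunn-Clark covariance evaluated at the
        simple mean correlation."""
        rb = (r_jk + r_jh) / 2.0
        num = r_kh * (1.0 - rb * rb - rb * rb) \
            - 0.5 * rb * rb * (1.0 - rb * rb - rb * rb - r_kh * r_kh)
        den = (1.0 - rb * rb) * (1.0 - rb * rb)
        c = num / den
        z1 = 0.5 * np.log((1 + r_jk) / (1 - r_jk))
        z2 = 0.5 * np.log((1 + r_jh) / (1 - r_jh))
        return (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - c)))

    def test_equal_correlations_give_zero(self):
        z, p = compare_dependent_correlations(0.4, 0.4, 0.1, 30)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_antisymmetric_under_swap(self):
        z1, _ = compare_dependent_correlations(0.5, -0.5, 0.2, 25)
        z2, _ = compare_dependent_correlations(-0.5, 0.5, 0.2, 25)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    @pytest.mark.parametrize("tup", [
        (0.42, -0.06, 0.30, 23),
        (0.45, 0.13, 0.25, 24),
        (-0.49, 0.34, 0.10, 24),
    ])
    def test_matches_independent_transcription(self, tup):
        z, p = compare_dependent_correlations(*tup)
        assert z == pytest.approx(self.oracle(*tup), abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            compare_dependent_correlations(1.0, 0.5, 0.2, 20)


class TestRegressionControl:
    def test_orthogonal_predictor_adds_nothing(self, rng):
        g = np.repeat([0.0, 1.0], 50)
        y = 2.0 * g + rng.normal(0, 1, 100)
        x = rng.normal(0, 1, 100)
        res = regression_control(y, x, g)
        assert abs(res.delta_r2) < 0.05

    def test_perfect_prediction(self, rng):
        x = rng.normal(0, 1, 40)
        g = np.repeat([0.0, 1.0], 20)
        res = regression_control(x, x, g)
        assert res.delta_r2 + 0.0 <= 1.0
        assert res.beta == pytest.approx(1.0, abs=1e-8)
        assert res.p < 1e-12

    def test_recovers_partial_effect(self):
        betas = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            g = np.repeat([0.0, 1.0], 100)
            x = rng.normal(0, 1, 200)
            y = 0.5 * x + 0.8 * g + rng.normal(0, np.sqrt(1 - 0.25), 200)
            betas.append(regression_control(y, x, g).beta)
        # y SD ~ sqrt(.25 + .16 + .75); standardized partial beta ~ .5/sd(y)
        assert np.mean(betas) == pytest.approx(0.5 / np.sqrt(1.16), abs=0.1)


class TestMediate:
    def test_outcome_identical_to_x_has_no_indirect_path(self, rng):
        x = np.tile([0.0, 1.0], 24)
        m = rng.normal(0, 1, 48)
        y = x + 1e-6 * rng.normal(0, 1, 48)  # pure direct effect
        res = mediate(x, m, y, n_boot=200, seed=0)
        assert abs(res.indirect) < 0.05
        assert abs(res.b) < 0.05
        assert res.c == pytest.approx(res.c_prime, abs=0.05)

    def test_indirect_is_product_of_paths(self, rng):
        x = np.tile([0.0, 1.0], 30)
        m = 0.5 * x + rng.normal(0, 1, 60)
        y = 0.5 * m + rng.normal(0, 1, 60)
        res = mediate(x, m, y, n_boot=200, seed=1)
        assert res.indirect == res.a * res.b

    def test_bootstrap_ci_reproducible_bit_for_bit(self, rng):
        x = np.tile([0.0, 1.0], 20)
        m = 0.6 * x + rng.normal(0, 1, 40)
        y = 0.5 * m + rng.normal(0, 1, 40)
        r1 = mediate(x, m, y, n_boot=500, seed=42)
        r2 = mediate(x, m, y, n_boot=500, seed=42)
        assert (r1.boot_ci_low, r1.boot_ci_high) == (r2.boot_ci_low, r2.boot_ci_high)
        r3 = mediate(x, m, y, n_boot=500, seed=43)
        assert (r1.boot_ci_low, r1.boot_ci_high) != (r3.boot_ci_low, r3.boot_ci_high)

    def test_covariate_effects_reported(self, rng):
        x = np.tile([0.0, 1.0], 25)
        cov = rng.normal(0, 1, 50)
        m = 0.5 * x + 0.4 * cov + rng.normal(0, 1, 50)
        y = 0.5 * m + rng.normal(0, 1, 50)
        res = mediate(x, m, y, covariate=cov, n_boot=200, seed=2)
        assert set(res.covariate_effects) == {"on_mediator", "on_outcome"}
        assert res.covariate_effects["on_mediator"] > 0.1

    def test_small_sample_refused(self, rng):
        x = np.array([0.0, 1.0] * 4)
        with pytest.raises(ConfigError, match="n ="):
            mediate(x, rng.normal(0, 1, 8), rng.normal(0, 1, 8))

    def test_non_binary_x_refused(self, rng):
        with pytest.raises(ConfigError, match="binary"):
            mediate(rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                    rng.normal(0, 1, 20))


class TestSmallHelpers:
    def test_bonferroni_caps_at_one(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.6, 4) == 1.0

    def test_one_sample_t_from_raw(self):
        x = np.array([0.5, 0.5, 0.5, 0.7, 0.3])
        res = one_sample_t_from_raw(x)
        assert res.t == pytest.approx(x.mean() / (x.std(ddof=1) / np.sqrt(5)))
        assert res.df == 4
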