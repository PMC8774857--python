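"""Wald ratios, IVW, medians, MR-Egger and Cochran's Q."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrscreen.estimators import (
    EggerRegression,
    IVWEstimator,
    cochran_q,
    egger,
    ivw,
    simple_median,
    wald_ratios,
    weighted_median,
)
from mrscreen.exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    InsufficientVariantsError,
    SingularFitError,
)
from conftest import random_instrument


def _frame(bx, sx, by, sy):
    return pd.DataFrame(dict(beta_x=bx, se_x=sx, beta_y=by, se_y=sy))


class TestWaldRatios:
    def test_first_order_arithmetic(self):
        r = wald_ratios(_frame([0.1], [0.01], [-0.05], [0.02]))
        assert r.theta.iloc[0] == pytest.approx(-0.5)
        assert r.se_theta.iloc[0] == pytest.approx(0.2)
        assert r.weight.iloc[0] == pytest.approx(0.2**-2)

    def test_null_outcome_effect(self):
        r = wald_ratios(_frame([0.1], [0.01], [0.0], [0.02]))
        assert r.theta.iloc[0] == 0.0
        assert r.se_theta.iloc[0] == pytest.approx(0.2)

    def test_negating_both_betas_preserves_theta(self):
        a = wald_ratios(_frame([0.1], [0.01], [0.04], [0.02]))
        b = wald_ratios(_frame([-0.1], [0.01], [-0.04], [0.02]))
        assert a.theta.iloc[0] == b.theta.iloc[0]
        assert a.se_theta.iloc[0] == b.se_theta.iloc[0]

    def test_zero_exposure_effect_names_snp(self):
        with pytest.raises(DegenerateInstrumentError, match="snp1"):
            wald_ratios(_frame([0.1, 0.0], [0.01, 0.01], [0.1, 0.1], [0.02, 0.02]))

    def test_second_order_se_is_larger(self):
        first = wald_ratios(_frame([0.1], [0.01], [0.05], [0.02]))
        second = wald_ratios(_frame([0.1], [0.01], [0.05], [0.02]), second_order=True)
        assert second.se_theta.iloc[0] > first.se_theta.iloc[0]


class TestIVW:
    def test_single_variant_degeneracy(self):
        r = wald_ratios(_frame([0.1], [0.01], [0.05], [0.02]))
        est = ivw(r)
        assert est.estimate == pytest.approx(0.5)
        assert est.q is None and est.q_pval is None
        assert est.phi == 1.0

    def test_homogeneous_ratios(self):
        # every theta_j = 0.5 exactly
        bx = np.array([0.05, 0.1, 0.15])
        est = ivw(wald_ratios(_frame(bx, 0.01, 0.5 * bx, 0.02)))
        assert est.estimate == pytest.approx(0.5)
        assert est.q == pytest.approx(0.0, abs=1e-20)
        assert est.phi == 1.0

    def test_matches_zero_intercept_wls_slope(self, rng):
        """Algebraic identity: ratio-pooled IVW equals the slope of
        zero-intercept WLS of beta_y on beta_x with weights se_y^-2."""
        import statsmodels.api as sm

        for _ in range(25):
            h = random_instrument(rng, j=int(rng.integers(2, 12)))
            est = ivw(wald_ratios(h))
            wls = sm.WLS(h.beta_y, h.beta_x, weights=h.se_y**-2).fit()
            assert est.estimate == pytest.approx(float(wls.params.iloc[0]), abs=1e-12)

    def test_doubling_se_quarters_q(self):
        h = random_instrument(np.random.default_rng(3), j=5)
        r1 = wald_ratios(h)
        h2 = h.assign(se_y=2 * h.se_y)
        r2 = wald_ratios(h2)
        q1, _ = cochran_q(r1, ivw(r1))
        est1 = ivw(r1)
        # at fixed theta and pooled estimate, halving each weight by 4 scales Q by 1/4
        q2 = float(np.sum(r2.weight * (r2.theta - est1.estimate) ** 2))
        q1_fixed = float(np.sum(r1.weight * (r1.theta - est1.estimate) ** 2))
        assert q2 == pytest.approx(q1_fixed / 4.0)

    def test_estimator_class_interface(self, rng):
        h = random_instrument(rng)
        est = IVWEstimator().fit(h)
        assert est.estimate_ == ivw(wald_ratios(h)).estimate
        assert est.ci_low_ <= est.estimate_ <= est.ci_high_
        preds = est.predict(h)
        assert preds == pytest.approx((est.estimate_ * h.beta_x).values)
        # sklearn protocol: params round-trip
        assert IVWEstimator().get_params() == {}

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientVariantsError):
            ivw(pd.DataFrame(columns=["theta", "se_theta", "weight"]))


class TestMedians:
    def test_simple_median_robust_to_outlier(self):
        r = pd.DataFrame(dict(theta=[1.0, 2.0, 30.0], se_theta=[0.1] * 3, weight=[100.0] * 3))
        assert simple_median(r, n_boot=100, seed=0).estimate == 2.0

    def test_even_j_midpoint_convention(self):
        r = pd.DataFrame(dict(theta=[1.0, 3.0], se_theta=[0.1] * 2, weight=[100.0] * 2))
        with pytest.warns(UserWarning):
            assert simple_median(r, n_boot=100, seed=0).estimate == 2.0

    def test_weighted_median_with_equal_weights_is_simple_median(self, rng):
        theta = rng.normal(0, 1, 7)
        r = pd.DataFrame(dict(theta=theta, se_theta=0.3, weight=0.3**-2))
        wm = weighted_median(r, n_boot=100, seed=0).estimate
        sm_ = simple_median(r, n_boot=100, seed=0).estimate
        assert wm == pytest.approx(sm_)

    def test_dominant_weight_pulls_estimate_to_that_snp(self):
        # middle SNP holds ~96% of the weight
        r = pd.DataFrame(dict(theta=[0.0, 1.0, 2.0],
                              se_theta=[1.0, 0.1, 1.0]))
        r["weight"] = r.se_theta**-2
        est = weighted_median(r, n_boot=100, seed=0).estimate
        # hand interpolation: cumulative midpoints ~ {0.0049, 0.5098, 0.9951};
        # 0.5 falls just below the dominant SNP's midpoint
        w = (r.se_theta**-2 / (r.se_theta**-2).sum()).values
        s = np.cumsum(w) - w / 2
        expected = np.interp(0.5, s, [0.0, 1.0, 2.0])
        assert est == pytest.approx(expected)
        assert abs(est - 1.0) < 0.05

    def test_permutation_invariance(self, rng):
        theta = rng.normal(0, 1, 6)
        se = rng.uniform(0.1, 0.5, 6)
        r1 = pd.DataFrame(dict(theta=theta, se_theta=se, weight=se**-2))
        perm = rng.permutation(6)
        r2 = r1.iloc[perm].reset_index(drop=True)
        assert (
            weighted_median(r1, n_boot=50, seed=0).estimate
            == weighted_median(r2, n_boot=50, seed=0).estimate
        )

    def test_bootstrap_se_stable_across_seeds(self, rng):
        h = random_instrument(rng, j=8)
        r = wald_ratios(h)
        se1 = simple_median(r, n_boot=10_000, seed=1).se
        se2 = simple_median(r, n_boot=10_000, seed=2).se
        assert abs(se1 - se2) / se1 < 0.05

    def test_n_boot_below_two_raises(self):
        r = pd.DataFrame(dict(theta=[1.0, 2.0, 3.0], se_theta=[0.1] * 3, weight=[100.0] * 3))
        with pytest.raises(ConfigurationError):
            simple_median(r, n_boot=1, seed=0)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.05, 0.08, 0.11, 0.14])
        by = 0.02 + 0.7 * bx  # no noise
        slope, intercept = egger(_frame(bx, 0.01, by, 0.02))
        assert slope.estimate == pytest.approx(0.7)
        assert intercept.estimate == pytest.approx(0.02)
        assert slope.phi == 1.0
        # with the phi >= 1 floor, zero residuals leave the unscaled SE
        assert slope.se > 0

    def test_orientation_negates_both_betas(self):
        bx = np.array([0.05, -0.08, 0.11, -0.14])
        by = 0.02 + 0.7 * np.abs(bx) * np.sign(bx)  # pleiotropy on oriented scale
        by_oriented = 0.02 + 0.7 * np.abs(bx)
        s1, i1 = egger(_frame(np.abs(bx), 0.01, by_oriented, 0.02))
        s2, i2 = egger(
            _frame(bx, 0.01, np.where(bx < 0, -by_oriented, by_oriented), 0.02)
        )
        assert s1.estimate == pytest.approx(s2.estimate)
        assert i1.estimate == pytest.approx(i2.estimate)

    def test_identical_exposure_effects_singular(self):
        with pytest.raises(SingularFitError):
            egger(_frame([0.1] * 4, 0.01, [0.1, 0.2, 0.3, 0.4], 0.02))

    def test_too_few_variants(self):
        with pytest.raises(InsufficientVariantsError):
            egger(_frame([0.1, 0.2], 0.01, [0.1, 0.2], 0.02))

    def test_overdispersion_floor(self, rng):
        h = random_instrument(rng, j=10)
        fit = EggerRegression().fit(h)
        assert fit.phi_ >= 1.0
        assert fit.slope_.pval <= 1.0 and fit.intercept_.pval <= 1.0


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        r = pd.DataFrame(dict(theta=[0.5] * 4, se_theta=[0.1] * 4, weight=[100.0] * 4))
        q, p = cochran_q(r, ivw(r))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_single_variant_gives_absent_result(self):
        r = pd.DataFrame(dict(theta=[0.5], se_theta=[0.1], weight=[100.0]))
        assert cochran_q(r, ivw(r)) == (None, None)

    def test_null_mean_approximates_degrees_of_freedom(self, rng):
        """Under homogeneity Q ~ chi-square with J-1 df, so mean Q ~ J-1."""
        qs = []
        for _ in range(400):
            bx = rng.uniform(0.05, 0.15, 5)
            sy = np.full(5, 0.02)
            by = 0.3 * bx + rng.normal(0, sy)
            q, _ = cochran_q(r := wald_ratios(_frame(bx, 0.01, by, sy)), ivw(r))
            qs.append(q)
        mean, se = np.mean(qs), np.std(qs, ddof=1) / np.sqrt(len(qs))
        assert abs(mean - 4.0) < 4 * se


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=3, max_value=12))
def test_sign_equivariance(seed, j):
    """Negating all beta_y negates every estimate and preserves SE, Q, phi."""
    h = random_instrument(np.random.default_rng(seed), j=j)
    neg = h.assign(beta_y=-h.beta_y)

    a, b = ivw(wald_ratios(h)), ivw(wald_ratios(neg))
    assert b.estimate == pytest.approx(-a.estimate)
    assert b.se == pytest.approx(a.se)
    assert b.q == pytest.approx(a.q)
    assert b.phi == pytest.approx(a.phi)

    sa = simple_median(wald_ratios(h), n_boot=2000, seed=7)
    sb = simple_median(wald_ratios(neg), n_boot=2000, seed=7)
    assert sb.estimate == pytest.approx(-sa.estimate)
    # bootstrap SEs agree in distribution, not draw-by-draw
    assert sb.se == pytest.approx(sa.se, rel=0.2)

    ea, eb = egger(h), egger(neg)
    assert eb[0].estimate == pytest.approx(-ea[0].estimate)
    assert eb[0].se == pytest.approx(ea[0].se)
    assert eb[1].estimate == pytest.approx(-ea[1].estimate)
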