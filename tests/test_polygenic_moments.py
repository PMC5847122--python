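import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from prsdesign import (
    EnvModel,
    PolygenicDesign,
    SimConfig,
    TraitModel,
    replicate_score_moments,
    score_moments,
    selection_quantiles,
    truncation_factor,
)


def second_moment_by_quadrature(x0, x1):
    """Independent oracle: integrate z^2 phi(z) over [x1, x0] adaptively."""
    hi = 12.0 if math.isinf(x0) else x0
    val, _ = quad(lambda z: z**2 * norm.pdf(z), x1, hi, limit=200)
    return val


class TestTruncationFactor:
    def test_upper_tail_from_zero_is_half(self):
        assert truncation_factor(math.inf, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_empty_window_is_zero(self):
        for x in (-2.0, 0.0, 1.3):
            assert truncation_factor(x, x) == 0.0

    def test_reversed_window_rejected(self):
        with pytest.raises(ValueError):
            truncation_factor(0.0, 1.0)

    def test_matches_quadrature_on_random_windows(self, rng):
        """T equals the second-moment integral for 50 random windows."""
        for _ in range(50):
            x1, x0 = sorted(rng.uniform(-4.0, 4.0, size=2))
            assert truncation_factor(x0, x1) == pytest.approx(
                second_moment_by_quadrature(x0, x1), abs=1e-9
            )
        # open upper windows, including the genome-wide significance quantile
        for x1 in (-1.0, 0.5, 1.959964, 3.0):
            assert truncation_factor(math.inf, x1) == pytest.approx(
                second_moment_by_quadrature(math.inf, x1), abs=1e-9
            )

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nonnegative_and_bounded_by_unit_variance(self, a, b):
        x1, x0 = sorted((a, b))
        t = truncation_factor(x0, x1)
        assert 0.0 <= t <= 1.0 + 1e-12


class TestSelectionQuantiles:
    def test_open_window_gives_infinite_upper_quantile(self, cvd):
        q = selection_quantiles(cvd.design, cvd.trait)
        assert math.isinf(q.q0) and math.isinf(q.r0)

    def test_genome_wide_quantile(self, cvd):
        q = selection_quantiles(cvd.design, cvd.trait)
        assert q.q1 == pytest.approx(5.4513, abs=1e-4)

    def test_shrinkage_decreases_with_n_and_vanishes_at_infinity(self, cvd):
        thetas = [
            selection_quantiles(replace(cvd.design, n=n), cvd.trait).theta
            for n in (1e3, 1e5, 1e7)
        ]
        assert thetas == sorted(thetas, reverse=True)
        assert all(0.0 < t <= 1.0 for t in thetas)
        q_inf = selection_quantiles(replace(cvd.design, n=math.inf), cvd.trait)
        assert q_inf.theta == 0.0 and q_inf.r1 == 0.0 and math.isinf(q_inf.r0)

    def test_quantile_ordering(self, breast_cancer):
        d = replace(breast_cancer.design, p0=1e-4, p1=0.5)
        q = selection_quantiles(d, breast_cancer.trait)
        assert q.q0 >= q.q1 and q.r0 >= q.r1


class TestScoreMoments:
    def test_complete_noiseless_score_recovers_chip_heritability(self):
        """With every marker kept and infinite training, R^2 equals h2."""
        design = PolygenicDesign(n=math.inf, m=1000, h2_chip=0.42, pi0=0.6, p1=1.0)
        m = score_moments(design, TraitModel.continuous())
        assert m.cov_sy == pytest.approx(0.42, abs=1e-12)
        assert m.var_s == pytest.approx(0.42, abs=1e-12)
        assert m.r2 == pytest.approx(0.42, abs=1e-12)

    def test_infinite_n_binary_also_recovers_chip_heritability(self, cvd):
        design = replace(cvd.design, n=math.inf, p1=1.0)
        m = score_moments(design, cvd.trait, cvd.env)
        assert m.r2 == pytest.approx(cvd.design.h2_chip, abs=1e-12)

    def test_zero_genetic_correlation_kills_cross_covariance(self, cvd):
        env = EnvModel(r2_xy=0.052, r2_gx=0.3, rho=0.0)
        m = score_moments(cvd.design, cvd.trait, env)
        assert m.cov_sx == 0.0

    def test_r2_nondecreasing_in_n(self, cvd, breast_cancer, height):
        for scn in (cvd, breast_cancer, height):
            design = replace(scn.design, p1=0.05)
            r2 = [
                score_moments(replace(design, n=float(n)), scn.trait, scn.env).r2
                for n in np.logspace(3, 7, 12)
            ]
            assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    @given(
        n=st.floats(1e2, 1e7),
        log_m=st.floats(2, 6),
        pi0=st.floats(0.0, 0.999),
        h2=st.floats(0.01, 1.0),
        p1=st.floats(1e-9, 1.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_r2_bounded_by_chip_heritability(self, n, log_m, pi0, h2, p1):
        design = PolygenicDesign(n=n, m=int(10**log_m), h2_chip=h2, pi0=pi0, p1=p1)
        m = score_moments(design, TraitModel.continuous())
        assert m.r2 <= h2 + 1e-10

    def test_binary_reduces_to_continuous_when_scale_factor_is_one(self, monkeypatch):
        """Internal consistency: with c forced to 1 the binary pipeline is the
        continuous one at effective sample size n / (P(1-P))."""
        monkeypatch.setattr(TraitModel, "c", property(lambda self: 1.0))
        trait = TraitModel.binary(K=0.2, P=0.4)
        design = PolygenicDesign(n=10_000, m=1000, h2_chip=0.3, pi0=0.9, p1=0.05)
        binary = score_moments(design, trait)
        n_eff = 10_000 / (0.4 * 0.6)
        continuous = score_moments(replace(design, n=n_eff), TraitModel.continuous())
        assert binary.cov_sy == pytest.approx(continuous.cov_sy, rel=1e-12)
        assert binary.var_s == pytest.approx(continuous.var_s, rel=1e-12)

    def test_degenerate_window_warns(self):
        design = PolygenicDesign(n=math.inf, m=100, h2_chip=0.3, pi0=0.5, p0=0.5, p1=0.6)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            m = score_moments(design, TraitModel.continuous())
        assert m.degenerate


class TestSimulatorAgreement:
    """Eqs for cov(S,Y), var(S), cov(S,X) against the Monte Carlo training oracle."""

    def test_continuous_moments_within_three_monte_carlo_ses(self):
        design = PolygenicDesign(n=2000, m=1000, h2_chip=0.3, pi0=0.9, p1=0.05)
        trait = TraitModel.continuous()
        env = EnvModel(r2_xy=0.1, r2_gx=0.5, rho=0.4)
        analytic = score_moments(design, trait, env)
        config = SimConfig(design, trait, env, n_target=1, n_reps=300, seed=11)
        mean, se = replicate_score_moments(config)
        assert abs(mean.cov_sy - analytic.cov_sy) < 3 * se.cov_sy
        assert abs(mean.var_s - analytic.var_s) < 3 * se.var_s
        assert abs(mean.cov_sx - analytic.cov_sx) < 3 * se.cov_sx

    def test_binary_moments_within_three_monte_carlo_ses(self, cvd):
        design = replace(cvd.design, m=1000, n=4000.0, p1=0.05)
        analytic = score_moments(design, cvd.trait, cvd.env)
        config = SimConfig(design, cvd.trait, cvd.env, n_target=1, n_reps=300, seed=13)
        mean, se = replicate_score_moments(config)
        assert abs(mean.cov_sy - analytic.cov_sy) < 3 * se.cov_sy
        assert abs(mean.var_s - analytic.var_s) < 3 * se.var_s
        assert abs(mean.cov_sx - analytic.cov_sx) < 3 * se.cov_sx
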