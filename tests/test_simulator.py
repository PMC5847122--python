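import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

from prsdesign import (
    SimConfig,
    auc,
    case_capture,
    categorical_nri,
    combine,
    continuous_nri,
    draw_effects,
    empirical_metrics,
    idi,
    score_moments,
    sens_spec,
    simulate_cohort,
    simulate_training_and_score,
    TrivariateJoint,
)


@pytest.fixture(scope="module")
def scaled_cvd():
    """CVD preset scaled to desk size: 2,000 markers, 20,000 training subjects."""
    from prsdesign import make_scenario

    scn = make_scenario("cvd")
    design = replace(scn.design, m=2000, n=20_000.0, p1=0.05)
    return SimConfig(design, scn.trait, scn.env, n_target=5000, n_reps=100, seed=7)


class TestDeterminism:
    def test_identical_config_reproduces_bit_for_bit(self, scaled_cvd):
        outputs = []
        for _ in range(2):
            rng = np.random.default_rng(scaled_cvd.seed)
            effects = draw_effects(scaled_cvd, rng)
            weights = simulate_training_and_score(scaled_cvd, effects, rng)
            cohort = simulate_cohort(scaled_cvd, effects, weights, rng)
            outputs.append((effects.beta, weights, cohort.score, cohort.y))
        for a, b in zip(*outputs):
            assert np.array_equal(a, b)


class TestEffects:
    def test_null_fraction_and_total_variance(self, scaled_cvd, rng):
        total = []
        nulls = []
        for _ in range(200):
            effects = draw_effects(scaled_cvd, rng)
            total.append((effects.beta**2).sum())
            nulls.append((effects.beta == 0).mean())
        se = np.std(total, ddof=1) / np.sqrt(len(total))
        assert abs(np.mean(total) - scaled_cvd.design.h2_chip) < 3 * se
        assert np.mean(nulls) == pytest.approx(scaled_cvd.design.pi0, abs=0.01)

    def test_perfect_correlation_makes_effects_proportional(self, rng):
        from prsdesign import EnvModel, PolygenicDesign, TraitModel

        design = PolygenicDesign(n=1000, m=500, h2_chip=0.3, pi0=0.5, p1=1.0)
        env = EnvModel(r2_xy=0.4, r2_gx=0.75, rho=1.0)  # genetic var of X = 0.3 = h2
        config = SimConfig(design, TraitModel.continuous(), env, n_target=10, n_reps=1, seed=1)
        effects = draw_effects(config, rng)
        assert np.allclose(effects.alpha, effects.beta)


class TestTraining:
    def test_open_window_keeps_every_marker(self, scaled_cvd, rng):
        config = SimConfig(
            replace(scaled_cvd.design, p0=0.0, p1=1.0),
            scaled_cvd.trait,
            scaled_cvd.env,
            n_target=10,
            n_reps=1,
            seed=2,
        )
        effects = draw_effects(config, rng)
        weights = simulate_training_and_score(config, effects, rng)
        assert np.count_nonzero(weights) == config.design.m

    def test_huge_training_sample_recovers_true_effects(self, scaled_cvd, rng):
        config = SimConfig(
            replace(scaled_cvd.design, n=1e9, p1=1.0),
            scaled_cvd.trait,
            scaled_cvd.env,
            n_target=10,
            n_reps=1,
            seed=3,
        )
        effects = draw_effects(config, rng)
        weights = simulate_training_and_score(config, effects, rng)
        assert np.corrcoef(weights, effects.beta)[0, 1] > 0.999


class TestCohort:
    def test_population_moments_and_prevalence(self, scaled_cvd, rng):
        config = replace(scaled_cvd, n_target=200_000)
        effects = draw_effects(config, rng)
        weights = simulate_training_and_score(config, effects, rng)
        cohort = simulate_cohort(config, effects, weights, rng)
        n = config.n_target
        # spread combines cohort sampling with the realized effect draws:
        # var(sum beta_i^2) = 2 h2^2 / k over k non-null markers
        k = (1 - config.design.pi0) * config.design.m
        effect_sd = math.sqrt(2.0 / k) * config.design.h2_chip
        assert cohort.y.var() == pytest.approx(
            1.0, abs=3 * (math.sqrt(2.0 / n) + effect_sd)
        )
        assert np.cov(cohort.x, cohort.y)[0, 1] == pytest.approx(
            config.env.r2_xy, abs=0.01
        )
        K = config.trait.K
        assert cohort.d.mean() == pytest.approx(
            K, abs=3 * math.sqrt(K * (1 - K) / n) + 0.015
        )

    def test_infeasible_moment_combination_raises(self):
        from prsdesign import EnvModel, PolygenicDesign, TraitModel

        # X almost fully heritable but uncorrelated with Y: cov(X, Y) = r2_xy
        # cannot be carried by residuals of variance r2_xy * (1 - r2_gx)
        design = PolygenicDesign(n=1000, m=200, h2_chip=0.9, pi0=0.5, p1=1.0)
        env = EnvModel(r2_xy=0.5, r2_gx=0.99, rho=0.0)
        config = SimConfig(design, TraitModel.binary(K=0.2), env, n_target=10, n_reps=1, seed=4)
        effects = draw_effects(config, np.random.default_rng(0))
        weights = np.zeros(design.m)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_cohort(config, effects, weights, np.random.default_rng(0))

    def test_perfect_and_random_scores_bracket_auc(self, scaled_cvd, rng):
        config = replace(scaled_cvd, n_target=20_000)
        effects = draw_effects(config, rng)
        weights = simulate_training_and_score(config, effects, rng)
        cohort = simulate_cohort(config, effects, weights, rng)
        perfect = cohort._replace(score=cohort.y - cohort.x)  # comb == y exactly
        report = empirical_metrics(perfect, config.trait)
        assert report.auc > 0.99
        random_score = cohort._replace(score=rng.standard_normal(config.n_target), x=np.zeros(config.n_target))
        report = empirical_metrics(random_score, config.trait, weights=(1.0, 0.0))
        assert report.auc == pytest.approx(0.5, abs=0.02)


RISK_THRESHOLD = 0.20
TOP_FRACTION = 0.2


@pytest.fixture(scope="module")
def replicated(scaled_cvd):
    """Empirical metric means and Monte Carlo SEs over replicate cohorts."""
    rng = np.random.default_rng(scaled_cvd.seed)
    rows = []
    for _ in range(scaled_cvd.n_reps):
        effects = draw_effects(scaled_cvd, rng)
        weights = simulate_training_and_score(scaled_cvd, effects, rng)
        cohort = simulate_cohort(scaled_cvd, effects, weights, rng)
        rep = empirical_metrics(
            cohort,
            scaled_cvd.trait,
            weights=(1.0, 1.0),
            risk_thresholds=(RISK_THRESHOLD,),
            quantiles=(TOP_FRACTION,),
        )
        rows.append(
            [
                rep.auc,
                rep.nri[RISK_THRESHOLD][0],
                rep.nri[RISK_THRESHOLD][1],
                rep.cnri_case,
                rep.cnri_control,
                rep.idi,
                rep.capture[TOP_FRACTION],
                rep.sens_spec[RISK_THRESHOLD][0],
                rep.sens_spec[RISK_THRESHOLD][1],
            ]
        )
    rows = np.asarray(rows)
    return rows.mean(axis=0), rows.std(axis=0, ddof=1) / math.sqrt(len(rows))


@pytest.fixture(scope="module")
def analytic(scaled_cvd):
    moments = score_moments(scaled_cvd.design, scaled_cvd.trait, scaled_cvd.env)
    comb = combine(moments, scaled_cvd.env, "unweighted")
    joint = TrivariateJoint.from_scores(comb, scaled_cvd.env)
    K = scaled_cvd.trait.K
    nri = categorical_nri(joint, RISK_THRESHOLD, K)
    cnri = continuous_nri(joint, K)
    ss = sens_spec(comb.r2_comb, K, RISK_THRESHOLD)
    return np.array(
        [
            auc(comb.r2_comb, K),
            nri[0],
            nri[1],
            cnri[0],
            cnri[1],
            idi(comb, scaled_cvd.env, K),
            case_capture(comb.r2_comb, K, TOP_FRACTION),
            ss[0],
            ss[1],
        ]
    )


class TestMetricAgreement:
    """Every analytic metric against the Monte Carlo cohort oracle (3-SE rule)."""

    @pytest.mark.parametrize(
        "index,name",
        list(
            enumerate(
                [
                    "auc",
                    "nri_case",
                    "nri_control",
                    "cnri_case",
                    "cnri_control",
                    "idi",
                    "capture",
                    "sensitivity",
                    "specificity",
                ]
            )
        ),
    )
    def test_metric_within_three_ses(self, replicated, analytic, index, name):
        mean, se = replicated
        assert abs(mean[index] - analytic[index]) < 3 * se[index], name
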