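"""Individual-level Monte Carlo oracle for the analytic accuracy formulas.

Genotypes are independent standardized Gaussians (the same abstraction the
analytic theory uses), marker effects follow the normal-null mixture, and
per-marker marginal estimation noise is drawn analytically — exact for
independent standardized markers — so a full training GWAS never has to be
regressed marker by marker.  Evaluation cohorts are population samples with
the mediation structure: the environmental score carries a genetic component
built from the same markers, and the non-genetic residuals of X and Y are
correlated exactly as needed to reproduce the moment model (var(Y) = 1,
cov(X, Y) = var(X) = r2_xy, chip covariance rho * sqrt(h2 * r2_xy * r2_gx)).
Infeasible moment combinations raise instead of silently renormalizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm, rankdata

from .model import AccuracyReport, EnvModel, PolygenicDesign, ScoreMoments, TraitModel

__all__ = [
    "SimConfig",
    "Effects",
    "Cohort",
    "draw_effects",
    "simulate_training_and_score",
    "simulate_cohort",
    "empirical_metrics",
    "replicate_score_moments",
    "simulate_trios",
]


@dataclass(frozen=True)
class SimConfig:
    """One simulation setting; the seed is mandatory (no hidden global state)."""

    design: PolygenicDesign
    trait: TraitModel
    env: EnvModel
    n_target: int = 10_000
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target <= 0 or self.n_reps <= 0:
            raise ValueError("n_target and n_reps must be positive")
        if math.isinf(self.design.n):
            raise ValueError("simulation needs a finite training sample size")


class Effects(NamedTuple):
    beta: np.ndarray   # per-marker effects on the outcome/liability
    alpha: np.ndarray  # per-marker effects on the environmental score


class Cohort(NamedTuple):
    score: np.ndarray       # estimated polygenic score S-hat
    x: np.ndarray           # environmental score
    y: np.ndarray           # outcome / latent liability
    d: np.ndarray | None    # disease status (binary traits)


def _residual_covariance(design: PolygenicDesign, env: EnvModel) -> tuple[float, float, float]:
    """Variances of the non-genetic residuals of X and Y and their covariance.

    Chosen so the simulated joint moments match the analytic model exactly:
    the part of cov(X, Y) = r2_xy not carried by the shared markers is routed
    through the residual covariance.
    """
    var_eta = env.r2_xy * (1.0 - env.r2_gx)
    var_eps = 1.0 - design.h2_chip
    cov_res = env.r2_xy - env.genetic_covariance(design.h2_chip)
    bound = math.sqrt(max(var_eta, 0.0) * max(var_eps, 0.0))
    if abs(cov_res) > bound + 1e-12:
        raise ValueError(
            "infeasible parameter combination: the non-genetic residuals of X and Y "
            f"would need correlation {cov_res / bound if bound else math.inf:.3f}"
        )
    return var_eta, var_eps, cov_res


def draw_effects(config: SimConfig, rng: np.random.Generator) -> Effects:
    """Draw per-marker effects under the shared-null normal mixture.

    Each marker is null with probability pi0; non-null outcome effects have
    variance ``h2 / ((1-pi0) m)`` and the environmental-score effects of the
    same markers are correlated at ``rho``, carrying total variance
    ``r2_xy * r2_gx``.
    """
    design, env = config.design, config.env
    m = design.m
    nonnull = rng.random(m) >= design.pi0
    sd_b = math.sqrt(design.h2_chip / ((1.0 - design.pi0) * m))
    sd_a = math.sqrt(env.r2_xy * env.r2_gx / ((1.0 - design.pi0) * m))
    beta = np.zeros(m)
    alpha = np.zeros(m)
    k = int(nonnull.sum())
    if k:
        z1 = rng.standard_normal(k)
        z2 = rng.standard_normal(k)
        beta[nonnull] = sd_b * z1
        alpha[nonnull] = sd_a * (env.rho * z1 + math.sqrt(1.0 - env.rho**2) * z2)
    return Effects(beta=beta, alpha=alpha)


def simulate_training_and_score(
    config: SimConfig, effects: Effects, rng: np.random.Generator
) -> np.ndarray:
    """Estimated per-marker score weights after training and P-value selection.

    Marginal estimates are the true effects plus analytic sampling noise
    (variance ``1/n`` for a continuous trait; ``P(1-P)/n`` on the observed
    0/1 scale for a binary trait, with the estimate back-transformed by 1/c).
    Markers outside the selection window get weight zero.
    """
    design, trait = config.design, config.trait
    if trait.is_binary:
        se = math.sqrt(trait.P * (1.0 - trait.P) / design.n)
        estimate_obs = trait.c * effects.beta + se * rng.standard_normal(design.m)
        z = estimate_obs / se
        weights = estimate_obs / trait.c
    else:
        se = math.sqrt(1.0 / design.n)
        estimate = effects.beta + se * rng.standard_normal(design.m)
        z = estimate / se
        weights = estimate
    pvalues = 2.0 * norm.sf(np.abs(z))
    # p0 = 0 admits P-values that underflow to exactly zero
    above = pvalues > design.p0 if design.p0 > 0.0 else np.ones(design.m, dtype=bool)
    selected = above & (pvalues <= design.p1)
    return np.where(selected, weights, 0.0)


def simulate_cohort(
    config: SimConfig,
    effects: Effects,
    weights: np.ndarray,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> Cohort:
    """Population evaluation cohort of ``n_target`` individuals.

    Per individual: genotypes G ~ N(0, I); X = alpha'G + eta;
    Y = beta'G + eps with (eta, eps) jointly normal per
    :func:`_residual_covariance`; binary status D = 1{Y > tau}.
    Genotypes are generated in chunks and discarded after projection.
    """
    design, trait, env = config.design, config.trait, config.env
    var_eta, var_eps, cov_res = _residual_covariance(design, env)

    n = config.n_target
    score = np.empty(n)
    gx = np.empty(n)
    gy = np.empty(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        g = rng.standard_normal((stop - start, design.m))
        score[start:stop] = g @ weights
        gx[start:stop] = g @ effects.alpha
        gy[start:stop] = g @ effects.beta

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    if var_eta > 1e-14:
        eta = math.sqrt(var_eta) * z1
        slope = cov_res / var_eta
        resid = var_eps - cov_res**2 / var_eta
        eps = slope * eta + math.sqrt(max(resid, 0.0)) * z2
    else:
        eta = np.zeros(n)
        eps = math.sqrt(var_eps) * z2
    x = gx + eta
    y = gy + eps
    d = (y > trait.tau).astype(np.int8) if trait.is_binary else None
    return Cohort(score=score, x=x, y=y, d=d)


def _empirical_auc(score: np.ndarray, d: np.ndarray) -> float:
    """Concordance probability via the rank-sum statistic."""
    n1 = int(d.sum())
    n0 = d.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("cohort must contain both cases and controls")
    ranks = rankdata(score)
    return (ranks[d == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def empirical_metrics(
    cohort: Cohort,
    trait: TraitModel,
    weights: tuple[float, float] = (1.0, 1.0),
    risk_thresholds: tuple[float, ...] = (),
    quantiles: tuple[float, ...] = (0.1, 0.2, 0.5),
) -> AccuracyReport:
    """Counting/averaging estimates of every analytic metric on one cohort.

    The combined score ``w1*S-hat + w2*X`` is calibrated empirically by its
    regression on the outcome; NRI, IDI and sensitivity/specificity compare
    it against the environmental score at the given absolute-risk thresholds.
    """
    if cohort.d is None:
        raise ValueError("empirical accuracy metrics need a binary cohort")
    from .reclassification import risk_from_score

    d = cohort.d
    n1 = int(d.sum())
    if n1 == 0 or n1 == d.size:
        raise ValueError("cohort must contain both cases and controls")
    case, ctrl = d == 1, d == 0

    w1, w2 = weights
    comb = w1 * cohort.score + w2 * cohort.x
    var_comb = comb.var()
    gamma = float(np.cov(comb, cohort.y)[0, 1] / var_comb) if var_comb > 0 else 0.0
    s = gamma * comb
    r2_comb = float(np.cov(s, cohort.y)[0, 1])  # calibrated: cov == var == r2
    r2_env = float(np.var(cohort.x))
    K = trait.K

    auc = _empirical_auc(s, d)
    risk_s = risk_from_score(s, min(r2_comb, 1.0 - 1e-9), K)
    risk_x = risk_from_score(cohort.x, min(r2_env, 1.0 - 1e-9), K)

    nri = {}
    sens_spec = {}
    for a in risk_thresholds:
        up = (risk_s > a) & (risk_x <= a)
        down = (risk_s <= a) & (risk_x > a)
        nri[a] = (
            (up[case].mean() - down[case].mean()),
            (down[ctrl].mean() - up[ctrl].mean()),
        )
        sens_spec[a] = ((risk_s > a)[case].mean(), (risk_s <= a)[ctrl].mean())

    diff = s - cohort.x
    cnri_case = 2.0 * (diff[case] > 0).mean() - 1.0
    cnri_control = 2.0 * (diff[ctrl] <= 0).mean() - 1.0
    idi = (risk_s[case].mean() - risk_s[ctrl].mean()) - (
        risk_x[case].mean() - risk_x[ctrl].mean()
    )

    capture = {}
    for q in quantiles:
        cut = np.quantile(s, 1.0 - q)
        capture[q] = 100.0 * (s[case] > cut).mean()

    return AccuracyReport(
        auc=float(auc),
        nri=nri,
        cnri_case=float(cnri_case),
        cnri_control=float(cnri_control),
        idi=float(idi),
        capture=capture,
        sens_spec=sens_spec,
    )


def replicate_score_moments(config: SimConfig) -> tuple[ScoreMoments, ScoreMoments]:
    """Empirical mean and standard error of the score moments over replicates.

    For fixed weights the population moments are exact sums over markers
    (``cov(S-hat, Y) = sum w_i beta_i``, ``var(S-hat) = sum w_i^2``,
    ``cov(S-hat, X) = sum w_i alpha_i``), so only the training randomness
    (effects + estimation noise) is replicated.  This is the direct oracle
    for the analytic expectations.
    """
    rng = np.random.default_rng(config.seed)
    draws = np.empty((config.n_reps, 3))
    for r in range(config.n_reps):
        effects = draw_effects(config, rng)
        w = simulate_training_and_score(config, effects, rng)
        draws[r] = (w @ effects.beta, w @ w, w @ effects.alpha)
    mean = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1) / math.sqrt(config.n_reps)
    return ScoreMoments(*mean), ScoreMoments(*se)


def simulate_trios(
    h2: float, h2_chip: float, n: int, seed: int = 0
) -> dict[str, float]:
    """Parent-offspring simulation for the family-history parameterization.

    Each parent's phenotype is chip genetic value (variance ``h2_chip``) plus
    non-chip genetic value (``h2 - h2_chip``) plus unique environment; the
    offspring inherits the parental mean of each genetic component plus
    segregation variance (half the component's variance).  The family-history
    predictor is the mid-parent phenotype scaled by ``h2`` so it has unit
    effect on the offspring.  Returns the empirical moments the analytic
    parameterization predicts.
    """
    rng = np.random.default_rng(seed)
    sd_u = math.sqrt(h2_chip)
    sd_v = math.sqrt(h2 - h2_chip)
    sd_e = math.sqrt(1.0 - h2)
    um, uf = sd_u * rng.standard_normal((2, n))
    vm, vf = sd_v * rng.standard_normal((2, n))
    em, ef = sd_e * rng.standard_normal((2, n))
    u_child = (um + uf) / 2.0 + math.sqrt(h2_chip / 2.0) * rng.standard_normal(n)
    v_child = (vm + vf) / 2.0 + math.sqrt((h2 - h2_chip) / 2.0) * rng.standard_normal(n)
    y_child = u_child + v_child + sd_e * rng.standard_normal(n)
    x = h2 * ((um + vm + em) + (uf + vf + ef)) / 2.0

    chip_slope = float(np.cov(x, u_child)[0, 1] / np.var(u_child))
    return {
        "var_x": float(np.var(x)),
        "cov_xy": float(np.cov(x, y_child)[0, 1]),
        "cov_sx": float(np.cov(u_child, x)[0, 1]),
        "r2_gx": chip_slope**2 * float(np.var(u_child)) / float(np.var(x)),
    }
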