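"""Reclassification metrics: categorical and continuous NRI, and IDI.

The liability ``Y``, the environmental score ``X`` and the calibrated
combined score ``gamma * S_comb`` are jointly normal with mean zero, so net
reclassification probabilities across an absolute-risk threshold are
rectangle probabilities of a trivariate normal, the continuous NRI reduces
to orthant probabilities of the bivariate normal of ``(Y, gamma*S_comb - X)``,
and the IDI is a pair of one-dimensional quadratures over the conditional
score densities of cases and controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.stats import multivariate_normal, norm

from .discrimination import conditional_moments
from .model import CombinedScore, EnvModel

__all__ = [
    "TrivariateJoint",
    "risk_from_score",
    "score_cutoff",
    "categorical_nri",
    "continuous_nri",
    "idi",
]

# Absolute tolerance of the multivariate-normal rectangle probabilities.
_MVN_ABSEPS = 1e-7
_MVN_MAXPTS = 2_000_000
# Fixed QMC seed: rectangle probabilities are deterministic across calls.
_MVN_SEED = 0x5EED

_DEGENERATE_VAR = 1e-14


@dataclass(frozen=True)
class TrivariateJoint:
    """Zero-mean joint normal of (liability Y, environmental score X,
    calibrated combined score gamma*S_comb).

    The covariance structure is fully determined by ``r2_comb`` (which is both
    the variance of the calibrated score and its covariance with liability),
    ``r2_xy`` (variance of X and its covariance with liability) and
    ``cov_gx = cov(gamma*S_comb, X)``.
    """

    r2_comb: float
    r2_xy: float
    cov_gx: float
    cov: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        cov = np.array(
            [
                [1.0, self.r2_xy, self.r2_comb],
                [self.r2_xy, self.r2_xy, self.cov_gx],
                [self.r2_comb, self.cov_gx, self.r2_comb],
            ]
        )
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError(
                "covariance of (liability, X, calibrated combined score) is not "
                "positive semi-definite; the score parameters are inconsistent"
            )
        object.__setattr__(self, "cov", cov)

    @classmethod
    def from_scores(cls, comb: CombinedScore, env: EnvModel) -> "TrivariateJoint":
        return cls(r2_comb=comb.r2_comb, r2_xy=env.r2_xy, cov_gx=comb.cov_gcomb_x)

    @property
    def var_difference(self) -> float:
        """Variance of the score difference gamma*S_comb - X."""
        return self.r2_comb + self.r2_xy - 2.0 * self.cov_gx


def _rectangle(lower, upper, cov) -> float:
    """P(lower < Z <= upper) for Z ~ N(0, cov); infinite limits allowed."""
    p = multivariate_normal.cdf(
        np.asarray(upper, dtype=float),
        cov=cov,
        allow_singular=True,
        lower_limit=np.asarray(lower, dtype=float),
        abseps=_MVN_ABSEPS,
        releps=0.0,
        maxpts=_MVN_MAXPTS,
        rng=np.random.default_rng(_MVN_SEED),
    )
    return float(min(max(p, 0.0), 1.0))


def risk_from_score(x: float, r2: float, K: float) -> float:
    """Absolute risk of a subject with calibrated score value ``x``.

    Conditional on the score, liability is normal with mean ``x`` and
    variance ``1 - r2``, so the risk is ``1 - Phi((tau - x)/sqrt(1 - r2))``.
    """
    if r2 >= 1.0:
        raise ValueError("r2 must be below 1")
    tau = float(norm.ppf(1.0 - K))
    risk = 1.0 - norm.cdf((tau - np.asarray(x)) / math.sqrt(1.0 - r2))
    return float(risk) if np.ndim(x) == 0 else risk


def score_cutoff(a: float, r2: float, K: float) -> float:
    """Calibrated-score value whose absolute risk equals ``a`` (inverse of
    :func:`risk_from_score`): ``tau - sqrt(1 - r2) * Phi^-1(1 - a)``."""
    if r2 >= 1.0:
        raise ValueError("r2 must be below 1")
    tau = float(norm.ppf(1.0 - K))
    return tau - math.sqrt(1.0 - r2) * float(norm.ppf(1.0 - a))


def categorical_nri(joint: TrivariateJoint, a: float, K: float) -> tuple[float, float]:
    """Two-category case and control NRI at absolute-risk threshold ``a``.

    Case NRI is the probability (among cases) of moving up across the risk
    threshold when replacing the environmental score by the combined score,
    minus the probability of moving down; the control NRI counts the same
    movements with opposite sign.  Each term is a trivariate-normal
    rectangle probability divided by ``K`` or ``1 - K``.
    """
    if joint.var_difference <= _DEGENERATE_VAR:
        return 0.0, 0.0
    tau = float(norm.ppf(1.0 - K))
    a_x = score_cutoff(a, joint.r2_xy, K)
    a_s = score_cutoff(a, joint.r2_comb, K)
    inf = math.inf
    cov = joint.cov

    up_case = _rectangle([tau, -inf, a_s], [inf, a_x, inf], cov) / K
    down_case = _rectangle([tau, a_x, -inf], [inf, inf, a_s], cov) / K
    down_control = _rectangle([-inf, a_x, -inf], [tau, inf, a_s], cov) / (1.0 - K)
    up_control = _rectangle([-inf, -inf, a_s], [tau, a_x, inf], cov) / (1.0 - K)
    return up_case - down_case, down_control - up_control


def continuous_nri(joint: TrivariateJoint, K: float) -> tuple[float, float]:
    """Category-free NRI: ``2 P(gamma*S_comb > X | D=1) - 1`` in cases and
    ``2 P(gamma*S_comb <= X | D=0) - 1`` in controls.

    The pair (liability, score difference) is bivariate normal with
    covariance ``r2_comb - r2_xy``; identical scores return (0, 0) by
    convention.
    """
    vd = joint.var_difference
    if vd <= _DEGENERATE_VAR:
        return 0.0, 0.0
    tau = float(norm.ppf(1.0 - K))
    cov = np.array(
        [[1.0, joint.r2_comb - joint.r2_xy], [joint.r2_comb - joint.r2_xy, vd]]
    )
    inf = math.inf
    p_case = _rectangle([tau, 0.0], [inf, inf], cov) / K
    p_control = _rectangle([-inf, -inf], [tau, 0.0], cov) / (1.0 - K)
    return 2.0 * p_case - 1.0, 2.0 * p_control - 1.0


def _mean_risk_contrast(r2: float, K: float) -> float:
    """E(risk | case) - E(risk | control) for a calibrated score of variance r2.

    Evaluated as the quadrature of Phi((tau - s)/sqrt(1-r2)) against the
    difference of the control and case conditional score densities.
    """
    if r2 == 0.0:
        return 0.0
    cm = conditional_moments(r2, K)
    tau = float(norm.ppf(1.0 - K))
    s1, s0 = math.sqrt(cm.var_case), math.sqrt(cm.var_control)
    scale = math.sqrt(1.0 - r2)

    def integrand(s: float) -> float:
        return float(norm.cdf((tau - s) / scale)) * (
            float(norm.pdf(s, cm.mean_control, s0)) - float(norm.pdf(s, cm.mean_case, s1))
        )

    # densities are negligible beyond ~8 conditional SDs from either mean
    lo = min(cm.mean_case - 8.0 * s1, cm.mean_control - 8.0 * s0)
    hi = max(cm.mean_case + 8.0 * s1, cm.mean_control + 8.0 * s0)
    value, err = quad(integrand, lo, hi, limit=200, epsabs=1e-12)
    if err > 1e-6:
        raise RuntimeError(f"IDI quadrature did not converge (error estimate {err:g})")
    return value


def idi(comb: CombinedScore, env: EnvModel, K: float) -> float:
    """Integrated discrimination improvement of the combined over the
    environmental score: the between-status contrast in mean absolute risk
    under the combined score minus the same contrast under ``X`` alone."""
    if comb.r2_comb >= 1.0 or env.r2_xy >= 1.0:
        raise ValueError("score R^2 must be below 1")
    return _mean_risk_contrast(comb.r2_comb, K) - _mean_risk_contrast(env.r2_xy, K)
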