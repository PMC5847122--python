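"""Moments of the estimated polygenic score under finite training and P-value selection.

The polygenic score is built from per-marker marginal OLS estimates in a
training sample of size ``n``, keeping markers whose two-sided P-value falls
in the window ``(p0, p1]``.  Because markers are independent and
standardized, the expected covariance of the score with the outcome, its
variance, and its covariance with the environmental score all reduce to
second-moment integrals of the standard normal over the selection region:

    T(x0, x1) = Phi(x0) - Phi(x1) + x1 phi(x1) - x0 phi(x0)
              = integral of z^2 phi(z) dz over [x1, x0].

Null markers are selected at quantiles ``(q0, q1)`` of their null test
statistic; non-null markers at the shrunken quantiles ``(r0, r1)`` where the
shrinkage ``theta`` accounts for the signal-to-noise ratio of a non-null
marker's estimate.  Binary traits use the liability-threshold model: effects
are estimated on the observed 0/1 scale (sampling variance ``P(1-P)/n``) and
back-transformed to the liability scale by the factor ``1/c``.
"""

from __future__ import annotations

import math
import warnings

from scipy.stats import norm

from .model import EnvModel, PolygenicDesign, ScoreMoments, SelectionQuantiles, TraitModel

__all__ = ["truncation_factor", "selection_quantiles", "score_moments"]


def _phi_terms(x: float) -> tuple[float, float]:
    """Return (Phi(x), x * phi(x)) with the exact limits at +/- infinity."""
    if math.isinf(x):
        return (1.0, 0.0) if x > 0 else (0.0, 0.0)
    return float(norm.cdf(x)), x * float(norm.pdf(x))


def truncation_factor(x0: float, x1: float) -> float:
    """Second moment of a standard normal over the two-sided selection region.

    ``T(x0, x1) = Phi(x0) - Phi(x1) + x1*phi(x1) - x0*phi(x0)``, requiring
    ``x0 >= x1``; ``x0 = +inf`` is the open upper selection window.  Equals
    ``int_{x1}^{x0} z^2 phi(z) dz`` and is therefore nonnegative.
    """
    if x0 < x1:
        raise ValueError(f"invalid selection window: x0={x0} < x1={x1}")
    c0, t0 = _phi_terms(x0)
    c1, t1 = _phi_terms(x1)
    return max(c0 - c1 + t1 - t0, 0.0)


def selection_quantiles(design: PolygenicDesign, trait: TraitModel) -> SelectionQuantiles:
    """Raw and shrunken selection quantiles for the design's P-value window.

    For a continuous trait ``theta = (n * h2 / ((1-pi0) m) + 1)^(-1/2)``; for
    a binary trait ``n`` is replaced by ``n / (P(1-P))`` and ``h2`` by
    ``c^2 h2`` (the chip heritability on the observed scale).  At ``n = inf``
    the shrinkage is exactly zero: every non-null marker's P-value collapses
    to 0, so it is selected iff the window includes 0 (i.e. ``p0 = 0``).
    """
    q0 = math.inf if design.p0 == 0.0 else float(norm.ppf(1.0 - design.p0 / 2.0))
    q1 = float(norm.ppf(1.0 - design.p1 / 2.0))

    if math.isinf(design.n):
        theta = 0.0
        r0 = math.inf if math.isinf(q0) else 0.0
        r1 = 0.0
    else:
        if trait.is_binary:
            eff_n = design.n / (trait.P * (1.0 - trait.P))
            signal = trait.c**2 * design.h2_chip
        else:
            eff_n = design.n
            signal = design.h2_chip
        theta = (eff_n * signal / ((1.0 - design.pi0) * design.m) + 1.0) ** -0.5
        r0 = math.inf if math.isinf(q0) else q0 * theta
        r1 = q1 * theta
    return SelectionQuantiles(q0=q0, q1=q1, r0=r0, r1=r1, theta=theta)


def score_moments(
    design: PolygenicDesign, trait: TraitModel, env: EnvModel | None = None
) -> ScoreMoments:
    """Expected moments of the estimated polygenic score on the trait/liability scale.

    Returns ``cov(S-hat, Y)``, ``var(S-hat)`` and ``cov(S-hat, X)``.  The
    factor 2 accounts for the two tails of the selection region; the
    variance splits into a null-marker part (estimation noise passing the
    window at the raw quantiles) and a non-null part (signal plus noise at
    the shrunken quantiles).  ``env=None`` sets ``cov(S-hat, X) = 0``.
    """
    if env is not None:
        env.validate_against(design.h2_chip)
    q = selection_quantiles(design, trait)
    t_non_null = truncation_factor(q.r0, q.r1)
    t_null = truncation_factor(q.q0, q.q1)

    h2 = design.h2_chip
    m, pi0 = design.m, design.pi0
    if trait.is_binary:
        c2 = trait.c**2
        noise = 0.0 if math.isinf(design.n) else trait.P * (1.0 - trait.P) / design.n
        signal_per_marker = c2 * h2 / ((1.0 - pi0) * m)
    else:
        c2 = 1.0
        noise = 0.0 if math.isinf(design.n) else 1.0 / design.n
        signal_per_marker = h2 / ((1.0 - pi0) * m)

    cov_sy = 2.0 * h2 * t_non_null
    var_s = (
        2.0 * m * pi0 * noise * t_null
        + 2.0 * m * (1.0 - pi0) * (signal_per_marker + noise) * t_non_null
    ) / c2
    if env is None or env.r2_xy == 0.0 or env.r2_gx == 0.0:
        cov_sx = 0.0
    else:
        cov_sx = 2.0 * env.genetic_covariance(h2) * t_non_null

    if var_s <= 0.0:
        warnings.warn(
            "no markers are expected to pass the selection window; "
            "the polygenic score is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return ScoreMoments(cov_sy=cov_sy, var_s=var_s, cov_sx=cov_sx)
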