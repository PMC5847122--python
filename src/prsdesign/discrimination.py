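"""Discrimination metrics for a calibrated risk score under the liability model.

All metrics are functions of the score's coefficient of determination with
liability, ``r2``, and the disease prevalence ``K``.  The score and the
liability are jointly normal, so conditioning on case/control status gives
(approximately normal) conditional distributions with closed-form moments;
AUC, top-quantile case capture, and sensitivity/specificity at an
absolute-risk cutoff all follow from these.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from scipy.stats import norm

__all__ = ["ConditionalMoments", "conditional_moments", "auc", "case_capture", "sens_spec"]


class ConditionalMoments(NamedTuple):
    mean_case: float
    var_case: float
    mean_control: float
    var_control: float


def conditional_moments(r2: float, K: float) -> ConditionalMoments:
    """Mean and variance of a calibrated score (variance ``r2``) given status.

    With ``tau = Phi^-1(1-K)`` and the truncated-normal mean liabilities
    ``phi(tau)/K`` (cases) and ``-phi(tau)/(1-K)`` (controls):

        E(S | D=1) = r2 * phi(tau)/K
        var(S | D=1) = r2 * (1 - r2 * (phi(tau)/K) * (phi(tau)/K - tau))

    and symmetrically for controls with ``phi(tau)/(1-K)`` and ``+tau``.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must be in (0, 1), got {K}")
    tau = float(norm.ppf(1.0 - K))
    i1 = float(norm.pdf(tau)) / K
    i0 = float(norm.pdf(tau)) / (1.0 - K)
    return ConditionalMoments(
        mean_case=r2 * i1,
        var_case=r2 * (1.0 - r2 * i1 * (i1 - tau)),
        mean_control=-r2 * i0,
        var_control=r2 * (1.0 - r2 * i0 * (i0 + tau)),
    )


def auc(r2: float, K: float) -> float:
    """Area under the ROC curve of a score with liability R^2 ``r2``.

    ``AUC = Phi((E(S|D=1) - E(S|D=0)) / sqrt(var(S|D=1) + var(S|D=0)))``;
    0.5 for an uninformative score.
    """
    if r2 == 0.0:
        if not (0.0 < K < 1.0):
            raise ValueError(f"prevalence K must be in (0, 1), got {K}")
        return 0.5
    cm = conditional_moments(r2, K)
    return float(
        norm.cdf((cm.mean_case - cm.mean_control) / math.sqrt(cm.var_case + cm.var_control))
    )


def case_capture(r2: float, K: float, q: float) -> float:
    """Percentage of cases found in the top fraction ``q`` of the population.

    The top-``q`` score threshold is ``sqrt(r2) * Phi^-1(1-q)`` (the score has
    variance ``r2``), and the captured share is the case tail beyond it — one
    point on the Lorenz-type risk concentration curve.  Random selection
    (``r2 = 0``) captures ``100 q``; ``q = 1`` captures everyone.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"population fraction q must be in (0, 1], got {q}")
    if r2 == 0.0:
        return 100.0 * q
    cm = conditional_moments(r2, K)
    threshold = math.sqrt(r2) * float(norm.ppf(1.0 - q))
    return 100.0 * float(1.0 - norm.cdf((threshold - cm.mean_case) / math.sqrt(cm.var_case)))


def sens_spec(r2: float, K: float, a: float) -> tuple[float, float]:
    """Sensitivity and specificity when flagging absolute risk above ``a``.

    The score value whose risk equals ``a`` is
    ``s* = tau - sqrt(1 - r2) * Phi^-1(1-a)``; sensitivity is the case
    probability above ``s*`` and specificity the control probability at or
    below it, from the conditional normal approximations.
    """
    if not (0.0 < a < 1.0):
        raise ValueError(f"risk threshold a must be in (0, 1), got {a}")
    if r2 >= 1.0:
        raise ValueError("r2 must be below 1")
    tau = float(norm.ppf(1.0 - K))
    cutoff = tau - math.sqrt(1.0 - r2) * float(norm.ppf(1.0 - a))
    if r2 == 0.0:
        # uninformative score: everyone shares risk K
        flagged = 1.0 if K >= a else 0.0
        return flagged, 1.0 - flagged
    cm = conditional_moments(r2, K)
    sens = float(1.0 - norm.cdf((cutoff - cm.mean_case) / math.sqrt(cm.var_case)))
    spec = float(norm.cdf((cutoff - cm.mean_control) / math.sqrt(cm.var_control)))
    return sens, spec
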