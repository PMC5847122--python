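"""Study-design inversions: optimal selection threshold, required sample size,
and the family-history environmental score.

These wrap the analytic accuracy chain (score moments -> combination ->
metric) into the two questions a consortium planner actually asks: which
P-value window maximizes a chosen accuracy metric at my sample size, and how
large must the training sample grow for a metric to reach a target?
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np
from scipy.optimize import minimize_scalar

from . import discrimination, reclassification
from .combined_score import combine
from .model import EnvModel, PolygenicDesign, TraitModel
from .polygenic_moments import score_moments

__all__ = [
    "OBJECTIVES",
    "evaluate_objective",
    "optimize_threshold",
    "required_sample_size",
    "family_history_params",
    "accuracy_curve",
]

OBJECTIVES = ("auc", "r2", "nri_case", "nri_control", "cnri", "idi")


def evaluate_objective(
    design: PolygenicDesign,
    trait: TraitModel,
    env: EnvModel,
    scheme: str,
    objective: str = "auc",
    a: float | None = None,
) -> float:
    """One accuracy metric of the (combined) score under the given design.

    ``cnri`` is the case component of the continuous NRI; the categorical
    NRI objectives need the absolute-risk threshold ``a``.  Metrics other
    than ``r2`` require a binary trait.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        moments = score_moments(design, trait, env)
        comb = combine(moments, env, scheme)
    if objective == "r2":
        return comb.r2_comb
    if not trait.is_binary:
        raise ValueError(f"objective {objective!r} requires a binary trait")
    if objective == "auc":
        return discrimination.auc(comb.r2_comb, trait.K)
    if objective == "idi":
        return reclassification.idi(comb, env, trait.K)
    joint = reclassification.TrivariateJoint.from_scores(comb, env)
    if objective == "cnri":
        return reclassification.continuous_nri(joint, trait.K)[0]
    if a is None:
        raise ValueError("categorical NRI objectives need a risk threshold a")
    case, control = reclassification.categorical_nri(joint, a, trait.K)
    return case if objective == "nri_case" else control


def optimize_threshold(
    design: PolygenicDesign,
    trait: TraitModel,
    env: EnvModel,
    scheme: str = "ols",
    objective: str = "auc",
    a: float | None = None,
    grid_points: int = 200,
) -> tuple[float, float]:
    """Upper selection threshold ``p1`` maximizing the objective (with p0 = 0).

    Scans a log-spaced grid over p1 in [1e-10, 1] and refines around the best
    grid point by bounded golden-section search in log10 p1 (relative
    tolerance 1e-3); exact ties break toward the smaller p1.  Returns
    ``(p1_opt, objective value)``.  A flat objective (degenerate score at
    every threshold) returns the grid boundary with a warning.
    """
    log_grid = np.linspace(-10.0, 0.0, grid_points)

    def value_at(log_p1: float) -> float:
        d = replace(design, p0=0.0, p1=float(10.0**log_p1))
        return evaluate_objective(d, trait, env, scheme, objective, a)

    values = np.array([value_at(g) for g in log_grid])
    best = int(np.argmax(values))  # argmax takes the first (smallest p1) on ties
    if np.allclose(values, values[0], rtol=0.0, atol=0.0):
        warnings.warn(
            "objective is flat over the threshold grid; returning the boundary",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(10.0 ** log_grid[0]), float(values[0])

    lo = log_grid[max(best - 1, 0)]
    hi = log_grid[min(best + 1, grid_points - 1)]
    res = minimize_scalar(
        lambda g: -value_at(g),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    if -res.fun >= values[best]:
        return float(10.0**res.x), float(-res.fun)
    return float(10.0 ** log_grid[best]), float(values[best])


def required_sample_size(
    design: PolygenicDesign,
    trait: TraitModel,
    env: EnvModel,
    scheme: str,
    objective: str,
    target: float,
    optimize_p1: bool = True,
    a: float | None = None,
    grid_points: int = 80,
) -> float:
    """Smallest training sample size n (3 significant figures) reaching the target.

    The asymptotic (n = inf) value of the objective is checked first; an
    unreachable target raises with the limit in the message.  The search
    bisects on log10 n; with ``optimize_p1`` the objective is maximized over
    the selection threshold at every n (the planner would tune it), otherwise
    the design's own window is kept.
    """

    def best_at(n: float) -> float:
        d = replace(design, n=n)
        if optimize_p1 and not math.isinf(n):
            return optimize_threshold(d, trait, env, scheme, objective, a, grid_points)[1]
        if math.isinf(n):
            # any window containing P = 0 keeps every informative marker
            d = replace(d, p0=0.0, p1=1.0)
        return evaluate_objective(d, trait, env, scheme, objective, a)

    limit = best_at(math.inf)
    if target > limit:
        raise ValueError(
            f"target {objective} = {target} exceeds asymptotic limit {limit:.6g} "
            "attainable with an infinite training sample"
        )

    lo, hi = 1e2, 1e9
    if best_at(lo) >= target:
        return lo
    while hi / lo > 1.0 + 1e-3:
        mid = math.sqrt(lo * hi)
        if best_at(mid) >= target:
            hi = mid
        else:
            lo = mid
    # round up to 3 significant figures so the returned n still meets the target
    exponent = math.floor(math.log10(hi)) - 2
    return math.ceil(hi / 10.0**exponent) * 10.0**exponent


def family_history_params(h2: float, h2_chip: float) -> EnvModel:
    """Environmental-score parameters when the predictor is mid-parent phenotype.

    Under a purely additive model with no shared environment, the mid-parent
    phenotype rescaled to unit effect on the offspring explains
    ``r2_xy = h2^2 / 2`` of the offspring variance.  The offspring's own
    genotypes explain half the chip heritability of this predictor
    (``r2_gx = h2_chip / 2``): only transmitted chip effects connect the two,
    so the per-marker effects on the predictor are exactly proportional to
    the chip effects on the outcome, i.e. ``rho = 1``.  The implied chip
    covariance between the polygenic score and the predictor is then
    ``h2 * h2_chip / 2``, which a parent-offspring trio simulation confirms.
    """
    if not (0.0 < h2_chip <= h2 <= 1.0):
        raise ValueError(
            f"need 0 < h2_chip <= h2 <= 1, got h2_chip={h2_chip}, h2={h2}"
        )
    return EnvModel(r2_xy=h2**2 / 2.0, r2_gx=h2_chip / 2.0, rho=1.0)


def accuracy_curve(
    design: PolygenicDesign,
    trait: TraitModel,
    env: EnvModel,
    scheme: str,
    objective: str = "auc",
    n_grid: np.ndarray | None = None,
    optimize_p1: bool = False,
    a: float | None = None,
):
    """Tabulate the objective against training sample size (40 log-spaced points
    from n/100 to 100n by default, plus the infinite-sample limit).  Returns a
    pandas DataFrame with columns ``n``, ``p1`` and the objective name."""
    import pandas as pd

    if n_grid is None:
        n_grid = np.logspace(
            math.log10(design.n) - 2.0, math.log10(design.n) + 2.0, 40
        )
    rows = []
    for n in [*n_grid, math.inf]:
        d = replace(design, n=float(n))
        if optimize_p1:
            p1, value = optimize_threshold(d, trait, env, scheme, objective, a)
        else:
            p1, value = d.p1, evaluate_objective(d, trait, env, scheme, objective, a)
        rows.append({"n": float(n), "p1": p1, objective: value})
    return pd.DataFrame(rows)
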