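"""Combination of polygenic and environmental scores.

``S_comb = w1 * S-hat + w2 * X``.  The unweighted sum takes ``w1 = w2 = 1``;
the least-squares weights solve the 2x2 normal equations of the regression
of the outcome on the two scores, which maximizes the combined R^2 and makes
the liability calibration coefficient ``gamma`` exactly 1.  Single-score
results run through the same path with weights (1, 0) or (0, 1).
"""

from __future__ import annotations

import warnings

from .model import CombinedScore, EnvModel, ScoreMoments

__all__ = ["combine", "SCHEMES"]

SCHEMES = ("unweighted", "ols", "polygenic", "environment")

_DET_TOL = 1e-12


def combine(moments: ScoreMoments, env: EnvModel, scheme: str = "ols") -> CombinedScore:
    """Combined score and its accuracy moments under the given weighting scheme.

    Parameters
    ----------
    moments : ScoreMoments
        Liability-scale moments of the estimated polygenic score.
    env : EnvModel
        Environmental score; ``env.r2_xy`` doubles as cov(X, Y) and var(X).
    scheme : {"unweighted", "ols", "polygenic", "environment"}
        ``unweighted`` adds the scores; ``ols`` solves the normal equations
        (closed form); ``polygenic``/``environment`` are the single-score
        reductions (1, 0) and (0, 1).

    A singular Gram matrix (for instance a degenerate polygenic score under
    ``ols``) falls back to the environment-only score with a warning.
    """
    var_s, cov_sy, cov_sx = moments.var_s, moments.cov_sy, moments.cov_sx
    r2_xy = env.r2_xy
    degenerate = False

    if scheme == "unweighted":
        w1, w2 = 1.0, 1.0
    elif scheme == "polygenic":
        w1, w2 = 1.0, 0.0
    elif scheme == "environment":
        w1, w2 = 0.0, 1.0
    elif scheme == "ols":
        det = var_s * r2_xy - cov_sx**2
        if abs(det) <= _DET_TOL:
            if r2_xy > 0.0 and var_s > _DET_TOL:
                # X carries no variance: polygenic-only is the solution
                w1, w2 = cov_sy / var_s, 0.0
            elif var_s <= _DET_TOL and r2_xy > 0.0:
                warnings.warn(
                    "degenerate polygenic score; falling back to environment-only weights",
                    RuntimeWarning,
                    stacklevel=2,
                )
                w1, w2 = 0.0, 1.0
                degenerate = True
            else:
                raise ValueError("both scores are degenerate; no combined score exists")
        else:
            # Cramer's rule on [[var_s, cov_sx], [cov_sx, r2_xy]] w = (cov_sy, r2_xy)
            w1 = (cov_sy * r2_xy - cov_sx * r2_xy) / det
            w2 = (var_s * r2_xy - cov_sx * cov_sy) / det
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")

    cov_comb_y = w1 * cov_sy + w2 * r2_xy
    var_comb = w1**2 * var_s + w2**2 * r2_xy + 2.0 * w1 * w2 * cov_sx
    if var_comb <= 0.0:
        return CombinedScore(w1, w2, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    r2_comb = cov_comb_y**2 / var_comb
    gamma = cov_comb_y / var_comb
    cov_gcomb_x = gamma * (w1 * cov_sx + w2 * r2_xy)
    return CombinedScore(
        w1=w1,
        w2=w2,
        cov_comb_y=cov_comb_y,
        var_comb=var_comb,
        r2_comb=r2_comb,
        gamma=gamma,
        cov_gcomb_x=cov_gcomb_x,
        degenerate=degenerate,
    )
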