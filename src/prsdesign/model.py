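"""Domain types and published scenario presets.

The framework describes a standardized outcome ``Y`` (observed directly for
continuous traits, or a latent liability thresholded at ``tau`` for binary
disease), a polygenic score ``S-hat`` estimated from a finite training GWAS
with P-value selection of markers, and an environmental risk score ``X`` with
unit effect on ``Y`` (so ``var(X) = r2_xy``).  ``X`` may itself be heritable,
with chip heritability ``r2_gx`` and per-marker effect correlation ``rho``
with the outcome's effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.stats import norm

__all__ = [
    "PolygenicDesign",
    "TraitModel",
    "EnvModel",
    "ScoreMoments",
    "SelectionQuantiles",
    "CombinedScore",
    "AccuracyReport",
    "Scenario",
    "make_scenario",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class PolygenicDesign:
    """Training design and genetic architecture of the outcome.

    Parameters
    ----------
    n : float
        Training sample size.  ``math.inf`` selects the exact
        infinite-training-sample limit (no estimation noise).
    m : int
        Number of independent standardized markers in the panel.
    h2_chip : float
        Chip heritability of the outcome (variance in the standardized
        outcome/liability explained by the marker panel).
    pi0 : float
        Proportion of markers with zero effect on the outcome.
    p0, p1 : float
        Lower and upper two-sided P-values delimiting the selection
        window: a marker enters the score iff its training P-value lies
        in ``(p0, p1]``.  ``p0 = 0`` with ``p1 = x`` is the usual
        "select by P < x" rule.
    """

    n: float
    m: int
    h2_chip: float
    pi0: float
    p0: float = 0.0
    p1: float = 1.0

    def __post_init__(self) -> None:
        if not (self.n > 0):
            raise ValueError(f"training sample size n must be positive, got {self.n}")
        if not (isinstance(self.m, int) and self.m > 0):
            raise ValueError(f"marker count m must be a positive integer, got {self.m}")
        if not (0.0 < self.h2_chip <= 1.0):
            raise ValueError(f"h2_chip must be in (0, 1], got {self.h2_chip}")
        if not (0.0 <= self.pi0 < 1.0):
            raise ValueError(f"pi0 must be in [0, 1), got {self.pi0}")
        if not (0.0 <= self.p0 < 1.0):
            raise ValueError(f"p0 must be in [0, 1), got {self.p0}")
        if not (0.0 < self.p1 <= 1.0):
            raise ValueError(f"p1 must be in (0, 1], got {self.p1}")
        if not (self.p0 < self.p1):
            raise ValueError(f"selection window requires p0 < p1, got ({self.p0}, {self.p1})")


@dataclass(frozen=True)
class TraitModel:
    """Outcome scale: continuous, or binary under the liability-threshold model.

    For a binary trait, ``K`` is the population prevalence and ``P`` the case
    fraction in the training sample (``P = K`` for a prospective design).
    The liability threshold ``tau`` and the observed-to-liability scale
    factor ``c`` are always derived from ``K`` and ``P``, never stored.
    """

    kind: str
    K: float | None = None
    P: float | None = None

    @classmethod
    def continuous(cls) -> "TraitModel":
        return cls(kind="continuous")

    @classmethod
    def binary(cls, K: float, P: float | None = None) -> "TraitModel":
        """Binary trait with prevalence ``K``; ``P`` defaults to ``K``."""
        return cls(kind="binary", K=K, P=K if P is None else P)

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.K is not None or self.P is not None:
                raise ValueError("continuous trait takes no prevalence or case fraction")
        elif self.kind == "binary":
            if self.K is None or not (0.0 < self.K < 1.0):
                raise ValueError(f"prevalence K must be in (0, 1), got {self.K}")
            if self.P is None or not (0.0 < self.P < 1.0):
                raise ValueError(f"training case fraction P must be in (0, 1), got {self.P}")
        else:
            raise ValueError(f"trait kind must be 'continuous' or 'binary', got {self.kind!r}")

    @property
    def is_binary(self) -> bool:
        return self.kind == "binary"

    @property
    def tau(self) -> float:
        """Liability threshold Phi^-1(1 - K)."""
        if not self.is_binary:
            raise AttributeError("continuous trait has no liability threshold")
        return float(norm.ppf(1.0 - self.K))

    @property
    def c(self) -> float:
        """Scale factor mapping liability-scale effects to the observed 0/1 scale.

        ``c = phi(tau) * P * (1 - P) / (K * (1 - K))``; reduces to ``phi(tau)``
        in a prospective design (``P = K``).
        """
        if not self.is_binary:
            raise AttributeError("continuous trait has no observed-scale factor")
        return float(norm.pdf(self.tau) * self.P * (1.0 - self.P) / (self.K * (1.0 - self.K)))


@dataclass(frozen=True)
class EnvModel:
    """Environmental (non-polygenic) risk score.

    ``r2_xy`` is the variance in the standardized outcome explained by the
    score (equal to ``var(X)`` because X has unit effect on Y), ``r2_gx``
    its chip heritability, and ``rho`` the chip correlation between the
    per-marker effects on X and on Y.
    """

    r2_xy: float
    r2_gx: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_xy < 1.0):
            raise ValueError(f"r2_xy must be in [0, 1), got {self.r2_xy}")
        if not (0.0 <= self.r2_gx <= 1.0):
            raise ValueError(f"r2_gx must be in [0, 1], got {self.r2_gx}")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")

    def genetic_covariance(self, h2_chip: float) -> float:
        """Chip covariance between the true polygenic values of X and Y."""
        return self.rho * math.sqrt(h2_chip * self.r2_xy * self.r2_gx)

    def validate_against(self, h2_chip: float) -> None:
        """Check the implied correlation between S and X is at most 1 in magnitude."""
        if self.r2_xy == 0.0:
            return
        denom = math.sqrt(h2_chip * self.r2_xy)
        if denom > 0 and abs(self.genetic_covariance(h2_chip)) > denom * (1 + 1e-12):
            raise ValueError(
                "implied correlation between polygenic and environmental scores exceeds 1"
            )


@dataclass(frozen=True)
class ScoreMoments:
    """Moments of the estimated polygenic score on the liability/trait scale."""

    cov_sy: float
    var_s: float
    cov_sx: float

    @property
    def r2(self) -> float:
        """Coefficient of determination of the score with the outcome."""
        if self.var_s <= 0.0:
            return 0.0
        return self.cov_sy**2 / self.var_s

    @property
    def degenerate(self) -> bool:
        return self.var_s <= 0.0


@dataclass(frozen=True)
class SelectionQuantiles:
    """Selection quantiles ``q_j = Phi^-1(1 - p_j / 2)`` and their shrunken
    counterparts ``r_j = q_j * theta`` applying to non-null markers.

    ``theta`` in (0, 1] is the shrinkage of a non-null marker's expected test
    statistic toward its estimation noise; ``theta -> 0`` as ``n -> inf``.
    """

    q0: float
    q1: float
    r0: float
    r1: float
    theta: float


@dataclass(frozen=True)
class CombinedScore:
    """Weighted combination ``S_comb = w1 * S-hat + w2 * X`` and its accuracy moments.

    ``gamma`` recalibrates the combined score to the liability scale so that
    ``var(gamma * S_comb) = r2_comb``; the least-squares weights give
    ``gamma = 1`` identically.
    """

    w1: float
    w2: float
    cov_comb_y: float
    var_comb: float
    r2_comb: float
    gamma: float
    cov_gcomb_x: float
    degenerate: bool = False


@dataclass(frozen=True)
class AccuracyReport:
    """Bundle of discrimination and reclassification metrics for one scenario."""

    auc: float
    nri: dict            # risk threshold a -> (case NRI, control NRI)
    cnri_case: float
    cnri_control: float
    idi: float
    capture: dict        # population fraction q -> % of cases captured
    sens_spec: dict      # risk threshold a -> (sensitivity, specificity)


@dataclass(frozen=True)
class Scenario:
    """A named parameter set: training design, trait scale and environmental score."""

    name: str
    design: PolygenicDesign
    trait: TraitModel
    env: EnvModel
    controls_per_case: float | None = None

    @property
    def cases(self) -> float | None:
        """Training case count implied by n and the case fraction P."""
        if self.trait.is_binary:
            return self.design.n * self.trait.P
        return None

    def with_(self, **kwargs) -> "Scenario":
        """Return a copy with replaced design/trait/env fields, e.g. ``with_(p1=0.05)``."""
        design_fields = {"n", "m", "h2_chip", "pi0", "p0", "p1"}
        env_fields = {"r2_xy", "r2_gx", "rho"}
        d = {k: v for k, v in kwargs.items() if k in design_fields}
        e = {k: v for k, v in kwargs.items() if k in env_fields}
        unknown = set(kwargs) - design_fields - env_fields - {"trait"}
        if unknown:
            raise TypeError(f"unknown scenario fields: {sorted(unknown)}")
        return replace(
            self,
            design=replace(self.design, **d) if d else self.design,
            trait=kwargs.get("trait", self.trait),
            env=replace(self.env, **e) if e else self.env,
        )


SCENARIO_NAMES = ("cvd", "breast_cancer", "height")

# Published training-cohort sizes behind the presets
_CVD_CASES = 63_746
_CVD_CONTROLS_PER_CASE = 2.05
_BC_CASES = 33_673
_BC_CONTROLS_PER_CASE = 0.99


def make_scenario(
    name: str,
    *,
    rho: float | None = None,
    r2_gx: float | None = None,
    K: float | None = None,
    pi0: float | None = None,
    p1: float = 5e-8,
) -> Scenario:
    """Build one of the three published scenario presets.

    ``cvd``
        Coronary disease: 63,746 training cases with 2.05 controls per case,
        m = 100,000 independent markers, chip heritability 0.3, pi0 = 0.8,
        prevalence 0.15; environmental score (Framingham/QRISK-type) with
        r2_xy = 0.052, r2_gx = 0.3, rho in {0.1, 0.4} (default 0.1).
    ``breast_cancer``
        33,673 cases with 0.99 controls per case, chip heritability 0.3,
        pi0 = 0.95, prevalence 0.05; environmental (Gail-type) score with
        r2_xy = 0.0375, r2_gx in {0.1, 0.8} and rho in {0.1, 0.4}
        (defaults 0.1, 0.1).
    ``height``
        Continuous trait, m = 2.5 million markers, chip heritability 0.48,
        pi0 = 0.995; the environmental score is mid-parent height (family
        history) parameterized from total heritability 0.8.

    ``K`` and ``pi0`` override the preset prevalence / null proportion so the
    published sensitivity variants (K = 0.06 or 0.1, pi0 = 0.95 or 0.8) are a
    configuration change only.
    """
    if name == "cvd":
        cpc = _CVD_CONTROLS_PER_CASE
        n = _CVD_CASES * (1.0 + cpc)
        design = PolygenicDesign(
            n=n, m=100_000, h2_chip=0.3, pi0=0.8 if pi0 is None else pi0, p1=p1
        )
        trait = TraitModel.binary(K=0.15 if K is None else K, P=1.0 / (1.0 + cpc))
        env = EnvModel(
            r2_xy=0.052,
            r2_gx=0.3 if r2_gx is None else r2_gx,
            rho=0.1 if rho is None else rho,
        )
        scn = Scenario("cvd", design, trait, env, controls_per_case=cpc)
    elif name == "breast_cancer":
        cpc = _BC_CONTROLS_PER_CASE
        n = _BC_CASES * (1.0 + cpc)
        design = PolygenicDesign(
            n=n, m=100_000, h2_chip=0.3, pi0=0.95 if pi0 is None else pi0, p1=p1
        )
        trait = TraitModel.binary(K=0.05 if K is None else K, P=1.0 / (1.0 + cpc))
        env = EnvModel(
            r2_xy=0.0375,
            r2_gx=0.1 if r2_gx is None else r2_gx,
            rho=0.1 if rho is None else rho,
        )
        scn = Scenario("breast_cancer", design, trait, env, controls_per_case=cpc)
    elif name == "height":
        from .design import family_history_params

        if K is not None:
            raise ValueError("height is a continuous trait; K does not apply")
        design = PolygenicDesign(
            n=250_000, m=2_500_000, h2_chip=0.48, pi0=0.995 if pi0 is None else pi0, p1=p1
        )
        env = family_history_params(h2=0.8, h2_chip=0.48)
        if rho is not None or r2_gx is not None:
            env = replace(
                env,
                rho=env.rho if rho is None else rho,
                r2_gx=env.r2_gx if r2_gx is None else r2_gx,
            )
        scn = Scenario("height", design, TraitModel.continuous(), env)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    scn.env.validate_against(scn.design.h2_chip)
    return scn
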