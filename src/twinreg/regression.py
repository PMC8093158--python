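"""Regression of the outcome on two predictors at a covariance level.

This is the core method of the package.  Given a 3x3 covariance matrix
``Sigma`` of (outcome, predictor 1, predictor 2) at some level — phenotypic,
broad-sense genetic G = A + D, or total environmental T = C + E — partition

    Sigma = [[s2_out, Sigma_1^t],
             [Sigma_1, Sigma_2 ]]

with ``Sigma_2`` the 2x2 predictor covariance block and ``Sigma_1`` the
predictor-outcome covariances, and solve the population regression

    b = Sigma_2^{-1} Sigma_1.

The outcome variance at that level then splits exactly into

    s2_out = b1^2 s1^2  +  b2^2 s2^2  +  2 b1 b2 s12  +  s2_eps,

a part attributable to each predictor, a cross term arising from their
covariance that cannot be attributed unambiguously to either, and the
residual.  The three explained components are reported separately.  Shares
can be standardized by the level's own outcome variance or by the total
phenotypic outcome variance; the latter makes genetic and environmental
contributions directly comparable on the phenotypic scale.

Regression on an individual component matrix (A, C, or D alone) is refused
when the predictor block is singular or near-singular — a structurally
rank-deficient component (single-factor C, predictors-only D) or a
near-rank-1 additive matrix cannot support the inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import RankDeficiencyError
from .model import ComponentEstimates, _check_symmetric

__all__ = [
    "CovRegressionResult",
    "covariance_regression",
    "variance_decomposition",
    "phenotypic_standardization",
    "regress_components",
    "check_claimed_total",
]

#: Condition-number threshold on the predictor block above which the
#: regression is refused rather than regularized.
CONDITION_THRESHOLD = 1e8

_ADDITIVITY_TOL = 1e-10


@dataclass
class CovRegressionResult:
    """Coefficients and variance decomposition of one covariance-level regression.

    Raw components are in squared score units; ``explained_total`` and the
    ``*_shares`` helpers give the standardized versions.
    """

    level: str
    outcome: str
    predictors: tuple[str, str]
    b: np.ndarray  # aligned with `predictors`
    v_pred: np.ndarray  # b_j^2 * s_j^2, aligned with `predictors`
    v_cross: float
    residual: float
    outcome_variance: float  # outcome variance at this level
    phenotypic_variance: float | None = None
    intervals: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def explained(self) -> float:
        """Raw explained variance at this level: v1 + v2 + cross."""
        return float(self.v_pred.sum() + self.v_cross)

    @property
    def explained_total(self) -> float:
        """Fraction of the level's outcome variance explained (additive total)."""
        return self.explained / self.outcome_variance

    def level_shares(self) -> dict[str, float]:
        """Components standardized by the outcome variance at this level."""
        d = {p: float(v / self.outcome_variance) for p, v in zip(self.predictors, self.v_pred)}
        d["cross"] = float(self.v_cross / self.outcome_variance)
        d["residual"] = float(self.residual / self.outcome_variance)
        return d

    def phenotypic_shares(self) -> dict[str, float]:
        """Components standardized by the total phenotypic outcome variance."""
        if self.phenotypic_variance is None:
            raise ValueError("phenotypic outcome variance not set on this result")
        return phenotypic_standardization(self, self.phenotypic_variance)


def covariance_regression(
    sigma,
    outcome: int = 0,
    predictors: tuple[int, int] = (1, 2),
    condition_threshold: float = CONDITION_THRESHOLD,
) -> np.ndarray:
    """Solve ``b = Sigma_2^{-1} Sigma_1`` on a symmetric 3x3 covariance matrix.

    Raises :class:`RankDeficiencyError`, citing the predictor-block
    eigenvalues, when that block is singular or its condition number exceeds
    ``condition_threshold``.
    """
    s = _check_symmetric(sigma)
    p = list(predictors)
    s2 = s[np.ix_(p, p)]
    s1 = s[p, outcome]
    w = np.linalg.eigvalsh(s2)
    if w[0] <= 0 or w[1] / max(w[0], 1e-300) > condition_threshold:
        raise RankDeficiencyError(
            "predictor covariance block is singular or ill-conditioned "
            f"(eigenvalues {w[0]:.4g}, {w[1]:.4g}); regression at this level "
            "is refused — use a full-rank level such as G = A + D or T = C + E",
            eigenvalues=tuple(float(v) for v in w),
        )
    return np.linalg.solve(s2, s1)


def variance_decomposition(
    sigma,
    b: np.ndarray,
    outcome: int = 0,
    predictors: tuple[int, int] = (1, 2),
    level: str = "",
    labels=("outcome", "pred1", "pred2"),
    phenotypic_variance: float | None = None,
) -> CovRegressionResult:
    """Split the outcome variance at this level along the regression.

    ``b`` must come from :func:`covariance_regression` on the same matrix;
    the additivity identity (components + residual = outcome variance) then
    holds exactly and is enforced to 1e-10 relative tolerance.
    """
    s = _check_symmetric(sigma)
    b = np.asarray(b, dtype=float)
    p = list(predictors)
    s2 = s[np.ix_(p, p)]
    s1 = s[p, outcome]
    out_var = float(s[outcome, outcome])
    v_pred = b**2 * np.diag(s2)
    v_cross = float(2.0 * b[0] * b[1] * s2[0, 1])
    residual = out_var - float(b @ s1)
    total = float(v_pred.sum() + v_cross + residual)
    if abs(total - out_var) > _ADDITIVITY_TOL * max(abs(out_var), 1.0):
        raise ValueError(
            "internal inconsistency: decomposition does not add to the outcome "
            f"variance ({total:.12g} vs {out_var:.12g}); was b computed on this matrix?"
        )
    scale = max(abs(out_var), 1.0)
    flags = []
    if residual < -1e-8 * scale:
        raise ValueError(f"negative residual variance {residual:.4g}")
    return CovRegressionResult(
        level=level,
        outcome=labels[outcome],
        predictors=(labels[p[0]], labels[p[1]]),
        b=b,
        v_pred=v_pred,
        v_cross=v_cross,
        residual=residual,
        outcome_variance=out_var,
        phenotypic_variance=phenotypic_variance,
        flags=flags,
    )


def phenotypic_standardization(
    result: CovRegressionResult, phenotypic_variance: float
) -> dict[str, float]:
    """Standardize a level's raw components by the phenotypic outcome variance.

    The level share and the phenotypic share of each component differ by the
    factor (level outcome variance / phenotypic outcome variance), so
    G-level and T-level phenotypic shares add up across levels to the
    phenotypic regression's total explained variance.
    """
    if phenotypic_variance <= 0:
        raise ValueError("phenotypic outcome variance must be positive")
    if result.outcome_variance > phenotypic_variance * (1 + 1e-8):
        raise ValueError(
            "level outcome variance exceeds the phenotypic outcome variance"
        )
    d = {p: float(v / phenotypic_variance) for p, v in zip(result.predictors, result.v_pred)}
    d["cross"] = float(result.v_cross / phenotypic_variance)
    d["total"] = float(result.explained / phenotypic_variance)
    return d


def regress_components(
    components: ComponentEstimates,
    levels: tuple[str, ...] = ("phenotypic", "G", "T"),
    condition_threshold: float = CONDITION_THRESHOLD,
) -> dict[str, CovRegressionResult]:
    """Run the covariance-level regression at each requested level.

    Levels ``phenotypic``, ``G`` (A + D), and ``T`` (C + E; E alone when the
    group has no C) are the supported analysis levels; individual component
    labels ``A``/``C``/``D``/``E`` are accepted for diagnostics but will be
    refused with a rank-deficiency error whenever the predictor block is
    singular — which for the structured C and D patterns it is by
    construction.
    """
    labels = components.order.labels
    pheno_var = float(components.sigma_ph[0, 0])
    out = {}
    for level in levels:
        if level == "phenotypic":
            s = components.sigma_ph
        elif level == "G":
            s = components.sigma_g
        elif level == "T":
            s = components.sigma_t
        elif level in ("A", "C", "D", "E"):
            s = components.component(level)
        else:
            raise ValueError(f"unknown regression level {level!r}")
        b = covariance_regression(s, condition_threshold=condition_threshold)
        out[level] = variance_decomposition(
            s, b, level=level, labels=labels, phenotypic_variance=pheno_var
        )
    return out


def check_claimed_total(
    result: CovRegressionResult, claimed_total: float, tol: float = 0.02
) -> str | None:
    """Compare the additive explained total against an externally claimed one.

    Published tables occasionally print an explained-variance total that is
    inconsistent with their own printed components.  The additive total is
    authoritative here; when the claim differs by more than ``tol`` a flag
    string is returned (and recorded on the result), else ``None``.
    """
    additive = result.explained_total
    if abs(additive - claimed_total) > tol:
        flag = (
            f"claimed {result.level}-level explained total {claimed_total:.3f} "
            f"is inconsistent with the sum of its components {additive:.3f}; "
            "reporting the additive total"
        )
        result.flags.append(flag)
        return flag
    return None
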