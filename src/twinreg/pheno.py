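"""Within-person phenotypic regression with twin-pair dependence.

The outcome is regressed on sex, age, and the two predictors with one set of
coefficients shared across zygosity groups and across twin 1 / twin 2.  The
dependence between the two outcome residuals of a pair is accommodated by
leaving the MZ and the DZ residual cross-twin covariance unconstrained
(estimated freely per zygosity), so the model is fitted by maximum
likelihood on pairs rather than by ordinary least squares on individuals.
With both residual twin covariances at zero the estimates coincide with
pooled individual-level least squares.

A twin contributes an outcome equation only when their outcome and both
predictors are observed; the co-twin's equation is retained regardless
(partial-pair likelihood, conditional on observed predictors).

Also houses :func:`score_scale`, the checklist sum-score rule with a
missing-item allowance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import DataError
from .model import TwinDataset

__all__ = [
    "PhenoRegResult",
    "fit_phenotypic",
    "explained_variance",
    "conditional_phenotypic_covariance",
    "score_scale",
]

_LOG2PI = math.log(2.0 * math.pi)
_COEF_NAMES = ("intercept", "sex", "age", "pred1", "pred2")


@dataclass
class PhenoRegResult:
    """Phenotypic regression estimates and residual twin structure."""

    order: object
    coef: pd.Series  # index: intercept, sex, age, <predictor labels>
    se: pd.Series | None
    s2_eps: float
    cov_mz: float
    cov_dz: float
    loglik: float
    converged: bool
    n_pairs_used: int
    n_equations: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def rho_mz(self) -> float:
        return self.cov_mz / self.s2_eps

    @property
    def rho_dz(self) -> float:
        return self.cov_dz / self.s2_eps


def _equations(data: TwinDataset):
    """Design matrices per twin: X = [1, sex, age, pred1, pred2], y = outcome."""
    order = data.order
    y = data.phenotype_matrix()
    df = data.df
    age = df["age"].to_numpy(dtype=float)
    out = []
    for t, sexcol in ((0, "sex1"), (1, "sex2")):
        sex = df[sexcol].to_numpy(dtype=float)
        yt = y[:, t * 3]
        p1 = y[:, t * 3 + 1]
        p2 = y[:, t * 3 + 2]
        usable = ~np.isnan(yt) & ~np.isnan(p1) & ~np.isnan(p2)
        x = np.column_stack([np.ones(len(df)), sex, age, p1, p2])
        out.append((yt, x, usable))
    return out


def fit_phenotypic(
    data: TwinDataset, maxiter: int = 1000, free_twin_cov: bool = True
) -> PhenoRegResult:
    """ML fit of the shared-coefficient regression with free MZ/DZ residual covariances.

    With ``free_twin_cov=False`` both residual cross-twin covariances are
    constrained to zero, in which case the coefficient estimates coincide
    with pooled individual-level least squares.
    """
    (y1, x1, u1), (y2, x2, u2) = _equations(data)
    n_any = int((u1 | u2).sum())
    if n_any < 10:
        raise DataError(
            f"need at least 10 pairs with outcome and both predictors observed, got {n_any}"
        )
    x_all = np.vstack([x1[u1], x2[u2]])
    y_all = np.concatenate([y1[u1], y2[u2]])
    sv = np.linalg.svd(x_all, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise DataError("predictors are collinear within tolerance; regression not identified")

    # pooled OLS start
    beta0, *_ = np.linalg.lstsq(x_all, y_all, rcond=None)
    resid0 = y_all - x_all @ beta0
    s2_0 = float(resid0 @ resid0 / max(len(y_all) - 5, 1))

    zyg = data.df["zygosity"].to_numpy()
    both = u1 & u2
    groups = {
        "MZ_pair": (zyg == "MZ") & both,
        "DZ_pair": (zyg == "DZ") & both,
    }
    single1 = u1 & ~u2
    single2 = u2 & ~u1

    def nll(theta):
        beta = theta[:5]
        s2 = math.exp(theta[5])
        if free_twin_cov:
            rho = {"MZ_pair": math.tanh(theta[6]), "DZ_pair": math.tanh(theta[7])}
        else:
            rho = {"MZ_pair": 0.0, "DZ_pair": 0.0}
        e1 = y1 - x1 @ beta
        e2 = y2 - x2 @ beta
        ll = 0.0
        for key, mask in groups.items():
            n = int(mask.sum())
            if n == 0:
                continue
            r = rho[key]
            det = s2 * s2 * (1 - r * r)
            a, b = e1[mask], e2[mask]
            quad = (a * a + b * b - 2 * r * a * b) / (s2 * (1 - r * r))
            ll += -0.5 * (n * (2 * _LOG2PI + math.log(det)) + float(quad.sum()))
        for e, mask in ((e1, single1), (e2, single2)):
            n = int(mask.sum())
            if n == 0:
                continue
            ll += -0.5 * (n * (_LOG2PI + math.log(s2)) + float((e[mask] ** 2).sum()) / s2)
        return -ll

    n_free = 8 if free_twin_cov else 6
    theta0 = np.concatenate([beta0, [math.log(max(s2_0, 1e-8)), 0.0, 0.0]])

    def nll_free(sub):
        full = np.zeros(8)
        full[:n_free] = sub
        return nll(full)

    res = optimize.minimize(nll_free, theta0[:n_free], method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-12})
    theta = np.zeros(8)
    theta[:n_free] = res.x
    s2 = math.exp(theta[5])
    rho_mz, rho_dz = math.tanh(theta[6]), math.tanh(theta[7])

    # Wald SEs for the coefficients from the observed information
    se = None
    try:
        from .estimation import _numerical_hessian

        hess = _numerical_hessian(nll_free, res.x, rel_step=1e-4)
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if np.all(d[:5] > 0):
            se = np.sqrt(d[:5])
    except np.linalg.LinAlgError:
        se = None

    labels = ["intercept", "sex", "age", data.order.labels[1], data.order.labels[2]]
    return PhenoRegResult(
        order=data.order,
        coef=pd.Series(theta[:5], index=labels),
        se=pd.Series(se, index=labels) if se is not None else None,
        s2_eps=s2,
        cov_mz=rho_mz * s2,
        cov_dz=rho_dz * s2,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_pairs_used=n_any,
        n_equations=int(u1.sum() + u2.sum()),
        diagnostics={"message": str(res.message), "n_iter": int(res.nit)},
    )


def conditional_phenotypic_covariance(data: TwinDataset) -> pd.DataFrame:
    """3x3 within-person phenotype covariance conditional on sex and age.

    Twins are pooled as individuals; each phenotype is residualized on
    [1, sex, age] over its observed rows and the residual covariance is
    assembled pairwise-complete.
    """
    y = data.phenotype_matrix()
    df = data.df
    age = df["age"].to_numpy(dtype=float)
    persons = np.vstack([y[:, :3], y[:, 3:]])
    sex = np.concatenate([df["sex1"].to_numpy(float), df["sex2"].to_numpy(float)])
    covars = np.column_stack([np.ones(persons.shape[0]), sex, np.tile(age, 2)])
    resid = np.full_like(persons, np.nan)
    for j in range(3):
        m = ~np.isnan(persons[:, j])
        if m.sum() < 4:
            raise DataError(f"too few observations for phenotype {data.order.labels[j]!r}")
        beta, *_ = np.linalg.lstsq(covars[m], persons[m, j], rcond=None)
        resid[m, j] = persons[m, j] - covars[m] @ beta
    rdf = pd.DataFrame(resid, columns=list(data.order.labels))
    return rdf.cov(min_periods=2)


def explained_variance(result: PhenoRegResult, predictor_cov) -> dict[str, float]:
    """Decompose the conditional outcome variance along the fitted regression.

    ``predictor_cov`` is the 2x2 covariance of the predictors (in the order
    of ``result.order.predictors``), conditional on sex and age.  Returns raw
    components and shares of the conditional outcome variance
    (b1^2 s1^2 + b2^2 s2^2 + 2 b1 b2 s12 + s2_eps); the shares sum to 1.
    """
    predictor_cov = np.asarray(predictor_cov, dtype=float)
    p1, p2 = result.order.predictors
    b1, b2 = float(result.coef[p1]), float(result.coef[p2])
    v1 = b1 * b1 * predictor_cov[0, 0]
    v2 = b2 * b2 * predictor_cov[1, 1]
    vx = 2 * b1 * b2 * predictor_cov[0, 1]
    total = v1 + v2 + vx + result.s2_eps
    if total <= 0:
        raise DataError("non-positive conditional outcome variance")
    return {
        p1: v1,
        p2: v2,
        "cross": vx,
        "residual": result.s2_eps,
        "outcome_variance": total,
        f"share_{p1}": v1 / total,
        f"share_{p2}": v2 / total,
        "share_cross": vx / total,
        "share_residual": result.s2_eps / total,
    }


def score_scale(items, max_missing: int, response_range=(0, 2)):
    """Checklist sum score with a missing-item allowance.

    Returns the simple sum of observed item responses if at most
    ``max_missing`` items are missing (``None``/``nan``), else ``nan``.
    No proration is applied.  An item outside ``response_range`` is an error.
    """
    lo, hi = response_range
    vals = []
    n_missing = 0
    for v in items:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_missing += 1
            continue
        v = float(v)
        if not (lo <= v <= hi):
            raise ValueError(f"item value {v} outside response range [{lo}, {hi}]")
        vals.append(v)
    if n_missing > max_missing:
        return float("nan")
    return float(sum(vals))
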