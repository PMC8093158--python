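"""Maximum-likelihood estimation of the structured twin model.

Two fitting modes are provided:

* :func:`fit_fiml` — full-information maximum likelihood on raw pair
  records.  Each pair contributes the log multivariate-normal density of its
  *observed* phenotype subvector (no imputation), with means from the
  fixed-effect mean model and covariance from the expected 6x6 MZ/DZ twin
  covariance restricted to the observed entries.  This handles arbitrary
  missingness patterns, including whole birth cohorts for which the
  predictors were never collected.

* :func:`fit_moments` — normal-theory discrepancy fitting when only MZ/DZ
  sample covariance matrices (e.g. transcribed from a publication) are
  available:  minimize ``sum_g n_g [ln|Sigma_g| + tr(S_g Sigma_g^-1) -
  ln|S_g| - 6]`` over the free factor cells.

Both optimize in Lambda-space (the free Cholesky cells), so every iterate
yields positive semi-definite component matrices without penalty terms;
diagonal factor cells are constrained non-negative to resolve the sign
indeterminacy of ``Lambda Lambda^t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular
from scipy.stats import chi2, norm

from .exceptions import ConvergenceError, DataError, NotPositiveDefiniteError
from .model import (
    DEFAULT_ORDER,
    ComponentEstimates,
    FactorPattern,
    MeanModel,
    PhenotypeOrder,
    TwinDataset,
    expected_twin_covariance,
    standardize_components,
)

__all__ = [
    "ComponentModelSpec",
    "ParameterVector",
    "FitResult",
    "fiml_loglik",
    "fit_fiml",
    "fit_moments",
    "parameter_uncertainty",
    "profile_interval",
    "share_target",
    "regression_target",
]

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1e12


@dataclass(frozen=True)
class ComponentModelSpec:
    """Which components exist for a group and the structure of each factor."""

    order: PhenotypeOrder
    patterns: tuple[FactorPattern, ...]
    group: str = ""

    def __post_init__(self):
        labels = [p.component for p in self.patterns]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate component patterns")

    @classmethod
    def children_adce(cls, order: PhenotypeOrder = DEFAULT_ORDER) -> "ComponentModelSpec":
        """ADCE with single-factor C and predictors-only D (the identified child model)."""
        return cls(
            order,
            (
                FactorPattern.full_cholesky("A", "children"),
                FactorPattern.single_factor("C", "children"),
                FactorPattern.predictors_only("D", "children"),
                FactorPattern.full_cholesky("E", "children"),
            ),
            group="children",
        )

    @classmethod
    def adults_ade(cls, order: PhenotypeOrder = DEFAULT_ORDER) -> "ComponentModelSpec":
        """ADE with full Cholesky factors (no common environment)."""
        return cls(
            order,
            (
                FactorPattern.full_cholesky("A", "adults"),
                FactorPattern.full_cholesky("D", "adults"),
                FactorPattern.full_cholesky("E", "adults"),
            ),
            group="adults",
        )

    @classmethod
    def ae(cls, order: PhenotypeOrder = DEFAULT_ORDER) -> "ComponentModelSpec":
        """Reduced AE model (additive genetic and unique environment only)."""
        return cls(
            order,
            (FactorPattern.full_cholesky("A"), FactorPattern.full_cholesky("E")),
            group="ae",
        )

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(p.component for p in self.patterns)

    @property
    def n_component_params(self) -> int:
        return sum(p.n_free for p in self.patterns)

    def parameter_names(self, include_means: bool = True) -> list[str]:
        names = [
            f"{p.component.lower()}{i + 1}{j + 1}"
            for p in self.patterns
            for (i, j) in p.free_cells
        ]
        if include_means:
            for kind in ("b0", "bsex", "bage"):
                names += [f"{kind}_{lab}" for lab in self.order.labels]
        return names

    def diagonal_cell_mask(self, include_means: bool = True) -> np.ndarray:
        """Boolean mask over the parameter vector marking diagonal factor cells."""
        mask = [i == j for p in self.patterns for (i, j) in p.free_cells]
        if include_means:
            mask += [False] * 9
        return np.asarray(mask)

    def unpack(
        self, values: np.ndarray, include_means: bool = True
    ) -> tuple[ComponentEstimates, MeanModel | None]:
        """Map a flat parameter vector to component estimates (and mean model)."""
        values = np.asarray(values, dtype=float)
        expected = self.n_component_params + (9 if include_means else 0)
        if values.size != expected:
            raise ValueError(f"expected {expected} parameters, got {values.size}")
        pos = 0
        factors = {}
        for p in self.patterns:
            factors[p.component] = p.build_factor(values[pos : pos + p.n_free])
            pos += p.n_free
        comps = ComponentEstimates.from_factors(self.order, factors, self.group)
        means = None
        if include_means:
            b0, bsex, bage = values[pos : pos + 3], values[pos + 3 : pos + 6], values[pos + 6 : pos + 9]
            means = MeanModel(self.order, tuple(b0), tuple(bsex), tuple(bage))
        return comps, means


@dataclass
class ParameterVector:
    """Flat free-parameter vector with a bijective map to named cells."""

    spec: ComponentModelSpec
    values: np.ndarray
    include_means: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = self.spec.n_component_params + (9 if self.include_means else 0)
        if self.values.size != expected:
            raise ValueError(
                f"parameter vector has {self.values.size} entries, expected {expected}"
            )

    @property
    def names(self) -> list[str]:
        return self.spec.parameter_names(self.include_means)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def unpack(self) -> tuple[ComponentEstimates, MeanModel | None]:
        return self.spec.unpack(self.values, self.include_means)


# ---------------------------------------------------------------------------
# FIML likelihood


class _FimlEvaluator:
    """Pre-grouped FIML likelihood: records sharing zygosity and missingness
    pattern are evaluated in one vectorized pass."""

    def __init__(self, data: TwinDataset, spec: ComponentModelSpec):
        self.spec = spec
        data, self.n_dropped = data.drop_unobserved()
        if len(data) == 0:
            raise DataError("no pair has any observed phenotype")
        self.data = data
        y = data.phenotype_matrix()
        obs = ~np.isnan(y)
        # a phenotype entirely missing in the data cannot be estimated
        labels = list(spec.order.labels)
        per_pheno = obs.reshape(len(data), 2, 3).any(axis=1)
        never = [labels[j] for j in range(3) if not per_pheno[:, j].any()]
        if never:
            raise DataError(f"phenotype(s) entirely missing from the data: {never}")
        df = data.df
        zyg = df["zygosity"].to_numpy()
        sex1 = df["sex1"].to_numpy(dtype=float)
        sex2 = df["sex2"].to_numpy(dtype=float)
        age = df["age"].to_numpy(dtype=float)
        pair_id = df["pair_id"].to_numpy()
        self.groups = []
        # group rows by (zygosity, observation pattern)
        key = obs @ (1 << np.arange(6))
        for z in ("MZ", "DZ"):
            zmask = zyg == z
            for k in np.unique(key[zmask]):
                rows = np.flatnonzero(zmask & (key == k))
                oidx = np.flatnonzero(obs[rows[0]])
                self.groups.append(
                    {
                        "zyg": z,
                        "obs": oidx,
                        "y": y[np.ix_(rows, oidx)],
                        "sex1": sex1[rows],
                        "sex2": sex2[rows],
                        "age": age[rows],
                        "first_pair": pair_id[rows[0]],
                        "n": len(rows),
                    }
                )
        self.n_used = len(data)

    def loglik(self, theta: np.ndarray) -> float:
        comps, means = self.spec.unpack(theta, include_means=True)
        sigma = {z: expected_twin_covariance(comps, z) for z in ("MZ", "DZ")}
        ll = 0.0
        for g in self.groups:
            oidx = g["obs"]
            s = sigma[g["zyg"]][np.ix_(oidx, oidx)]
            try:
                chol = np.linalg.cholesky(s)
            except np.linalg.LinAlgError:
                raise NotPositiveDefiniteError(
                    f"expected covariance of the observed subvector is not positive "
                    f"definite for pair {g['first_pair']!r} (pattern {tuple(oidx)})"
                )
            mu = means.expected_means(g["sex1"], g["sex2"], g["age"])[:, oidx]
            r = g["y"] - mu
            z = solve_triangular(chol, r.T, lower=True)
            k = len(oidx)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            ll -= 0.5 * (g["n"] * (k * _LOG2PI + logdet) + float((z**2).sum()))
        return ll

    #: cross-twin block weight of each component, by zygosity
    _CROSS_WEIGHT = {
        "MZ": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 0.0},
        "DZ": {"A": 0.5, "C": 1.0, "D": 0.25, "E": 0.0},
    }

    def loglik_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood with its analytic gradient.

        For a group with observed-subvector covariance ``S``, precision
        ``P = S^-1``, ``n`` records and residual cross-product ``M = R'R``,
        the derivative with respect to ``S`` is ``-(n P - P M P)/2``; this is
        scattered back into 6x6 position and chained through the cross-twin
        weights and ``dSigma_c/dlambda_ij = E_ij Lambda' + Lambda E_ij'``.
        The mean gradient uses ``dll/dmu_n = P r_n``.
        """
        comps, means = self.spec.unpack(theta, include_means=True)
        sigma = {z: expected_twin_covariance(comps, z) for z in ("MZ", "DZ")}
        ll = 0.0
        acc = {z: np.zeros((6, 6)) for z in ("MZ", "DZ")}  # d ll / d Sigma6
        mean_grad = np.zeros(9)  # b0 (3), bsex (3), bage (3)
        for g in self.groups:
            oidx = g["obs"]
            s = sigma[g["zyg"]][np.ix_(oidx, oidx)]
            try:
                chol = np.linalg.cholesky(s)
            except np.linalg.LinAlgError:
                raise NotPositiveDefiniteError(
                    f"expected covariance of the observed subvector is not positive "
                    f"definite for pair {g['first_pair']!r} (pattern {tuple(oidx)})"
                )
            mu = means.expected_means(g["sex1"], g["sex2"], g["age"])[:, oidx]
            r = g["y"] - mu
            z = solve_triangular(chol, r.T, lower=True)
            k = len(oidx)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            ll -= 0.5 * (g["n"] * (k * _LOG2PI + logdet) + float((z**2).sum()))
            inv_chol = solve_triangular(chol, np.eye(k), lower=True)
            p = inv_chol.T @ inv_chol
            m = r.T @ r
            gmat = -0.5 * (g["n"] * p - p @ m @ p)
            acc[g["zyg"]][np.ix_(oidx, oidx)] += gmat
            u = np.zeros((g["n"], 6))
            u[:, oidx] = r @ p  # d ll / d mu per record, scattered
            u1, u2 = u[:, :3], u[:, 3:]
            mean_grad[0:3] += u1.sum(axis=0) + u2.sum(axis=0)
            mean_grad[3:6] += g["sex1"] @ u1 + g["sex2"] @ u2
            mean_grad[6:9] += g["age"] @ (u1 + u2)
        grad = np.empty(theta.size)
        pos = 0
        for pat in self.spec.patterns:
            lam = comps.factors[pat.component]
            total = np.zeros((3, 3))
            for z in ("MZ", "DZ"):
                b11 = acc[z][:3, :3] + acc[z][3:, 3:]
                b12 = acc[z][:3, 3:] + acc[z][3:, :3]
                total += b11 + self._CROSS_WEIGHT[z][pat.component] * b12
            dlam = 2.0 * (total @ lam)
            for i, j in pat.free_cells:
                grad[pos] = dlam[i, j]
                pos += 1
        grad[pos : pos + 9] = mean_grad
        return ll, grad


def fiml_loglik(data: TwinDataset, params, spec: ComponentModelSpec) -> float:
    """Full-information ML log-likelihood of a twin dataset.

    ``params`` is a :class:`ParameterVector` (with means) or a flat array in
    the spec's parameter order.  Pairs with no observed phenotype are
    dropped; every other record contributes the density of its observed
    subvector.
    """
    theta = params.values if isinstance(params, ParameterVector) else np.asarray(params, float)
    return _FimlEvaluator(data, spec).loglik(theta)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """A fitted twin model: parameters, likelihood, and diagnostics."""

    params: ParameterVector
    loglik: float
    converged: bool
    grad_norm: float
    components: ComponentEstimates
    means: MeanModel | None
    spec: ComponentModelSpec
    method: str
    param_cov: np.ndarray | None = None
    n_used: int = 0
    n_dropped: int = 0
    diagnostics: dict = field(default_factory=dict)
    _objective: Callable[[np.ndarray], float] | None = None

    def standardized_shares(self) -> pd.DataFrame:
        return standardize_components(self.components)

    def parameter_se(self) -> pd.Series | None:
        if self.param_cov is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.param_cov)), index=self.params.names)


def _start_from_phenotypic_cov(
    spec: ComponentModelSpec, s_ph: np.ndarray, means_start: np.ndarray | None
) -> np.ndarray:
    """Starting values: the phenotypic covariance split equally over components.

    Each component's start target is ``S_ph / k`` (k = number of components),
    which is positive definite whenever ``S_ph`` is and therefore always
    factorizable under every pattern.
    """
    k = len(spec.patterns)
    s_ph = np.asarray(s_ph, dtype=float)
    w = np.linalg.eigvalsh(s_ph)
    if w[0] <= 0:  # guard degenerate sample moments
        s_ph = s_ph + (abs(w[0]) + 1e-3 * max(w[-1], 1.0)) * np.eye(3)
    target = s_ph / k
    vals = []
    for p in spec.patterns:
        cells = p.free_cells
        rows = sorted({i for i, _ in cells})
        sub = target[np.ix_(rows, rows)]
        if p.n_free == len(rows):  # single-factor: one column
            col = sub[:, 0] / math.sqrt(sub[0, 0])
            vals.extend(col)
        else:
            chol = np.linalg.cholesky(sub)
            lam = np.zeros((3, 3))
            for a, ia in enumerate(rows):
                for b, jb in enumerate(rows[: a + 1]):
                    lam[ia, jb] = chol[a, b]
            vals.extend(lam[i, j] for i, j in cells)
    vals = np.asarray(vals)
    if means_start is not None:
        vals = np.concatenate([vals, means_start])
    return vals


def _minimize_multistart(
    objective: Callable[[np.ndarray], float],
    start: np.ndarray,
    bounds,
    n_starts: int,
    seed: int,
    gtol_scale: float,
    jac=None,
) -> tuple[optimize.OptimizeResult, list[dict]]:
    rng = np.random.default_rng(seed)
    starts = [start]
    for _ in range(max(0, n_starts - 1)):
        jitter = start * (1.0 + 0.1 * rng.standard_normal(start.shape)) + 0.01 * rng.standard_normal(
            start.shape
        )
        starts.append(jitter)
    best = None
    history = []
    for i, x0 in enumerate(starts):
        x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in bounds], np.inf)
        res = optimize.minimize(
            jac if jac is not None else objective,
            x0,
            jac=True if jac is not None else None,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "maxfun": 200000, "ftol": 1e-11, "gtol": 1e-7 * gtol_scale},
        )
        history.append({"start": i, "fun": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    return best, history


def _finalize_fit(spec, res, history, evaluator_loglik, method, n_used, n_dropped, compute_cov, objective, include_means, grad_fn=None):
    theta = res.x.copy()
    # canonicalize sign indeterminacy: non-negative diagonal cells (enforced by
    # bounds, but flip a column if a jittered start ended with a -0 diagonal)
    loglik = evaluator_loglik(theta)
    grad = np.asarray(res.jac, dtype=float)
    grad_norm = float(np.abs(grad).max()) if grad.size else float("nan")
    # relative gradient criterion: with finite-difference gradients on a
    # likelihood of magnitude |ll|, absolute gradient noise scales with |ll|
    converged = bool(res.success) and grad_norm <= 1e-5 * max(1.0, abs(loglik))
    param_cov = None
    if compute_cov:
        try:
            if grad_fn is not None:
                hess = _hessian_from_gradient(grad_fn, theta)
            else:
                hess = _numerical_hessian(objective, theta)
            param_cov = np.linalg.inv(hess)
            w = np.linalg.eigvalsh(0.5 * (param_cov + param_cov.T))
            if w[0] <= 0:
                param_cov = None
        except np.linalg.LinAlgError:
            param_cov = None
    comps, means = spec.unpack(theta, include_means=include_means)
    return FitResult(
        params=ParameterVector(spec, theta, include_means=include_means),
        loglik=float(loglik),
        converged=converged,
        grad_norm=grad_norm,
        components=comps,
        means=means,
        spec=spec,
        method=method,
        param_cov=param_cov,
        n_used=n_used,
        n_dropped=n_dropped,
        diagnostics={"starts": history, "n_iter": int(res.nit), "message": str(res.message),
                     "information_singular": compute_cov and param_cov is None},
        _objective=objective,
    )


def fit_fiml(
    data: TwinDataset,
    spec: ComponentModelSpec,
    start: ParameterVector | np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
    compute_cov: bool = True,
) -> FitResult:
    """Fit the structured twin model to raw pair records by FIML.

    Optimization runs in Lambda-space with L-BFGS-B and finite-difference
    gradients, from ``n_starts`` jittered starting points (seeded).  A fit
    that stops without meeting the gradient criterion is returned with
    ``converged=False`` and full diagnostics, never silently.
    """
    ev = _FimlEvaluator(data, spec)
    counts = ev.data.counts_by_zygosity()
    if counts["MZ"] < 2 or counts["DZ"] < 2:
        raise DataError(
            f"need at least 2 MZ and 2 DZ pairs with observations, got {counts}"
        )

    def objective(theta):
        try:
            return -ev.loglik(theta)
        except NotPositiveDefiniteError:
            return _PENALTY

    def objective_grad(theta):
        try:
            ll, grad = ev.loglik_and_grad(theta)
            return -ll, -grad
        except NotPositiveDefiniteError:
            return _PENALTY, np.zeros_like(theta)

    if start is None:
        # pooled within-person sample moments for starting values
        y = ev.data.phenotype_matrix()
        persons = np.vstack([y[:, :3], y[:, 3:]])
        pdf = pd.DataFrame(persons, columns=list(spec.order.labels))
        s_ph = pdf.cov(min_periods=2).to_numpy()
        if np.isnan(s_ph).any():
            s_ph = np.eye(3)
        means_start = np.concatenate([np.nanmean(persons, axis=0), np.zeros(6)])
        x0 = _start_from_phenotypic_cov(spec, s_ph, means_start)
    else:
        x0 = start.values if isinstance(start, ParameterVector) else np.asarray(start, float)

    diag = spec.diagonal_cell_mask(include_means=True)
    bounds = [(0.0, None) if d else (None, None) for d in diag]
    n6 = ev.n_used * 6
    best, history = _minimize_multistart(
        objective, x0, bounds, n_starts, seed, gtol_scale=max(1.0, n6), jac=objective_grad
    )
    return _finalize_fit(
        spec, best, history, ev.loglik, "fiml", ev.n_used, ev.n_dropped,
        compute_cov, objective, include_means=True,
        grad_fn=lambda th: objective_grad(th)[1],
    )


def _validate_sample_cov(s, name) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (6, 6):
        raise ValueError(f"{name} must be 6x6, got {s.shape}")
    if np.abs(s - s.T).max() > 1e-8 * max(1.0, np.abs(s).max()):
        raise ValueError(f"{name} is asymmetric")
    s = 0.5 * (s + s.T)
    try:
        np.linalg.cholesky(s)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(f"{name} is not positive definite")
    return s


def fit_moments(
    s_mz,
    s_dz,
    n_mz: int,
    n_dz: int,
    spec: ComponentModelSpec,
    start: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
    compute_cov: bool = True,
) -> FitResult:
    """Fit the model to MZ/DZ sample covariance matrices.

    Minimizes the normal-theory maximum-likelihood discrepancy
    ``sum_g n_g [ln|Sigma_g| + tr(S_g Sigma_g^-1) - ln|S_g| - 6]``; the
    discrepancy is zero iff the model reproduces both sample matrices
    exactly.  Useful for re-analyzing published summary tables when raw
    records are unavailable.
    """
    s_mz = _validate_sample_cov(s_mz, "S_mz")
    s_dz = _validate_sample_cov(s_dz, "S_dz")
    if min(n_mz, n_dz) < 1 or (n_mz + n_dz) < spec.n_component_params:
        raise DataError("pair counts too small for the number of free parameters")
    sign, logdet_mz = np.linalg.slogdet(s_mz)
    _, logdet_dz = np.linalg.slogdet(s_dz)
    consts = {"MZ": (s_mz, n_mz, logdet_mz), "DZ": (s_dz, n_dz, logdet_dz)}

    def discrepancy(theta):
        comps, _ = spec.unpack(theta, include_means=False)
        f = 0.0
        for z, (s_obs, n, logdet_obs) in consts.items():
            sig = expected_twin_covariance(comps, z)
            try:
                chol = np.linalg.cholesky(sig)
            except np.linalg.LinAlgError:
                return _PENALTY
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            x = solve_triangular(chol, s_obs, lower=True)
            tr = float(np.trace(solve_triangular(chol, x.T, lower=True)))
            f += n * (logdet + tr - logdet_obs - 6.0)
        return f

    if start is None:
        within = 0.25 * (s_mz[:3, :3] + s_mz[3:, 3:] + s_dz[:3, :3] + s_dz[3:, 3:])
        x0 = _start_from_phenotypic_cov(spec, within, None)
    else:
        x0 = np.asarray(start, dtype=float)
    diag = spec.diagonal_cell_mask(include_means=False)
    bounds = [(0.0, None) if d else (None, None) for d in diag]
    objective = lambda th: 0.5 * discrepancy(th)  # noqa: E731 — half-discrepancy = negative loglik shift
    best, history = _minimize_multistart(
        objective, x0, bounds, n_starts, seed, gtol_scale=max(1.0, float(n_mz + n_dz))
    )

    def loglik_of(theta):
        # implied normal-theory log-likelihood (up to the saturated constant)
        f = objective(theta)
        const = -0.5 * (n_mz + n_dz) * 6 * _LOG2PI - 0.5 * (
            n_mz * logdet_mz + n_dz * logdet_dz + (n_mz + n_dz) * 6
        )
        return const - f

    fit = _finalize_fit(
        spec, best, history, loglik_of, "moments", n_mz + n_dz, 0,
        compute_cov, objective, include_means=False,
    )
    fit.diagnostics["discrepancy"] = float(2.0 * best.fun)
    return fit


# ---------------------------------------------------------------------------
# Uncertainty


def _hessian_from_gradient(grad: Callable[[np.ndarray], np.ndarray], x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of an (analytic) gradient."""
    x = np.asarray(x, dtype=float)
    p = x.size
    hess = np.empty((p, p))
    for i in range(p):
        h = rel_step * max(abs(x[i]), 0.1)
        e = np.zeros(p); e[i] = h
        hess[i] = (grad(x + e) - grad(x - e)) / (2 * h)
    return 0.5 * (hess + hess.T)


def _numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 0.1)
    hess = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p); ej[j] = h[j]
            fij = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4 * h[i] * h[j])
    return 0.5 * (hess + hess.T)


def _numerical_gradient(f, x, rel_step=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.empty(x.size)
    h = rel_step * np.maximum(np.abs(x), 0.1)
    for i in range(x.size):
        e = np.zeros(x.size); e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


def share_target(spec: ComponentModelSpec, component: str, phenotype: str, include_means=True):
    """Derived quantity: the standardized variance share of one component."""
    j = spec.order.index(phenotype)
    def g(theta):
        comps, _ = spec.unpack(theta, include_means=include_means)
        return float(comps.component(component)[j, j] / comps.sigma_ph[j, j])
    g.__name__ = f"{component.lower()}2_{phenotype}"
    return g


def regression_target(spec: ComponentModelSpec, level: str, predictor: str, include_means=True):
    """Derived quantity: a covariance-level regression coefficient."""
    from .regression import covariance_regression

    k = {spec.order.labels[1]: 0, spec.order.labels[2]: 1}[predictor]
    def g(theta):
        comps, _ = spec.unpack(theta, include_means=include_means)
        s = {"G": comps.sigma_g, "T": comps.sigma_t, "phenotypic": comps.sigma_ph}[level]
        return float(covariance_regression(s)[k])
    g.__name__ = f"b_{level}_{predictor}"
    return g


def parameter_uncertainty(
    fit: FitResult,
    targets: Mapping[str, Callable[[np.ndarray], float]] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Delta-method standard errors and Wald intervals for derived quantities.

    ``targets`` maps names to differentiable functions of the raw parameter
    vector (see :func:`share_target` and :func:`regression_target`); when
    omitted, the raw parameters themselves are reported.  If the information
    matrix was singular, intervals are returned as NaN with ``flagged=True``
    rather than fabricated.
    """
    names = fit.params.names
    theta = fit.params.values
    z = norm.ppf(0.5 + level / 2)
    rows = []
    if targets is None:
        targets = {n: (lambda th, i=i: float(th[i])) for i, n in enumerate(names)}
    singular = fit.param_cov is None
    for name, g in targets.items():
        est = g(theta)
        if singular:
            rows.append((name, est, np.nan, np.nan, np.nan, True))
            continue
        jac = _numerical_gradient(g, theta)
        var = float(jac @ fit.param_cov @ jac)
        se = math.sqrt(max(var, 0.0))
        rows.append((name, est, se, est - z * se, est + z * se, False))
    return pd.DataFrame(
        rows, columns=["name", "estimate", "se", "lower", "upper", "flagged"]
    ).set_index("name")


def profile_interval(
    fit: FitResult, name: str, level: float = 0.95, expand: float = 5.0
) -> tuple[float, float]:
    """Profile-likelihood interval for one raw parameter.

    Re-optimizes the stored objective over the remaining parameters at fixed
    values of the target parameter and inverts the likelihood-ratio statistic
    at the requested level.
    """
    if fit._objective is None:
        raise ConvergenceError("fit carries no objective; cannot profile")
    names = fit.params.names
    idx = names.index(name)
    theta = fit.params.values
    crit = 0.5 * chi2.ppf(level, df=1)
    f_min = fit._objective(theta)
    diag = fit.spec.diagonal_cell_mask(fit.params.include_means)
    others = [i for i in range(theta.size) if i != idx]
    bounds = [(0.0, None) if diag[i] else (None, None) for i in others]

    def profile_nll(v):
        def obj(sub):
            full = theta.copy()
            full[idx] = v
            full[others] = sub
            return fit._objective(full)
        res = optimize.minimize(obj, theta[others], method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-10})
        return res.fun

    se = None
    if fit.param_cov is not None:
        se = math.sqrt(max(fit.param_cov[idx, idx], 1e-12))
    step = se if se else max(abs(theta[idx]) * 0.25, 0.1)

    def root(direction):
        lo = theta[idx]
        hi = theta[idx] + direction * step
        for _ in range(30):
            if diag[idx] and hi < 0:
                hi = 0.0
                break
            if profile_nll(hi) - f_min >= crit:
                break
            lo, hi = hi, hi + direction * step * expand
        else:
            return direction * np.inf
        if hi == 0.0 and profile_nll(0.0) - f_min < crit:
            return 0.0
        return optimize.brentq(lambda v: profile_nll(v) - f_min - crit, min(lo, hi), max(lo, hi), xtol=1e-4)

    return (root(-1.0), root(+1.0))
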