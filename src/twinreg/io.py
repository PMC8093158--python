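"""Readers, writers, and report assembly.

Data travel as wide one-row-per-pair CSV (columns ``pair_id``, ``zygosity``,
``sex1``, ``sex2``, ``age``, and ``<phenotype>1``/``<phenotype>2``); empty
cells or a designated token mark missing values.  Component matrices and
results serialize to a versioned JSON schema so the CLI subcommands can be
chained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DataError
from .model import (
    DEFAULT_ORDER,
    ComponentEstimates,
    PhenotypeOrder,
    TwinDataset,
)

__all__ = [
    "MomentInput",
    "read_twin_csv",
    "write_twin_csv",
    "long_to_wide",
    "summary_to_covariance",
    "read_summary_tables",
    "components_to_json",
    "components_from_json",
    "report",
]

SCHEMA_VERSION = "1.0"
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


@dataclass
class MomentInput:
    """Moment-mode input: MZ/DZ 6x6 sample covariances and pair counts."""

    order: PhenotypeOrder
    s_mz: np.ndarray
    s_dz: np.ndarray
    n_mz: int
    n_dz: int


def read_twin_csv(
    path,
    mapping: Mapping[str, str] | None = None,
    order: PhenotypeOrder = DEFAULT_ORDER,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    zygosity_map: Mapping[str, str] | None = None,
) -> TwinDataset:
    """Read a wide per-pair CSV into a :class:`TwinDataset`.

    ``mapping`` renames file columns onto the canonical ones (e.g.
    ``{"agg_t1": "aggression1"}``); ``zygosity_map`` translates zygosity
    labels (e.g. ``{"OS": "DZ"}``).  Errors cite the offending row.
    """
    df = pd.read_csv(path, dtype={"pair_id": str}, na_values=list(missing_tokens), keep_default_na=False)
    if mapping:
        df = df.rename(columns=dict(mapping))
    required = list(TwinDataset.META_COLUMNS) + TwinDataset.phenotype_columns(order)
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: missing required column(s) {missing_cols}")
    if zygosity_map:
        df["zygosity"] = df["zygosity"].astype(str).replace(dict(zygosity_map))
    for c in TwinDataset.phenotype_columns(order) + ["age"]:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else "?"
            raise DataError(f"{path}: non-numeric value in column {c!r} at row {row}") from exc
    return TwinDataset(df, order)


def write_twin_csv(data: TwinDataset, path) -> None:
    data.df.to_csv(path, index=False, na_rep="NA")


def long_to_wide(
    long_df: pd.DataFrame,
    order: PhenotypeOrder = DEFAULT_ORDER,
    pair_col: str = "pair_id",
    twin_col: str = "twin",
) -> pd.DataFrame:
    """Convert a long table (one row per twin) to the wide per-pair layout.

    The long table needs columns ``pair_id``, ``twin`` (1 or 2),
    ``zygosity``, ``sex``, ``age``, and one column per phenotype label.
    """
    wide = None
    for t in (1, 2):
        sub = long_df[long_df[twin_col] == t].set_index(pair_col)
        cols = {lab: f"{lab}{t}" for lab in order.labels}
        cols["sex"] = f"sex{t}"
        sub = sub.rename(columns=cols)
        keep = list(cols.values()) + (["zygosity", "age"] if t == 1 else [])
        sub = sub[keep]
        wide = sub if wide is None else wide.join(sub, how="outer")
    return wide.reset_index().rename(columns={pair_col: "pair_id"})


def summary_to_covariance(correlations, sds) -> np.ndarray:
    """Covariance ``S = D R D`` from a correlation matrix and SDs.

    Validates unit diagonal and |r| <= 1; symmetry is enforced by averaging.
    """
    r = np.asarray(correlations, dtype=float)
    d = np.asarray(sds, dtype=float)
    if r.shape != (d.size, d.size):
        raise ValueError("correlation matrix and SD vector sizes disagree")
    r = 0.5 * (r + r.T)
    if np.any(np.abs(np.diag(r) - 1.0) > 1e-8):
        raise DataError("correlation matrix must have a unit diagonal")
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise DataError("correlations must lie in [-1, 1]")
    if np.any(d <= 0):
        raise DataError("standard deviations must be positive")
    return (d[:, None] * r) * d[None, :]


def read_summary_tables(
    corr_mz, sd_mz, n_mz: int, corr_dz, sd_dz, n_dz: int,
    order: PhenotypeOrder = DEFAULT_ORDER,
) -> MomentInput:
    """Assemble moment-mode input from per-zygosity correlation tables and SDs."""
    return MomentInput(
        order=order,
        s_mz=summary_to_covariance(corr_mz, sd_mz),
        s_dz=summary_to_covariance(corr_dz, sd_dz),
        n_mz=int(n_mz),
        n_dz=int(n_dz),
    )


def components_to_json(components: ComponentEstimates, path=None) -> dict:
    """Serialize component matrices keyed by label, with the phenotype order."""
    obj = {
        "schema_version": SCHEMA_VERSION,
        "phenotypes": list(components.order.labels),
        "group": components.group,
        "components": {k: np.asarray(v).tolist() for k, v in components.sigma.items()},
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=2))
    return obj


def components_from_json(source) -> ComponentEstimates:
    """Read component matrices from a JSON object, string, or file path."""
    if isinstance(source, Mapping):
        obj = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
    order = PhenotypeOrder(tuple(obj["phenotypes"]))
    sigmas = {k: np.asarray(v, dtype=float) for k, v in obj["components"].items()}
    return ComponentEstimates.from_sigmas(order, sigmas, group=obj.get("group", ""))


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def report(bundle: Mapping | None = None, path=None) -> tuple[str, dict]:
    """Assemble a human-readable report and a schema-stable JSON object.

    ``bundle`` may contain any of: ``components`` (ComponentEstimates),
    ``regressions`` (mapping level -> CovRegressionResult), ``fit``
    (FitResult), ``pheno`` (PhenoRegResult), ``missingness`` (DataFrame).
    An empty bundle yields an empty-but-valid skeleton.
    """
    from .model import standardize_components

    bundle = dict(bundle or {})
    out = {"schema_version": SCHEMA_VERSION, "sections": {}}
    lines = []

    fit = bundle.get("fit")
    if fit is not None:
        out["sections"]["fit"] = {
            "method": fit.method,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "grad_norm": fit.grad_norm,
            "n_used": fit.n_used,
            "n_dropped": fit.n_dropped,
            "parameters": dict(zip(fit.params.names, fit.params.values.tolist())),
        }
        lines += [
            f"Model fit ({fit.method}): loglik = {fit.loglik:.3f}, "
            f"converged = {fit.converged}, pairs used = {fit.n_used} "
            f"(dropped {fit.n_dropped})",
            "",
        ]
        if "components" not in bundle:
            bundle["components"] = fit.components

    comps = bundle.get("components")
    if comps is not None:
        out["sections"]["components"] = {
            "phenotypes": list(comps.order.labels),
            "group": comps.group,
            "matrices": {k: np.asarray(v).tolist() for k, v in comps.sigma.items()},
        }
        shares = standardize_components(comps)
        out["sections"]["standardized_shares"] = {
            ph: {c: float(shares.loc[ph, c]) for c in shares.columns}
            for ph in shares.index
        }
        lines += ["Component covariance matrices (" + ", ".join(comps.components) + "):"]
        for lab in comps.components:
            lines.append(f"  Sigma_{lab}:")
            for row in comps.sigma[lab]:
                lines.append("    " + "  ".join(f"{v:8.3f}" for v in row))
        lines += ["", "Standardized variance shares (rows sum to 1):",
                  shares.round(3).to_string(), ""]

    regs = bundle.get("regressions")
    if regs is not None:
        sec = {}
        lines.append("Covariance-level regression of the outcome on the two predictors:")
        for level, r in regs.items():
            sec[level] = {
                "outcome": r.outcome,
                "predictors": list(r.predictors),
                "coefficients": dict(zip(r.predictors, r.b.tolist())),
                "raw_components": {
                    r.predictors[0]: float(r.v_pred[0]),
                    r.predictors[1]: float(r.v_pred[1]),
                    "cross": r.v_cross,
                    "residual": r.residual,
                },
                "level_shares": r.level_shares(),
                "explained_total": r.explained_total,
                "flags": list(r.flags),
            }
            if r.phenotypic_variance is not None:
                sec[level]["phenotypic_shares"] = r.phenotypic_shares()
            bstr = ", ".join(f"{p} {v:.3f}" for p, v in zip(r.predictors, r.b))
            lines.append(
                f"  [{level}] b: {bstr}; explained {100 * r.explained_total:.1f}% "
                f"of the {level}-level outcome variance"
            )
            for fl in r.flags:
                lines.append(f"    flag: {fl}")
        out["sections"]["regressions"] = sec
        lines.append("")

    pheno = bundle.get("pheno")
    if pheno is not None:
        out["sections"]["phenotypic_regression"] = {
            "coefficients": pheno.coef.to_dict(),
            "se": pheno.se.to_dict() if pheno.se is not None else None,
            "s2_eps": pheno.s2_eps,
            "residual_twin_cov": {"MZ": pheno.cov_mz, "DZ": pheno.cov_dz},
            "loglik": pheno.loglik,
            "n_pairs_used": pheno.n_pairs_used,
        }
        lines += ["Phenotypic regression (pair-likelihood):",
                  pheno.coef.round(4).to_string(), ""]

    miss = bundle.get("missingness")
    if miss is not None:
        out["sections"]["missingness"] = miss.to_dict(orient="records")
        lines += ["Missingness by zygosity and variable:", miss.to_string(index=False), ""]

    out = _round_floats(out, 10)
    text = "\n".join(lines) if lines else "(empty report)"
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))
    return text, out
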