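"""Structured twin-model types and deterministic covariance algebra.

The model decomposes the 3x3 phenotypic covariance matrix of an outcome and
two correlated predictors (canonically aggression, hyperactivity, and
inattention) into additive-genetic (A), dominance (D), common-environment
(C), and unique-environment (E) components, each parameterized through a
structured lower-triangular factor ``Lambda`` so that ``Sigma = Lambda
Lambda^t`` is positive semi-definite by construction.

In a joint analysis of monozygotic (MZ) and dizygotic (DZ) twin pairs a full
ADCE model is not identified; identification is achieved with structural
constraints: the common-environment factor is a single column (one shared
factor loading on all three traits) and dominance is restricted to the two
predictor traits.  Adults are modelled without a C component (ADE) with full
Cholesky factors for A, D, and E.

This module contains no estimation: it provides the deterministic mapping
from factors to component matrices, the expected 6x6 MZ/DZ twin covariance
(3 traits per twin), standardized variance shares (h2, d2, c2, e2), and
eigenvalue/rank diagnostics used to decide on which component matrices a
regression may be performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, StructuralViolationError

__all__ = [
    "PhenotypeOrder",
    "DEFAULT_ORDER",
    "FactorPattern",
    "ComponentEstimates",
    "MeanModel",
    "TwinPairRecord",
    "TwinDataset",
    "RankDiagnostics",
    "TRANSCRIPTION_TOL",
    "build_component_matrix",
    "expected_twin_covariance",
    "standardize_components",
    "rank_diagnostics",
]

COMPONENT_LABELS = ("A", "C", "D", "E")

#: Relative eigenvalue tolerance below which a matrix is treated as rank-deficient.
DEFAULT_RANK_TOL = 1e-9

#: Relative tolerance for matrices transcribed from rounded published tables:
#: entries printed to ~3 significant figures perturb eigenvalues by up to
#: about 1e-2 of the leading one, so smaller eigenvalues are indistinguishable
#: from rounding noise.  Used both for PSD acceptance of transcribed matrices
#: and for near-rank diagnosis.
TRANSCRIPTION_TOL = 1e-2


@dataclass(frozen=True)
class PhenotypeOrder:
    """Ordered phenotype labels; index 0 is the regression outcome.

    The canonical order is (aggression, hyperactivity, inattention): the
    outcome first, then the two predictors.  All I/O maps user-facing column
    names onto this order explicitly.
    """

    labels: tuple[str, str, str]

    def __post_init__(self):
        if len(self.labels) != 3 or len(set(self.labels)) != 3:
            raise ValueError("exactly 3 unique phenotype labels are required")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def outcome(self) -> str:
        return self.labels[0]

    @property
    def predictors(self) -> tuple[str, str]:
        return self.labels[1:]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __iter__(self):
        return iter(self.labels)


DEFAULT_ORDER = PhenotypeOrder(("aggression", "hyperactivity", "inattention"))


def _as_free_grid(free_cells: Iterable[tuple[int, int]]) -> tuple[tuple[bool, ...], ...]:
    grid = [[False] * 3 for _ in range(3)]
    for i, j in free_cells:
        if j > i:
            raise StructuralViolationError(
                f"cell ({i},{j}) is strictly upper-triangular and always fixed to zero"
            )
        grid[i][j] = True
    return tuple(tuple(row) for row in grid)


@dataclass(frozen=True)
class FactorPattern:
    """Structural pattern of one 3x3 lower-triangular factor matrix.

    ``free`` marks the cells estimated freely; every other cell is fixed to
    zero.  Strictly upper-triangular cells are always fixed.
    """

    component: str
    free: tuple[tuple[bool, ...], ...]
    group: str = ""

    def __post_init__(self):
        if self.component not in COMPONENT_LABELS:
            raise ValueError(f"unknown component label {self.component!r}")
        for i in range(3):
            for j in range(3):
                if j > i and self.free[i][j]:
                    raise StructuralViolationError(
                        "strictly upper-triangular cells must be fixed to zero"
                    )

    @classmethod
    def full_cholesky(cls, component: str, group: str = "") -> "FactorPattern":
        """All six lower-triangular cells free (the standard Cholesky factor)."""
        return cls(component, _as_free_grid([(i, j) for i in range(3) for j in range(i + 1)]), group)

    @classmethod
    def single_factor(cls, component: str, group: str = "") -> "FactorPattern":
        """One shared factor: only the first column free (rank <= 1 component).

        Used for the common environment in children, where a single shared
        factor loading on all three traits identifies C next to D.
        """
        return cls(component, _as_free_grid([(0, 0), (1, 0), (2, 0)]), group)

    @classmethod
    def predictors_only(cls, component: str, group: str = "") -> "FactorPattern":
        """Outcome row and column fixed to zero (rank <= 2 component).

        Used for dominance in children: non-additive genetic effects load on
        the two predictors only, which together with the single-factor C
        pattern renders the ADCE model identified.
        """
        return cls(component, _as_free_grid([(1, 1), (2, 1), (2, 2)]), group)

    @property
    def free_cells(self) -> tuple[tuple[int, int], ...]:
        """Free cells in row-major order."""
        return tuple((i, j) for i in range(3) for j in range(i + 1) if self.free[i][j])

    @property
    def n_free(self) -> int:
        return len(self.free_cells)

    def build_factor(self, values) -> np.ndarray:
        """Assemble the 3x3 factor matrix Lambda from free-cell values.

        ``values`` is either a mapping ``{(row, col): value}`` covering
        exactly the free cells, or a flat sequence in row-major free-cell
        order.  Supplying a value for a fixed-zero cell is a structural
        violation.
        """
        lam = np.zeros((3, 3))
        cells = self.free_cells
        if isinstance(values, Mapping):
            extra = set(values) - set(cells)
            if extra:
                raise StructuralViolationError(
                    f"value supplied for fixed-zero cell(s) {sorted(extra)} "
                    f"of the {self.component} pattern"
                )
            missing = set(cells) - set(values)
            if missing:
                raise ValueError(f"missing values for free cells {sorted(missing)}")
            for (i, j), v in values.items():
                lam[i, j] = v
        else:
            values = np.asarray(values, dtype=float).ravel()
            if values.size != len(cells):
                raise ValueError(
                    f"{self.component} pattern has {len(cells)} free cells, "
                    f"got {values.size} values"
                )
            for (i, j), v in zip(cells, values):
                lam[i, j] = v
        return lam


def build_component_matrix(pattern: FactorPattern, values) -> np.ndarray:
    """Return ``Sigma = Lambda Lambda^t`` for a factor pattern and its values.

    The result is symmetric positive semi-definite by construction.
    """
    lam = pattern.build_factor(values)
    return lam @ lam.T


def _check_symmetric(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {matrix.shape}")
    scale = max(1.0, float(np.abs(matrix).max()))
    if np.abs(matrix - matrix.T).max() > tol * scale:
        raise ValueError("matrix is asymmetric beyond tolerance")
    return 0.5 * (matrix + matrix.T)


@dataclass
class ComponentEstimates:
    """The component covariance matrices of one group, with optional factors.

    ``sigma`` maps component labels (subset of A, C, D, E) to 3x3 symmetric
    matrices in squared phenotype-score units.  When built from factors each
    ``Sigma`` equals ``Lambda Lambda^t`` exactly; matrices transcribed from
    published tables can be supplied directly (factors absent), in which case
    a small negative eigenvalue from printed rounding is tolerated.
    """

    order: PhenotypeOrder
    sigma: dict[str, np.ndarray]
    factors: dict[str, np.ndarray] = field(default_factory=dict)
    group: str = ""

    def __post_init__(self):
        for label in self.sigma:
            if label not in COMPONENT_LABELS:
                raise ValueError(f"unknown component label {label!r}")
            self.sigma[label] = _check_symmetric(self.sigma[label])

    @classmethod
    def from_factors(
        cls,
        order: PhenotypeOrder,
        factors: Mapping[str, np.ndarray],
        group: str = "",
    ) -> "ComponentEstimates":
        sig = {lab: np.asarray(lam) @ np.asarray(lam).T for lab, lam in factors.items()}
        return cls(order, sig, {lab: np.asarray(lam, dtype=float) for lab, lam in factors.items()}, group)

    @classmethod
    def from_sigmas(
        cls,
        order: PhenotypeOrder,
        sigmas: Mapping[str, np.ndarray],
        group: str = "",
        psd_tol: float = TRANSCRIPTION_TOL,
    ) -> "ComponentEstimates":
        """Build from component covariance matrices given directly.

        ``psd_tol`` is the tolerated relative magnitude of a negative
        eigenvalue; published matrices rounded to 2-3 decimals are often very
        slightly indefinite.
        """
        out = {}
        for lab, s in sigmas.items():
            s = _check_symmetric(s)
            w = np.linalg.eigvalsh(s)
            lead = max(abs(w[-1]), 1e-12)
            if w[0] < -psd_tol * lead:
                raise ValueError(
                    f"component {lab} is not positive semi-definite "
                    f"(min eigenvalue {w[0]:.3g} vs leading {w[-1]:.3g})"
                )
            out[lab] = s
        return cls(order, out, {}, group)

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(lab for lab in COMPONENT_LABELS if lab in self.sigma)

    def component(self, label: str) -> np.ndarray:
        if label not in self.sigma:
            raise KeyError(f"component {label!r} absent for group {self.group!r}")
        return self.sigma[label]

    def _sum(self, labels: Sequence[str]) -> np.ndarray:
        out = np.zeros((3, 3))
        for lab in labels:
            if lab in self.sigma:
                out = out + self.sigma[lab]
        return out

    @property
    def sigma_g(self) -> np.ndarray:
        """Broad-sense genetic covariance matrix, ``Sigma_A + Sigma_D``."""
        return self._sum(("A", "D"))

    @property
    def sigma_t(self) -> np.ndarray:
        """Total environmental covariance, ``Sigma_C + Sigma_E`` (``Sigma_E`` when C absent)."""
        return self._sum(("C", "E"))

    @property
    def sigma_ph(self) -> np.ndarray:
        """Phenotypic covariance conditional on covariates: sum of all components."""
        return self._sum(COMPONENT_LABELS)


@dataclass(frozen=True)
class MeanModel:
    """Fixed-effect mean structure: per phenotype an intercept, sex and age effect.

    Sex is coded 0 = male, 1 = female; age is in years.  The same
    coefficients apply to both members of a pair, each evaluated at their own
    sex and the shared age.
    """

    order: PhenotypeOrder
    intercept: tuple[float, float, float]
    sex_effect: tuple[float, float, float]
    age_effect: tuple[float, float, float]

    def __post_init__(self):
        for name in ("intercept", "sex_effect", "age_effect"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != 3 or not all(np.isfinite(vals)):
                raise ValueError(f"{name} must be 3 finite values")
            object.__setattr__(self, name, vals)

    @classmethod
    def zero(cls, order: PhenotypeOrder = DEFAULT_ORDER) -> "MeanModel":
        return cls(order, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))

    def expected_means(self, sex1, sex2, age) -> np.ndarray:
        """Expected (n, 6) phenotype means: twin-1 triple then twin-2 triple."""
        sex1 = np.asarray(sex1, dtype=float)
        sex2 = np.asarray(sex2, dtype=float)
        age = np.asarray(age, dtype=float)
        b0 = np.asarray(self.intercept)
        bs = np.asarray(self.sex_effect)
        ba = np.asarray(self.age_effect)
        mu1 = b0[None, :] + np.outer(sex1, bs) + np.outer(age, ba)
        mu2 = b0[None, :] + np.outer(sex2, bs) + np.outer(age, ba)
        return np.hstack([mu1, mu2])


def expected_twin_covariance(components: ComponentEstimates, zygosity: str) -> np.ndarray:
    """Expected 6x6 covariance of the three traits measured in both twins.

    The within-person diagonal blocks are the phenotypic covariance
    ``Sigma_A + Sigma_C + Sigma_D + Sigma_E``.  The cross-twin block is
    ``Sigma_A + Sigma_C + Sigma_D`` for MZ pairs (who share all genetic
    effects) and ``0.5*Sigma_A + Sigma_C + 0.25*Sigma_D`` for DZ pairs (who
    share on average half of additive and a quarter of dominance effects).
    """
    zyg = str(zygosity).upper()
    if zyg not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    within = components.sigma_ph
    if zyg == "MZ":
        cross = components._sum(("A", "C", "D"))
    else:
        cross = (
            0.5 * components._sum(("A",))
            + components._sum(("C",))
            + 0.25 * components._sum(("D",))
        )
    top = np.hstack([within, cross])
    bot = np.hstack([cross.T, within])
    return np.vstack([top, bot])


def standardize_components(components: ComponentEstimates) -> pd.DataFrame:
    """Per-phenotype standardized variance shares h2, d2, c2, e2.

    Each share is the component's variance divided by the total phenotypic
    variance of that phenotype (conditional on covariates); shares sum to 1.
    Components absent from the group contribute a share of 0.
    """
    total = np.diag(components.sigma_ph)
    if np.any(total <= 0):
        bad = [lab for lab, t in zip(components.order, total) if t <= 0]
        raise ValueError(f"non-positive total variance for phenotype(s) {bad}")
    share_names = {"A": "h2", "D": "d2", "C": "c2", "E": "e2"}
    data = {}
    for comp, name in share_names.items():
        if comp in components.sigma:
            data[name] = np.diag(components.sigma[comp]) / total
        else:
            data[name] = np.zeros(3)
    df = pd.DataFrame(data, index=list(components.order.labels))
    return df[["h2", "d2", "c2", "e2"]]


@dataclass(frozen=True)
class RankDiagnostics:
    """Eigenvalues (descending) and numerical rank of a symmetric matrix."""

    eigenvalues: tuple[float, ...]
    rank: int
    tol: float

    @property
    def leading(self) -> float:
        return self.eigenvalues[0]


def rank_diagnostics(matrix, tol: float = DEFAULT_RANK_TOL) -> RankDiagnostics:
    """Eigenvalues and numerical rank at a relative tolerance.

    The rank counts eigenvalues exceeding ``tol`` times the largest
    eigenvalue.  The strict default suits exactly-structured matrices (a
    rank-1 single-factor C, a rank-2 predictors-only D); matrices transcribed
    from rounded published tables should use :data:`TRANSCRIPTION_TOL` to
    expose near-singularity, such as an additive-genetic matrix whose second
    eigenvalue is a fraction of a percent of the first.
    """
    s = _check_symmetric(matrix)
    w = np.linalg.eigvalsh(s)[::-1]
    lead = max(abs(w[0]), 1e-300)
    rank = int(np.sum(w > tol * lead))
    return RankDiagnostics(tuple(float(v) for v in w), rank, tol)


@dataclass
class TwinPairRecord:
    """One twin pair: zygosity, covariates, and six phenotype slots.

    Phenotype values use ``nan`` as the missing marker; at least one observed
    phenotype is required for the record to enter a likelihood.
    """

    pair_id: str
    zygosity: str
    sex1: int
    sex2: int
    age: float
    phenotypes1: tuple[float, float, float]
    phenotypes2: tuple[float, float, float]

    def __post_init__(self):
        zyg = str(self.zygosity).upper()
        if zyg not in ("MZ", "DZ"):
            raise DataError(f"pair {self.pair_id}: zygosity must be MZ or DZ, got {self.zygosity!r}")
        self.zygosity = zyg
        for s in (self.sex1, self.sex2):
            if s not in (0, 1):
                raise DataError(f"pair {self.pair_id}: sex must be coded 0/1, got {s!r}")


class TwinDataset:
    """Wide per-pair twin table: one row per pair, six phenotype columns.

    Backed by a :class:`pandas.DataFrame` with columns ``pair_id``,
    ``zygosity``, ``sex1``, ``sex2``, ``age``, and ``<label>1``/``<label>2``
    for each phenotype in ``order``.  Missing phenotype values are ``nan``.
    """

    META_COLUMNS = ("pair_id", "zygosity", "sex1", "sex2", "age")

    def __init__(self, df: pd.DataFrame, order: PhenotypeOrder = DEFAULT_ORDER):
        self.order = order
        cols = list(self.META_COLUMNS) + self.phenotype_columns(order)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DataError(f"dataset is missing required columns {missing}")
        df = df.loc[:, cols].reset_index(drop=True).copy()
        zyg = df["zygosity"].astype(str).str.upper()
        bad = ~zyg.isin(["MZ", "DZ"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"row {row}: unknown zygosity label {df['zygosity'].iloc[row]!r}"
            )
        df["zygosity"] = zyg
        if df["pair_id"].duplicated().any():
            dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
            raise DataError(f"duplicate pair id {dup!r}")
        for c in ("sex1", "sex2"):
            vals = df[c].to_numpy()
            if not np.isin(vals, [0, 1]).all():
                raise DataError(f"column {c} must be coded 0/1")
        self.df = df

    @staticmethod
    def phenotype_columns(order: PhenotypeOrder) -> list[str]:
        return [f"{lab}{t}" for t in (1, 2) for lab in order.labels]

    @classmethod
    def from_records(
        cls, records: Iterable[TwinPairRecord], order: PhenotypeOrder = DEFAULT_ORDER
    ) -> "TwinDataset":
        rows = []
        for r in records:
            row = {
                "pair_id": r.pair_id,
                "zygosity": r.zygosity,
                "sex1": r.sex1,
                "sex2": r.sex2,
                "age": r.age,
            }
            for lab, v in zip(order.labels, r.phenotypes1):
                row[f"{lab}1"] = v
            for lab, v in zip(order.labels, r.phenotypes2):
                row[f"{lab}2"] = v
            rows.append(row)
        return cls(pd.DataFrame(rows), order)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    def counts_by_zygosity(self) -> dict[str, int]:
        c = self.df["zygosity"].value_counts()
        return {"MZ": int(c.get("MZ", 0)), "DZ": int(c.get("DZ", 0))}

    def phenotype_matrix(self) -> np.ndarray:
        """(n, 6) float array: twin-1 triple then twin-2 triple, nan = missing."""
        return self.df[self.phenotype_columns(self.order)].to_numpy(dtype=float)

    def subset(self, mask) -> "TwinDataset":
        return TwinDataset(self.df.loc[np.asarray(mask)].reset_index(drop=True), self.order)

    def drop_unobserved(self) -> tuple["TwinDataset", int]:
        """Drop pairs with all six phenotypes missing; return (dataset, n_dropped)."""
        y = self.phenotype_matrix()
        keep = ~np.isnan(y).all(axis=1)
        return self.subset(keep), int((~keep).sum())
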