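"""Sum-to-zero-coded factorial linear model: OLS fit and type-III ANOVA.

Type-III sums of squares test each effect after removing all others, which is
only meaningful under a coding whose columns are centred over the factor
levels.  Deviation (sum-to-zero) coding is therefore mandatory here: each
k-level factor contributes k-1 columns, the first k-1 levels get an indicator
and the last level -1 in every column.  Interaction columns are elementwise
products of the parent main-effect columns, and covariates are centred at
their grand mean so that the intercept is the grand-mean prediction.

Type-III SS are computed by full-vs-reduced refits (drop the effect's columns,
refit, difference the residual sums of squares), which is algebraically
identical to the hypothesis-matrix route and easy to verify independently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Cell, ConfigurationError, FactorialDataset

__all__ = [
    "RankDeficiencyError",
    "SaturationError",
    "DesignMatrix",
    "LinearModelFit",
    "AnovaTable",
    "build_design",
    "fit_ols",
    "anova_type3",
]


class RankDeficiencyError(ValueError):
    """The design matrix is singular (typically an empty cell)."""


class SaturationError(ValueError):
    """No residual degrees of freedom left to estimate error variance."""


def _level_codes(levels: Sequence[str]) -> dict[str, np.ndarray]:
    """Sum-to-zero contrast codes: level -> vector of length k-1."""
    k = len(levels)
    codes = {}
    for i, level in enumerate(levels):
        v = np.zeros(k - 1)
        if i < k - 1:
            v[i] = 1.0
        else:
            v[:] = -1.0
        codes[level] = v
    return codes


@dataclass
class DesignMatrix:
    """Model matrix plus the metadata needed to rebuild prediction rows."""

    X: np.ndarray
    columns: list[str]
    term_map: dict[str, list[int]]  # effect name -> column indices
    factors: dict[str, list[str]]
    covariates: list[str]
    covariate_means: dict[str, float]
    interaction_terms: list[tuple[str, ...]]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def row(
        self,
        levels: Mapping[str, str],
        covariate_values: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """One prediction row: given level per factor, covariates centred.

        Covariate values default to the grand mean (i.e. a centred value of
        zero); supplied values are centred with the training means.
        """
        parts = [np.ones(1)]
        coded: dict[str, np.ndarray] = {}
        for f, lv in self.factors.items():
            if levels[f] not in lv:
                raise ConfigurationError(f"unknown level {levels[f]!r} for factor {f!r}")
            coded[f] = _level_codes(lv)[levels[f]]
            parts.append(coded[f])
        for term in self.interaction_terms:
            prod = coded[term[0]]
            for f in term[1:]:
                prod = np.einsum("i,j->ij", prod, coded[f]).ravel()
            parts.append(prod)
        for c in self.covariates:
            raw = covariate_values.get(c, self.covariate_means[c]) if covariate_values else self.covariate_means[c]
            parts.append(np.array([raw - self.covariate_means[c]]))
        return np.concatenate(parts)


def build_design(
    data: FactorialDataset,
    include_interactions: bool | int = True,
) -> DesignMatrix:
    """Build the sum-to-zero design: intercept, mains, interactions, covariates.

    ``include_interactions`` may be True (all orders), False (additive model),
    or an integer maximum interaction order.
    """
    factors = data.factors
    names = list(factors)
    if include_interactions is True:
        max_order = len(names)
    elif include_interactions is False:
        max_order = 1
    else:
        max_order = int(include_interactions)

    if max_order > 1:
        occupied = set(data.cell_index())
        for cell in data.cell_labels():
            if cell not in occupied:
                raise RankDeficiencyError(
                    f"cell {dict(zip(names, cell))} is empty; interactions are "
                    "not estimable with empty cells"
                )

    n = data.n
    cols: list[np.ndarray] = [np.ones(n)]
    col_names: list[str] = ["(Intercept)"]
    term_map: dict[str, list[int]] = {"(Intercept)": [0]}

    coded_cols: dict[str, np.ndarray] = {}  # factor -> (n, k-1) matrix
    for f in names:
        codes = _level_codes(factors[f])
        M = np.vstack([codes[l] for l in data.frame[f].astype(str)])
        coded_cols[f] = M
        idx = list(range(len(col_names), len(col_names) + M.shape[1]))
        term_map[f] = idx
        for j, lvl in enumerate(factors[f][:-1]):
            col_names.append(f"{f}[S.{lvl}]")
        cols.append(M)

    interaction_terms: list[tuple[str, ...]] = []
    for order in range(2, max_order + 1):
        for term in itertools.combinations(names, order):
            prod = coded_cols[term[0]]
            for f in term[1:]:
                prod = np.einsum("ni,nj->nij", prod, coded_cols[f]).reshape(n, -1)
            interaction_terms.append(term)
            idx = list(range(len(col_names), len(col_names) + prod.shape[1]))
            term_map[":".join(term)] = idx
            col_names.extend(f"{':'.join(term)}[{j}]" for j in range(prod.shape[1]))
            cols.append(prod)

    covariate_means: dict[str, float] = {}
    for c in data.covariates:
        x = data.frame[c].to_numpy(dtype=float)
        covariate_means[c] = float(np.mean(x))
        term_map[c] = [len(col_names)]
        col_names.append(c)
        cols.append((x - covariate_means[c])[:, None])

    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            "design matrix is rank-deficient; check for empty cells or "
            "collinear covariates"
        )
    return DesignMatrix(
        X=X,
        columns=col_names,
        term_map=term_map,
        factors={f: list(l) for f, l in factors.items()},
        covariates=list(data.covariates),
        covariate_means=covariate_means,
        interaction_terms=interaction_terms,
    )


@dataclass
class LinearModelFit:
    """OLS fit: coefficients, their covariance (= MSE * (X'X)^-1), MSE, df."""

    coefficients: np.ndarray
    coef_cov: np.ndarray
    mse: float
    df_error: int
    rss: float
    design: DesignMatrix
    data: FactorialDataset
    xtx_inv: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def predict_row(self, row: np.ndarray) -> float:
        return float(row @ self.coefficients)


def fit_ols(design: DesignMatrix, data: FactorialDataset) -> LinearModelFit:
    """Ordinary least squares on the given design.

    Raises :class:`SaturationError` when there are no residual degrees of
    freedom (need at least two records in some cell).
    """
    X = design.X
    y = data.response_values
    n, p = X.shape
    if n - p <= 0:
        raise SaturationError(
            f"no residual df: N={n}, p={p}; at least 2 records per cell are needed"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise RankDeficiencyError("design matrix is singular in fit")
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_error = n - p
    mse = rss / df_error
    xtx_inv = np.linalg.inv(X.T @ X)
    return LinearModelFit(
        coefficients=beta,
        coef_cov=mse * xtx_inv,
        mse=mse,
        df_error=df_error,
        rss=rss,
        design=design,
        data=data,
        xtx_inv=xtx_inv,
    )


@dataclass
class AnovaTable:
    """Type-III ANOVA rows: (effect, SS, df, F, p), plus the residual row."""

    rows: list[tuple[str, float, int, float, float]]
    df_error: int
    mse: float

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.rows, columns=["effect", "ss", "df", "F", "p"])
        resid = pd.DataFrame(
            [("Residual", self.mse * self.df_error, self.df_error, np.nan, np.nan)],
            columns=out.columns,
        )
        return pd.concat([out, resid], ignore_index=True)

    def __getitem__(self, effect: str) -> dict[str, float]:
        for name, ss, df, F, p in self.rows:
            if name == effect:
                return {"ss": ss, "df": df, "F": F, "p": p}
        raise KeyError(effect)

    @property
    def effects(self) -> list[str]:
        return [r[0] for r in self.rows]


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_type3(fit: LinearModelFit) -> AnovaTable:
    """Type-III table by full-vs-reduced refits, one per non-intercept effect.

    For each effect, SS = RSS(model without that effect's columns, all other
    columns retained) - RSS(full model); F = (SS/df)/MSE with p from
    F(df_effect, df_error).
    """
    design = fit.design
    X = design.X
    y = fit.data.response_values
    rows = []
    for effect, idx in design.term_map.items():
        if effect == "(Intercept)":
            continue
        keep = [j for j in range(design.p) if j not in set(idx)]
        rss_red = _rss(X[:, keep], y)
        ss = max(rss_red - fit.rss, 0.0)
        df = len(idx)
        if fit.mse > 0:
            F = (ss / df) / fit.mse
            p = float(stats.f.sf(F, df, fit.df_error))
        else:
            F = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        rows.append((effect, ss, df, float(F), p))
    return AnovaTable(rows=rows, df_error=fit.df_error, mse=fit.mse)
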