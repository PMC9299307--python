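"""Estimated marginal means, CI-overlap decisions, and model-based contrasts.

An estimated marginal mean (EMM) is the model prediction averaged over a
reference grid: equal weights across the levels of every factor not in the
requested grid, covariates held at their grand mean.  Equal weighting — not
observed-frequency weighting — is what makes EMMs "cleansed" of imbalance and
of the influence of nuisance factors.  Standard errors propagate from the OLS
coefficient covariance, and confidence intervals use the central t critical
value at the model's error df, the same error term the ANOVA uses.

The overlap rule treats two independent means as credibly different when
their CIs overlap by less than a threshold fraction (default 0.25) of the
full CI length.  When the two intervals differ in length the denominator is
the mean of the two full lengths.  For equal-SE means at large df the 0.25
boundary corresponds to a two-sided difference p of about 0.037.  The rule
presumes independent means (between-subjects designs); repeated-measures data
are out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Cell, ConfigurationError, SpecificationError
from .factorial_lm import LinearModelFit
from .posthoc import adjust_pvalues

__all__ = [
    "EMMTable",
    "OverlapDecision",
    "estimate_emms",
    "ci_overlap_fraction",
    "overlap_decisions",
    "emm_contrasts",
]


@dataclass
class EMMTable:
    """Per-cell EMM, SE and CI over the grid of the requested factors."""

    by: list[str]
    cells: list[Cell]
    emm: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float
    df: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame([dict(zip(self.by, c)) for c in self.cells])
        out["emm"] = self.emm
        out["se"] = self.se
        out["ci_low"] = self.ci_low
        out["ci_high"] = self.ci_high
        out["level"] = self.level
        out["df"] = self.df
        return out

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class OverlapDecision:
    """CI-overlap verdict for one unordered cell pair.

    ``flagged`` is True exactly when the overlap fraction is below the
    threshold, i.e. the pair shows reasonable evidence of a difference.
    """

    pair: tuple[Cell, Cell]
    overlap_fraction: float
    threshold: float

    @property
    def flagged(self) -> bool:
        return self.overlap_fraction < self.threshold


def _grid_rows(fit: LinearModelFit, by: Sequence[str]) -> tuple[list[Cell], np.ndarray]:
    """Prediction rows for the `by` grid, averaged over the other factors."""
    design = fit.design
    for f in by:
        if f not in design.factors:
            raise ConfigurationError(
                f"factor {f!r} is not in the model (has: {list(design.factors)})"
            )
    others = [f for f in design.factors if f not in by]
    cells = list(itertools.product(*(design.factors[f] for f in by)))
    rows = np.empty((len(cells), design.p))
    other_grid = list(itertools.product(*(design.factors[f] for f in others)))
    for i, cell in enumerate(cells):
        acc = np.zeros(design.p)
        for combo in other_grid:
            levels = dict(zip(by, cell)) | dict(zip(others, combo))
            acc += design.row(levels)
        rows[i] = acc / len(other_grid)
    return cells, rows


def estimate_emms(
    fit: LinearModelFit,
    by: Sequence[str] | None = None,
    level: float = 0.95,
) -> EMMTable:
    """EMMs with SEs and t confidence intervals over the `by` factor grid.

    ``by`` defaults to all factors in the model (the full cell grid).
    """
    by = list(by) if by is not None else list(fit.design.factors)
    cells, G = _grid_rows(fit, by)
    emm = G @ fit.coefficients
    var = np.einsum("ij,jk,ik->i", G, fit.coef_cov, G)
    se = np.sqrt(np.maximum(var, 0.0))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, fit.df_error))
    return EMMTable(
        by=by,
        cells=cells,
        emm=emm,
        se=se,
        ci_low=emm - tcrit * se,
        ci_high=emm + tcrit * se,
        level=level,
        df=fit.df_error,
    )


def ci_overlap_fraction(a: Sequence[float], b: Sequence[float]) -> float:
    """Overlap of two intervals as a fraction of their mean full length.

    Returns max(0, overlap length) / mean(length a, length b), capped at 1.
    Two zero-length intervals give 1.0 if they are the same point, else 0.0.
    """
    lo_a, hi_a = float(a[0]), float(a[1])
    lo_b, hi_b = float(b[0]), float(b[1])
    if lo_a > hi_a or lo_b > hi_b:
        raise ValueError("interval bounds must satisfy low <= high")
    mean_len = ((hi_a - lo_a) + (hi_b - lo_b)) / 2.0
    if mean_len == 0.0:
        return 1.0 if lo_a == lo_b else 0.0
    overlap = min(hi_a, hi_b) - max(lo_a, lo_b)
    return min(max(overlap, 0.0) / mean_len, 1.0)


def overlap_decisions(emms: EMMTable, threshold: float = 0.25) -> list[OverlapDecision]:
    """One decision per unordered cell pair of the EMM grid."""
    if len(emms) < 2:
        raise ValueError("need at least 2 cells to compare")
    out = []
    for i, j in itertools.combinations(range(len(emms)), 2):
        frac = ci_overlap_fraction(
            (emms.ci_low[i], emms.ci_high[i]), (emms.ci_low[j], emms.ci_high[j])
        )
        out.append(
            OverlapDecision(
                pair=(emms.cells[i], emms.cells[j]),
                overlap_fraction=frac,
                threshold=threshold,
            )
        )
    return out


def overlap_frame(decisions: Sequence[OverlapDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": " vs ".join(":".join(c) for c in d.pair),
                "overlap_fraction": d.overlap_fraction,
                "threshold": d.threshold,
                "flagged": d.flagged,
            }
            for d in decisions
        ]
    )


def emm_contrasts(
    fit: LinearModelFit,
    contrasts: Sequence[tuple[Cell, Cell]] | Sequence[Sequence[float]],
    correction: str = "none",
    by: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Model-based contrasts among EMM grid cells, with optional correction.

    Each contrast is either a pair of cells (tested as cell_a - cell_b) or an
    arbitrary vector of cell weights summing to zero (e.g. +1, -1/3, -1/3,
    -1/3 for one-vs-rest).  The SE comes from the whole-model coefficient
    covariance, t uses the model error df, and p values are corrected over
    the supplied family with :func:`adjust_pvalues`.
    """
    by = list(by) if by is not None else list(fit.design.factors)
    cells, G = _grid_rows(fit, by)
    cell_pos = {c: i for i, c in enumerate(cells)}
    vectors: list[np.ndarray] = []
    labels: list[str] = []
    for con in contrasts:
        if (
            len(con) == 2
            and isinstance(con[0], tuple)
            and all(isinstance(x, str) for x in con[0])
        ):
            a, b = con  # type: ignore[misc]
            for c in (a, b):
                if c not in cell_pos:
                    raise ConfigurationError(f"unknown cell {c!r}")
            v = np.zeros(len(cells))
            v[cell_pos[a]] += 1.0
            v[cell_pos[b]] -= 1.0
            labels.append(f"{':'.join(a)} - {':'.join(b)}")
        else:
            v = np.asarray(con, dtype=float)
            if v.shape != (len(cells),):
                raise SpecificationError(
                    f"contrast vector must have {len(cells)} weights, got {v.shape}"
                )
            labels.append("[" + ", ".join(f"{w:g}" for w in v) + "]")
        if abs(v.sum()) > 1e-10:
            raise SpecificationError(f"contrast weights must sum to zero (got {v.sum():g})")
        vectors.append(v)
    C = np.vstack(vectors)
    L = C @ G
    est = L @ fit.coefficients
    var = np.einsum("ij,jk,ik->i", L, fit.coef_cov, L)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p_raw = 2.0 * stats.t.sf(np.abs(t), fit.df_error)
    p_raw = np.where(se > 0, p_raw, np.where(np.abs(est) > 0, 0.0, 1.0))
    p_adj = adjust_pvalues(list(p_raw), method=correction)
    return pd.DataFrame(
        {
            "contrast": labels,
            "estimate": est,
            "se": se,
            "t": t,
            "df": fit.df_error,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "method": correction,
        }
    )
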