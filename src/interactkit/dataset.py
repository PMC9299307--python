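"""Data model and I/O for long-format factorial data.

A :class:`FactorialDataset` holds one row per observation: a level for each
categorical factor, optionally one or more numeric covariates, and a numeric
response.  This long format maps one-to-one onto the linear model; wide
layouts must be reshaped by the caller.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("interactkit")

__all__ = [
    "ConfigurationError",
    "ParseError",
    "SpecificationError",
    "FactorialDataset",
    "CellSummary",
    "load_csv",
    "summarize_cells",
]


class ConfigurationError(ValueError):
    """A column, factor, method or option named by the user does not exist."""


class ParseError(ValueError):
    """Input data could not be interpreted (bad value, bad syntax)."""


class SpecificationError(ValueError):
    """A user-supplied contrast or hypothesis is malformed."""


Cell = tuple[str, ...]


@dataclass(frozen=True)
class CellSummary:
    """Raw (model-free) summary of one occupied design cell.

    ``observed_se`` is the sample standard deviation divided by sqrt(n); it is
    ``nan`` when n == 1 (undefined, deliberately not zero).
    """

    cell: Cell
    n: int
    observed_mean: float
    observed_se: float


@dataclass
class FactorialDataset:
    """Long-format factorial data: factors, optional covariates, one response.

    ``factors`` maps each factor name to its ordered level labels (first
    appearance order unless an explicit order was supplied).  ``frame`` holds
    the validated observations, one per row.
    """

    frame: pd.DataFrame
    factors: dict[str, list[str]]
    response: str
    covariates: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self._validate()

    # -- construction ----------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        factor_names: Sequence[str],
        response_name: str,
        covariate_names: Sequence[str] = (),
        level_order: Mapping[str, Sequence[str]] | None = None,
    ) -> "FactorialDataset":
        """Validate a raw dataframe and build a dataset.

        Rows with a missing value in any used column are dropped (listwise
        deletion) with a logged count.  Non-numeric response or covariate
        values raise :class:`ParseError` naming the offending row.
        """
        if frame.shape[0] == 0:
            raise ParseError("input contains no data rows")
        used = list(factor_names) + list(covariate_names) + [response_name]
        missing = [c for c in used if c not in frame.columns]
        if missing:
            raise ConfigurationError(
                f"column(s) {missing} not found; available: {list(frame.columns)}"
            )
        sub = frame[used].copy()
        for col in list(covariate_names) + [response_name]:
            coerced = pd.to_numeric(sub[col], errors="coerce")
            bad = coerced.isna() & sub[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"non-numeric value {sub[col].iloc[row]!r} in column "
                    f"{col!r} at data row {row}"
                )
            if np.isinf(coerced.to_numpy(dtype=float, na_value=np.nan)).any():
                row = int(np.flatnonzero(np.isinf(coerced.to_numpy(float)))[0])
                raise ParseError(f"non-finite value in column {col!r} at data row {row}")
            sub[col] = coerced
        n_before = len(sub)
        sub = sub.dropna(axis=0, how="any").reset_index(drop=True)
        n_dropped = n_before - len(sub)
        if n_dropped:
            logger.info("dropped %d row(s) with missing values", n_dropped)
        if len(sub) == 0:
            raise ParseError("all rows contained missing values")
        factors: dict[str, list[str]] = {}
        for f in factor_names:
            sub[f] = sub[f].astype(str)
            seen = list(dict.fromkeys(sub[f]))
            if level_order and f in level_order:
                order = [str(l) for l in level_order[f]]
                unknown = sorted(set(seen) - set(order))
                if unknown:
                    raise ConfigurationError(
                        f"levels {unknown} of factor {f!r} missing from supplied order"
                    )
                seen = [l for l in order if l in seen]
            factors[f] = seen
        return cls(
            frame=sub,
            factors=factors,
            response=response_name,
            covariates=list(covariate_names),
            n_dropped=n_dropped,
        )

    def _validate(self) -> None:
        for f, levels in self.factors.items():
            if f not in self.frame.columns:
                raise ConfigurationError(f"factor column {f!r} missing from frame")
            observed = set(self.frame[f].astype(str))
            if not observed <= set(levels):
                raise ConfigurationError(
                    f"factor {f!r} has records at unknown level(s) {observed - set(levels)}"
                )
        y = self.frame[self.response].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ParseError(f"response {self.response!r} contains non-finite values")
        for c in self.covariates:
            x = self.frame[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(x)):
                raise ParseError(f"covariate {c!r} contains non-finite values")

    # -- basic introspection ---------------------------------------------

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def response_values(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    def cell_labels(self, factors: Sequence[str] | None = None) -> list[Cell]:
        """All cells of the (sub)grid, in level product order, occupied or not."""
        names = list(factors) if factors is not None else self.factor_names
        for f in names:
            if f not in self.factors:
                raise ConfigurationError(f"unknown factor {f!r}")
        return list(itertools.product(*(self.factors[f] for f in names)))

    def cell_index(self, factors: Sequence[str] | None = None) -> pd.Series:
        """Per-record cell membership as tuples over the named factors."""
        names = list(factors) if factors is not None else self.factor_names
        return pd.Series(
            list(zip(*(self.frame[f].astype(str) for f in names))),
            index=self.frame.index,
        )

    def occupied_cells(self) -> list[Cell]:
        present = set(self.cell_index())
        return [c for c in self.cell_labels() if c in present]

    def min_cell_n(self) -> int:
        return int(self.cell_index().value_counts().min())

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_csv(
    path: str | Path,
    factor_names: Sequence[str],
    response_name: str,
    covariate_names: Sequence[str] = (),
    level_order: Mapping[str, Sequence[str]] | None = None,
) -> FactorialDataset:
    """Read a long-format CSV (RFC-4180, header row required) into a dataset."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, dtype=object, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path} is empty") from None
    return FactorialDataset.from_frame(
        frame, factor_names, response_name, covariate_names, level_order
    )


def summarize_cells(data: FactorialDataset) -> list[CellSummary]:
    """Observed per-cell summaries (mean and SE from raw records only).

    Output order follows the factor-level grid; unoccupied cells are absent.
    Invariant to record order.  A singleton cell reports SE = nan.
    """
    idx = data.cell_index()
    y = data.response_values
    out = []
    groups: dict[Cell, np.ndarray] = {
        cell: y[(idx == cell).to_numpy()] for cell in set(idx)
    }
    for cell in data.cell_labels():
        if cell not in groups:
            continue
        v = groups[cell]
        n = len(v)
        se = float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        out.append(CellSummary(cell=cell, n=n, observed_mean=float(np.mean(v)), observed_se=se))
    return out
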