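"""Classical follow-up path: pairwise t-tests on observed cell data.

These are the widely used — and widely criticised — independent two-sample
tests between every pair of design cells, each using only the two cells' raw
data (so each test has its own pooled variance and df, disconnected from the
factorial model's error term).  They exist here as the comparison point for
the model-based contrasts in :mod:`interactkit.emm`: observed and
model-estimated errors are always different, and that difference is what the
false-positive-risk simulation measures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import Cell, ConfigurationError, FactorialDataset

__all__ = ["PairwiseResult", "pairwise_observed", "adjust_pvalues", "CORRECTIONS"]

CORRECTIONS = ("bonferroni", "sidak", "holm", "none")


@dataclass(frozen=True)
class PairwiseResult:
    """One observed-means pairwise test: estimate, t, df, raw/adjusted p."""

    pair: tuple[Cell, Cell]
    estimate: float
    t: float
    df: float
    p_raw: float
    p_adj: float
    method: str
    m: int


def adjust_pvalues(
    p: Sequence[float], method: str = "bonferroni", m: int | None = None
) -> list[float]:
    """Multiplicity-adjusted p values (Bonferroni, Sidak, Holm, or none).

    Bonferroni: min(1, m*p).  Sidak: 1 - (1-p)^m.  Holm: step-down
    Bonferroni.  ``m`` defaults to the number of p values supplied; a larger
    family size may be given explicitly.  Output order matches input order.
    """
    p = [float(x) for x in p]
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than number of p values {len(p)}")
    method = method.lower()
    if method == "none":
        return p
    if method == "bonferroni":
        return [min(1.0, m * x) for x in p]
    if method == "sidak":
        return [1.0 - (1.0 - x) ** m for x in p]
    if method == "holm":
        order = np.argsort(p, kind="stable")
        adj = np.empty(len(p))
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[idx]))
            adj[idx] = running
        return adj.tolist()
    raise ConfigurationError(
        f"unknown correction {method!r}; supported: {', '.join(CORRECTIONS)}"
    )


def _two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float, float]:
    """Two-sample t (pooled by default, Welch optional): (t, df, p).

    Degenerate case — zero variance in both samples and equal means — is
    reported as t=0, p=1 rather than NaN.
    """
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math.inf if diff > 0 else -math.inf, float(na + nb - 2), 0.0
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
    t = diff / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def pairwise_observed(
    data: FactorialDataset,
    correction: str = "bonferroni",
    welch: bool = False,
    alpha_family: int | None = None,
) -> list[PairwiseResult]:
    """Independent two-sample t-tests between all occupied cell pairs.

    Each test uses only the two cells' raw records (pooled variance by
    default; Welch behind a flag); the correction is applied over the full
    family of unordered pairs unless ``alpha_family`` overrides the size.
    """
    cells = data.occupied_cells()
    if len(cells) < 2:
        raise ValueError("need at least 2 occupied cells")
    idx = data.cell_index()
    y = data.response_values
    samples = {c: y[(idx == c).to_numpy()] for c in cells}
    for c, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"cell {c!r} has n={len(v)} < 2")
    pairs = list(itertools.combinations(cells, 2))
    m = alpha_family if alpha_family is not None else len(pairs)
    stats_raw = [_two_sample_t(samples[a], samples[b], welch) for a, b in pairs]
    p_adj = adjust_pvalues([s[2] for s in stats_raw], method=correction, m=m)
    return [
        PairwiseResult(
            pair=(a, b),
            estimate=float(samples[a].mean() - samples[b].mean()),
            t=t,
            df=df,
            p_raw=p,
            p_adj=pa,
            method=correction,
            m=m,
        )
        for (a, b), (t, df, p), pa in zip(pairs, stats_raw, p_adj)
    ]
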