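"""Synthetic-data generators for the worked examples and the null worlds.

Three generators:

* :func:`generate_example1` — a balanced 2 (group: control/lesion) x 2
  (stimulus: neutral/fearful) arousal experiment, n = 50 per cell.  True cell
  means are the published observed means of the worked example (0.624, 0.589,
  0.755, 0.651) and the residual sd is the value those printed observed SEs
  imply, sqrt(50 * mean(SE^2)) ~= 0.0545.  In this balanced, covariate-free
  design the EMMs coincide with the observed cell means while the EMM SEs are
  all sqrt(MSE/50) — the equality/inequality the toolkit demonstrates.
* :func:`generate_example2` — the same 2x2 plus a dichotomous working-memory
  factor with a strong main effect, no interactions with the other factors,
  and a deliberately unbalanced allocation of working-memory levels across
  the group x stimulus cells.  The imbalance makes the observed cell means
  diverge from the EMMs, which average the working-memory levels equally.
* :func:`generate_null` — additive-null data for the false-positive-risk
  simulation: purely additive true cell means (zero interaction contrast)
  with iid normal noise.

Exact replication of any published dataset is not attempted (the original
random draws are not printed); the generators target the printed summary
structure instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import FactorialDataset

__all__ = [
    "GeneratorSpec",
    "EXAMPLE1_MEANS",
    "EXAMPLE1_OBSERVED_SES",
    "EXAMPLE1_SIGMA",
    "generate_example1",
    "generate_example2",
    "generate_null",
]

# Published worked-example cell means (balanced 2x2, n=50/cell) and the
# printed observed SEs they come with; sigma is the residual sd those SEs
# imply: SE_obs = sd_cell/sqrt(50), so sigma^2 = 50 * mean(SE_obs^2).
EXAMPLE1_MEANS: dict[tuple[str, str], float] = {
    ("control", "neutral"): 0.624,
    ("lesion", "neutral"): 0.589,
    ("control", "fearful"): 0.755,
    ("lesion", "fearful"): 0.651,
}
EXAMPLE1_OBSERVED_SES = (0.010, 0.007, 0.008, 0.005)
EXAMPLE1_SIGMA = math.sqrt(50 * float(np.mean(np.square(EXAMPLE1_OBSERVED_SES))))


@dataclass
class GeneratorSpec:
    """Ground truth for a factorial generator: means, noise, allocation."""

    factors: dict[str, list[str]]
    cell_means: dict[tuple[str, ...], float]
    sigma: float
    n_per_cell: int | dict[tuple[str, ...], int]
    response: str = "y"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        ns = (
            self.n_per_cell.values()
            if isinstance(self.n_per_cell, dict)
            else [self.n_per_cell]
        )
        if any(n < 2 for n in ns):
            raise ValueError("need n >= 2 per cell")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _realize(spec: GeneratorSpec, rng: np.random.Generator) -> FactorialDataset:
    names = list(spec.factors)
    level_cols: list[list[str]] = [[] for _ in names]
    chunks = []
    for cell, mu in spec.cell_means.items():
        n = spec.n_per_cell[cell] if isinstance(spec.n_per_cell, dict) else spec.n_per_cell
        chunks.append(mu + spec.sigma * rng.standard_normal(n))
        for col, level in zip(level_cols, cell):
            col.extend([level] * n)
    frame = pd.DataFrame(dict(zip(names, level_cols)))
    frame[spec.response] = np.concatenate(chunks)
    return FactorialDataset.from_frame(
        frame, names, spec.response, level_order=spec.factors
    )


def generate_example1(seed, n_per_cell: int = 50) -> FactorialDataset:
    """Balanced 2x2 arousal dataset at the worked example's ground truth."""
    spec = GeneratorSpec(
        factors={"group": ["control", "lesion"], "stimulus": ["neutral", "fearful"]},
        cell_means=dict(EXAMPLE1_MEANS),
        sigma=EXAMPLE1_SIGMA,
        n_per_cell=n_per_cell,
        response="arousal",
    )
    return _realize(spec, _as_rng(seed))


# Group x stimulus ground-truth means for example 2 (the published EMMs of the
# three-way worked example), working-memory main effect on top.
EXAMPLE2_BASE_MEANS: dict[tuple[str, str], float] = {
    ("control", "neutral"): 1.281,
    ("lesion", "neutral"): 0.981,
    ("control", "fearful"): 2.274,
    ("lesion", "fearful"): 1.086,
}


def generate_example2(
    seed,
    n_group_stim: int = 50,
    imbalance: float = 0.7,
    wm_effect: float = 1.2,
    sigma: float = 0.9,
) -> FactorialDataset:
    """2x2x2 dataset with an influential, unbalanced working-memory factor.

    Within each group x stimulus cell (n = ``n_group_stim``), the share of
    high-working-memory subjects is ``imbalance`` in the control cells and
    ``1 - imbalance`` in the lesion cells.  Working memory shifts the response
    by +/- ``wm_effect``/2 and interacts with nothing, so the group x stimulus
    EMMs (equal-weight average over working memory) stay at the base means
    while the observed cell means are pulled toward the over-represented
    working-memory level.  ``imbalance=0.5`` restores balance and the
    observed-mean/EMM identity.
    """
    if not 0.0 < imbalance < 1.0:
        raise ValueError("imbalance must be in (0, 1)")
    factors = {
        "group": ["control", "lesion"],
        "stimulus": ["neutral", "fearful"],
        "wm": ["low", "high"],
    }
    cell_means: dict[tuple[str, ...], float] = {}
    alloc: dict[tuple[str, ...], int] = {}
    for (g, s), base in EXAMPLE2_BASE_MEANS.items():
        p_high = imbalance if g == "control" else 1.0 - imbalance
        n_high = int(round(n_group_stim * p_high))
        n_high = min(max(n_high, 2), n_group_stim - 2)
        for wm, sign, n in (("low", -1, n_group_stim - n_high), ("high", +1, n_high)):
            cell_means[(g, s, wm)] = base + sign * wm_effect / 2.0
            alloc[(g, s, wm)] = n
    spec = GeneratorSpec(
        factors=factors,
        cell_means=cell_means,
        sigma=sigma,
        n_per_cell=alloc,
        response="arousal",
    )
    return _realize(spec, _as_rng(seed))


def generate_null(
    design: Sequence[int],
    delta: float,
    n_per_cell: int,
    sigma: float = 1.0,
    seed=None,
) -> FactorialDataset:
    """Additive-null factorial data: no interaction, optional main effects.

    True cell means come from :func:`interactkit.fpr_sim.make_null_means`
    (mu_ij = alpha_i + beta_j with adjacent effects spaced by ``delta``), so
    every interaction contrast of the truth is exactly zero for any delta.
    """
    from .fpr_sim import make_null_means  # local import avoids a cycle

    mu = make_null_means(design, delta)
    names = ["A", "B", "C"][: mu.ndim]
    factors = {
        name: [f"{name.lower()}{i + 1}" for i in range(k)]
        for name, k in zip(names, mu.shape)
    }
    cell_means = {
        tuple(factors[n][i] for n, i in zip(names, idx)): float(mu[idx])
        for idx in np.ndindex(mu.shape)
    }
    spec = GeneratorSpec(
        factors=factors, cell_means=cell_means, sigma=sigma, n_per_cell=n_per_cell
    )
    return _realize(spec, _as_rng(seed))
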