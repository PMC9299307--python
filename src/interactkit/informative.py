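"""Bayesian informative hypotheses over factorial cell means.

A research expectation is written as inequality constraints among the cell
means, e.g. ``(cf - cn) > (lf - ln)`` for "the fearful-minus-neutral effect
is larger in controls".  Each hypothesis H is scored by

* fit ``f``: the probability that the posterior of the cell means satisfies
  all constraints, and
* complexity ``c``: the probability that an exchangeable reference
  distribution satisfies them (how easy the constraints are to satisfy by
  chance — a full ordering of k means has c = 1/k!, a single inequality 1/2).

Their ratio ``f/c`` is the Bayes factor of H against the unconstrained
hypothesis Hu, and normalising the Bayes factors over the compared set (with
equal prior model weights) gives posterior model probabilities summing to 1.

The posterior is a multivariate-normal approximation centred at the EMMs with
covariance propagated from the OLS coefficient covariance; both probabilities
are estimated by Monte Carlo, deterministically given the seed.  Only strict
inequality constraints are supported (no equality or about-equality bands).

Constraint syntax: cell labels (factor levels joined by ``:``), ``+``/``-``
arithmetic, parentheses, chains ``a < b < c`` (one sense per chain), and
comma groups ``(x, y) > (u, v)`` meaning every left member exceeds every
right member, with no constraint inside a group.  ``Hu`` or an empty string
is the unconstrained hypothesis.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ConfigurationError, ParseError
from .emm import _grid_rows
from .factorial_lm import LinearModelFit

__all__ = [
    "ConstraintSet",
    "PMPResult",
    "parse_hypothesis",
    "cell_posterior",
    "compute_pmps",
    "bf_vs_complement",
]


@dataclass
class ConstraintSet:
    """Inequality constraints c . mu > 0 over an ordered set of cell means."""

    cells: list[str]
    rows: np.ndarray  # (n_constraints, n_cells); empty (0, k) for Hu
    source_text: str = ""
    name: str | None = None

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.size == 0:
            self.rows = np.empty((0, len(self.cells)))
        if self.rows.shape[1] != len(self.cells):
            raise ValueError("constraint width does not match number of cells")
        if any(np.all(r == 0) for r in self.rows):
            raise ValueError("constraint rows must be non-zero")

    @property
    def is_unconstrained(self) -> bool:
        return self.rows.shape[0] == 0

    def satisfied(self, mu: np.ndarray) -> np.ndarray:
        """Boolean per draw (rows of ``mu``): all constraints strictly hold."""
        mu = np.atleast_2d(mu)
        if self.is_unconstrained:
            return np.ones(mu.shape[0], dtype=bool)
        return np.all(mu @ self.rows.T > 0, axis=1)


# -- hypothesis string parsing -----------------------------------------------

_NAME_PREFIX = re.compile(r"^\s*([A-Za-z]\w*)\s*[:=]")


def _tokenize(text: str, cells: list[str]) -> list[tuple[str, str, int]]:
    """(kind, value, position) tokens; labels matched longest-first."""
    labels = sorted(cells, key=len, reverse=True)
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        matched = None
        for lab in labels:
            if text.startswith(lab, i):
                matched = lab
                break
        if matched is not None:
            tokens.append(("label", matched, i))
            i += len(matched)
            continue
        if ch in "()+-<>,":
            kind = {"(": "open", ")": "close", ",": "comma", "<": "op", ">": "op"}.get(
                ch, "arith"
            )
            tokens.append((kind, ch, i))
            i += 1
            continue
        raise ParseError(
            f"unrecognised token at position {i}: {text[i:i + 12]!r} "
            f"(known cells: {', '.join(cells)})"
        )
    return tokens


class _ExprParser:
    """Recursive-descent parser for +/- combinations of cell labels."""

    def __init__(self, tokens, cells: list[str], text: str):
        self.toks = tokens
        self.pos = 0
        self.cells = cells
        self.index = {c: i for i, c in enumerate(cells)}
        self.text = text

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def error(self, msg: str):
        at = self.toks[self.pos][2] if self.pos < len(self.toks) else len(self.text)
        raise ParseError(f"{msg} at position {at} in {self.text!r}")

    def expr(self) -> np.ndarray:
        vec = self.term()
        while (tok := self.peek()) and tok[0] == "arith":
            self.pos += 1
            sign = 1.0 if tok[1] == "+" else -1.0
            vec = vec + sign * self.term()
        return vec

    def term(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            self.error("dangling operator")
        if tok[0] == "label":
            self.pos += 1
            v = np.zeros(len(self.cells))
            v[self.index[tok[1]]] = 1.0
            return v
        if tok[0] == "open":
            self.pos += 1
            v = self.expr()
            if not (t := self.peek()) or t[0] != "close":
                self.error("unbalanced parenthesis")
            self.pos += 1
            return v
        self.error(f"unexpected token {tok[1]!r}")

    def done(self) -> bool:
        return self.pos >= len(self.toks)


def _split_top(tokens, kinds: set[str]):
    """Split a token list at depth-0 tokens of the given kinds."""
    parts, seps, depth, cur = [], [], 0, []
    for tok in tokens:
        if tok[0] == "open":
            depth += 1
        elif tok[0] == "close":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced ')' at position {tok[2]}")
        if depth == 0 and tok[0] in kinds:
            parts.append(cur)
            seps.append(tok)
            cur = []
        else:
            cur.append(tok)
    if depth != 0:
        raise ParseError("unbalanced '('")
    parts.append(cur)
    return parts, seps


def _parse_side(tokens, cells: list[str], text: str) -> list[np.ndarray]:
    """One side of an inequality: a single expression or a comma group."""
    if not tokens:
        raise ParseError(f"empty side of inequality in {text!r}")
    # a parenthesised comma group: ( e1 , e2 , ... ) spanning the whole side
    def _outer_parens_span(toks) -> bool:
        if toks[0][0] != "open" or toks[-1][0] != "close":
            return False
        depth = 0
        for i, tok in enumerate(toks):
            depth += tok[0] == "open"
            depth -= tok[0] == "close"
            if depth == 0:
                return i == len(toks) - 1
        return False

    if _outer_parens_span(tokens):
        parts, seps = _split_top(tokens[1:-1], {"comma"})
        if len(parts) > 1:
            vecs = []
            for part in parts:
                p = _ExprParser(part, cells, text)
                vecs.append(p.expr())
                if not p.done():
                    p.error("trailing tokens in group member")
            return vecs
    p = _ExprParser(tokens, cells, text)
    vec = p.expr()
    if not p.done():
        p.error("trailing tokens")
    return [vec]


def parse_hypothesis(text: str, cells: list[str] | tuple[str, ...]) -> ConstraintSet:
    """Parse one hypothesis string into a constraint set over ``cells``.

    A chain ``a < b < c`` yields one row per adjacent pair; a comma group on
    one side of an inequality yields one row per cross pair and no constraint
    within the group.  ``Hu``, ``hu`` or an empty string is unconstrained.
    """
    cells = [str(c) for c in cells]
    original = text
    name = None
    m = _NAME_PREFIX.match(text)
    if (
        m
        and m.group(1) not in cells
        # not the start of a cell label that itself contains the separator
        and not any(lab.startswith(text[: m.end()].lstrip()) for lab in cells)
    ):
        name = m.group(1)
        text = text[m.end():]
    if text.strip() in ("", "Hu", "hu", "HU"):
        return ConstraintSet(
            cells=cells,
            rows=np.empty((0, len(cells))),
            source_text=original,
            name=name or "Hu",
        )
    tokens = _tokenize(text, cells)
    sides_tokens, seps = _split_top(tokens, {"op"})
    if not seps:
        raise ParseError(f"no inequality operator in {original!r}")
    senses = {s[1] for s in seps}
    if len(senses) > 1:
        raise ParseError(
            f"mixed '<' and '>' in one chain in {original!r}; use parentheses "
            "or separate hypotheses"
        )
    sides = [_parse_side(st, cells, original) for st in sides_tokens]
    sense = seps[0][1]
    rows = []
    for left, right in zip(sides[:-1], sides[1:]):
        for u, v in itertools.product(left, right):
            row = (v - u) if sense == "<" else (u - v)
            if np.all(row == 0):
                raise ParseError(f"degenerate constraint (both sides equal) in {original!r}")
            rows.append(row)
    return ConstraintSet(
        cells=cells, rows=np.vstack(rows), source_text=original, name=name
    )


# -- posterior machinery ------------------------------------------------------

def cell_posterior(fit: LinearModelFit) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Approximate posterior of the full-grid cell means: labels, mean, cov.

    Multivariate normal centred at the EMMs with covariance G Sigma G' from
    the OLS coefficient covariance (residual-variance uncertainty neglected;
    adequate at moderate cell sizes).
    """
    grid_cells, G = _grid_rows(fit, list(fit.design.factors))
    labels = [":".join(c) for c in grid_cells]
    mean = G @ fit.coefficients
    cov = G @ fit.coef_cov @ G.T
    return labels, mean, cov


def _mvn_draws(
    mean: np.ndarray, cov: np.ndarray, draws: int, rng: np.random.Generator
) -> np.ndarray:
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) * np.eye(len(mean)))
    return mean + rng.standard_normal((draws, len(mean))) @ L.T


def _default_names(hypotheses: list[ConstraintSet]) -> list[str]:
    names = []
    k = 1
    for h in hypotheses:
        if h.name:
            names.append(h.name)
        elif h.is_unconstrained:
            names.append("Hu")
        else:
            names.append(f"H{k}")
        k += 1
    return names


@dataclass
class PMPResult:
    """Fit, complexity, Bayes factors and posterior model probabilities."""

    names: list[str]
    cells: list[str]
    f: np.ndarray
    c: np.ndarray
    bf_u: np.ndarray
    pmp: np.ndarray
    mc_se: dict[str, np.ndarray]
    draws: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hypothesis": self.names,
                "fit": self.f,
                "complexity": self.c,
                "bf_u": self.bf_u,
                "pmp": self.pmp,
                "mc_se_fit": self.mc_se["f"],
                "mc_se_complexity": self.mc_se["c"],
                "mc_se_pmp": self.mc_se["pmp"],
            }
        )

    def bf_matrix(self) -> pd.DataFrame:
        """Pairwise Bayes factors BF[i, j] = bf_u_i / bf_u_j."""
        with np.errstate(divide="ignore", invalid="ignore"):
            M = np.outer(self.bf_u, 1.0 / self.bf_u)
        return pd.DataFrame(M, index=self.names, columns=self.names)

    @property
    def best(self) -> str:
        return self.names[int(np.argmax(self.pmp))]


def _fit_and_complexity(
    h: ConstraintSet, post: np.ndarray, ref: np.ndarray
) -> tuple[float, float]:
    return float(h.satisfied(post).mean()), float(h.satisfied(ref).mean())


def compute_pmps(
    hypotheses: list[ConstraintSet],
    fit: LinearModelFit,
    draws: int = 100_000,
    seed: int | None = None,
) -> PMPResult:
    """Posterior model probabilities for a set of hypotheses (equal priors).

    Fit is estimated on shared draws from the cell-mean posterior, complexity
    on shared draws from an exchangeable standard-normal reference (so it
    depends only on the constraint geometry).  Raises if any complexity is
    estimated as zero at the given draw count.
    """
    if not hypotheses:
        raise ConfigurationError("need at least one hypothesis")
    labels, mean, cov = cell_posterior(fit)
    for h in hypotheses:
        if list(h.cells) != labels:
            raise ConfigurationError(
                f"hypothesis cells {h.cells} do not match the model grid {labels}"
            )
    rng = np.random.default_rng(seed)
    post = _mvn_draws(mean, cov, draws, rng)
    ref = rng.standard_normal((draws, len(labels)))
    f = np.empty(len(hypotheses))
    c = np.empty(len(hypotheses))
    for i, h in enumerate(hypotheses):
        f[i], c[i] = _fit_and_complexity(h, post, ref)
        if c[i] == 0.0:
            raise RuntimeError(
                f"complexity of {h.name or h.source_text!r} estimated as 0 at "
                f"{draws} draws; increase draws"
            )
    bf = f / c
    total = bf.sum()
    if total == 0.0:
        raise RuntimeError("all hypotheses have zero posterior fit; cannot normalise")
    pmp = bf / total
    se_f = np.sqrt(f * (1 - f) / draws)
    se_c = np.sqrt(c * (1 - c) / draws)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(
            np.where(f > 0, se_f**2 / np.maximum(f, 1e-300) ** 2, 0.0)
            + se_c**2 / c**2
        )
    se_bf = np.where(f > 0, bf * rel, se_f / c)
    # delta method on pmp_i = bf_i / sum(bf), treating bf errors as independent
    J = (np.eye(len(bf)) * total - bf[:, None]) / total**2
    se_pmp = np.sqrt((J**2) @ se_bf**2)
    return PMPResult(
        names=_default_names(hypotheses),
        cells=labels,
        f=f,
        c=c,
        bf_u=bf,
        pmp=pmp,
        mc_se={"f": se_f, "c": se_c, "bf_u": se_bf, "pmp": se_pmp},
        draws=draws,
        seed=seed,
    )


def bf_vs_complement(
    h: ConstraintSet,
    fit: LinearModelFit,
    draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """Bayes factor of a hypothesis against its complement.

    BF_hc = (f/c) / ((1-f)/(1-c)).  Returns ``inf`` (with a Monte-Carlo
    caveat warning) when the estimated fit reaches 1 at the given draw count.
    """
    if h.is_unconstrained:
        raise ValueError("the unconstrained hypothesis has no complement")
    labels, mean, cov = cell_posterior(fit)
    if list(h.cells) != labels:
        raise ConfigurationError("hypothesis cells do not match the model grid")
    rng = np.random.default_rng(seed)
    post = _mvn_draws(mean, cov, draws, rng)
    ref = rng.standard_normal((draws, len(labels)))
    f, c = _fit_and_complexity(h, post, ref)
    if c in (0.0, 1.0):
        raise RuntimeError(f"degenerate complexity {c} at {draws} draws; increase draws")
    if f >= 1.0:
        warnings.warn(
            "posterior fit estimated as 1 at the given draw count; BF vs "
            "complement overflows (reported as inf)",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    return (f / c) / ((1.0 - f) / (1.0 - c))
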