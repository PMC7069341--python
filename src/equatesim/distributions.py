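"""Discrete sum-score distributions and bivariate (total, anchor) score tables.

Sum scores on a J-item binary test live on the integer grid 0..J.  A
:class:`ScoreDistribution` is the basic currency of every equating method in
this package: observed relative frequencies, log-linear presmoothed
probabilities, and IRT-model-implied probabilities are all represented the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoreDistribution",
    "BivariateScoreTable",
    "score_moments",
]

_PROB_TOL = 1e-8


@dataclass(frozen=True)
class ScoreDistribution:
    """Probability distribution over integer sum scores 0..J.

    Parameters
    ----------
    probabilities : array of shape (J + 1,)
        Nonnegative weights over the score points ``0..J``; normalized on
        construction if they do not already sum to one.
    """

    probabilities: np.ndarray
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("need a 1-d probability vector over >= 2 score points")
        if np.any(p < -_PROB_TOL) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be finite and nonnegative")
        p = np.clip(p, 0.0, None)
        total = p.sum()
        if total <= 0:
            raise ValueError("probabilities sum to zero")
        p = p / total
        object.__setattr__(self, "probabilities", p)
        scores = self.scores
        if scores is None:
            scores = np.arange(p.size)
        scores = np.asarray(scores)
        if scores.size != p.size:
            raise ValueError("scores and probabilities length mismatch")
        object.__setattr__(self, "scores", scores)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_scores(cls, observed: np.ndarray, n_items: int) -> "ScoreDistribution":
        """Empirical distribution of observed integer sum scores on 0..n_items."""
        observed = np.asarray(observed)
        if observed.size == 0:
            raise ValueError("no observed scores")
        counts = np.bincount(observed.astype(int), minlength=n_items + 1)
        if counts.size > n_items + 1:
            raise ValueError("observed scores exceed n_items")
        return cls(counts.astype(float))

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "ScoreDistribution":
        return cls(np.asarray(counts, dtype=float))

    # -- basic quantities -------------------------------------------------
    @property
    def n_score_points(self) -> int:
        return self.probabilities.size

    @property
    def max_score(self) -> int:
        return int(self.scores[-1])

    def cdf(self) -> np.ndarray:
        """Discrete CDF at each score point."""
        return np.minimum(np.cumsum(self.probabilities), 1.0)

    @property
    def mean(self) -> float:
        return float(self.scores @ self.probabilities)

    @property
    def var(self) -> float:
        m = self.mean
        return float(((self.scores - m) ** 2) @ self.probabilities)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.var))

    def moment(self, k: int, central: bool = True) -> float:
        x = self.scores - (self.mean if central else 0.0)
        return float((x ** k) @ self.probabilities)


def score_moments(scores: np.ndarray) -> dict:
    """Mean, SD, skewness and excess kurtosis of a score vector.

    Population divisors (n) throughout, matching descriptive summary tables.
    """
    x = np.asarray(scores, dtype=float)
    m = x.mean()
    dev = x - m
    var = np.mean(dev ** 2)
    sd = np.sqrt(var)
    if sd == 0:
        skew = np.nan
        kurt = np.nan
    else:
        skew = np.mean(dev ** 3) / sd ** 3
        kurt = np.mean(dev ** 4) / sd ** 4 - 3.0
    return {
        "mean": float(m),
        "sd": float(sd),
        "min": float(x.min()),
        "max": float(x.max()),
        "skewness": float(skew),
        "kurtosis": float(kurt),
    }


@dataclass(frozen=True)
class BivariateScoreTable:
    """Joint distribution of (total score, anchor score) for one group.

    ``table[x, a]`` holds the probability (or count, normalized on
    construction) of total score ``x`` and anchor score ``a``.  For an
    internal anchor the anchor items are part of the total, so cells with
    ``a > x`` or ``x - a > n_unique`` are structurally impossible; the
    ``support`` mask marks the admissible cells.
    """

    table: np.ndarray
    support: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 2:
            raise ValueError("bivariate table must be 2-d")
        if np.any(t < -_PROB_TOL) or not np.all(np.isfinite(t)):
            raise ValueError("table entries must be finite and nonnegative")
        t = np.clip(t, 0.0, None)
        total = t.sum()
        if total <= 0:
            raise ValueError("table sums to zero")
        object.__setattr__(self, "table", t / total)
        supp = self.support
        if supp is None:
            supp = np.ones_like(t, dtype=bool)
        supp = np.asarray(supp, dtype=bool)
        if supp.shape != t.shape:
            raise ValueError("support mask shape mismatch")
        object.__setattr__(self, "support", supp)

    @classmethod
    def from_scores(
        cls,
        total: np.ndarray,
        anchor: np.ndarray,
        n_total_items: int,
        n_anchor_items: int,
        internal_anchor: bool = True,
    ) -> "BivariateScoreTable":
        total = np.asarray(total, dtype=int)
        anchor = np.asarray(anchor, dtype=int)
        if total.shape != anchor.shape:
            raise ValueError("total/anchor length mismatch")
        t = np.zeros((n_total_items + 1, n_anchor_items + 1))
        np.add.at(t, (total, anchor), 1.0)
        supp = internal_anchor_support(n_total_items, n_anchor_items) if internal_anchor else None
        return cls(t, supp)

    def margin_total(self) -> ScoreDistribution:
        return ScoreDistribution(self.table.sum(axis=1))

    def margin_anchor(self) -> ScoreDistribution:
        return ScoreDistribution(self.table.sum(axis=0))


def internal_anchor_support(n_total_items: int, n_anchor_items: int) -> np.ndarray:
    """Admissible (total, anchor) cells when the anchor is internal.

    With K anchor items inside a J-item total, an anchor score a and total x
    must satisfy ``a <= x`` and ``x - a <= J - K``.
    """
    x = np.arange(n_total_items + 1)[:, None]
    a = np.arange(n_anchor_items + 1)[None, :]
    return (a <= x) & (x - a <= n_total_items - n_anchor_items)
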