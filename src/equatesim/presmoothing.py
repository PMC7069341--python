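"""Log-linear presmoothing of score frequencies.

Polynomial log-linear models fitted by Poisson maximum likelihood.  A
degree-``d`` univariate fit reproduces the first ``d`` raw moments of the
observed score distribution exactly (the Poisson score equations), which is
the property that makes log-linear presmoothing attractive for equating:
the smoothed distribution keeps the sample's mean, variance, ... while
ironing out sampling lumps and gaps.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm

from .distributions import BivariateScoreTable, ScoreDistribution

__all__ = ["presmooth_loglinear", "presmooth_bivariate", "PresmoothingWarning"]


class PresmoothingWarning(UserWarning):
    pass


def _poisson_fit(y, X):
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=300, tol=1e-10)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("log-linear fit produced non-finite coefficients")
    return res.mu


def presmooth_loglinear(freqs, degree: int = 3) -> ScoreDistribution:
    """Fit a polynomial log-linear model to univariate score frequencies.

    Parameters
    ----------
    freqs : counts (or proportions) over the full score grid 0..J.
    degree : highest power of the score retained in the log-linear model;
        the fitted distribution matches the observed first ``degree`` moments.

    When ``degree`` is at least the number of distinct observed scores the
    model is saturated or overparametrized; the observed proportions are
    returned with a warning.  The same fallback applies if the fit fails.
    """
    f = np.asarray(freqs, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if f.sum() <= 0:
        raise ValueError("total frequency must be positive")
    n_distinct = int((f > 0).sum())
    if degree >= n_distinct:
        warnings.warn(
            f"degree {degree} >= {n_distinct} distinct observed scores; "
            "returning the observed (saturated) distribution",
            PresmoothingWarning,
        )
        return ScoreDistribution(f)
    x = np.arange(f.size) / (f.size - 1)
    X = np.column_stack([x ** k for k in range(degree + 1)])
    try:
        mu = _poisson_fit(f, X)
    except Exception as exc:  # noqa: BLE001 - any GLM failure falls back
        warnings.warn(
            f"log-linear fit failed ({exc}); returning observed distribution",
            PresmoothingWarning,
        )
        return ScoreDistribution(f)
    return ScoreDistribution(mu)


def presmooth_bivariate(
    table: BivariateScoreTable,
    margin_degrees: tuple[int, int] = (3, 3),
    cross_terms: list[tuple[int, int]] | int = 1,
) -> BivariateScoreTable:
    """Log-linear presmoothing of a joint (total, anchor) score table.

    The model contains polynomial terms in each margin up to
    ``margin_degrees`` plus cross-product terms; ``cross_terms=k`` is
    shorthand for the products ``x^i * a^i`` for ``i = 1..k``.  Structurally
    impossible cells (``table.support``) are excluded from the fit and keep
    probability zero, which is the standard treatment of structural zeros
    with an internal anchor.  The fit preserves the margin moments up to the
    margin degrees and the cross moments of the included products.
    """
    d1, d2 = margin_degrees
    if d1 < 1 or d2 < 1:
        raise ValueError("margin degrees must be >= 1")
    if isinstance(cross_terms, int):
        cross = [(i, i) for i in range(1, cross_terms + 1)]
    else:
        cross = list(cross_terms)

    t = table.table
    supp = table.support
    nx, na = t.shape
    xg, ag = np.meshgrid(np.arange(nx) / max(nx - 1, 1),
                         np.arange(na) / max(na - 1, 1), indexing="ij")
    y = t[supp]
    cols = [np.ones(y.size)]
    cols += [xg[supp] ** k for k in range(1, d1 + 1)]
    cols += [ag[supp] ** k for k in range(1, d2 + 1)]
    cols += [(xg[supp] ** i) * (ag[supp] ** j) for i, j in cross]
    X = np.column_stack(cols)

    n_cells = int(y.size)
    if X.shape[1] >= n_cells or (y > 0).sum() <= X.shape[1]:
        warnings.warn(
            "bivariate log-linear model is saturated/overparametrized; "
            "returning the observed table",
            PresmoothingWarning,
        )
        return table
    try:
        mu = _poisson_fit(y, X)
    except Exception as exc:  # noqa: BLE001
        warnings.warn(
            f"bivariate log-linear fit failed ({exc}); returning observed table",
            PresmoothingWarning,
        )
        return table
    out = np.zeros_like(t)
    out[supp] = mu
    return BivariateScoreTable(out, table.support)
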