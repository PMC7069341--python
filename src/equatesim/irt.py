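"""Two-parameter logistic IRT model: estimation, linking, score distributions.

The 2PL item response function is ``P(theta) = 1 / (1 + exp(-D a (theta - b)))``
with discrimination ``a > 0``, difficulty ``b``, and scaling constant ``D``
(``D = 1``, the pure logistic metric, is the package default).  Marginal
maximum likelihood estimation uses an EM algorithm with a fixed Gaussian
quadrature over ability; observed-score distributions come from the
Lord-Wingersky recursion mixed over an ability density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .distributions import ScoreDistribution

__all__ = [
    "irf_2pl",
    "lord_wingersky",
    "marginal_score_distribution",
    "gaussian_quadrature",
    "TwoParameterLogistic",
    "LinkingTransform",
    "link_scales",
    "ConvergenceError",
    "InsufficientAnchorError",
]

DEFAULT_D = 1.0


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


class InsufficientAnchorError(ValueError):
    """Raised when fewer than two anchor items are available for linking."""


def irf_2pl(theta, slope, location, D: float = DEFAULT_D):
    """2PL probability of a correct response; broadcasts over inputs."""
    z = D * np.asarray(slope) * (np.asarray(theta) - np.asarray(location))
    return 1.0 / (1.0 + np.exp(-z))


def gaussian_quadrature(
    n_points: int = 61, bound: float = 6.0, mean: float = 0.0, sd: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced ability grid with renormalized Gaussian weights."""
    nodes = np.linspace(-bound, bound, n_points)
    w = stats.norm.pdf(nodes, loc=mean, scale=sd)
    return nodes, w / w.sum()


def lord_wingersky(probabilities: np.ndarray) -> ScoreDistribution:
    """Distribution of the number-correct score given per-item probabilities.

    Standard dynamic-programming recursion over items: after item j the
    distribution over scores 0..j is updated by the jth Bernoulli success
    probability.  Exact to floating point.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    dist = _lw_recursion(p)[0]
    return ScoreDistribution(dist)


def _lw_recursion(p: np.ndarray) -> np.ndarray:
    """Vectorized recursion: p is (Q, J); returns (Q, J + 1)."""
    q_pts, n_items = p.shape
    dist = np.zeros((q_pts, n_items + 1))
    dist[:, 0] = 1.0
    for j in range(n_items):
        pj = p[:, j][:, None]
        upper = dist[:, : j + 1] * pj
        dist[:, : j + 1] *= 1.0 - pj
        dist[:, 1 : j + 2] += upper
    return dist


def marginal_score_distribution(
    slopes: np.ndarray,
    locations: np.ndarray,
    theta_grid: np.ndarray,
    weights: np.ndarray,
    D: float = DEFAULT_D,
) -> ScoreDistribution:
    """Quadrature mixture of conditional sum-score distributions."""
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ValueError("quadrature weights must sum to 1")
    p = irf_2pl(np.asarray(theta_grid)[:, None], np.asarray(slopes)[None, :],
                np.asarray(locations)[None, :], D)
    cond = _lw_recursion(p)
    return ScoreDistribution(weights @ cond)


class TwoParameterLogistic(BaseEstimator):
    """2PL model fitted by marginal maximum likelihood (EM, fixed quadrature).

    Parameters
    ----------
    D : logistic scaling constant (default 1.0, pure logistic metric).
    n_quadrature, theta_bound : ability grid, ``n_quadrature`` equally spaced
        points on ``[-theta_bound, theta_bound]`` with standard-normal weights.
    max_iter, tol : EM stops when every parameter moves by less than ``tol``
        between cycles, or errors after ``max_iter`` cycles.
    slope_floor, location_bound : degenerate all-0/all-1 item columns are not
        dropped (so the score scale keeps its length) but clamped to
        ``location = +/- location_bound`` with ``slope = slope_floor``.

    Attributes
    ----------
    slope_, location_ : fitted item parameters, shape (J,).
    theta_ : EAP ability estimate per examinee.
    ability_weights_ : aggregated posterior ability density on ``theta_grid_``
        (the sample's estimated latent distribution, used for model-implied
        observed-score distributions).
    degenerate_items_ : boolean mask of clamped columns.
    n_iter_, converged_ : EM diagnostics.
    """

    def __init__(
        self,
        D: float = DEFAULT_D,
        n_quadrature: int = 61,
        theta_bound: float = 6.0,
        max_iter: int = 500,
        tol: float = 1e-4,
        slope_floor: float = 0.2,
        location_bound: float = 6.0,
    ):
        self.D = D
        self.n_quadrature = n_quadrature
        self.theta_bound = theta_bound
        self.max_iter = max_iter
        self.tol = tol
        self.slope_floor = slope_floor
        self.location_bound = location_bound

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        Y = np.asarray(X)
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise ValueError("need an (n_persons, n_items >= 2) response matrix")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")
        Y = Y.astype(float)
        n, J = Y.shape

        nodes, w_prior = gaussian_quadrature(self.n_quadrature, self.theta_bound)
        col_mean = Y.mean(axis=0)
        degenerate = (col_mean <= 0.0) | (col_mean >= 1.0)
        free = ~degenerate

        # working parametrization: logit P = slope * theta + intercept
        slope = np.ones(J)
        pbar = np.clip(col_mean, 1e-3, 1 - 1e-3)
        intercept = np.log(pbar / (1 - pbar))
        slope[degenerate] = self.slope_floor
        intercept[degenerate] = np.where(
            col_mean[degenerate] >= 1.0,
            self.slope_floor * self.location_bound,
            -self.slope_floor * self.location_bound,
        )

        log_w = np.log(w_prior)
        converged = False
        post = None
        loglik_path = []
        for it in range(1, self.max_iter + 1):
            P = self._prob(nodes, slope, intercept)          # (Q, J)
            logP = np.log(P)
            log1mP = np.log1p(-P)
            ll = Y @ logP.T + (1.0 - Y) @ log1mP.T + log_w    # (n, Q)
            ll_max = ll.max(axis=1, keepdims=True)
            ll -= ll_max
            post = np.exp(ll)
            norm = post.sum(axis=1, keepdims=True)
            loglik_path.append(float(np.sum(ll_max + np.log(norm))))
            post /= norm

            nq = post.sum(axis=0)                             # (Q,)
            rq = post.T @ Y                                   # (Q, J)

            new_slope, new_intercept = self._mstep(
                nodes, nq, rq, slope.copy(), intercept.copy(), free
            )
            delta = max(
                np.max(np.abs(new_slope[free] - slope[free]), initial=0.0),
                np.max(np.abs(new_intercept[free] - intercept[free]), initial=0.0),
            )
            slope, intercept = new_slope, new_intercept
            if delta < self.tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"2PL EM did not converge in {self.max_iter} cycles "
                f"(last max parameter change {delta:.2e})"
            )

        a = slope / self.D
        b = -intercept / np.maximum(slope, 1e-12)
        a[degenerate] = self.slope_floor
        b[degenerate] = np.where(col_mean[degenerate] >= 1.0,
                                 -self.location_bound, self.location_bound)
        b[free] = np.clip(b[free], -self.location_bound * 2, self.location_bound * 2)

        self.slope_ = a
        self.location_ = b
        self.degenerate_items_ = degenerate
        self.theta_grid_ = nodes
        self.prior_weights_ = w_prior
        self.ability_weights_ = post.sum(axis=0) / n
        self.theta_ = post @ nodes
        self.loglik_path_ = np.asarray(loglik_path)
        self.n_iter_ = it
        self.converged_ = converged
        self.n_items_ = J
        return self

    def _prob(self, nodes, slope, intercept):
        z = nodes[:, None] * slope[None, :] + intercept[None, :]
        return np.clip(1.0 / (1.0 + np.exp(-z)), 1e-10, 1 - 1e-10)

    def _mstep(self, nodes, nq, rq, slope, intercept, free, n_newton: int = 5):
        """Per-item Newton updates of the expected complete-data likelihood.

        Items are independent given the quadrature tallies, so the 2x2 Newton
        systems are solved for all items simultaneously.
        """
        idx = np.where(free)[0]
        s, c = slope[idx], intercept[idx]
        r, n_q = rq[:, idx], nq[:, None]
        for _ in range(n_newton):
            z = nodes[:, None] * s[None, :] + c[None, :]
            p = np.clip(1.0 / (1.0 + np.exp(-z)), 1e-10, 1 - 1e-10)
            resid = r - n_q * p                          # (Q, m)
            g_s = (nodes[:, None] * resid).sum(axis=0)
            g_c = resid.sum(axis=0)
            w = n_q * p * (1 - p)
            h_ss = (nodes[:, None] ** 2 * w).sum(axis=0)
            h_sc = (nodes[:, None] * w).sum(axis=0)
            h_cc = w.sum(axis=0)
            det = np.maximum(h_ss * h_cc - h_sc ** 2, 1e-12)
            ds = (h_cc * g_s - h_sc * g_c) / det
            dc = (h_ss * g_c - h_sc * g_s) / det
            step = np.maximum(1.0, np.maximum(np.abs(ds), np.abs(dc)) / 1.0)
            s = s + ds / step
            c = c + dc / step
            s = np.clip(s, 1e-2, 50.0)
            c = np.clip(c, -40.0, 40.0)
        slope[idx], intercept[idx] = s, c
        return slope, intercept

    # ------------------------------------------------------------------
    def predict_proba(self, theta):
        """Response probabilities for abilities ``theta``: shape (n, J)."""
        self._check_fitted()
        return irf_2pl(np.asarray(theta)[:, None], self.slope_[None, :],
                       self.location_[None, :], self.D)

    def score_distribution(self, items=None, weights=None, theta_grid=None) -> ScoreDistribution:
        """Model-implied observed-score distribution.

        By default uses the fitted ability density (aggregated posterior) and
        all items; ``items`` restricts to a subset, ``weights``/``theta_grid``
        override the ability density.
        """
        self._check_fitted()
        if items is None:
            items = np.arange(self.n_items_)
        grid = self.theta_grid_ if theta_grid is None else np.asarray(theta_grid)
        w = self.ability_weights_ if weights is None else np.asarray(weights)
        return marginal_score_distribution(
            self.slope_[items], self.location_[items], grid, w / w.sum(), self.D
        )

    def _check_fitted(self):
        if not hasattr(self, "slope_"):
            raise RuntimeError("model is not fitted")


@dataclass(frozen=True)
class LinkingTransform:
    """Affine ability-scale transform theta* = A theta + B (A > 0)."""

    A: float
    B: float

    def __post_init__(self):
        if not (self.A > 0 and np.isfinite(self.A) and np.isfinite(self.B)):
            raise ValueError("require finite A > 0")

    def transform_theta(self, theta):
        return self.A * np.asarray(theta) + self.B

    def transform_items(self, slopes, locations):
        """Map item parameters onto the target scale."""
        return np.asarray(slopes) / self.A, self.A * np.asarray(locations) + self.B


def link_scales(
    slopes_target,
    locations_target,
    slopes_source,
    locations_source,
    method: str = "stocking-lord",
    D: float = DEFAULT_D,
    n_quadrature: int = 61,
) -> LinkingTransform:
    """Transform putting the *source* calibration onto the *target* scale.

    Inputs are the anchor-item parameters as estimated in each calibration.
    ``stocking-lord`` (default) minimizes the squared difference between the
    anchor test characteristic curves over a standard-normal quadrature;
    ``haebara`` matches item characteristic curves; ``mean-mean`` and
    ``mean-sigma`` are the classical moment methods.
    """
    at = np.asarray(slopes_target, dtype=float)
    bt = np.asarray(locations_target, dtype=float)
    a_s = np.asarray(slopes_source, dtype=float)
    b_s = np.asarray(locations_source, dtype=float)
    if at.size != a_s.size or bt.size != b_s.size or at.size != bt.size:
        raise ValueError("anchor parameter arrays must have equal length")
    if at.size < 2:
        raise InsufficientAnchorError("need at least 2 anchor items to link scales")

    if method == "mean-mean":
        A = a_s.mean() / at.mean()
        B = bt.mean() - A * b_s.mean()
        return LinkingTransform(A, B)
    if method == "mean-sigma":
        sd_s = b_s.std()
        if sd_s == 0:
            A = 1.0
        else:
            A = bt.std() / sd_s
        B = bt.mean() - A * b_s.mean()
        return LinkingTransform(A, B)
    if method not in ("stocking-lord", "haebara"):
        raise ValueError(f"unknown linking method {method!r}")

    nodes, w = gaussian_quadrature(n_quadrature)
    p_target = irf_2pl(nodes[:, None], at[None, :], bt[None, :], D)

    def loss(params):
        logA, B = params
        A = np.exp(logA)
        a_star = a_s / A
        b_star = A * b_s + B
        p_star = irf_2pl(nodes[:, None], a_star[None, :], b_star[None, :], D)
        if method == "stocking-lord":
            d = p_target.sum(axis=1) - p_star.sum(axis=1)
            return float(w @ d ** 2)
        return float(w @ ((p_target - p_star) ** 2).sum(axis=1))

    res = optimize.minimize(loss, x0=np.array([0.0, 0.0]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    if not res.success:  # pragma: no cover - Nelder-Mead rarely reports failure here
        warnings.warn(f"linking optimizer stopped early: {res.message}")
    return LinkingTransform(float(np.exp(res.x[0])), float(res.x[1]))
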