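"""Observed-score equating methods: EE, KE, IRTOSE, and IRTKE.

Four engines that map scores on test form X onto the scale of form Y:

* equipercentile equating (EE) — classical percentile-rank method with
  uniform within-score continuization;
* kernel equating (KE) — log-linear presmoothing, Gaussian-kernel
  continuization with penalty-selected bandwidth, equipercentile-like
  inversion of the continuized CDFs;
* IRT observed-score equating (IRTOSE) — 2PL-model-implied sum-score
  distributions equated by the equipercentile rule;
* IRT observed-score kernel equating (IRTKE) — the same model-implied score
  probabilities pushed through the kernel continuization and equated as KE.

Each method supports the random equivalent-groups design (EG) and the
non-equivalent-groups internal-anchor design (NEAT, chained; IRTOSE uses a
linked-calibration synthetic target population instead, which is how the
method is conventionally run in NEAT).

The functional layer operates on :class:`ScoreDistribution` objects; the
estimator classes wrap it with a scikit-learn fit/transform interface on raw
sample data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .distributions import BivariateScoreTable, ScoreDistribution
from .irt import TwoParameterLogistic, link_scales, marginal_score_distribution
from .kernel import BANDWIDTH_BOUNDS, continuize, select_bandwidth
from .presmoothing import presmooth_bivariate, presmooth_loglinear

__all__ = [
    "EquatingFunction",
    "equipercentile_equate",
    "kernel_equate",
    "chained_equate",
    "design_function",
    "irt_observed_equate",
    "irt_kernel_equate",
    "EquipercentileEquating",
    "KernelEquating",
    "IRTObservedScoreEquating",
    "IRTKernelEquating",
    "make_equating_estimator",
]

_MONOTONE_TOL = 1e-8


@dataclass(frozen=True)
class EquatingFunction:
    """Tabulated map from form-X score points to form-Y equivalents."""

    x: np.ndarray
    y: np.ndarray
    method: str = ""
    design: str = "eg"

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("equating function values must be finite")
        if np.any(np.diff(y) < -_MONOTONE_TOL):
            raise ValueError("equated values must be nondecreasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", np.maximum.accumulate(y))

    def __call__(self, scores):
        return np.interp(np.asarray(scores, dtype=float), self.x, self.y)


# ----------------------------------------------------------------------
# functional layer
# ----------------------------------------------------------------------

def equipercentile_equate(
    dist_X: ScoreDistribution, dist_Y: ScoreDistribution, method: str = "EE",
    design: str = "eg",
) -> EquatingFunction:
    """Classical equipercentile equating with percentile-rank continuization.

    The percentile rank of integer score x is ``F(x - 1) + p(x) / 2``
    (uniform continuization within each score).  Its inverse on the Y scale
    places the equated value inside the smallest score interval whose upper
    cumulative proportion strictly exceeds the rank.  Equated values are
    clamped to ``[-0.5, J_Y + 0.5]``.
    """
    pX = dist_X.probabilities
    FX = dist_X.cdf()
    pY = dist_Y.probabilities
    FY = dist_Y.cdf()
    jy = dist_Y.max_score
    out = np.empty(pX.size)
    for i in range(pX.size):
        prev = FX[i - 1] if i > 0 else 0.0
        rank = prev + pX[i] / 2.0
        idx = np.searchsorted(FY, rank, side="right")
        if idx >= FY.size:
            out[i] = jy + 0.5
            continue
        f_prev = FY[idx - 1] if idx > 0 else 0.0
        # p_Y(idx) > 0 by construction of the strict search
        out[i] = (idx - 0.5) + (rank - f_prev) / pY[idx]
    out = np.clip(out, -0.5, jy + 0.5)
    return EquatingFunction(dist_X.scores.astype(float), out, method, design)


def kernel_equate(
    dist_X: ScoreDistribution,
    dist_Y: ScoreDistribution,
    h_x: float | None = None,
    h_y: float | None = None,
    penalty_weight: float = 1.0,
    bandwidth_bounds: tuple[float, float] = BANDWIDTH_BOUNDS,
    method: str = "KE",
    design: str = "eg",
) -> EquatingFunction:
    """Kernel equating of two (presmoothed) score distributions.

    Bandwidths default to the penalty-minimizing choice per distribution.
    The equating function is ``e(x) = G_h^{-1}(F_h(x))`` with both CDFs
    Gaussian-continuized; the inverse is found by monotone root finding.
    """
    if h_x is None:
        h_x = select_bandwidth(dist_X, penalty_weight, bandwidth_bounds)
    if h_y is None:
        h_y = select_bandwidth(dist_Y, penalty_weight, bandwidth_bounds)
    F = continuize(dist_X, h_x)
    G = continuize(dist_Y, h_y)
    u = F.cdf(dist_X.scores.astype(float))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    y = np.atleast_1d(G.ppf(u))
    fn = EquatingFunction(dist_X.scores.astype(float), y, method, design)
    object.__setattr__(fn, "h_x", float(h_x))
    object.__setattr__(fn, "h_y", float(h_y))
    return fn


def chained_equate(
    link_XA: EquatingFunction, link_AY: EquatingFunction, method: str = "",
) -> EquatingFunction:
    """Compose X->A and A->Y links; the second link is linearly interpolated
    at non-integer anchor values (clamped at the ends of its grid)."""
    y = np.interp(link_XA.y, link_AY.x, link_AY.y)
    return EquatingFunction(link_XA.x, y, method or link_XA.method, "neat")


def design_function(design: str, *inputs):
    """Map collected score data to the marginal distributions equating needs.

    EG: identity on the two univariate distributions.  NEAT (chained): the
    two bivariate (total, anchor) tables of populations P and Q are reduced
    to the marginals (X and A in P; A and Y in Q).
    """
    if design == "eg":
        if len(inputs) != 2 or not all(isinstance(d, ScoreDistribution) for d in inputs):
            raise ValueError("EG design function expects two ScoreDistributions")
        return inputs
    if design == "neat":
        if len(inputs) != 2 or not all(isinstance(t, BivariateScoreTable) for t in inputs):
            raise ValueError("NEAT design function expects two BivariateScoreTables")
        table_p, table_q = inputs
        return (
            table_p.margin_total(),
            table_p.margin_anchor(),
            table_q.margin_anchor(),
            table_q.margin_total(),
        )
    raise ValueError(f"unknown design {design!r}")


# ----------------------------------------------------------------------
# estimator layer
# ----------------------------------------------------------------------

class BaseEquating(TransformerMixin, BaseEstimator):
    """Common fit/transform surface of the equating estimators.

    After ``fit`` the tabulated map is available as ``equating_function_``
    and ``transform(scores)`` interpolates it at (possibly non-integer)
    form-X scores.
    """

    method_name = ""

    def transform(self, X):
        if not hasattr(self, "equating_function_"):
            raise RuntimeError("estimator is not fitted")
        return self.equating_function_(np.asarray(X, dtype=float))

    def _scores_to_dist(self, scores, n_items):
        return ScoreDistribution.from_scores(np.asarray(scores), n_items)

    def _neat_tables(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2 or y.ndim != 2 or y.shape[1] != 2:
            raise ValueError(
                "NEAT fit expects (n, 2) arrays of (total, anchor) scores "
                "for group P (form X) and group Q (form Y)"
            )
        tp = BivariateScoreTable.from_scores(
            X[:, 0], X[:, 1], self.n_items_x, self.n_anchor, internal_anchor=True
        )
        tq = BivariateScoreTable.from_scores(
            y[:, 0], y[:, 1], self.n_items_y, self.n_anchor, internal_anchor=True
        )
        return tp, tq


class EquipercentileEquating(BaseEquating):
    """Equipercentile equating (EE); chained through the anchor in NEAT.

    Parameters
    ----------
    design : "eg" or "neat".
    n_items_x, n_items_y, n_anchor : score-scale lengths (items per form;
        anchor length required for NEAT).
    presmooth_degree : optional log-linear degree applied to the univariate
        margins before equating (EE runs on raw frequencies by default).
    """

    method_name = "EE"

    def __init__(self, design="eg", n_items_x=None, n_items_y=None,
                 n_anchor=None, presmooth_degree=None):
        self.design = design
        self.n_items_x = n_items_x
        self.n_items_y = n_items_y
        self.n_anchor = n_anchor
        self.presmooth_degree = presmooth_degree

    def _maybe_smooth(self, dist):
        if self.presmooth_degree is None:
            return dist
        return presmooth_loglinear(dist.probabilities, self.presmooth_degree)

    def fit(self, X, y):
        if self.design == "eg":
            dx = self._maybe_smooth(self._scores_to_dist(X, self.n_items_x))
            dy = self._maybe_smooth(self._scores_to_dist(y, self.n_items_y))
            self.equating_function_ = equipercentile_equate(
                dx, dy, self.method_name, "eg")
            return self
        tp, tq = self._neat_tables(X, y)
        dist_xp, dist_ap, dist_aq, dist_yq = design_function("neat", tp, tq)
        link_xa = equipercentile_equate(self._maybe_smooth(dist_xp),
                                        self._maybe_smooth(dist_ap))
        link_ay = equipercentile_equate(self._maybe_smooth(dist_aq),
                                        self._maybe_smooth(dist_yq))
        self.links_ = (link_xa, link_ay)
        self.equating_function_ = chained_equate(link_xa, link_ay, self.method_name)
        return self


class KernelEquating(BaseEquating):
    """Kernel equating (KE): presmooth, continuize, equate; chained in NEAT.

    ``margin_degrees``/``cross_terms`` parametrize the bivariate log-linear
    model used in NEAT; ``presmooth_degree`` the univariate model in EG.
    """

    method_name = "KE"

    def __init__(self, design="eg", n_items_x=None, n_items_y=None,
                 n_anchor=None, presmooth_degree=3, margin_degrees=(3, 3),
                 cross_terms=1, bandwidth_x=None, bandwidth_y=None,
                 penalty_weight=1.0, bandwidth_bounds=BANDWIDTH_BOUNDS):
        self.design = design
        self.n_items_x = n_items_x
        self.n_items_y = n_items_y
        self.n_anchor = n_anchor
        self.presmooth_degree = presmooth_degree
        self.margin_degrees = margin_degrees
        self.cross_terms = cross_terms
        self.bandwidth_x = bandwidth_x
        self.bandwidth_y = bandwidth_y
        self.penalty_weight = penalty_weight
        self.bandwidth_bounds = bandwidth_bounds

    def fit(self, X, y):
        if self.design == "eg":
            dx = presmooth_loglinear(
                self._scores_to_dist(X, self.n_items_x).probabilities,
                self.presmooth_degree)
            dy = presmooth_loglinear(
                self._scores_to_dist(y, self.n_items_y).probabilities,
                self.presmooth_degree)
            self.smoothed_ = (dx, dy)
            self.equating_function_ = kernel_equate(
                dx, dy, self.bandwidth_x, self.bandwidth_y,
                self.penalty_weight, self.bandwidth_bounds,
                self.method_name, "eg")
            return self
        tp, tq = self._neat_tables(X, y)
        sp = presmooth_bivariate(tp, self.margin_degrees, self.cross_terms)
        sq = presmooth_bivariate(tq, self.margin_degrees, self.cross_terms)
        dist_xp, dist_ap, dist_aq, dist_yq = design_function("neat", sp, sq)
        self.equating_function_ = _chained_kernel(
            dist_xp, dist_ap, dist_aq, dist_yq,
            self.penalty_weight, self.bandwidth_bounds, self.method_name)
        return self


def _chained_kernel(dist_xp, dist_ap, dist_aq, dist_yq, penalty_weight,
                    bounds, method):
    """Chained kernel equating through continuized CDFs (no interpolation):
    e(x) = G_Y|Q^{-1}( H_A|Q( H_A|P^{-1}( F_X|P(x) ) ) )."""
    cont = {}
    for key, d in (("xp", dist_xp), ("ap", dist_ap), ("aq", dist_aq),
                   ("yq", dist_yq)):
        h = select_bandwidth(d, penalty_weight, bounds)
        cont[key] = continuize(d, h)
    x = dist_xp.scores.astype(float)
    u = np.clip(cont["xp"].cdf(x), 1e-12, 1 - 1e-12)
    a_vals = np.atleast_1d(cont["ap"].ppf(u))
    v = np.clip(cont["aq"].cdf(a_vals), 1e-12, 1 - 1e-12)
    y = np.atleast_1d(cont["yq"].ppf(v))
    fn = EquatingFunction(x, y, method, "neat")
    object.__setattr__(fn, "bandwidths", {k: c.h for k, c in cont.items()})
    return fn


class _IRTEquatingBase(BaseEquating):
    def __init__(self, design="eg", anchor_x=None, anchor_y=None, D=1.0,
                 linking="stocking-lord", mixture_weight=0.5,
                 model_params=None):
        self.design = design
        self.anchor_x = anchor_x
        self.anchor_y = anchor_y
        self.D = D
        self.linking = linking
        self.mixture_weight = mixture_weight
        self.model_params = model_params

    def _fit_models(self, X, y):
        kwargs = dict(self.model_params or {})
        kwargs.setdefault("D", self.D)
        self.model_x_ = TwoParameterLogistic(**kwargs).fit(np.asarray(X))
        self.model_y_ = TwoParameterLogistic(**kwargs).fit(np.asarray(y))

    def _check_anchor(self):
        ax = np.asarray(self.anchor_x)
        ay = np.asarray(self.anchor_y)
        if ax.size < 2 or ay.size < 2 or ax.size != ay.size:
            raise ValueError(
                "NEAT needs the same >= 2 anchor item columns in both forms")
        return ax, ay


class IRTObservedScoreEquating(_IRTEquatingBase):
    """IRT observed-score equating (IRTOSE).

    EG: each group's 2PL fit yields a model-implied sum-score distribution
    over that group's estimated ability density; the two distributions are
    equated by the equipercentile rule.

    NEAT: separate calibrations are linked through the anchor-item
    parameters (Stocking-Lord by default); both full forms' distributions
    are computed on a synthetic target population mixing the two groups'
    ability densities with weight ``mixture_weight``, then equated.

    ``anchor_x`` / ``anchor_y`` are the column indices of the (internal)
    anchor items within each form's response matrix.
    """

    method_name = "IRT"

    def fit(self, X, y):
        self._fit_models(X, y)
        mx, my = self.model_x_, self.model_y_
        if self.design == "eg":
            dx = mx.score_distribution()
            dy = my.score_distribution()
        else:
            ax, ay = self._check_anchor()
            self.linking_ = link_scales(
                mx.slope_[ax], mx.location_[ax],
                my.slope_[ay], my.location_[ay],
                method=self.linking, D=self.D)
            a_star, b_star = self.linking_.transform_items(my.slope_, my.location_)
            grid_p, w_p = mx.theta_grid_, mx.ability_weights_
            grid_q = self.linking_.transform_theta(my.theta_grid_)
            w_q = my.ability_weights_
            w = self.mixture_weight
            dx = _mixture_dist(mx.slope_, mx.location_, self.D,
                               (grid_p, w_p, w), (grid_q, w_q, 1 - w))
            dy = _mixture_dist(a_star, b_star, self.D,
                               (grid_p, w_p, w), (grid_q, w_q, 1 - w))
        self.score_distributions_ = (dx, dy)
        self.equating_function_ = equipercentile_equate(
            dx, dy, self.method_name, self.design)
        return self


def _mixture_dist(slopes, locations, D, *components):
    """Weighted mixture of model-implied distributions over several ability
    densities (grid, weights, mixture weight)."""
    total = None
    for grid, w, mix in components:
        d = marginal_score_distribution(slopes, locations, grid,
                                        np.asarray(w) / np.sum(w), D)
        part = mix * d.probabilities
        total = part if total is None else total + part
    return ScoreDistribution(total)


class IRTKernelEquating(_IRTEquatingBase):
    """IRT observed-score kernel equating (IRTKE).

    Identical score-probability pipeline to IRTOSE, but the model-implied
    distributions are kernel-continuized and equated under the KE rule.  In
    NEAT the method is chained through the anchor (X->A on group P, A->Y on
    group Q, both model-implied), matching the chained EE convention, so no
    scale linking is required.
    """

    method_name = "IRTKE"

    def __init__(self, design="eg", anchor_x=None, anchor_y=None, D=1.0,
                 linking="stocking-lord", mixture_weight=0.5,
                 model_params=None, bandwidth_x=None, bandwidth_y=None,
                 penalty_weight=1.0, bandwidth_bounds=BANDWIDTH_BOUNDS):
        super().__init__(design, anchor_x, anchor_y, D, linking,
                         mixture_weight, model_params)
        self.bandwidth_x = bandwidth_x
        self.bandwidth_y = bandwidth_y
        self.penalty_weight = penalty_weight
        self.bandwidth_bounds = bandwidth_bounds

    def fit(self, X, y):
        self._fit_models(X, y)
        mx, my = self.model_x_, self.model_y_
        if self.design == "eg":
            dx = mx.score_distribution()
            dy = my.score_distribution()
            self.score_distributions_ = (dx, dy)
            self.equating_function_ = kernel_equate(
                dx, dy, self.bandwidth_x, self.bandwidth_y,
                self.penalty_weight, self.bandwidth_bounds,
                self.method_name, "eg")
            return self
        ax, ay = self._check_anchor()
        dist_xp = mx.score_distribution()
        dist_ap = mx.score_distribution(items=ax)
        dist_aq = my.score_distribution(items=ay)
        dist_yq = my.score_distribution()
        self.equating_function_ = _chained_kernel(
            dist_xp, dist_ap, dist_aq, dist_yq,
            self.penalty_weight, self.bandwidth_bounds, self.method_name)
        return self


def irt_observed_equate(resp_X, resp_Y, design="eg", anchor_x=None,
                        anchor_y=None, **kwargs) -> EquatingFunction:
    """Functional wrapper over :class:`IRTObservedScoreEquating`."""
    est = IRTObservedScoreEquating(design=design, anchor_x=anchor_x,
                                   anchor_y=anchor_y, **kwargs)
    return est.fit(resp_X, resp_Y).equating_function_


def irt_kernel_equate(resp_X, resp_Y, design="eg", anchor_x=None,
                      anchor_y=None, **kwargs) -> EquatingFunction:
    """Functional wrapper over :class:`IRTKernelEquating`."""
    est = IRTKernelEquating(design=design, anchor_x=anchor_x,
                            anchor_y=anchor_y, **kwargs)
    return est.fit(resp_X, resp_Y).equating_function_


METHODS = ("EE", "IRT", "KE", "IRTKE")


def make_equating_estimator(method: str, design: str, n_items: int,
                            n_anchor: int | None = None,
                            anchor_x=None, anchor_y=None,
                            **options) -> BaseEquating:
    """Factory used by the simulation layer: one estimator per method tag."""
    if method == "EE":
        return EquipercentileEquating(design=design, n_items_x=n_items,
                                      n_items_y=n_items, n_anchor=n_anchor,
                                      **options)
    if method == "KE":
        return KernelEquating(design=design, n_items_x=n_items,
                              n_items_y=n_items, n_anchor=n_anchor, **options)
    if method == "IRT":
        return IRTObservedScoreEquating(design=design, anchor_x=anchor_x,
                                        anchor_y=anchor_y, **options)
    if method == "IRTKE":
        return IRTKernelEquating(design=design, anchor_x=anchor_x,
                                 anchor_y=anchor_y, **options)
    raise ValueError(f"unknown equating method {method!r}")
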