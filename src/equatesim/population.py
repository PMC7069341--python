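"""Synthetic two-form item bank and examinee population.

Emulates a large-scale 80-item-per-form verbal admission test: two forms of
80 binary items taken by the same examinees, with sum-score mean near
43.3/44.2, SD near 12.7/12.6, KR-20 reliability near 0.90, and a
between-form sum-score correlation near 0.71.  Items follow a 2PL model with
lognormal discriminations and normal difficulties; abilities for the two
forms are bivariate normal.  The calibration step tunes a location shift and
a slope scale per form (and the latent correlation) so that the bank's
*model-implied* moments — computed by the Lord-Wingersky recursion over the
ability density, no sampling involved — hit the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distributions import score_moments
from .irt import gaussian_quadrature, irf_2pl, marginal_score_distribution

__all__ = [
    "GeneratorConfig",
    "ItemBank",
    "Population",
    "CalibrationError",
    "UndefinedReliabilityError",
    "calibrate_item_bank",
    "generate_population",
    "summarize_form",
    "implied_form_summary",
    "implied_sumscore_correlation",
]

FORMS = ("I", "II")
N_ITEMS_PER_FORM = 80

#: Calibration targets per form: sum-score mean, SD, KR-20 reliability,
#: and the between-form sum-score correlation of the emulated test.
DEFAULT_TARGETS = {
    "I": {"mean": 43.33, "sd": 12.66},
    "II": {"mean": 44.24, "sd": 12.59},
    "reliability": 0.90,
    "correlation": 0.71,
}


class CalibrationError(RuntimeError):
    """Raised when the item-bank calibration cannot reach its targets."""


class UndefinedReliabilityError(ValueError):
    """Raised when KR-20 is requested for a zero-variance score vector."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Hyperparameters of the synthetic test generator.

    ``slope_sigma_log`` and ``location_sd`` control item heterogeneity; the
    calibration tunes ``slope_mu_log`` (via a multiplicative slope scale) and
    a difficulty shift per form, so only the spreads matter to the user.
    ``theta_correlation=None`` means: calibrate the latent correlation so the
    implied between-form sum-score correlation matches the target.
    """

    n: int = 8000
    seed: int = 0
    theta_correlation: float | None = None
    slope_mu_log: float = np.log(0.85)
    slope_sigma_log: float = 0.30
    location_mu: float = 0.0
    location_sd: float = 1.15
    mean_sd_tol: float = 0.02
    reliability_tol: float = 0.02
    correlation_tol: float = 0.01
    max_restarts: int = 5
    n_quadrature: int = 61

    def __post_init__(self):
        for name in ("slope_mu_log", "slope_sigma_log", "location_mu", "location_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.theta_correlation is not None and not (0 < self.theta_correlation < 1):
            raise ValueError("theta_correlation must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class ItemBank:
    """160 2PL items: 80 per form, with the calibrated latent correlation."""

    item_id: np.ndarray
    form: np.ndarray
    slope: np.ndarray
    location: np.ndarray
    theta_correlation: float = 0.79

    def __post_init__(self):
        if np.any(np.asarray(self.slope) <= 0):
            raise ValueError("slopes must be strictly positive")
        ids = np.asarray(self.item_id)
        if ids.size != np.unique(ids).size:
            raise ValueError("item_ids must be unique")
        for f in FORMS:
            if int((np.asarray(self.form) == f).sum()) != N_ITEMS_PER_FORM:
                raise ValueError(f"form {f} must contain {N_ITEMS_PER_FORM} items")

    def form_params(self, form: str) -> tuple[np.ndarray, np.ndarray]:
        mask = np.asarray(self.form) == form
        return np.asarray(self.slope)[mask], np.asarray(self.location)[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item_id": self.item_id, "form": self.form,
             "slope": self.slope, "location": self.location}
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "theta_correlation", self.theta_correlation)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        df = pd.read_csv(path)
        return cls(
            item_id=df["item_id"].to_numpy(),
            form=df["form"].to_numpy(),
            slope=df["slope"].to_numpy(float),
            location=df["location"].to_numpy(float),
            theta_correlation=float(df["theta_correlation"].iloc[0]),
        )


@dataclass(frozen=True)
class Population:
    """Examinee abilities and binary responses for both forms."""

    theta_I: np.ndarray
    theta_II: np.ndarray
    responses_I: np.ndarray
    responses_II: np.ndarray

    @property
    def n(self) -> int:
        return self.responses_I.shape[0]

    def responses(self, form: str) -> np.ndarray:
        return self.responses_I if form == "I" else self.responses_II

    def sum_scores(self, form: str) -> np.ndarray:
        return self.responses(form).sum(axis=1)


# ----------------------------------------------------------------------
# implied (model-based) summaries used by the calibration
# ----------------------------------------------------------------------

def implied_form_summary(slopes, locations, n_quadrature: int = 61) -> dict:
    """Model-implied sum-score mean/SD/skew/kurtosis and KR-20 for one form.

    Ability is standard normal; everything is computed from the
    Lord-Wingersky mixture, so no Monte-Carlo error enters.
    """
    nodes, w = gaussian_quadrature(n_quadrature)
    dist = marginal_score_distribution(slopes, locations, nodes, w)
    pbar = w @ irf_2pl(nodes[:, None], np.asarray(slopes)[None, :],
                       np.asarray(locations)[None, :])
    item_var = (pbar * (1 - pbar)).sum()
    j = len(np.asarray(slopes))
    total_var = dist.var
    rel = (j / (j - 1)) * (1 - item_var / total_var) if total_var > 0 else np.nan
    sd = dist.sd
    return {
        "mean": dist.mean,
        "sd": sd,
        "skewness": dist.moment(3) / sd ** 3,
        "kurtosis": dist.moment(4) / sd ** 4 - 3.0,
        "reliability": float(rel),
    }


def implied_sumscore_correlation(
    bank_or_params, rho: float, n_quadrature: int = 41
) -> float:
    """Implied correlation of the two forms' sum scores under latent corr rho.

    Uses the fact that, given abilities, the two sum scores are independent
    with means equal to the test characteristic curves; the covariance is the
    covariance of the two TCCs over the bivariate-normal ability pair.
    """
    if isinstance(bank_or_params, ItemBank):
        params = [bank_or_params.form_params(f) for f in FORMS]
    else:
        params = bank_or_params
    nodes, w = gaussian_quadrature(n_quadrature)
    tcc = []
    var = []
    for slopes, locations in params:
        t = irf_2pl(nodes[:, None], np.asarray(slopes)[None, :],
                    np.asarray(locations)[None, :]).sum(axis=1)
        tcc.append(t)
        dist = marginal_score_distribution(slopes, locations, nodes, w)
        var.append(dist.var)
    mu = [w @ t for t in tcc]
    # E[T1(th1) T2(th2)] with th2 | th1 ~ N(rho th1, 1 - rho^2)
    z, wz = gaussian_quadrature(n_quadrature)
    s2, l2 = params[1]
    cross = 0.0
    sq = np.sqrt(max(1.0 - rho ** 2, 0.0))
    for zi, wzi in zip(z, wz):
        th2 = rho * nodes + sq * zi
        t2 = irf_2pl(th2[:, None], np.asarray(s2)[None, :],
                     np.asarray(l2)[None, :]).sum(axis=1)
        cross += wzi * (w @ (tcc[0] * t2))
    cov = cross - mu[0] * mu[1]
    return float(cov / np.sqrt(var[0] * var[1]))


# ----------------------------------------------------------------------
# calibration and generation
# ----------------------------------------------------------------------

def _calibrate_form(raw_slopes, raw_locations, target_mean, target_sd, nq):
    """Solve for a difficulty shift and slope scale hitting (mean, SD)."""

    def resid(x):
        shift, log_scale = x
        s = implied_form_summary(raw_slopes * np.exp(log_scale),
                                 raw_locations + shift, nq)
        return [s["mean"] - target_mean, s["sd"] - target_sd]

    sol = optimize.least_squares(resid, x0=[0.0, 0.0], xtol=1e-12, ftol=1e-12)
    shift, log_scale = sol.x
    return raw_slopes * np.exp(log_scale), raw_locations + shift, sol


def calibrate_item_bank(
    config: GeneratorConfig = GeneratorConfig(),
    targets: dict | None = None,
) -> ItemBank:
    """Draw and calibrate the 160-item two-form bank.

    Item parameters are drawn from the configured hyper-distributions, then a
    per-form difficulty shift and slope scale are solved so the implied
    sum-score mean and SD match the targets; the implied KR-20 must land
    within ``reliability_tol`` or the draw is restarted (up to
    ``max_restarts`` times, after which :class:`CalibrationError` is raised).
    Finally the latent correlation is tuned (unless fixed in the config) so
    the implied between-form sum-score correlation matches its target.
    """
    targets = DEFAULT_TARGETS if targets is None else targets
    rng = np.random.default_rng(config.seed)
    nq = config.n_quadrature

    for attempt in range(config.max_restarts):
        params = {}
        ok = True
        for f in FORMS:
            raw_a = rng.lognormal(config.slope_mu_log, config.slope_sigma_log,
                                  N_ITEMS_PER_FORM)
            raw_b = rng.normal(config.location_mu, config.location_sd,
                               N_ITEMS_PER_FORM)
            a, b, sol = _calibrate_form(raw_a, raw_b, targets[f]["mean"],
                                        targets[f]["sd"], nq)
            summ = implied_form_summary(a, b, nq)
            if (
                abs(summ["mean"] - targets[f]["mean"]) > config.mean_sd_tol
                or abs(summ["sd"] - targets[f]["sd"]) > config.mean_sd_tol
                or abs(summ["reliability"] - targets["reliability"]) > config.reliability_tol
            ):
                ok = False
                break
            params[f] = (a, b)
        if ok:
            break
    else:
        raise CalibrationError(
            f"item-bank calibration failed after {config.max_restarts} restarts"
        )

    if config.theta_correlation is not None:
        rho = config.theta_correlation
    else:
        pair = [params[f] for f in FORMS]
        target_r = targets["correlation"]

        def f_rho(r):
            return implied_sumscore_correlation(pair, r) - target_r

        rho = float(optimize.brentq(f_rho, 0.05, 0.999, xtol=1e-6))
        if abs(implied_sumscore_correlation(pair, rho) - target_r) > config.correlation_tol:
            raise CalibrationError("latent-correlation calibration failed")

    slope = np.concatenate([params[f][0] for f in FORMS])
    location = np.concatenate([params[f][1] for f in FORMS])
    return ItemBank(
        item_id=np.arange(1, 2 * N_ITEMS_PER_FORM + 1),
        form=np.repeat(FORMS, N_ITEMS_PER_FORM),
        slope=slope,
        location=location,
        theta_correlation=rho,
    )


def generate_population(bank: ItemBank, config: GeneratorConfig) -> Population:
    """Simulate abilities and binary responses for ``config.n`` examinees.

    Responses are drawn item by item: a person answers correctly when the 2PL
    probability exceeds an independent uniform draw.  Fully deterministic
    given the config seed.
    """
    rng = np.random.default_rng(config.seed + 1)  # offset: item draw vs person draw
    rho = bank.theta_correlation
    z = rng.standard_normal((config.n, 2))
    theta1 = z[:, 0]
    theta2 = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
    resp = {}
    for f, theta in zip(FORMS, (theta1, theta2)):
        a, b = bank.form_params(f)
        p = irf_2pl(theta[:, None], a[None, :], b[None, :])
        u = rng.random(p.shape)
        resp[f] = (p > u).astype(np.int8)
    return Population(theta_I=theta1, theta_II=theta2,
                      responses_I=resp["I"], responses_II=resp["II"])


def summarize_form(matrix: np.ndarray) -> dict:
    """Sum-score moments plus KR-20 for one binary response matrix.

    Population (divisor n) moments.  Raises
    :class:`UndefinedReliabilityError` when the total-score variance is zero.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("need a nonempty 2-d response matrix")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("responses must be binary 0/1")
    scores = m.sum(axis=1)
    out = score_moments(scores)
    total_var = np.mean((scores - scores.mean()) ** 2)
    if total_var == 0:
        raise UndefinedReliabilityError("total-score variance is zero")
    pj = m.mean(axis=0)
    j = m.shape[1]
    out["reliability"] = float((j / (j - 1)) * (1 - (pj * (1 - pj)).sum() / total_var))
    return out


def write_responses(matrix: np.ndarray, path) -> None:
    """Headered CSV, one row per examinee, columns item_1..item_J."""
    j = matrix.shape[1]
    pd.DataFrame(matrix, columns=[f"item_{k}" for k in range(1, j + 1)]).to_csv(
        path, index=False
    )


def read_responses(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.int8)
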