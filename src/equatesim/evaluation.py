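"""Criterion equatings and Monte-Carlo equating-error indices.

For a condition with equated functions e_Yr(x_i) over replications r = 1..R
and a criterion ("true") equating e_YC(x_i):

    AB(x_i)   = | mean_r e_Yr(x_i) - e_YC(x_i) |          (systematic error)
    SE(x_i)   = sqrt( (1/R) sum_r (e_Yr(x_i) - mean_r)^2 ) (random error)
    RMSE(x_i) = sqrt( AB^2 + SE^2 )                        (total error)

with divisor R (not R - 1) in the SE.  Weighted global versions WAB, WSE,
WRMSE sum the local indices with weights w_i = N_i / N_T, the relative
form-X score frequencies of the sampled equating groups.

Criterion equatings: IE is the identity e(x) = x; the LSSG families equate
the pseudo-tests on the entire population as a single group with the named
method (EE/IRT/KE/IRTKE), and the per-replication criterion functions are
averaged over R to give e_YC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulation import ReplicationSet

__all__ = [
    "identity_criterion",
    "criterion_function",
    "local_indices",
    "global_indices",
    "evaluate_cell",
    "dtm_compare",
]


def identity_criterion(score_grid) -> np.ndarray:
    """IE criterion: the form-Y equivalent of x is x itself."""
    return np.asarray(score_grid, dtype=float).copy()


def criterion_function(rep_set: ReplicationSet, tag: str) -> np.ndarray:
    """The final true equating for a tag: IE is exact; LSSG tags average
    the per-replication criterion functions over R."""
    if tag == "IE":
        return identity_criterion(rep_set.x)
    if tag not in rep_set.criteria:
        raise KeyError(f"criterion {tag!r} was not computed for this cell")
    return rep_set.criteria[tag].mean(axis=0)


def local_indices(replicated: np.ndarray, criterion: np.ndarray) -> pd.DataFrame:
    """Per-score-point AB, SE and RMSE from an (R, n_points) array."""
    e = np.asarray(replicated, dtype=float)
    c = np.asarray(criterion, dtype=float)
    if e.ndim != 2 or e.shape[0] < 2:
        raise ValueError("need an (R >= 2, n_points) replication array")
    if c.shape != (e.shape[1],):
        raise ValueError("criterion grid does not match replication grid")
    mean = e.mean(axis=0)
    ab = np.abs(mean - c)
    se = e.std(axis=0, ddof=0)
    return pd.DataFrame(
        {"AB": ab, "SE": se, "RMSE": np.sqrt(ab ** 2 + se ** 2)}
    )


def global_indices(local: pd.DataFrame, counts: np.ndarray) -> dict:
    """Frequency-weighted WAB/WSE/WRMSE from local indices."""
    w = np.asarray(counts, dtype=float)
    if w.size != len(local) or np.any(w < 0):
        raise ValueError("counts must be nonnegative and match the score grid")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    w = w / total
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights do not normalize to 1")
    return {
        "WAB": float(w @ local["AB"]),
        "WSE": float(w @ local["SE"]),
        "WRMSE": float(w @ local["RMSE"]),
    }


def evaluate_cell(rep_set: ReplicationSet,
                  criteria: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Global indices for every method x criterion of one cell group.

    One row per (method, criterion) with WAB/WSE/WRMSE — the long-format
    analogue of the study's summary tables.
    """
    tags = tuple(rep_set.criteria) if criteria is None else tuple(criteria)
    rows = []
    for tag in tags:
        crit = criterion_function(rep_set, tag)
        for m, arr in rep_set.methods.items():
            loc = local_indices(arr, crit)
            g = global_indices(loc, rep_set.x_counts)
            rows.append(
                {
                    "design": rep_set.design,
                    "sim_method": rep_set.sim_method,
                    "n": rep_set.n,
                    "test_length": rep_set.test_length,
                    "criterion": tag,
                    "method": m,
                    **g,
                }
            )
    return pd.DataFrame(rows)


def dtm_compare(difference: float, threshold: float = 0.5) -> bool:
    """Difference That Matters rule: True when |difference| is below the
    practical-significance threshold (i.e. it does *not* matter).

    The conventional threshold is half a raw-score unit; differences equal
    to or above the threshold matter (strict inequality).
    """
    if not threshold > 0:
        raise ValueError("DTM threshold must be positive")
    return bool(abs(difference) < threshold)
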