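"""Pseudo-test/pseudo-group resampling study of equating error.

The study resamples an 80-item form (and its examinee population) into
pseudo-tests X and Y and pseudo-groups P and Q, equates X to Y with each of
the four methods, and repeats.  Two ways of producing the response data are
compared:

* PTPG — slice the actual (here: synthetic) response matrix for the drawn
  items and persons, staying agnostic to any generating model;
* IRT — fit a 2PL once to the full form, then regenerate responses for the
  drawn items/persons from the fitted parameters (Bernoulli draws by
  comparing the model probability to a uniform number).

Designs: EG draws two randomly equivalent groups; NEAT splits the
population into high/low strata at the mean of the *other* form's sum score
and samples the two groups from different strata, linking X and Y through an
internal anchor (30% of the test length, rounded half-up).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .distributions import ScoreDistribution
from .equating import (
    METHODS,
    equipercentile_equate,
    kernel_equate,
    make_equating_estimator,
)
from .irt import TwoParameterLogistic, irf_2pl
from .population import Population
from .presmoothing import presmooth_loglinear

__all__ = [
    "CRITERIA",
    "SAMPLE_SIZES",
    "TEST_LENGTHS",
    "SIM_METHODS",
    "ConditionSpec",
    "PseudoAssembly",
    "ReplicationSet",
    "InfeasibleConditionError",
    "anchor_count",
    "condition_grid",
    "assemble_pseudo_tests",
    "sample_groups",
    "simulate_irt_responses",
    "fit_population_model",
    "run_replication",
    "run_condition",
    "run_study",
]

CRITERIA = ("IE", "LSSG-EE", "LSSG-IRT", "LSSG-KE", "LSSG-IRTKE")
SAMPLE_SIZES = (500, 1000, 2500)
TEST_LENGTHS = (30, 45)
SIM_METHODS = ("PTPG", "IRT")
POOL_SIZE = 80
ANCHOR_FRACTION = 0.30
MAX_RETRIES = 5


class InfeasibleConditionError(ValueError):
    """Raised when an assembly or condition cannot be built from the pool."""


def anchor_count(test_length: int, fraction: float = ANCHOR_FRACTION) -> int:
    """Internal-anchor length: ``fraction`` of the test, rounded half-up
    (30% of 30 -> 9 items, 30% of 45 -> 14 items)."""
    return int(np.floor(fraction * test_length + 0.5))


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the method x n x length x simulation x criterion grid."""

    method: str
    n: int
    test_length: int
    sim_method: str
    criterion: str
    design: str = "eg"
    replications: int = 500

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.sim_method not in SIM_METHODS:
            raise ValueError(f"sim_method must be one of {SIM_METHODS}")
        if self.design not in ("eg", "neat"):
            raise ValueError("design must be 'eg' or 'neat'")
        if self.replications < 2:
            raise ValueError("need at least 2 replications")

    @property
    def feasible(self) -> bool:
        """LSSG in EG needs two disjoint pseudo-tests, impossible at 45
        items (2 x 45 > 80-item pool)."""
        return not (
            self.design == "eg"
            and self.criterion.startswith("LSSG")
            and 2 * self.test_length > POOL_SIZE
        )


def condition_grid(design: str = "eg", replications: int = 500) -> list[ConditionSpec]:
    """The full 4 x 3 x 2 x 2 x 5 = 240-cell grid for one design."""
    return [
        ConditionSpec(m, n, L, sim, crit, design, replications)
        for m, n, L, sim, crit in itertools.product(
            METHODS, SAMPLE_SIZES, TEST_LENGTHS, SIM_METHODS, CRITERIA
        )
    ]


@dataclass(frozen=True)
class PseudoAssembly:
    """Item index sets (into the 80-item pool) for one replication.

    For NEAT the anchor items are internal: they open both ``x_items`` and
    ``y_items`` (the first ``len(anchor_items)`` columns of each pseudo-test
    are the anchor).
    """

    x_items: np.ndarray
    y_items: np.ndarray
    anchor_items: np.ndarray | None = None

    @property
    def n_anchor(self) -> int:
        return 0 if self.anchor_items is None else self.anchor_items.size


def assemble_pseudo_tests(
    test_length: int,
    design: str,
    rng: np.random.Generator,
    pool_size: int = POOL_SIZE,
    anchor_fraction: float = ANCHOR_FRACTION,
    allow_overlap: bool = False,
) -> PseudoAssembly:
    """Randomly draw pseudo-tests (and the NEAT anchor) without replacement.

    EG: two disjoint ``test_length``-item sets.  When ``2 * test_length``
    exceeds the pool this is infeasible; with ``allow_overlap=True`` the two
    tests are instead drawn independently (each without replacement within
    itself), which supports identity-criterion conditions but not LSSG.

    NEAT: the internal anchor is drawn first, then the disjoint unique parts
    of X and Y.
    """
    if design == "eg":
        if 2 * test_length <= pool_size:
            perm = rng.permutation(pool_size)
            return PseudoAssembly(np.sort(perm[:test_length]),
                                  np.sort(perm[test_length : 2 * test_length]))
        if not allow_overlap:
            raise InfeasibleConditionError(
                f"two disjoint {test_length}-item tests need "
                f"{2 * test_length} > {pool_size} items"
            )
        x = np.sort(rng.choice(pool_size, test_length, replace=False))
        y = np.sort(rng.choice(pool_size, test_length, replace=False))
        return PseudoAssembly(x, y)
    if design != "neat":
        raise ValueError("design must be 'eg' or 'neat'")
    k = anchor_count(test_length, anchor_fraction)
    n_unique = test_length - k
    if k + 2 * n_unique > pool_size:
        raise InfeasibleConditionError(
            f"NEAT assembly needs {k + 2 * n_unique} > {pool_size} items"
        )
    perm = rng.permutation(pool_size)
    anchor = perm[:k]
    ux = perm[k : k + n_unique]
    uy = perm[k + n_unique : k + 2 * n_unique]
    return PseudoAssembly(
        np.concatenate([anchor, np.sort(ux)]),
        np.concatenate([anchor, np.sort(uy)]),
        anchor,
    )


def sample_groups(
    population: Population, n: int, design: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two examinee groups without replacement.

    EG: disjoint simple random groups.  NEAT: the population is split at the
    mean of the form-II sum score; group P (taking form X) is sampled from
    the high stratum and group Q (taking form Y) from the low stratum,
    giving the two pseudo-groups a real ability difference.
    """
    n_pop = population.n
    if design == "eg":
        if 2 * n > n_pop:
            raise ValueError(f"need 2n = {2 * n} <= population size {n_pop}")
        perm = rng.permutation(n_pop)
        return perm[:n], perm[n : 2 * n]
    scores = population.sum_scores("II")
    high = np.flatnonzero(scores >= scores.mean())
    low = np.flatnonzero(scores < scores.mean())
    if n > high.size or n > low.size:
        raise ValueError("stratum smaller than requested group size")
    p = rng.choice(high, n, replace=False)
    q = rng.choice(low, n, replace=False)
    return p, q


def simulate_irt_responses(
    slopes: np.ndarray,
    locations: np.ndarray,
    thetas: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Regenerate binary responses from fitted 2PL parameters: a person
    scores 1 when the model probability exceeds an independent uniform."""
    p = irf_2pl(np.asarray(thetas)[:, None], np.asarray(slopes)[None, :],
                np.asarray(locations)[None, :])
    return (p > rng.random(p.shape)).astype(np.int8)


def fit_population_model(population: Population, form: str = "I",
                         **model_params) -> TwoParameterLogistic:
    """The once-per-study 2PL calibration of the full form used by the IRT
    simulation method."""
    return TwoParameterLogistic(**model_params).fit(population.responses(form))


# ----------------------------------------------------------------------
# one replication
# ----------------------------------------------------------------------

@dataclass
class ReplicationResult:
    assembly: PseudoAssembly
    methods: dict
    criteria: dict
    x_counts: np.ndarray


def _responses_for(population, person_idx, item_idx, sim_method, pop_model, rng):
    if sim_method == "PTPG":
        return population.responses_I[np.ix_(person_idx, item_idx)]
    return simulate_irt_responses(
        pop_model.slope_[item_idx], pop_model.location_[item_idx],
        pop_model.theta_[person_idx], rng,
    )


def _lssg_functions(tags, population, assembly, test_length, sim_method,
                    pop_model, rng, ke_degree=3):
    """Criterion equatings on the whole population as a single group."""
    all_persons = np.arange(population.n)
    resp_x = _responses_for(population, all_persons, assembly.x_items,
                            sim_method, pop_model, rng)
    resp_y = _responses_for(population, all_persons, assembly.y_items,
                            sim_method, pop_model, rng)
    dist_x = ScoreDistribution.from_scores(resp_x.sum(axis=1), test_length)
    dist_y = ScoreDistribution.from_scores(resp_y.sum(axis=1), test_length)
    out = {}
    irt_dists = None
    for tag in tags:
        fam = tag.split("-", 1)[1]
        if fam == "EE":
            out[tag] = equipercentile_equate(dist_x, dist_y).y
        elif fam == "KE":
            sx = presmooth_loglinear(dist_x.probabilities, ke_degree)
            sy = presmooth_loglinear(dist_y.probabilities, ke_degree)
            out[tag] = kernel_equate(sx, sy).y
        elif fam in ("IRT", "IRTKE"):
            if irt_dists is None:
                mx = TwoParameterLogistic().fit(resp_x)
                my = TwoParameterLogistic().fit(resp_y)
                irt_dists = (mx.score_distribution(), my.score_distribution())
            if fam == "IRT":
                out[tag] = equipercentile_equate(*irt_dists).y
            else:
                out[tag] = kernel_equate(*irt_dists).y
        else:
            raise ValueError(f"unknown LSSG family in {tag!r}")
    return out


def run_replication(
    condition: ConditionSpec,
    population: Population,
    rng: np.random.Generator,
    methods: tuple[str, ...] | None = None,
    criteria: tuple[str, ...] | None = None,
    pop_model: TwoParameterLogistic | None = None,
    force_identical_tests: bool = False,
    method_options: dict | None = None,
) -> ReplicationResult:
    """Assemble, sample, (re)generate, and equate once.

    ``methods``/``criteria`` default to the condition's single cells but may
    list several tags — they then share the replication's draws, as in the
    original repeated-sampling design.  ``force_identical_tests`` overrides
    the EG assembly with X = Y (a null-equating check).
    """
    methods = (condition.method,) if methods is None else tuple(methods)
    criteria = (condition.criterion,) if criteria is None else tuple(criteria)
    L = condition.test_length
    design = condition.design
    lssg_tags = [c for c in criteria if c.startswith("LSSG")]
    if lssg_tags and design == "eg" and 2 * L > POOL_SIZE:
        raise InfeasibleConditionError(
            "LSSG criterion in EG needs two disjoint pseudo-tests: "
            f"{2 * L} > {POOL_SIZE} items"
        )
    if condition.sim_method == "IRT" and pop_model is None:
        pop_model = fit_population_model(population)

    allow_overlap = design == "eg" and 2 * L > POOL_SIZE and not lssg_tags
    assembly = assemble_pseudo_tests(L, design, rng, allow_overlap=allow_overlap)
    if force_identical_tests:
        if design != "eg":
            raise ValueError("identical pseudo-tests only meaningful in EG")
        assembly = PseudoAssembly(assembly.x_items, assembly.x_items)
    idx_p, idx_q = sample_groups(population, condition.n, design, rng)

    resp_p = _responses_for(population, idx_p, assembly.x_items,
                            condition.sim_method, pop_model, rng)
    resp_q = _responses_for(population, idx_q, assembly.y_items,
                            condition.sim_method, pop_model, rng)
    x_scores = resp_p.sum(axis=1)
    y_scores = resp_q.sum(axis=1)

    k = assembly.n_anchor
    opts = method_options or {}
    fitted = {}
    for m in methods:
        est = make_equating_estimator(
            m, design, L, n_anchor=k or None,
            anchor_x=np.arange(k) if k else None,
            anchor_y=np.arange(k) if k else None,
            **opts.get(m, {}),
        )
        if m in ("IRT", "IRTKE"):
            est.fit(resp_p, resp_q)
        elif design == "eg":
            est.fit(x_scores, y_scores)
        else:
            anchor_p = resp_p[:, :k].sum(axis=1)
            anchor_q = resp_q[:, :k].sum(axis=1)
            est.fit(np.column_stack([x_scores, anchor_p]),
                    np.column_stack([y_scores, anchor_q]))
        fitted[m] = est.equating_function_.y

    # IRTOSE and IRTKE in a replication share their 2PL fits conceptually;
    # the estimators refit for API cleanliness only when both are requested
    # on small data, which is cheap relative to the study loop.

    crit = {}
    if lssg_tags:
        crit.update(_lssg_functions(lssg_tags, population, assembly, L,
                                    condition.sim_method, pop_model, rng))
    if "IE" in criteria:
        crit["IE"] = np.arange(L + 1, dtype=float)

    counts = np.bincount(x_scores, minlength=L + 1).astype(float)
    return ReplicationResult(assembly, fitted, crit, counts)


# ----------------------------------------------------------------------
# the replication loop
# ----------------------------------------------------------------------

@dataclass
class ReplicationSet:
    """All replications for one (design, sim_method, n, length) cell group."""

    design: str
    sim_method: str
    n: int
    test_length: int
    x: np.ndarray
    methods: dict = field(default_factory=dict)     # name -> (R, L+1)
    criteria: dict = field(default_factory=dict)    # tag  -> (R, L+1)
    x_counts: np.ndarray | None = None              # pooled form-X frequencies
    n_retries: int = 0

    @property
    def n_replications(self) -> int:
        return next(iter(self.methods.values())).shape[0]


def run_condition(
    population: Population,
    design: str,
    sim_method: str,
    n: int,
    test_length: int,
    methods: tuple[str, ...] = METHODS,
    criteria: tuple[str, ...] = ("IE",),
    replications: int = 50,
    seed: int | np.random.SeedSequence = 0,
    pop_model: TwoParameterLogistic | None = None,
    force_identical_tests: bool = False,
    method_options: dict | None = None,
    progress=None,
) -> ReplicationSet:
    """Run ``replications`` shared draws for one cell group.

    A replication that fails (e.g. a non-convergent fit) is redrawn with a
    fresh seed stream, up to 5 retries, so the replication count stays fixed.
    """
    feasible = [
        c for c in criteria
        if ConditionSpec("EE", n, test_length, sim_method, c, design, max(replications, 2)).feasible
    ]
    if len(feasible) < len(criteria):
        raise InfeasibleConditionError(
            "infeasible criteria for this cell: "
            f"{sorted(set(criteria) - set(feasible))}"
        )
    cond = ConditionSpec("EE", n, test_length, sim_method, criteria[0],
                         design, max(replications, 2))
    if sim_method == "IRT" and pop_model is None:
        pop_model = fit_population_model(population)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(replications)
    out = ReplicationSet(design, sim_method, n, test_length,
                         np.arange(test_length + 1, dtype=float))
    m_rows = {m: [] for m in methods}
    c_rows = {c: [] for c in criteria}
    counts = np.zeros(test_length + 1)
    retries = 0
    for r, child in enumerate(children):
        streams = child.spawn(MAX_RETRIES + 1)
        for attempt in range(MAX_RETRIES + 1):
            rng = np.random.default_rng(streams[attempt])
            try:
                res = run_replication(cond, population, rng, methods, criteria,
                                      pop_model, force_identical_tests,
                                      method_options)
                break
            except InfeasibleConditionError:
                raise
            except Exception:  # noqa: BLE001 - redrawn, counted
                retries += 1
                if attempt == MAX_RETRIES:
                    raise
        for m in methods:
            m_rows[m].append(res.methods[m])
        for c in criteria:
            c_rows[c].append(res.criteria[c])
        counts += res.x_counts
        if progress is not None:
            progress(r)
    out.methods = {m: np.vstack(v) for m, v in m_rows.items()}
    out.criteria = {c: np.vstack(v) for c, v in c_rows.items()}
    out.x_counts = counts
    out.n_retries = retries
    return out


def run_study(
    population: Population,
    design: str = "eg",
    sim_methods: tuple[str, ...] = SIM_METHODS,
    sample_sizes: tuple[int, ...] = SAMPLE_SIZES,
    test_lengths: tuple[int, ...] = TEST_LENGTHS,
    methods: tuple[str, ...] = METHODS,
    criteria: tuple[str, ...] = CRITERIA,
    replications: int = 500,
    seed: int = 0,
    method_options: dict | None = None,
    progress=None,
) -> dict:
    """Run the full grid for one design.

    Cells sharing (sim_method, n, test_length) reuse the same replication
    draws across methods and criteria, mirroring the original repeated-
    sampling layout.  Infeasible cell groups (LSSG in EG at 45 items) drop
    the infeasible criteria rather than the whole group.  Returns a dict
    keyed by (design, sim_method, n, test_length).
    """
    ss = np.random.SeedSequence(seed)
    cells = list(itertools.product(sim_methods, sample_sizes, test_lengths))
    children = ss.spawn(len(cells))
    results = {}
    pop_models = {}
    for (sim, n, L), child in zip(cells, children):
        crit = tuple(
            c for c in criteria
            if ConditionSpec("EE", n, L, sim, c, design, max(replications, 2)).feasible
        )
        if sim == "IRT" and "IRT" not in pop_models:
            pop_models["IRT"] = fit_population_model(population)
        results[(design, sim, n, L)] = run_condition(
            population, design, sim, n, L, methods, crit, replications,
            child, pop_models.get(sim), method_options=method_options,
            progress=(lambda r, _c=(sim, n, L): progress(_c, r)) if progress else None,
        )
    return results
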