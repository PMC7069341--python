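# Methods

This note documents the models, conventions and numerical choices behind
`equatesim`, in the spirit of a statistical package's methods appendix.

## Synthetic population generator

**Model.** Items follow a two-parameter logistic (2PL) response function
P(θ) = 1/(1 + exp(−a(θ − b))) with scaling constant D = 1 (the pure
logistic metric; nothing downstream depends on this choice, since a and θ
rescale jointly). Discriminations are lognormal, difficulties normal;
abilities for the two 80-item forms are bivariate standard normal with
correlation ρ. Responses are Bernoulli draws: a person answers correctly
when the model probability exceeds an independent uniform draw.

**Calibration.** The generator emulates a large-scale verbal admission
test: per-form sum-score mean 43.33/44.24, SD 12.66/12.59, KR-20 ≈ 0.90,
between-form sum-score correlation ≈ 0.71, with n = 8000 examinees per
form. Rather than hand-picking item parameters, the calibration draws raw
parameters from the hyper-distributions (defaults: a ~ LogNormal(log 0.85,
0.30), b ~ N(0, 1.15)) and solves, per form, for a difficulty shift and a
multiplicative slope scale such that the **model-implied** mean and SD —
computed exactly from the Lord–Wingersky recursion over a 61-point Gaussian
quadrature, no sampling — hit the targets (tolerance 0.02). The implied
KR-20 must land within 0.02 of 0.90, or the draw is restarted (up to 5
restarts, then a calibration error). Finally ρ is solved by root finding so
the implied between-form correlation (computed from the covariance of the
two test characteristic curves over the bivariate-normal ability pair)
matches 0.71 within 0.01; with the default reliability this puts ρ ≈ 0.79.

**What the generator does and does not emulate.** Means, SDs, reliability
and between-form correlation are matched tightly; skewness and excess
kurtosis come out at roughly −0.06 and −0.50 against nominal targets of
+0.12 and −0.65 — a symmetric 2PL/normal model cannot hit those exactly
while the first two moments and reliability are pinned, and the residual
discrepancy (≲ 0.25) is accepted and asserted only loosely in tests.
Content structure, item-format effects, and differential item functioning
of real test data are not emulated. Passing simulation results therefore
speak to the statistical behavior of the equating methods under a clean
2PL world with realistic score moments, not to operational data quirks.

## 2PL estimation

Marginal maximum likelihood via EM: fixed quadrature of 61 equally spaced
nodes on [−6, 6] with renormalized standard-normal weights; no priors on
item parameters (pure MML). The E-step computes per-person posteriors over
the grid in two matrix products; the M-step solves each item's 2×2 Newton
system (5 damped steps) in the slope–intercept parametrization,
vectorized over items. Convergence: max parameter change < 1e-4, cap 500
cycles, error on non-convergence; the marginal log-likelihood path is
retained and is non-decreasing (tested). Abilities are EAP; the aggregated
posterior over the grid serves as the sample's estimated ability density
for model-implied score distributions. Degenerate all-0/all-1 item columns
are not dropped (the score scale must keep its length across replications)
but clamped to b = ±6 with slope 0.2.

Scale linking for NEAT separate calibrations is Stocking–Lord by default
(Nelder–Mead on (log A, B), minimizing the squared anchor-TCC difference
over a standard-normal quadrature); Haebara, mean-mean and mean-sigma are
available. Whether the original-style analysis calibrated NEAT forms
concurrently or separately is an open choice; separate calibration plus
linking is implemented, with the linking method exposed.

## Presmoothing

Univariate: Poisson ML log-linear fit with polynomial terms up to degree 3
(default), which preserves the observed first `degree` raw moments
(score-equation identity; asserted to 1e-6). Degrees at or above the number
of distinct observed scores, or any fit failure, fall back to the observed
(saturated) proportions with a warning. Bivariate (NEAT): margin degrees
(3, 3) plus one cross-product term x·a by default. Structurally impossible
(total, anchor) cells of the internal-anchor geometry (a > x or
x − a > J − K) are excluded from the log-linear support and keep
probability zero. Equipercentile equating runs on raw frequencies by
default (presmoothing available by flag); kernel equating always
presmooths.

## Continuization and bandwidth

Gaussian kernel with the standard variance-preserving shrinkage
X(h) = a(X + hV) + (1 − a)μ, a² = σ²/(σ² + h²), so mean and variance of
the discrete distribution are preserved exactly for every h. Bandwidth
minimizes PEN1 + K·PEN2 (K = 1): PEN1 the squared deviation between the
continuized density and the score-point probabilities, PEN2 the count of
score points with a U-shaped density (decreasing at x − ¼, not increasing
at x + ¼). The objective is discontinuous in h, so the minimizer is a
deterministic 120-point log-spaced grid search on [0.08, 30] polished by
bounded scalar minimization within the bracketing interval; the
conventional 0.622·SD value is the last-resort fallback. Large h collapses
kernel equating onto the linear-equating line (tested at h = 10³, max
deviation < 0.05 interior to the score range).

The continuized inverse CDF uses bracketed Brent root finding (xtol 1e-10);
CDF arguments are clipped to [1e-12, 1 − 1e-12] before inversion.

## Equating conventions

Percentile ranks use the textbook convention F(x − 1) + p(x)/2; the
inverse places the equated value in the smallest Y-score interval whose
upper cumulative proportion strictly exceeds the rank, which handles
zero-frequency scores and guarantees monotonicity; equated values are
clamped to [−0.5, J_Y + 0.5]. Chained NEAT composition interpolates the
second link linearly at non-integer anchor values (clamped at the grid
ends); chained *kernel* equating composes the continuized CDFs directly,
with no interpolation. IRTOSE in NEAT uses the linked-calibration
synthetic-population route (mixture weight 0.5 between the two groups'
estimated ability densities, configurable), which is how that method is
conventionally run; IRTKE follows the chained convention to match EE/KE.
Every tabulated equating function is validated nondecreasing (tiny
numerical dips ≤ 1e-8 are monotonized).

## Study design choices

- Pseudo-tests are drawn from the 80-item form-I pool without replacement.
  EG tests are disjoint; at 45 items two disjoint tests are impossible
  (90 > 80), so EG-45 draws the two tests independently (overlap allowed),
  which supports the identity criterion but rules out LSSG — hence LSSG at
  45 items exists only in NEAT (76 distinct items needed).
- NEAT anchor length is 30% of the test, rounded half-up: 9 of 30, 14 of 45.
- NEAT groups: the population is split at the mean form-II sum score;
  group P (form X) is drawn from the high stratum, group Q (form Y) from
  the low stratum, whole-stratum sampling without replacement. The
  magnitude of the induced ability gap is a design choice (the mean split
  yields a large, realistic gap); stratum rules are configurable.
- The IRT simulation method calibrates the full form once per study and
  regenerates responses for each replication's drawn items/persons from
  the fitted parameters (per-replication refit available by flag).
- Replications: independent seed streams per condition × replication via
  `SeedSequence.spawn`; a failed replication (e.g. non-convergent fit) is
  redrawn with a fresh stream, capped at 5 retries, keeping R fixed.
- LSSG criterion equatings treat the full population as a single group
  taking both pseudo-tests; the LSSG-IRT/IRTKE families fit both
  pseudo-test matrices on the same examinees (a common latent scale by
  construction, no linking needed). Per-replication criterion functions
  are averaged over R to form the final true equating.

## Evaluation conventions

- SE uses divisor R (not R − 1), matching the index's definition as an
  average over the fixed set of replications; hence RMSE² = AB² + SE²
  exactly.
- Global weights w_i are the pooled form-X score frequencies of the
  sampled equating groups across replications (the reference sample for
  w_i = N_i/N_T is otherwise unspecified; this choice is documented and
  configurable by passing any count vector).
- DTM (Difference That Matters) threshold defaults to 0.5 raw-score
  units, strict inequality ("matters" at exactly the threshold).
- "Interior" scores, where pointwise claims are evaluated in tests, means
  the central score range away from the extreme tails (where frequencies
  vanish and percentile methods clamp).

## Problem sizes in the test suite

The packaged checks run the study at reduced size by design: 50
replications (rather than 500) for the qualitative reproductions —
WSE monotone in n ∈ {500, 1000, 2500}, SE identical across LSSG criterion
families, IRTOSE least biased in NEAT, null-equating WAB < 0.1 — and a
20-replication example in the README. At R = 50 the weighted absolute bias
of an unbiased method is dominated by the Monte-Carlo error of the
replication mean (≈ WSE/√R), which is why the null-equating check is
evaluated on the frequency-weighted aggregate rather than pointwise.

## Known limitations

- Dichotomous items and the 2PL only; no 3PL guessing parameter, no
  polytomous or mixed-format support.
- Monte-Carlo standard errors only; no analytic (delta-method) standard
  errors of equating or SEED bands.
- NEAT post-stratification equating is not implemented (chained only, plus
  the IRTOSE synthetic-population route); no counter-balanced design.
- The bandwidth penalty uses the Gaussian kernel only.
- The generator's shape moments (skewness/kurtosis) match the emulated
  test only approximately, as discussed above.
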