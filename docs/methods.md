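# Methods

## Dominance indices

Hierarchies are inferred from decided directional interactions (supplants).

**Normalised David's Scores.** Dyadic win proportions are corrected for
chance, `Dij = Pij − (Pij − 0.5)/(nij + 1)` with `Dij = 0.5` for unobserved
dyads; `DS = w + w2 − l − l2` where `w2`/`l2` weight the dyadic terms by the
opponents' totals, normalised as `(DS + N(N−1)/2)/N`. Scores lie in
`[0, N−1]` and sum to `N(N−1)/2`.

**Optimised Elo.** Sequential ratings with win probability
`p = logistic((R_w − R_l)/c)` and zero-sum update `±k(1 − p)`. The update
constant `k` is chosen on a grid (default `{0, 5, …, 200}`, bracketing
published primate values) by maximising the total log-probability of
observed winners, with the start values optimised continuously at each `k`
(L-BFGS with exact forward-accumulated gradients — each event's ratings
depend on the start values through all earlier updates). Two identifiability
devices: the mean start value is anchored at 0 (adding a constant to all
start values changes nothing) and a weak ridge (1e-3) regularises
separations that the likelihood cannot resolve (e.g. a dyad never observed).
Grid ties break toward smaller `k`, so a single event returns `k = 0`. The
logistic scale is configurable and defaults to 1; it is absorbed by the
units of the start values. On a temporally static hierarchy the optimisation
selects `k = 0` and the fitted start values carry all rank information; the
rating in force on the first day of a year-block represents that block's
hierarchy.

**Standardisations.** `raw` leaves index values untouched; `ordinal` maps to
ranks 1..N (1 = highest); `proportional` to `(N − ordinal)/(N − 1)`, i.e.
equidistant in [0, 1] with 1 at the top. Ordinal and proportional are exact
affine images of each other (Pearson r = −1 within a block). Tied raw values
are broken by stable id order with a warning — ties are degenerate under a
strictly linear hierarchy. All rank covariates are z-scored over the rows
entering a model before any product terms are formed.

## Model specifications

Six fixed-effect structures for the two ranks of a dyad (sender s, receiver
r), all including sender rank: main effects {z_s, z_r}; higher-ranking
factor {z_s, 1[s outranks r]} with the indicator taken from the raw Elo
index; rank difference {z_s, z_s − z_r}; absolute rank difference as the
full interaction expansion {z_s, |z_s − z_r|, z_s·|z_s − z_r|} (an
additive-only variant is a switch); linear interaction {z_s, z_r, z_s·z_r};
and a tensor-product smooth of (z_s, z_r) plus intercept.

**Tensor smooths.** Marginal cubic B-spline bases of dimension 5 (quantile
knots — robust to skewed rank distributions; 25 tensor coefficients, a
scale suited to tables of a few hundred rows), with marginal penalties
`S_x ⊗ I` and `I ⊗ S_y` built from exact integrated-squared-second-derivative
Gram matrices (Simpson-exact per knot span). Curvature penalties — rather
than coefficient-difference penalties — keep every bilinear surface
`a + bx + cy + dxy` exactly in the combined null space under unequal knot
spacing. A sum-to-zero constraint over the observed rows removes one
dimension so the intercept stays estimable.

## Observation families and priors

Aggression and supplant counts: zero-inflated Poisson. Grooming minutes:
zero-inflated negative binomial (mean–dispersion form, `var = μ + μ²/φ`);
minutes are treated as integer counts. Proximity: Poisson, with the
symmetric data entered as both mirrored directed rows (an option collapses
to unordered dyads). Zero inflation is intercept-only: one structural-zero
probability π per model.

Priors: Normal(0, 1) on fixed effects; half-Normal(0, 1) on the SDs of the
crossed random effects (year, sender identity, receiver identity, and dyad
identity — the dyad is the unordered pair, one id for A→B and B→A);
Beta(1, 1) on π; Exponential(1) on 1/φ. The smooth is fitted by
hierarchical shrinkage: the roughness penalty becomes a Gaussian prior whose
single smoothing SD (shared by both marginal penalties — isotropic
smoothing keeps the outer optimisation low-dimensional) acts on the penalty
range space, while the penalty null space (the bilinear part) is treated
like a fixed effect with a N(0, 1) prior. The log observation effort in
hours enters as an offset.

## Fitting

Two modes share one model object with analytic first and second derivatives
of all three families with respect to the linear predictor.

*MAP/Laplace (default, deterministic).* At fixed hyperparameters
θ = (log RE SDs, log smoothing SD, logit π, log φ) the coefficient mode is
found by damped Newton (observed-information weights, clipped at 1e-10, with
step halving). θ maximises the Laplace-approximate marginal posterior
(Nelder-Mead, warm-started inner solves; xatol 0.02 — hyperparameters do not
need more resolution than that). Posterior draws are Gaussian: coefficients
from the inverse curvature at the joint mode, θ from the numeric Hessian of
the marginal objective. The θ and coefficient draws are sampled
independently, a simplification that slightly understates the propagation of
hyperparameter uncertainty into coefficients.

*HMC.* Hamiltonian Monte Carlo over coefficients and hyperparameters
jointly, preconditioned by the Laplace scales, with dual-averaging step-size
adaptation (target acceptance 0.8) over the first half of each chain;
defaults are 3 chains of 3000 iterations. Gradients are analytic except for
π and φ (central finite differences of the data log-likelihood). On
well-identified fits the two modes agree on fixed-effect point estimates
within a fraction of a posterior SD; the test suite and the multiverse grid
use the MAP mode.

Degenerate cases: a grouping factor with a single level is dropped from the
random effects; non-finite pointwise log-likelihoods are floored and
flagged; a failing fit inside the multiverse grid is recorded as a failed
cell and the grid continues.

**Bayesian R².** Per draw, `var(fitted means)/(var(fitted means) + mean
model-based residual variance)` on the response scale, using the family's
mean and variance functions; degenerate zero-variance predictions give 0.

## Model comparison

PSIS-LOO from the draws-by-observations log-likelihood matrix (conditional
on the random effects, as is standard for these models): per observation the
importance ratios `exp(−loglik)` have their largest 20% (minimum 5)
tail-fitted by an empirical-Bayes generalised-Pareto estimator and replaced
by expected order statistics, capped at the observed maximum. The
tail-shape diagnostic k̂ is reported per observation with a warning above
0.7; constant-draw observations fall back to the unsmoothed estimate. With
the tail fraction matched, the implementation agrees with the independent
arviz reference to machine precision, and on small datasets it sits within
its standard error of exact leave-one-out refits. LOO-IC = −2·elpd; within a
behaviour every model is reported as ΔLOO to the best model (exactly one 0
per behaviour, ties to earlier grid order). SEs are computed but not used
for ranking. Comparisons never cross behaviours.

## Interpretation codes

A coefficient's arrow is `none` if the central 95% credible interval
contains 0, otherwise its direction after orientation normalisation — for
ordinal standardisation the sign is inverted so that "up" always means
higher-ranking individuals show higher rates. Interaction patterns are read
off the posterior prediction surface on a 21×21 grid of (z_s, z_r) within
the observed range (offset and random effects excluded): within each sender
stratum (top/bottom half — the simplest formalisation of a
high-/low-ranking narrative) the mean predicted rate for receivers below
the sender, within the closest quartile of |z_s − z_r|, and above the
sender are contrasted; a code (DTH/CRR/UTH) is assigned when the relevant
ratio exceeds 1.5 with ≥ 95% posterior probability. By construction the
factor and rank-difference specifications can only yield DTH/UTH and the
absolute distance only CRR. The ratio threshold and probability level are
configurable; the defaults are a deliberate formalisation of what is usually
read qualitatively from prediction plots, and the precise code sets near the
thresholds depend on them.

## Synthetic study conditions

The generator mirrors a field study of adult females in one wild group:
18 individuals per year-block (configurable 17–18), 3 blocks, no
within-block turnover; a strictly linear latent hierarchy with equidistant
scores; supplant sequences with uniform dyad selection (the simplest
exchangeable scheme) and logistic outcomes whose scale is tuned so the
expected against-hierarchy proportion is 0.7% — the regime of a clearly
linear female hierarchy; dyad-year tables covering every ordered coresident
pair each year. Counts follow the same log-linear structure the models
assume: baseline, sender/receiver rank effects, DTH boost, CRR distance
decay, UTH boost, crossed random effects, and log-normal dyadic effort
(median 10 h, log-SD 0.5 — strictly positive and right-skewed like field
follow time; how effort is derived from focal follows is outside the
generator, which treats it as given per dyad-year). Per-behaviour presets
produce totals of the order seen in the field (roughly 1000 aggressions, 800
supplants, 3000 grooming minutes, 6000 proximity events per 3-block study)
with heavy zero inflation for the agonistic behaviours. A named
displaced-ridge mechanism provides the genuinely nonlinear scenario: low
senders target closely ranked receivers symmetrically, high senders target
receivers about a quarter of the hierarchy below themselves.

What the generator does *not* emulate: kinship and reciprocity structure,
age/sex classes, demographic turnover within blocks, spatial structure, and
measurement error in the event log. Passing tests therefore show that the
pipeline recovers what it assumes — not that those assumptions hold in any
real population.

## Problem sizes and numerical choices

The test suite runs everything in the deterministic MAP/Laplace mode at
reduced scale, chosen as the smallest sizes at which the scientific
contrasts are clearly resolved: recovery checks use 10 individuals × 1
block (90 dyad rows) with 50 replicates per specification; mechanism
recovery uses 12–18 individuals with 20 replicates per scenario; grid
audits use 10 individuals × 2 blocks. Elo grids in multiverse runs default
to a coarse subset, configurable. Posterior summaries use 300–400 Laplace
draws; 1000 is the library default. Known limitations: Laplace intervals
can be slightly anticonservative for variance components near zero; PSIS
k̂ > 0.7 occurs for a handful of observations in small zero-inflated fits
(warned, expected); the single shared smoothing SD cannot represent
strongly anisotropic surfaces.
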