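# Methods

This note documents the models implemented in `benthic_encounters`, the
defaults and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## Functional responses and the depletion correction

The generalised functional response
`f(N) = b N^(q+1) / (1 + b h N^(q+1))` nests the classical types:
type I (linear, `h = q = 0`), type II (hyperbolic, `q = 0`) and type
III (sigmoidal, `q = 1`), with the general model leaving `q >= 0`
free.  Units: `b` is in individuals^-q x arena-units per time, `h` in
time per resource unit, `q` dimensionless.

Non-replacement trials deplete resources, so fitted expectations come
from the Rogers random-predator equation
`Ne = N0 (1 - exp(c (h Ne - T)))`.  Two conventions exist for the
density dependence of the depletion coefficient; we default to
`c = b N0^q` because it reduces exactly to the classic Rogers equation
at `q = 0` and matches the instantaneous per-capita attack `b N^q` of
the generalised response, while the steeper `c = b N0^(q+1)` variant is
available via `exponent_convention="q_plus_1"`.

### Solver

For `h > 0` the unique root in `[0, N0]` has the Lambert-W closed form
`Ne = N0 - W(c h N0 e^{-c (T - h N0)}) / (c h)`.  The W argument
overflows for strongly depleting parameter combinations, so when its
logarithm exceeds 700 we evaluate `W(e^y)` by the rapidly converging
iteration `w <- y - log(w)`.  A bracketed Brent root-finder over
`[0, N0]` (with the exponent clipped at 700) provides an independent
second path; the test suite requires the two to agree to 1e-8 relative
over a ~10^3-combination grid spanning `b` in [1e-4, 10], `h` in
[0, 10], `q` in {0, 0.5, 1, 2} and `N0` in [1, 1e3].  At `h = 0` the
equation collapses to `N0 (1 - e^{-cT})`.

### Likelihood and optimisation

Each replicate contributes `Binomial(eaten | N0, Ne/N0)`; probabilities
are clipped to `[1e-9, 1 - 1e-9]`.  Optimisation is over `log b` and
`log h` (scale invariance; the `h -> 0` boundary maps to a finite
parameter range) with `q` box-constrained to `[0, 5]`, using L-BFGS-B
from a coarse multi-start grid (5 `b` scales x 3 `h` scales x 3 `q`
values, seeded from crude moment estimates) to escape local optima.
Standard errors are Wald errors from a central finite-difference
observed-information matrix, delta-transformed back to the natural
scale.  Trial sets with no consumption at all return a flagged null
fit (`b = 0`) rather than an error; non-convergence of every start is
flagged, never silently returned.

### Model selection

`AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)` with `n` the number of
replicate rows.  The lowest-AICc variant wins outright; when fits are
competitive (delta AICc < 2) the proportional-consumption diagnostic
decides: flat -> type I, decreasing -> type II, rise-then-fall -> type
III, with the general model classified as II-like (`q < 0.5`) or
III-like (`q >= 0.5`).  The diagnostic smooths per-density-level mean
proportions with lowess (span 0.75) on the log-density axis — per-level
means because replicate-level smoothing at that span washes out
interior structure on geometric density designs — and declares "flat"
when the smoothed end-to-end change is below 5% of the mean proportion
per decade of density.  Both span and tolerance are exposed.

### Derived rates

Responses with different `q` are made commensurable by evaluating the
effective attack coefficient `b N^q` at the half-saturation density
`N_half = (b h)^{-1/(q+1)}`, which equals `b` itself at `q = 0`.  A
local-slope alternative (`mode="derivative"`, the curve's derivative at
`N_half`) is provided because "the slope at half-saturation" admits
both readings.  Rates are converted to biomass units (g per day, per
m^2 or m^3 via the arena measure) for the meta-analysis.  Maximum
feeding rate is `1/h` (infinite, and excluded downstream, for
unsaturating fits).  Mean shape exponents are compared between
strategies by within-group bootstrap (default 2000 resamples,
percentile intervals) because fitted `q` values mix exact 0s and 1s
with positive reals.

## Synthetic data

The generator draws eaten counts `Binomial(N0, E[Ne]/N0)` around the
deterministic depletion expectation — deliberately the same expectation
the estimator uses, so recovery tests probe the estimator rather than
model mismatch.  Meta-level datasets draw consumer masses log-uniformly
over 1e-6 to 1e2 g (eight orders of magnitude), give each pair true
`b` and `h` from mass power laws with log-normal scatter (sigma 0.3),
and draw `q` from a mixture of exact 0s (p = 0.5), exact 1s (p = 0.3)
and half-normal positives — mirroring the empirical predominance of
type-II and type-III forms.  Strategy-specific regimes give filter
feeders the smallest resources at the highest unitary densities and a
3-D arena.  Replicates per density level default to 10 (a free design
choice; source studies rarely report it) and density series are
doubling by default.  Each pair consumes an independent RNG substream
spawned from the master seed, so partial regeneration leaves other
pairs' draws untouched.

What the generator does *not* emulate: event-level depletion
stochasticity (binomial noise is an approximation to the full birth-
death depletion process), overdispersion between replicates,
digitisation error in literature-mined data, and correlated covariates
(e.g. temperature-latitude structure).  Passing recovery tests
therefore demonstrate estimator correctness under the assumed noise
model, not robustness to real-data misspecification.

## Allometries

- Velocity-length: `V = 2.67 l^1.05` (m/s, l in m), a literature refit
  of compiled swimming/crawling speeds.
- Length-mass: `l = (m / rho)^(1/3)` with tissue density 1 g/cm^3
  (neutral buoyancy) and an optional shape factor; 1 g maps to 1 cm.
- Reaction distance: `r = r0 m^0.36`; the exponent is a literature
  value, the coefficient `r0 = 0.01` m g^-0.36 is a declared
  calibration constant.
- Clearance-region radius: a filter feeder clearing `Q` m^3/s from a
  current `U` has an effective seabed-hemisphere radius
  `r = sqrt(2Q / (pi U))` — a flux-balance reconstruction (the
  hemisphere's flow-facing half-disc intercepts exactly `Q`), offered
  as a sensitivity alternative to the reaction-distance radius.
- Per-strategy resource regimes (unitary resource mass and density vs
  consumer mass) are configuration values chosen to span realistic
  ranges — filter feeders: ~1e-8 g resources at ~1e7 m^-3; active
  searchers: 1e-2 to 1 g resources at 10-30 m^-2 — and are meant to be
  overridden by `fit_power_law` on real data.  The
  `minimum_density_law` helper fits per-consumer-mass minima (or a low
  quantile) because encounter-limited feeding is governed by resource
  scarcity.

## The encounter simulator

One consumer occupies a square toroidal arena (side auto-sized to hold
at least 30 resources at the strategy's density and at least 4 reaction
distances; 3-D slab height 10 reaction distances).  Movers take steps
of `speed * dt` with heading perturbed by Normal(0, 30 deg) per step
(a uniform-heading redraw mode exists); 3-D walkers perturb a unit
direction vector isotropically.  `dt` adapts to
`min(r / (5 v_max), 1 s)` so nothing tunnels through an encounter
region between checks.  Encounter = position inside the region at a
step boundary (in-plane distance for the discoid, Euclidean distance
for the seabed hemisphere); encountered resources are immediately
relocated uniformly so density is conserved — encounters, not feeding,
are modelled (no capture probability, handling or satiation).

The laminar current is drawn per resource and step as
Normal(0.1, 0.01) m/s in +x ("± 0.01" read as a standard deviation).
Planktonic resources reflect at the seabed and slab ceiling.  When a
planktonic resource wraps in x it re-enters with freshly uniform
cross-flow coordinates: the wrap represents an uncorrelated upstream
water parcel, and this boundary condition makes the simulated steady
state match the advective flux `n U pi r^2 / 2` exactly (without it, a
purely advected field near the hemisphere is progressively depleted
because relocation alone cannot remix the cross-flow plane).

Very high resource counts (filter feeders can imply >1e5 per arena) are
capped (default 2000) and rates rescaled by the density ratio — exact
in the encounter-limited regime because independent resources
contribute additively.

### Validation and a known bias

Kinetic-theory oracles: `2 r V n` for a 2-D searcher among static
resources, `2 r <V_rel> n` with the elliptic-integral mean relative
speed when both parties walk, and `n U pi r^2 / 2` for the advective
hemisphere.  Validation runs use short replicates from a fresh field:
with *static* resources and long runs, a subtle conditioning effect
inflates rates — a resource that has survived since its last relocation
is uniform over the *unswept* region only, so the consumer's leading
edge sees enhanced density once its path has covered an appreciable
arena fraction (measured at roughly +35% when a replicate sweeps ~100%
of the arena; ~+4% at the ~12% coverage used for validation).  Mixing
(resource motion, advective re-injection) removes the effect, which is
why the filter scenario needs no such care.  Long default runs for
*active* strategies therefore overestimate absolute rates somewhat;
strategy orderings and mass scalings, which span orders of magnitude,
are unaffected.

Mass sweeps report medians, means and 0.025/0.975 quantiles across
replicates (default seed-spawned substreams per mass x replicate);
quantiles from fewer than 40 replicates are flagged unstable.  At small
consumer masses and short runs most active-search replicates record no
encounter, so medians can be zero while means remain informative; the
strategy-ordering checks use means.  Problem sizes in the test suite
(e.g. 1500 steps x 20 replicates x 3 masses for the ordering check, 100
x 500-step replicates for 2-D validation) were chosen as the smallest
designs whose Monte-Carlo error is comfortably below the effect sizes
under test.

## Meta-analysis

Capture and maximum feeding rates are log_e-transformed and z-scored
across the table; masses are log_e grams.  Temperature enters as
log_e(deg C) — deliberately not an Arrhenius correction, which is
available behind `temp_transform="arrhenius"` for sensitivity analysis;
records at <= 0 deg C are rejected with an explicit message under the
log axis.  Candidate fixed-effect structures are the 36
marginality-closed combinations of the three metabolic predictors,
their two-way interactions, and the strategy term.  Comparison fits use
maximum likelihood (not REML) so likelihoods are comparable across
fixed structures; `k` counts fixed effects plus both variance
components.  The default optimiser occasionally drives the group
variance exactly to zero and returns a non-finite likelihood; such fits
are retried with Powell's method and flagged `variance_boundary` when
the variance sits at the boundary.  Fit failures are recorded in the
ranked table and excluded from ranking.  Prediction bands case-resample
records stratified by strategy (preserving group sizes), refit the
selected structure, and take 2.5/97.5 percentiles of the fixed-effect
prediction over a log-mass grid at median covariates; resamples that
fail to fit are redrawn up to a capped number of attempts.

## Pipeline

Stages run in dependency order (generate -> fit -> meta -> simulate)
with every CSV artifact schema-validated before use and recorded in a
JSON manifest (path, rows, SHA-256, input hashes, seed).  All
randomness derives from one master seed via named substreams; a stage
whose inputs, seed and output hashes match the prior manifest is
skipped as a no-op.  Exit codes of the CLI: 0 ok, 1 validation error,
2 runtime error.

## Limitations

- Type IV (dome-shaped) responses, predator interference and
  replacement designs are out of scope (`holling_rate` is provided as a
  utility only).
- The binomial likelihood treats replicates as independent and
  identically distributed around the depletion expectation;
  overdispersed data will understate parameter uncertainty.
- Wald standard errors can be poor near the `h -> 0` boundary.
- The simulator's hydrodynamics are a uniform laminar slab — no
  boundary layers, turbulence or siphon-scale flow; filter-feeder
  detection is a phenomenological region, not a particle-capture model.
- Sit-and-wait, deposit-feeding and grazing strategies appear in the
  data model and generator but are not simulated and are excluded from
  mixed-model fitting, mirroring their scarcity in compiled datasets.
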