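# Methods

This note documents the models implemented in `edna_dispersal`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Decay kinetics

Concentrations follow either a single exponential, C(t) = C₀₀·e^(−k·t),
or a two-exponential mixture, C(t) = C₀₁·e^(−k₁·t) + C₀₂·e^(−k₂·t), with
t in hours since shedding and concentrations in ddPCR copies·µL⁻¹. The
mixture covers both empirical departures from simple decay with one
parameterization: *biphasic* decay has both amplitudes positive and
k₁ ≫ k₂ (a fast phase draining into a persistent one), while *delayed*
decay is encoded by one negative amplitude (C₀₁ < 0, C₀₁ + C₀₂ ≥ 0): the
negative fast component represents DNA that is initially present but not
yet measurable, so the observed concentration rises for the first hours
before declining. Validity requires C(t) ≥ 0 over the modelled range;
the parameter containers enforce the sign constraints that can be checked
locally (k ≥ 0, C₀₁ + C₀₂ ≥ 0) and the series generator rejects truth
curves that go negative at any sampled time.

The decay rate depends on water temperature as k(T) = a·e^(b·T) with
defaults a = 0.0419 h⁻¹ (rate at 0 °C) and b = 0.0776 °C⁻¹ — the median
decay–temperature relationship for teleost-fish eDNA. It is accepted
over −2…35 °C; outside that range the empirical law has no support.

**Half-life** is defined as the smallest t with C(t) = C(0)/2 and found
by expanding-bracket bisection to 10⁻⁶ h, returning `inf` when the curve
never halves (no decay, k = 0). For scenario objects the expected-count
curve is used: the biphasic mixture halves at ≈ 2.41 h — noticeably
faster than the slow tail suggests, because 70% of the material drains at
0.50 h⁻¹ — and the delayed scenario (tripling first, then decaying at
k(12 °C)) halves only at ≈ 22.8 h.

**Fitting.** Both forms are fitted to replicate-level data by nonlinear
least squares on concentrations with seeded multi-starts over log-spaced
rate grids. Each temperature level has its own fixed-effect parameters
(2 or 4); each (temperature × tank) group has a log-amplitude offset
constrained to sum to zero within its temperature — the deterministic
analogue of a random intercept on log-amplitude, chosen because the
emulated experiment's tanks differ by a level factor, not by decay rate.
Internally the search uses variable projection: given rates and offsets
the amplitudes enter linearly and are solved exactly, so the nonlinear
search runs over at most three parameters per temperature, is fast, and
recovers noiseless data to machine precision. AIC is computed from the
pooled Gaussian log-likelihood (σ² = SSR/n, p = fixed parameters +
offsets + 1); R² = 1 − SSR/SST on the pooled observations. Outlier
handling is explicit only: `exclude_times` removes whole sampling hours
and records them on the result — no automatic detection.

Known limitation: under the generator's constant-CV multiplicative noise
the homoscedastic Gaussian likelihood is misspecified. This barely
affects parameter recovery (the slow-phase rate of the delayed truth is
recovered with ≈ 10% median relative error at CV = 0.2), and
delayed-vs-exponential selection is essentially perfect, but when the
truth *is* a single exponential the large absolute scatter of early
high-concentration samples lets a spurious second component outbid its
AIC penalty in roughly a third of datasets. The same selection is
reliable when the noise is additive and homoscedastic. A CV-weighted or
log-scale likelihood would remove the asymmetry at the cost of departing
from the plain Gaussian NLS model documented here.

**Classification** of a single-condition series applies ordered rules to
the per-time replicate means: a rise of more than 25% over C(0) within
the first 6 h ⇒ delayed; otherwise a two-exponential fit with both
amplitudes positive, rate ratio ≥ 5 and lower AIC than the single
exponential ⇒ biphasic; otherwise exponential. Fewer than two sampling
times inside the early window makes the series unclassifiable — the
early phase is where the patterns differ, which is also why decay
studies that skip the first 12 h cannot distinguish them.

## Synthetic flow fields

The generator emulates the *statistical character* of hourly surface
currents at two coastal sites, not their bathymetry or coastline. The
velocity is

u = u_res + A(t)·(cos θ(t), sin θ(t)) + u_eddy(x, y),

with θ advancing at the semidiurnal period 12.42 h (an anticlockwise
rotary tide), A(t) = A₀·(1 − m·cos(2π t / 14.8 d)) a spring–neap
envelope, u_res a steady residual in a seeded random direction, and
u_eddy a steady divergence-free perturbation from a random streamfunction
whose modes have wavelengths of 10–20 grid cells (so bilinear
interpolation is meaningful and the discrete divergence of the tide, a
spatially uniform field, is identically zero). Site parameters were
chosen once so the speed series at the release point spans the declared
envelopes: the dynamic site (A₀ = 1.1 m s⁻¹, m = 0.9, residual
0.04 m s⁻¹) peaks at ≈ 2.1 m s⁻¹ at spring tide and drops to
≈ 0.06–0.08 m s⁻¹ at neap (envelope 0.01–2.4); the quiet site
(A₀ = 0.25, m = 0.8, residual 0.02) stays within 0.02–0.5 m s⁻¹
(envelope 0.01–0.6). The generator validates the generated series
against the envelope and raises if a parameter change breaks it.

Temperature is spatially uniform and constant per run, 12 °C by default:
the implied exponential decay rate k(12 °C) ≈ 0.106 h⁻¹ matches a 6.5-h
half-life, consistent with the winter-month release schedule the
pipeline emulates. Fields are written as classic netCDF (dims
time/lat/lon; u, v in m s⁻¹, temp in °C; grid spacing recorded in
metres).

Not emulated: bathymetry, land masks, 3-D shear, baroclinic structure,
sigma-coordinate regridding, and any spatial correlation between
temperature and flow. Passing tests therefore demonstrate correctness of
the transport/decay machinery under controlled forcing — not realism of
any particular coastal sea.

## Particle tracking

Trajectories integrate dx/dt = u(x, t) with the classical fourth-order
Runge–Kutta scheme at a fixed 180-s step, converting metric velocities to
angular rates with a local equirectangular scaling (cos-latitude, Earth
radius 6 371 000 m) — adequate for the ≤ 50 km footprints simulated here.
Unresolved motion is a per-axis Gaussian random walk with standard
deviation √(2KΔt), K = 1 m² s⁻¹ by default, giving the 2-D law
MSD = 4Kt. A particle whose RK4 stages or diffused position leave the
grid is marked dead at its last in-domain position and never revived.

Decay is a per-step Bernoulli survival draw with probability
e^(−k·Δt) — the semigroup-consistent choice, so survival over an hour of
3-min steps equals one draw at the hourly rate. The four scenarios:

* **no_decay** — nothing dies (transport-only reference);
* **exponential** — k = k(T) with T sampled from the field at each
  particle's position;
* **biphasic** — the release is split exactly (round(0.7N) fast at
  0.50 h⁻¹, remainder slow at 0.013 h⁻¹, membership a seeded
  permutation) and each particle keeps its group's constant rate;
* **delayed** — during the first 6 h, at each whole hour,
  round(0.2·N_alive) particles chosen without replacement are duplicated
  in place (children get fresh ids and their parent recorded), tripling
  the count by hour 6 (1.2⁶ ≈ 2.99; the exact-count engine gives
  29 860 ± 1 from 10 000); no decay draws during the growth phase, then
  exponential decay. Treating the growth phase as division-only is a
  modelling choice: the alternative (decay running concurrently with
  division) would damp the early surge.

Randomness is split into two seeded streams per event: *transport* noise
keyed by (master seed, site, release time) and *fate* draws keyed by the
full event id. Scenarios of the same release therefore see identical
currents and identical diffusion draws (array-aligned even as divisions
append particles), so scenario contrasts are paired — decay differences
are not diluted by transport noise — while remaining independently
reproducible event by event.

The release schedule places one event per (site, scenario, time) at a
fixed cadence across whole months: 2-hourly releases over January and
September 2018 give 372 + 360 = 732 release times, 2 928 events across
four scenarios for one site, and 29.28 million initialized trajectories
at 10 000 particles per event. Sites enter multiplicatively (two sites
double the counts).

## Dispersal metrics

For each (scenario, event, hour), computed from living particles only:
count alive; centre of mass as the plain arithmetic mean of longitudes
and latitudes (per the event-metrics convention; not a spherical
centroid); mean distance as the haversine distance (R = 6 371 km) from
the release point to the centre of mass; dispersion as the mean squared
haversine distance of particles from the centre of mass (km²);
convex-hull area from a local tangent-plane projection about the centre
of mass (scipy's Qhull; a rank check returns exactly 0 for collinear
clouds; adequate below ~50 km); and density = alive / hull area
(particles km⁻²). Hours with no survivors or a zero-area hull carry NaN
sentinels and are never silently dropped, so ρ·A = N holds exactly
wherever both sides are defined. Relative density divides each event's
density by the across-event *median* density of a reference scenario at
the same hour and summarizes the ratios by their median and 20–80%
percentile band.

## Variance decomposition

The four continuous metrics are z-scored within standardization groups —
by default (metric × site), which preserves scenario level differences;
the literal (metric × site × scenario) grouping is available but removes
scenario main effects by construction, and the choice is recorded in the
output metadata. Constant groups become all-zero with a flag rather than
an error. Hour 0 is excluded from the decomposition: the plume is a
point mass at release, so density is undefined there, leaving 24 hourly
levels.

The standardized long table is decomposed by ordinary least squares with
sum-to-zero contrasts: fixed effects for scenario, metric and hour (an
unordered factor), all interactions, and the release event as a fixed
blocking factor — a deterministic, closed-form stand-in for a random
intercept; exact replication of mixed-model software output is out of
scope. Type III sums of squares are reported with
partial η² = SS_term / (SS_term + SS_residual), which is invariant to
affine rescaling of the response; on balanced designs the decomposition
is orthogonal, so the term and residual sums of squares add to the total.
Factors with a single level are dropped from the formula, letting a
one-factor table collapse to a plain one-way ANOVA. Missing cells abort
with the offending cells named. p-values are reported raw (no
multiple-testing correction).

## Synthetic tank experiment

The series generator reproduces the emulated experiment's design: three
temperature treatments (13, 20, 27 °C), two tanks, three technical
replicates, sampling at t = 0, 0.5, 1, 2, 4, 6, 23, 26 h. The default
truth is a delayed curve per temperature, built as
C₀₂ = C(0)/f with f = 0.1 of the pool initially detectable, release rate
k₁ = 0.5 h⁻¹ and decay rate k₂ = k(T) from the temperature law — giving
the observed several-fold rise over the first ~4–6 h. Tanks differ by a
fixed multiplicative level offset (default ratio 2, applied symmetrically
in log space so the across-tank geometric mean follows the truth curve).
Noise is multiplicative lognormal with unit mean and CV 0.3 by default
(0.2 in the model-selection study) — matching the high unexplained
variability of replicate-level ddPCR data; it does not emulate
zero-inflation, droplet counting error, or pipetting covariance between
technical replicates.

## Problem sizes used in the checks

The test suite exercises the survival laws at 10 000 particles per event
(binomial standard errors are then small enough to resolve the closed
forms), the diffusion law at 10⁵ walkers, and the scenario-contrast
study at a reduced scale of 50 releases × 2 000 particles × 3 scenarios
in a synthetic quiet-site field — enough events for stable per-hour
medians and percentile bands of the relative density. At that scale the
delayed scenario's median density relative to exponential rises to a
peak of ≈ 4.6× at hour 6 and stays above 1 throughout, and the biphasic
scenario drops to ≈ 0.65× early and crosses above 1 near hour 13: the
orderings are robust, but the exact multiples and crossing hour depend
on the forcing and on the growth-phase convention, so only the ordering
is asserted.
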