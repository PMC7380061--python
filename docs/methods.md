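# Methods

## The model

`sizebef` is a trait-based plankton ecosystem model in which cell size —
the master trait, expressed as log cell volume `l = ln V` (V in μm³;
equivalent spherical diameter d gives `V = (π/6) d³`) — controls all
phytoplankton physiology:

- maximal growth rate `μ_m(l) = μ0 exp(α_μ l + β_μ l²)`, unimodal
  (β_μ < 0) because picoplankton pay higher respiratory costs;
- half-saturation constants for nitrogen and dissolved iron,
  `K(l) = K0 exp(α l)`, increasing with size (small cells are gleaners);
- the initial slope of the photosynthesis–irradiance curve,
  `α_c(l) = α0_c exp(α_I l)` with `α_I < α_K` (light selects on size more
  weakly than nutrients).

Realised growth follows Liebig's law over Monod terms times a saturating
light response:

    μ(l, N, fer, I) = μ_m · min(N/(N+K_N), fer/(fer+K_fer)) · (1 − e^(−α_c I / μ_m)).

The cellular N:C quota is flexible,

    Q_N = Q_min / (1 − (1 − Q_min/Q_max) L),   L = min-limitation ∈ [0, 1],

bounded in [Q_min, Q_max] and rising with nutrient availability. Carbon
production per unit nitrogen biomass is `μ/Q_N`, so well-fed (high-Q_N)
communities yield *less* carbon per unit nitrogen — the stoichiometric
counterweight that recurs in every diagnostic.

### Moment closure

Instead of resolving species, the community is summarised by biomass P,
mean trait `l̄` and trait variance `v` (the size-diversity metric),
closing growth at second order in the trait:

    μ_com     = μ(l̄) + (v/2) μ''(l̄)
    d l̄ / dt = v μ'(l̄)                 (Fisher selection / insurance effect)
    d v / dt  = v² μ''(l̄)              (competitive exclusion near a peak)

Community carbon production applies the same closure to `μ/Q_N`:

    NPP = 12 P [ (μ/Q_N)(l̄) + (v/2) (μ/Q_N)''(l̄) ]   (mg C m⁻³ d⁻¹).

The closure is exact for trait-quadratic fitness; against 64-node
Gauss–Hermite quadrature over a normal trait distribution it stays within
2% for v ≤ 0.2 (tested). Trait derivatives are central finite differences
with step 1e-3 ln μm³; at a Liebig crossover the derivatives follow the
limiter active at `l̄` exactly (ties to nitrogen). An analytic-derivative
path would be possible; finite differences are the contract because they
extend unchanged to `μ/Q_N` and to forced-limiter evaluations.

### The box ecosystem

Eight tracers: N, P, Z, D (nitrogen units), dissolved and detrital iron,
and the raw moments `P l̄` and `P(l̄² + v)`, which advance like ordinary
tracers (so the same state could be advected in a spatial model).
Process structure:

- uptake `P μ_com`; Holling type-III grazing `g_max Z P²/(K_p² + P²)`;
  linear phytoplankton mortality; quadratic zooplankton mortality (routed
  to detritus); detritus remineralisation and export; mixing/dilution of
  the dissolved pools toward (seasonally forced) deep concentrations —
  the box stand-in for advection and entrainment. Grazing is split
  GGE → Z, unassimilated fraction → D, remainder excreted → N.
- iron mirrors nitrogen at a fixed Fe:N ratio with scavenging on the
  dissolved pool; phytoplankton and zooplankton iron are implicit, so
  total iron `fer + DETFe + R(P+Z)` is conserved in the closed
  configuration, as is total nitrogen `N+P+Z+D` (< 1e-8 relative over
  10 years, tested at ~1e-12).

Two mechanisms sustain diversity against exclusion:

- **trait diffusion** (coefficient u): offspring appear in neighbouring
  trait classes (mutation / transgenerational plasticity), a variance
  source `dv = 2 u μ(l̄) δl²` with class width δl = 1 ln μm³;
- **kill-the-winner grazing** (coefficient a_g): size-specific grazing
  ∝ (biomass density)^(1+a_g). For a Gaussian trait distribution the
  grazed material is Gaussian with variance v/(1+a_g), so survivors keep
  their mean, and variance grows at `(G/P) v a_g/(1+a_g)`.

Both forms honour their qualitative definitions (zero at zero
coefficient, non-negative variance sources, monotone in the coefficient);
equilibrium v is strictly increasing in each (tested), and with both off
under constant forcing v erodes hyperbolically toward its floor
(`dv/dt = v²μ''` never reaches the floor in finite time; tests assert
monotone decay and a large decrease, not attainment).

### Discrete counterpart

The n-species model shares the physiology and all pool couplings; each
species is a fixed trait point (no mutation), and kill-the-winner
allocates total grazing ∝ `P_i^(1+a_g)`. It serves both as the richness
experiment engine and as the brute-force closure oracle: a 2000-bin
Gaussian community tracks the moment model's (P, l̄, v) trajectory within
5% RMS on l̄ over a seasonal year (tested).

## Numerics

RK4 with a nominal step of 0.05 d. Seasonal bloom drawdowns are stiff:
the linearised uptake rate `P μ_m K/(N+K)²` reaches ~100–250 d⁻¹ when a
bloom (P ~ 10–20 mmol N m⁻³ under the default mixing and high-amplitude
supply) exhausts the mixed-layer nitrogen. Each step is therefore bounded
by (a) that rate times the step staying well inside the RK4 stability
region and (b) a "cliff" bound — no step may consume more than 60% of a
pool plus its half-saturation — so stage evaluations never approach the
Monod pole at `pool = −K`. An absolute step floor of 1e-4 d applies; below
it the post-step clamp (negatives zeroed, the deficit charged to the
largest pool of the same element, so budgets close exactly) absorbs the
residual jitter, and clamp events are counted in the run metadata.
Sustained negative excursions beyond −0.1 abort the run as instability.
Daily outputs are trapezoidal time-weighted means; derived diagnostics
(μ, Q_N, NPP, curvature) are evaluated at the daily-mean state with
mid-day forcing. The integration kernels are numba-compiled; replicate
batches integrate as columns of one array and share the adaptive step
sequence, which keeps a 400-replicate, 10-year sweep at a few minutes on
one CPU and makes the across-level comparison numerically uniform.

Floors: biomass 1e-6 mmol N m⁻³ (a seed stock that lets a community
recover when conditions improve; the mean trait is preserved through the
floor so a maladapted community cannot "teleport" to a better size), and
variance 1e-4 (ln μm³)², the competitive-exclusion asymptote.

## Synthetic forcing

Deterministic sinusoids emulate the seasonal variability structure of a
mid-latitude ocean water column: deep-nutrient concentration
`supply_mean (1 + A sin(2πt/365))` with A = 0.2 (low) or 0.8 (high
variability treatment), iron supply in phase with nitrogen, light
(mean 100 W m⁻², relative amplitude 0.3) peaking half a period after the
nutrient supply (winter mixing vs. summer stratification), temperature
constant at 15 °C. The annual-mean supply is exactly amplitude-independent,
so amplitude changes variability without changing mean input. An optional
Eppley-type temperature factor on μ_m exists but is off in all shipped
configurations. What this forcing does *not* emulate: vertical structure,
self-shading, storm-scale (weather) variability, advective transport of
the moments between water masses, and iron deposition events; passing
tests therefore speak to the seasonal-cycle mechanism only, not to
spatial effects, which can sustain diversity by themselves.

## Idealised experiments

- **Continuous / fixed variance**: variance pinned at each level of
  {0.001, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0} (ln μm³)²; 50 replicates
  per level; each replicate draws an initial `l̄` uniformly on
  [−2.73, 15.2] ln μm³ (0.5–200 μm); 10 years; annual NPP = mean daily
  NPP of the final year (the integral variant is a config option).
- **Discrete / richness**: n = 1..10 species at uniform random trait
  positions, equal initial biomasses, 50 replicates, otherwise identical.

Seeding: the master seed spawns one child stream per (level index,
replicate) by counter, so reruns are bit-identical and appending levels
never reshuffles existing replicates. Within an amplitude treatment the
diversity level is the *only* difference across levels. Initial pools
(N = 2, Z = 0.1, D = 0.1, fer = 0.6, DETFe = 0.01, P = 0.25 mmol N m⁻³
equivalents) are mid-range values whose transient washes out well before
the analysed final year.

Observed behaviour under the shipped defaults (recomputed by
`scripts/acceptance.py`, not asserted here): the continuous curve rises
by almost an order of magnitude from the lowest level (immobile mean
trait, productivity set by the luck of the initial size) to the
0.02–0.2 plateau and declines at v ≥ 0.5 (the unproductive-edge
penalty); the exact interior level holding the maximal median is
parameter-sensitive since the plateau levels differ by under 2%. The
richness curve rises steeply to n ≈ 4 and plateaus. At the lowest
diversity levels the low-amplitude treatment out-produces the
high-amplitude one: an immobile community cannot track a strongly
varying environment.

## Attribution diagnostics

- **Chain-rule split** of ΔNPP/Δcoefficient between a paired run into six
  routes (P, μ, Q_N, curvature, P×curvature, v). Non-differenced factors
  are evaluated at the (A+B)/2 midpoint — second-order accurate for the
  product forms — and the residual (exact total minus the term sum) is
  always reported rather than folded in.
- **Seasonal Taylor expansion** of the window-mean growth rate to second
  order around the annual means of (l̄, limiting nutrient, light), using
  population (ddof = 0) moments of the daily series — the convention for
  which reconstruction is exact when fitness is quadratic (tested to
  1e-10). The limiting nutrient is chosen per window (flagged if the
  Liebig branch switches inside it); cross-derivatives are central finite
  differences with relative steps 1e-3.
- **Size observables**: picophytoplankton fraction Φ((l_c − l̄)/√v) under
  the lognormal assumption (threshold 2 μm by default, 3 μm available)
  and size diversity = trait variance.

## Known limitations

- The box model is a 0-D stand-in: mixing/dilution subsumes advection and
  entrainment, and results scale with that single rate rather than a
  circulation field.
- One zooplankton compartment; no light attenuation with depth; no
  chlorophyll state; no phosphorus or silicon.
- The closure carries no skewness/kurtosis; strongly bimodal transients
  (two competing size modes) are outside its validity, which the
  discrete-model comparison bounds but does not eliminate.
- The trait-diffusion and kill-the-winner closed forms are this package's
  concrete realisations of their verbal definitions; their contracts
  (zeros, signs, monotonicity) are the tested surface, and quantitative
  results depend on the chosen forms.
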