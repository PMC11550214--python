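# Methods

## The biokinetic models

`biokin` models the whole-organism concentration `C_org(t)` of a contaminant
(typically an engineered nanomaterial) in an invertebrate during a two-phase
exposure experiment: an uptake phase in contaminated medium until time `t_e`,
then depuration in clean medium until `t_total`.

**One-compartment (OC) model.** The organism is a single well-mixed
compartment with first-order exchange against the medium:

    uptake (0 <= t <= t_e):
        C(t) = C0 + Cexp * (k1/k2) * (1 - exp(-k2 t))
    elimination (t > t_e):
        C(t) = C0 + Cexp * (k1/k2) * (exp(-k2 (t - t_e)) - exp(-k2 t))

with `k1` the uptake rate constant (L or kg of medium per kg organism per
time), `k2` the elimination rate constant (per time), `Cexp` the
exposure-medium concentration and `C0` the initial body burden. During
prolonged exposure the burden plateaus at `C0 + Cexp * k1/k2`
(`steady_state_burden`).

**Stored-fraction (OC-SF) model.** Organisms such as isopods and earthworms
sequester part of the absorbed material (hepatopancreas, chloragogenous
tissue) where it is no longer subject to first-order elimination. A
dimensionless stored fraction `SF` of the influx accrues linearly and is
retained through depuration; the remaining `1 - SF` follows OC kinetics:

    uptake:       C(t) = C0 + SF*Cexp*k1*t   + (1-SF) * [OC uptake term]
    elimination:  C(t) = C0 + SF*Cexp*k1*t_e + (1-SF) * [OC elimination term]

`SF = 0` collapses OC-SF onto OC exactly, so the two models are nested
(2 vs 3 fitted parameters). Storage operates in **both** phases, not only
during depuration.

Conventions and edge cases:

- `t = t_e` is evaluated on the uptake branch; both branches agree there
  (verified to 1e-9 in the tests), so this is a labelling convention only.
- The background burden `C0` is treated as inert: it persists through
  elimination exactly as the closed forms state.
- `k2 = 0` is rejected rather than replaced by its linear limit; the fitting
  box keeps `k2 >= 0.001` anyway.
- No unit conversion is performed anywhere. `k1`, `k2` and concentrations are
  interpreted in whatever units the scenario declares (the bundled scenarios
  mix per-hour aquatic and per-day soil kinetics).
- Simulation grids are `{0, dt, 2dt, ...}` up to `t_total`, with `t_e`
  inserted when it is not a grid point so the kink is always represented.

## Genetic-algorithm nonlinear regression

The fitted parameters minimise the unweighted residual sum of squares (RSS)
over all observation points, replicates included. The RSS surface is
ill-conditioned: `k1` and `k2` are nearly collinear when the data end before
the uptake plateau, and the OC-SF surface adds a shallow `SF` direction.
Gradient-based and Levenberg-Marquardt fitters need good starting values
here; the bounded real-coded genetic algorithm does not, which is why it is
the fitting engine.

Configuration (defaults in `FitConfig`):

| setting | default | notes |
| --- | --- | --- |
| population size | 1000 | candidate parameter vectors per generation |
| steady-fitness window | 300 | stop after this many generations without improvement of the best RSS |
| generation cap | 10 000 | hard termination guarantee |
| mutation probability | 0.2 | per gene |
| crossover probability | 0.5 | per consecutive pair, single-point |
| tournament size | 3 | selection pressure |
| k1 box | [0, 1e6] | bundled fitted values reach ~3.1e4; the bound leaves a wide safety margin |
| k2 box | [0.001, 100] | observed k2 rarely exceeds ~3; upper bound inflated as a margin |
| SF box | [0, 1] | definition of a fraction |

Design choices that were genuinely open:

- **Gene encoding.** The rate genes are evolved as `log10(k1)` and
  `log10(k2)`; `SF` stays linear. A linear encoding cannot refine parameters
  like `k1 = 0.196` inside a `[0, 1e6]` box — uniform mutation essentially
  never proposes values below 1, and the selection pressure then strands the
  population on ridge local optima. On the log scale every decade is equally
  reachable and the same operator refines `k1 = 0.06` and `k1 = 3e4` equally
  well. A zero lower bound is floored at 1e-12 of the upper bound in gene
  space, indistinguishable from zero at data scale.
- **Mutation operator.** Per-gene, a 50/50 mixture of (i) uniform reset over
  the gene range — the classical real-gene mutator, providing global
  exploration — and (ii) Gaussian creep whose step size is drawn
  log-uniformly from 1 down to 1e-5 gene units (decades). The creep ladder
  lets the same operator both hop between basins and polish the optimum to
  far below 1% relative error; no gradient or simplex polish is bolted on.
- **Selection / crossover.** Tournament of 3; single-point crossover on
  consecutive pairs of selected parents. The best-ever individual is copied
  into every generation (elitism), so the best RSS is monotone.
- **Ties and degeneracies.** The earliest-found best individual is retained
  (strict `<` improvement test). Candidate vectors whose predictions
  overflow get `+inf` RSS instead of raising. Negative observed
  concentrations (blank-corrected data) are accepted with a logged warning.

Everything is driven by one `numpy.random.Generator` seeded from
`FitConfig.seed`, single-threaded, so a fit is bit-reproducible.

**Reference fitter.** `reference_fit` is an independent oracle used in the
test suite: exhaustive RSS evaluation on a dense log-spaced grid over the
same box (linear in `SF`), followed by a derivative-free Nelder-Mead polish
in log-parameter space, never returning anything worse than the best grid
point. It shares no search logic with the GA.

## Goodness of fit and model selection

- `R^2 = 1 - RSS/TSS`; may be negative for fits worse than the mean.
- Adjusted `R^2 = 1 - (n-1)/(n-p) * (1 - R^2)` with denominator `n - p` —
  a deliberate convention choice over the more common `n - p - 1`.
- Profile Gaussian log-likelihood
  `ln L = 0.5 * (-n (ln 2*pi + 1 - ln n + ln RSS))`; the error variance is
  profiled out and **not** counted in `p`, so `p = 2` (OC) and `p = 3`
  (OC-SF).
- `AIC = 2p - 2 ln L`; `AICc = AIC + 2p(p+1)/(n-p-1)`, used whenever models
  are compared (the datasets here are always small, `n/p << 40`).
- Akaike weights `w_i = exp(-delta_i/2) / sum_k exp(-delta_k/2)` with
  `delta_i` the AICc difference to the best model; the minimum is subtracted
  before exponentiation (algebraically an identity, numerically stable).
- A zero-RSS fit makes `ln L` unbounded; `compare_models` then reports the
  perfect fit(s) as decisively best with the weight split among them and a
  `degenerate` flag, rather than emitting non-finite numbers.

Adjusted `R^2` and Akaike weights can disagree — the three-parameter model
often has the higher adjusted `R^2` while the AICc penalty still favours the
two-parameter model. Both are reported so users can see the disagreement.

## Scenario registry

`biokin.data/scenarios.json` bundles 22 records: eight published
organism/nanomaterial datasets fitted with both models (green algae / C60,
water flea / TiO2, SiO2, C60 dietary, graphene, graphene oxide, Au,
zebrafish / TiO2), plus silver case studies (water flea / Ag-NP, earthworm /
Ag-NP and AgNO3). Each record stores a canonical genetic-algorithm fit, the
previously published fit of the same digitized data as a comparison
sub-record, reported adjusted `R^2` (and, where available, the reported
Akaike weight), unit labels, and a provenance note where the source layout
was ambiguous (the dietary C60 exposure concentration). `t_e`, `t_total` and
sometimes `C_exposure` were not published with the fits and are `null`;
`to_exposure_scenario` requires the caller to supply them. The registry is
immutable at runtime; user scenarios load from separate JSON files.

## Synthetic data generator

The generator emulates the kind of data these models are fitted to in
practice: sparse two-phase whole-body concentration series with replicate
scatter.

- **Sampling design** (default): 10 evenly spaced times in the uptake phase
  and 10 in the elimination phase — a typical OECD-style toxicokinetic
  layout. A design covering only one phase triggers a warning (the kinetics
  become weakly identifiable).
- **Noise**: Gaussian, either additive (`sigma` in concentration units) or
  proportional (`sigma` as coefficient of variation); proportional with
  `sigma = 0.05` is the default, matching the roughly constant relative
  error of ICP-MS body-burden assays. Negative draws are clipped to zero
  (counted and logged) because concentrations are physical; clipping can be
  disabled for statistically pure recovery experiments.

What the generator does **not** emulate: medium transformation (dissolution,
sedimentation, aging), organism growth dilution, particle-vs-ion
speciation, tissue-level distribution, non-Gaussian outliers, or the
figure-digitization error that contaminates the literature datasets. Passing
recovery tests therefore demonstrate correctness of the estimation machinery
under the stated error model, not robustness to every pathology of real
bioaccumulation data.

## Problem sizes and numerical tolerances in the validation studies

- Analytic-vs-ODE agreement: 1000 random parameter sets (300 in the
  acceptance script), RK45 at `rtol 1e-10` on the two-pool mass-balance
  system, agreement required at relative 1e-6; phase continuity at 1e-9.
- Noiseless recovery and the GA-vs-reference cross-check run at the full GA
  defaults.
- Replicated studies (20-seed noisy recovery, 50-replicate selection
  consistency) use a reduced GA profile — population 250, steady-fitness
  window 120, generation cap 2000 (`study_fit_config`) — chosen as the
  package's own problem-size scaling: its residual convergence error is far
  below the 5% / 2% noise floors those studies probe, while the full profile
  adds nothing but wall-clock time. The fitted-nesting study, whose 0.5%
  tolerance is tighter than the reduced profile's occasional local-optimum
  excursions on three-parameter fits, runs at the full defaults.

## Known limitations

- The GA is stochastic; on ill-identified datasets (single-phase designs,
  data far from plateau) different seeds can return different points on the
  `k1`-`k2` ridge with nearly equal RSS. This is a property of the problem,
  not the optimiser; no confidence intervals are reported.
- `reference_fit` is an oracle for RSS, not a production fitter: its grid
  stage costs grow geometrically with parameter count.
- The bundled scenario constants are data entries transcribed from published
  tables of fits to digitized figures; they carry the digitization noise of
  their sources and cannot be re-derived from raw data within this package.
- Michaelis-Menten uptake, growth dilution, elimination-only storage and
  ion/particle dual tracking are out of scope.
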