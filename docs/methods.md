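# Methods

## Model structure and assumptions

`landshift` models global, non-spatial land-use change. Non-barren land of
fixed total area `T` is partitioned into seven stocks — forest `F`, wild
pasture `P`, agricultural land by origin `A_F`/`A_P`, abandoned land by
natural state `B_F`/`B_P`, and urban land `U` — whose sum is conserved
exactly. "Wild pasture" means grassland untouched by domestic grazing;
"abandoned" means former farmland recovering toward its natural state.

The model is demand-driven. Required farmland is the world food equation
`D(t) = c(t) p(t) / y(t)` and urban demand is `s p(t)` with a constant
per-person footprint `s`; agricultural area tracks `D` exactly for as long
as land sources allow. Conversion is one-directional: farmland returns to
nature only through abandonment and recovery, never directly. Because the
Heaviside gates depend only on the sign of `dD/dt` — a pure function of
time — the switching structure is state-independent, which simplifies both
integration and classification.

The three drivers are translated logistics
`x(t) = x0 + K / (1 + exp(-r (t - tI)))`. The floor `x0` encodes the
pre-industrial state and is fixed by initial conditions rather than fitted;
`K` is the gain to the industrialised ceiling. A logistic is the natural
shape here: yield and consumption gains spread through a patchwork of
countries like a metapopulation contagion, and population projections
saturate by fertility transition.

Assumptions worth keeping in mind: no trade or spatial leakage (the model
is global by construction), no climate or carbon feedback, constant `s`,
and a single aggregate yield across all products.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `T` | non-barren land | 11.26e9 | ha |
| `alpha` | share of agricultural expansion from forest | 0.4 | – |
| `zeta` | share of urban expansion from forest | 0.9 | – |
| `gamma` | share of abandoned land naturally forest | 0.4 | – |
| `beta` | forest recovery rate | 0.01 | 1/yr |
| `delta` | pasture recovery rate | 1.0 | 1/yr |
| `s` | urban area per person | 0.06 | ha |
| `p`: `x0, K, r, tI` | population | 310e6, 10.5e9, 0.032, 1998.3 | persons, 1/yr, yr |
| `c`: `x0, K, r, tI` | consumption | 571, 1940, 0.019, 1995.8 | kg/person/yr |
| `y`: `x0, K, r, tI` | yield | 150, 3391, 0.039, 1995.7 | kg/ha/yr |

Two reporting/initialisation constants are not part of the dynamics:

* `total_land_with_barren` defaults to `T / 0.85` (about 15% of global
  land is arid/barren), used only to express results as "% of all land".
* `preag_forest_frac = 0.575`: the share of `T` that is naturally forest
  in the pre-agricultural landscape. Historical reconstructions give no
  single number; 0.575 anchors the simulated trajectory to the
  historical/recent forest share and yields the ~25% (non-barren) / ~22%
  (total) ultimate forest cover. It is a config knob.

The initial yield floor `y0 = 150 kg/ha/yr` respects the historical upper
bound of 420 kg/ha (medieval grain yields ~700 kg/ha times the ~0.6 ratio
of all-product to cereal yield; see `constrain_initial_yield`).

## Initialisation and integration

At `t_start = 1000` (all drivers effectively at their floors) the
landscape is pre-agricultural: a fraction `preag_forest_frac` of `T` is
forest, the rest wild pasture, minus the farmland `D(t_start)` and urban
area `s p(t_start)` already in use, carved out in the `alpha`/`zeta`
proportions. Abandoned stocks start at zero; the components sum to `T`
exactly.

Integration is fixed-step classical Runge-Kutta (RK4), `dt = 0.1 yr`. No
event location is needed: the only discontinuities are the time-driven
Heaviside gates, and halving `dt` moves every reported fraction by far
less than 1e-4. After each step, stocks inside `(-1e-6 T, 0)` are clamped
to zero with the mass restored from the largest stock; anything more
negative raises an error. Conservation drift is checked against `1e-6 T`
(observed: ~1e-15 relative).

**Depletion guards.** A nearly exhausted source cannot supply an arbitrary
flow. Each source's outflow is capped at `stock / tau` with `tau = 1 yr`
(an exponential drain, which no step size can push negative), and demand
above capacity is redirected: forest to pasture and vice versa, then the
abandoned stocks, in that priority. If demand remains after every source
is exhausted the run is flagged infeasible (the no-forest-remaining
corner of the phase space). By default renewed expansion after an
abandonment era draws from forest and pasture, not the abandoned stocks;
`reexpand_from_abandoned = true` selects the alternative reading.

**Steady state.** A run is converged when every stock rate stays below
`1e-6 T` per year for 50 consecutive years — but only after the
driver-implied forcing (`|dD/dt|`, `s dp/dt`) has *permanently* fallen
below that tolerance, which is pre-scanned over the horizon. Without that
condition a purely local criterion would declare the dormant medieval era
"steady". Baseline convergence occurs around year 2550; the horizon cap
(default 2000 yr) reports, rather than raises, non-convergence.

## Calibration

`fit_logistic` minimises unweighted linear-scale least squares of the
vertically translated series over `(K, r, tI)` with `x0` held fixed, via
`scipy.optimize.least_squares` on data normalised by the series scale.
Logistic fits are multimodal in `(r, tI)`, so a 3×3 multistart grid
(`r` in {0.01, 0.03, 0.1}; `tI` at the first, middle and last year) is
tried and the lowest residual kept. R² is reported on the untranslated
series. Constant series are rejected as non-identifiable (`r` is
unconstrained). Anomalous interior points (e.g. bad fodder-crop records)
are replaced by linear interpolation between clean neighbours, an
idempotent operation that refuses endpoint flags.

The synthetic generator `synth_series` adds seeded i.i.d. Gaussian noise
to a driver curve. It emulates the *shape and sampling* of the annual FAO
records (47 yearly points, 1961–2007) but not their autocorrelated errors,
revision artefacts or reporting gaps — so exact-recovery and
bias-vs-noise tests validate the fitting machinery, not the provenance of
the real data. The shipped driver parameters are the external
calibration; re-fitting real records is the user's step (`landshift
calibrate`).

## Transition detection and classification

A forest transition is detected as the first time the forest rate crosses
from below `-eps` to above `+eps` with `eps = 1e-7 T`/yr. Classification:
infeasible runs or runs whose forest cover ever falls to `1e-3 T` are NFR;
no detected upturn is NFT; otherwise the sign changes of the analytic
`dD/dt` (dead band `1e-7 max D` against numerical chatter) decide — one
interior maximum of `D` is CFT; a re-rising `D` is OFT when its asymptote
stays below the first interior maximum and FFT when it exceeds it (a
second deforestation era passing the first peak). Trajectories that have
not stabilised are refused (or flagged `converged=False` on request)
rather than classified silently.

The phase scan replaces the yield and consumption curves with smooth
logistic continuations at `t_e = 2009`: same floor, new gain `K'`, value
and slope matched at `t_e` (closed form; the identity continuation
reproduces the original parameters to 1e-9). The published figure does not
state the scanned extents; the default grid spans asymptotic gains from
1.02× to 3× the 2009 above-floor values, 30×30 cells, so the 2009 state
sits at the grid origin. The transition-timing and forest-at-transition
summaries depend on this choice and are always reported together with the
scan bounds. Near the NFT boundary, abandonment is vanishingly small and
the forest upturn (recovery `beta B_F` overtaking ongoing urban loss
`zeta s dp/dt`) can lag the demand peak by a century or more; the timing
map therefore has a long tail that a coarser detection convention (e.g.
dating the transition at the demand peak) would not show. The demand peak
itself is independent of `beta`; the upturn time is not.

## Scenarios and sensitivity

Consumption-reduction scenarios multiply `c(t)` by a factor after 2009
with a 10-year linear ramp (steady-state comparisons are ramp-invariant;
the ramp only avoids injecting a rate step). The 32%→29% food-wastage case
is read as a 3-percentage-point reduction of required supply (factor
0.97); the alternative edible-share reading (68/71 ≈ 0.958) is available
via `wastage_factor(..., reading="ratio")`. Ultimate spared farmland obeys
`(1 - factor) x` baseline ultimate agricultural area to within 2% whenever
no depletion guard fires, and the spared land accrues to forest and wild
pasture in the `alpha : 1-alpha` split.

The sensitivity analysis varies one parameter at a time by ±10% and
tabulates the absolute change of the ultimate F, P, A, U fractions of `T`.
Inflection times are calendar years, so their "relative" perturbation is
applied to the horizontal translation measured from the start of the
annual record (1961), a ~3.5-year shift; scaling the raw A.D. number would
displace a curve by ~200 years and collide population growth with
pre-industrial yields, which is not a perturbation of anything the
calibration fitted. Equilibrium fractions are exactly invariant to `tI`
and `r` (these shape timing, not asymptotes); the largest equilibrium
sensitivities are to `T`, `K_p` and `K_y` (≤ 0.08 absolute at ±10%).

## Numerical summary

* RK4, `dt = 0.1 yr`; step-halving changes reported fractions < 1e-4.
* Conservation enforced to `1e-6 T`; observed drift ~1e-15 relative.
* Steady state: all rates < `1e-6 T`/yr over 50 yr, after permanent
  forcing quiescence; baseline stabilises ~year 2550.
* Scan: 900 cells × (2009 → steady state) ≈ 1–2 minutes on one CPU.
* Depletion guard time constant `tau = 1 yr`; guard inert away from
  exhaustion.
* Tie-breaks: `Theta(0) = 0` (no flux at exact stationarity of `D`);
  OFT/FFT discriminated by asymptotic `D` vs its first interior maximum,
  ties to OFT.

## Known limitations

* Global aggregation hides trade, leakage and national heterogeneity; the
  FFT regime is suggestive of, not a statement about, national relapses.
* The synthetic data generator does not emulate FAO error structure (see
  above), so calibration tests bound estimator behaviour under ideal
  noise only.
* The phase-scan summaries (latest onset, forest cover at transition) are
  functions of the unpublished scan extents; treat them as
  scan-conditional.
* `delta = 1/yr` makes pasture recovery effectively instantaneous; the
  model is insensitive to it absent a transition, but post-transition
  pasture dynamics at sub-decadal resolution should not be over-read.
* The urban footprint `s` is constant; long-horizon urban densification
  or sprawl is outside the model.
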