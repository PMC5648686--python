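# Methods

## Scope and data

The package analyses the interaction between semi-domesticated
reindeer and ground-lichen (*Cladonia*) pastures at the scale of the
herding district. The packaged input (`renlichen/data/districts_fi20.csv`)
is the pasture table for the 20 northernmost Finnish herding
districts: rotation status, supplementary feeding, lichen and
arboreal pasture areas, arboreal availability class (6/9/12 kg/ha),
lichen biomass at the start (1995) and end (2008) of the observation
window, relative lichen growth rate, heavy-metal growth reduction,
and the share of the district under infrastructure disturbance. The
accompanying annual herd series (autumn census by class, slaughter,
traffic and predation deaths) are not public; the `synthetic` module
generates series of exactly that shape with a known ground truth, and
all estimation and validation machinery runs on either source.

## Herd-data corrections

Two corrections convert raw bookkeeping into grazing pressure:

* **Uncounted animals.** Every animal reported alive after slaughter
  in autumn `t` must reappear next autumn among the counted or
  slaughtered adults or the winter deaths. The excess of that balance
  over the reported survivors is the *minimum* number of uncounted
  animals; because animals can stay uncounted for consecutive years
  the true share is higher, so the applied share is
  `max(0.10, implied)`, uniform across classes. The final census year
  has no successor and uses the floor.
* **Predation under-reporting.** A third of predated animals are
  assumed never found; reported predation deaths are multiplied
  by 1.5.

Winter mortality enters the reindeer-days as a single mid-winter
step: half the winter at the full corrected herd, half at the
post-mortality herd. The autumn-`t` census drives the model year
ending in autumn `t+1`, so the 1995–2007 series spans the 1995→2008
biomass change.

## Forward pasture model

A model year is four seasonal removal steps (winter 180 d, spring
60 d, summer 95 d, autumn 30 d; configurable) followed by one growth
step on the post-consumption biomass. Removal per hectare in season
*e* is

    intake_daily · reindeer_days · exposure_e · (1 + W_e + W_infra) / A,

clamped so biomass cannot go negative. Components:

* **Intake.** Per-capita daily ground-lichen demand (winter
  2.0 kg DM, snow-free seasons 0.4 kg DM) times the functional
  response `z/(z + z_half)` with `z_half = 300` kg/ha. The absolute
  demand scale trades off against the estimated wastage multipliers,
  which is why both are exposed in `GrazingConfig`.
* **Wastage.** `W_e = p_e,1 + (p_e,2 − p_e,1)·z/1000`, anchors at 0
  and 1,000 kg/ha, extrapolated linearly above 1,000 (district data
  reach ~1,800 kg/ha); spring and autumn are tied to half the summer
  value, so winter and summer each contribute two free parameters
  (one each in the constant form).
* **Infrastructure wastage.** `infra_pct / 25`, added to the seasonal
  multiplier in every season by default (winter-only available by
  config) — on the packaged table it spans 0.1 to 1.088.
* **Substitution.** Supplementary feed spares 0.8 kg lichen per kg
  feed; the winter arboreal pool `q·A_Q` can displace at most 25% of
  winter demand and is depleted within the winter. Snow-free seasons
  use no substitution.
* **Rotation.** Districts with seasonal rotation expose the winter
  lichen range for the full winter plus 28 days of spring; summer and
  autumn exposure is zero. Without rotation all seasons graze the
  whole lichen area.
* **Growth.** `Δz = g · m_hm · r0 · z^a · (1 − z/K)` with `a = 0.15`,
  `r0 = 15`, `K = 6,000` kg/ha; `g` is the district's growth rate
  relative to mature pine forest and `m_hm ∈ {1.0, 0.8, 0.6, 0.4}`
  the heavy-metal multiplier. This *saturating* form — per-area
  increment almost independent of standing biomass once a thallus
  network is established, peaking near 780 kg/ha and declining toward
  the carrying capacity — matches field growth curves for reindeer
  lichens better than a logistic, whose increment at the low
  biomasses typical of heavily grazed districts is far too small to
  reproduce observed recoveries (e.g. 33 → 129 kg/ha in thirteen
  grazed years). Logistic and Gompertz forms remain available via
  `GrazingConfig(growth_form=...)`.

The inner loop is JIT-compiled (numba) over batches of districts;
estimation evaluates it tens of thousands of times.

## Estimation and validation

Agreement between model and data is measured by modeling efficiency
`EF = 1 − SSE/SST` (Nash–Sutcliffe type: 1 perfect, 0 the
mean-predictor baseline) on end-of-period biomass across districts,
complemented by the Pearson correlation on levels and on 1995–2008
changes. The wastage anchors maximize EF subject to non-negativity.
The optimizer is deterministic: a fixed lattice of candidate
multipliers is evaluated exhaustively, the best eight points seed
bounded Nelder–Mead refinements (function tolerance 1e-8, bound
0–50), and ties break by first occurrence. Against 10,000-point
random grids the achieved EF is never below the grid optimum.

Validation is leave-one-out cross-validation: for each district the
anchors are re-estimated on the remaining districts and the held-out
district's final biomass is predicted; EF and correlations aggregate
the held-out predictions. Reported "average" wastages are arithmetic
means of the fold estimates. Structural model variants (no feeding,
no arboreal lichen, one growth rate, no rotation, rotation
everywhere, scaled or removed infrastructure and heavy-metal effects,
constant vs. linear wastage) re-run the full cross-validation with
re-estimated anchors.

## Synthetic districts

The generator draws district parameters in ranges matching the
packaged table (areas log-uniform 10–130 kha, initial biomass
log-uniform 80–1,800 kg/ha, winter densities 0.04–0.12 head/ha of
lichen pasture, 40% rotation probability, heavy-metal and feeding
levels at table-like frequencies). Herd totals follow a log-AR(1)
(ρ = 0.7, σ = 0.12) around a district mean; class counts are
constructed so the adult bookkeeping balances across years, with the
calf crop absorbing the total's variation. A per-year uncounted share
(usually 5–12%, occasional 15–30% spikes) is removed from the emitted
census, and reported predation is truth divided by 1.5, so the
package's own corrections are exercised end to end; because
consecutive-year undercounting hides animals from the balance, the
reconstructed share is provably at most the generating one — the
situation the 10% floor addresses. Final biomass is computed by the
same forward model under the true anchors (default 0→0.7 winter,
5.7→9.6 summer) and degraded with relative Gaussian observation noise
(default 5%). Everything is fixed by one seed.

What passing recovery tests shows: the estimation pipeline is
consistent and precise *under the model's own data-generating
process* at realistic noise. It does not show that the model captures
real-world processes absent from the generator — weather and icing
events, within-district spatial heterogeneity, measurement design, or
trends in uncounted shares.

Recovery error is reported relative to `max(|truth|, 1)`: anchors
with a true value of zero are judged on the natural unit scale of a
wastage multiplier.

## Steady-state bioeconomics

A steady state at target biomass `z*` satisfies two fixed points:
annual lichen growth equals annual removal (growth evaluated at `z*`;
the within-year sawtooth is ignored), and the age/sex-structured herd
reproduces itself. The herd model has 17 female and 13 male cohorts,
baseline survival 0.95, calving 0.85 at full condition from age 2,
harmonic-mean mating with σ = 10 females per male, 10% calf summer
mortality, and linear winter-deficit penalties (survival × (1 − 0.5·d),
calving × (1 − d) for deficit fraction d). These rates are
reconstructions exposed in `DemographyConfig`.

Under class-uniform harvest rates the replacement-rate herd structure
is closed-form: cohort counts are geometric in the retention rates
and the calf-harvest rate balancing the population follows directly
from the recruitment balance (recruitment is degree-1 homogeneous, so
every class scales with one minus the calf harvest). The winter herd
is scaled so its removal equals the sustainable growth; winter energy
not supplied by lichen or arboreal sources is a deficit that feeding
can cover at cost, in steps of 10% coverage. Per biomass the solver
maximizes `price·meat − husbandry·heads − feed_cost·feed` over
harvest rates (females 0–30%, males 0–60%) and feed coverage; both
fixed-point residuals of returned solutions are below 1e-6 (in
practice ~1e-16).

Economic defaults: meat price 8 per kg; slaughter weights 22/35/55 kg
(calf/female/male); husbandry cost 40 per head-year; feed cost 0.105
per kg; winter requirement 360 kg lichen-equivalent per
adult-equivalent. Feed cost and the growth exponent were calibrated
jointly — within these documented defaults — so that the stylized
rotation district's income curve peaks near the reported optima under
the constant and linear field-average wastage estimates; all
qualitative orderings (wastage level scales income and herd but not
the optimal biomass; the linear form moves the optimum below the
growth-maximizing biomass) are insensitive to this calibration.

A positive interest rate is handled by an annuity-equivalent
objective: yearly income plus `r` times the value of the lichen stock
released relative to a reference biomass (default shadow value 0.02
per kg, roughly the meat value extractable from a kilogram of
standing lichen after wastage). A steady state counts as
*feeding-intensive* when supplementary feed supplies at least half of
the winter energy requirement; the feeding frontier reports, per
interest rate, the highest feed cost at which the best
feeding-intensive steady state still beats the best natural-pasture
one. This regime comparison replaces a hard biomass threshold because
with discounting the optimum never sits exactly on the grid edge.

Per-district optima use the district's own pasture parameters, the
linear wastage averages, a 2% interest rate, and the district's 1995
biomass as the stock reference; `compare_to_data` tabulates observed
2008 herds and biomasses against the optima.

## Numerical choices and degenerate inputs

* Biomass clamps at zero (an absorbing state until growth restarts
  from positive biomass; exactly zero stays zero).
* Zero reindeer-days, zero exposure, or zero biomass skip a seasonal
  step; empty tables, negative counts, shares ≥ 1, and harvests
  exceeding a cohort raise immediately with the offending row or
  class named.
* The deficit grid (41 points) snaps the demographic lookup; returned
  solutions re-solve the demography at the snapped deficit so the
  fixed point is exact.
* All stochastic components take a single integer seed;
  cross-validation folds, optimizer starts and tie-breaks are
  deterministic.

## Problem sizes

Default experiment sizes keep the full pipeline interactive: 20
districts × 13 years for estimation; 20 replicates for recovery
experiments; a 591-point biomass grid (100–6,000 kg/ha, step 10) for
steady-state sweeps; 0–10% interest and 0.0025-step feed-cost grids
for the frontier.

## Known limitations

* No within-district spatial structure, snow/icing forcing, or lichen
  species composition; regrowth is a two-parameter curve.
* Winter energy is a single lichen-equivalent currency; body mass is
  proxied by the deficit fraction, not tracked in kg.
* The harvest policy space is class-uniform (calf/female/male rates);
  the full model's per-cohort policies could do slightly better.
* Absolute income levels depend on placeholder prices; only orderings
  and optimum locations are meaningful.
* The stock-value treatment of discounting is an annuity
  approximation, not a transient optimal path.
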