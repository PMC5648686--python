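# renlichen

Reindeer–lichen pasture dynamics for semi-domesticated reindeer
husbandry: forward simulation of ground-lichen biomass under grazing
and trampling wastage, data-based estimation of the wastage
parameters, cross-validated model validation, and steady-state
bioeconomic optimization of herd management.

The package is aimed at quantitative ecologists and resource
economists working on ungulate–pasture systems where the resource is
destroyed by trampling as much as it is eaten — reindeer on
*Cladonia* lichen ranges being the canonical case.

## The model in brief

The observational unit is the herding district. Each model year is
four seasonal consumption steps followed by one growth step. In
season *e* the biomass removed from the grazed lichen area is

```
removal = intake · (1 + W_e + W_infra)
```

where per-capita intake follows a saturating functional response
`z/(z + z_half)` of standing biomass `z`, `W_infra` is an
infrastructure-disturbance wastage (equal to 1 when 25% of the
district area is disturbed), and `W_e` is the seasonal
wastage-to-intake multiplier, either constant or linear in biomass:

```
W_e = p_e,1 + (p_e,2 − p_e,1) · z / 1000 ,   e ∈ {wi, sp, su, au}
```

with spring and autumn wastage fixed at half the summer value.
Districts operating seasonal pasture rotation expose their winter
lichen ranges only during winter plus four weeks of spring. Annual
regrowth depends on habitat quality (growth relative to mature pine
forest) and is suppressed where airborne heavy metals accumulate.

The winter and summer anchors `(p_wi,1, p_wi,2, p_su,1, p_su,2)` are
estimated by maximizing **modeling efficiency**

```
EF = 1 − Σ (z_obs − z_model)² / Σ (z_obs − mean(z_obs))²
```

of predicted vs. observed end-of-period biomass, with leave-one-out
cross-validation across districts for validation: each district's
biomass is predicted with parameters estimated without it.

For management analysis, an age/sex-structured herd (17 female, 13
male cohorts, harmonic-mean mating, winter-energy deficits penalizing
survival and calving) is coupled to the pasture at a steady state:
annual lichen growth equals annual removal, and the herd reproduces
itself under a constant harvest and feeding policy. Yearly net
revenue `R − C = price·meat − husbandry·heads − feed_cost·feed` is
maximized at each target biomass, tracing the income curve over
steady states and the frontier between natural-pasture and
feeding-intensive management.

## Worked example

```python
import renlichen as rl
from renlichen.synthetic import SyntheticConfig, generate_district_set
from renlichen.economics import fictional_district, steady_state_sweep

# 20 synthetic districts with known wastage truth and 5% noise
records, truth = generate_district_set(SyntheticConfig(seed=42, obs_noise_sd=0.05))
result = rl.loocv(records, form="linear")
print(round(result.ef, 3), result.mean_params.as_free_vector().round(2))

# income-maximizing steady-state biomass for a stylized rotation district
sweep = steady_state_sweep(fictional_district(),
                           wastage_params=rl.LINEAR_WASTAGE_ESTIMATE)
print(sweep.optimal_z, round(sweep.optimal_income))
```

prints

```
0.98 [0.12 0.89 5.34 8.67]
740.0 13043
```

The cross-validated modeling efficiency of 0.98 says the model
explains essentially all between-district variance in final lichen
biomass; the mean fold estimates recover the generating anchors
(0, 0.7, 5.7, 9.6) closely. The steady-state sweep finds the yearly
net income (currency units per year for a 10,000 ha district) peaking
at a lichen biomass of 740 kg/ha under the linear wastage form.

A thin CLI wraps the same functions:

```sh
renlichen validate --seed 42
renlichen optimize sweep --wastage linear
renlichen synth --seed 1 --out out/
```

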