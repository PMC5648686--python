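"""Age- and sex-structured reindeer population for optimization mode.

Validation mode is driven by observed counts; this module supplies the
population machinery needed when herd size, harvest and feeding are
decision variables.  The herd has 17 female cohorts (ages 0-16) and 13
male cohorts (ages 0-12).  Reproduction follows a harmonic-mean mating
system in which one male can serve ``sigma`` females; winter energy
deficits reduce survival and calving linearly.  All demographic rate
constants are reconstructions exposed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "N_FEMALE_CLASSES",
    "N_MALE_CLASSES",
    "PopulationState",
    "DemographyConfig",
    "recruitment",
    "winter_energy_balance",
    "population_step",
]

N_FEMALE_CLASSES = 17
N_MALE_CLASSES = 13


@dataclass
class PopulationState:
    """Cohort counts (autumn) with a per-class body-condition index."""

    females: np.ndarray
    males: np.ndarray
    condition_f: np.ndarray | None = None
    condition_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.females = np.asarray(self.females, dtype=float)
        self.males = np.asarray(self.males, dtype=float)
        if self.females.shape != (N_FEMALE_CLASSES,):
            raise ValueError(f"females must have {N_FEMALE_CLASSES} classes")
        if self.males.shape != (N_MALE_CLASSES,):
            raise ValueError(f"males must have {N_MALE_CLASSES} classes")
        if np.any(self.females < 0) or np.any(self.males < 0):
            raise ValueError("cohort counts must be >= 0")
        if self.condition_f is None:
            self.condition_f = np.ones(N_FEMALE_CLASSES)
        if self.condition_m is None:
            self.condition_m = np.ones(N_MALE_CLASSES)

    @property
    def total(self) -> float:
        return float(self.females.sum() + self.males.sum())

    def frame(self) -> pd.DataFrame:
        rows = [
            {"sex": "f", "age": a, "count": c, "condition": k}
            for a, (c, k) in enumerate(zip(self.females, self.condition_f))
        ] + [
            {"sex": "m", "age": a, "count": c, "condition": k}
            for a, (c, k) in enumerate(zip(self.males, self.condition_m))
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DemographyConfig:
    """Demographic rates and energy-requirement constants.

    ``sigma`` is the number of females one male can serve in the
    harmonic-mean mating system.  A winter energy deficit of fraction
    ``d`` of the requirement multiplies survival by
    ``1 - pen_survival * d`` and calving by ``1 - pen_calving * d``.
    Adult-equivalent (AE) weights express class-specific winter energy
    demand relative to an adult female.
    """

    survival: float = 0.95
    calving_rate: float = 0.85
    sigma: float = 10.0
    min_age_breeding_f: int = 2
    min_age_breeding_m: int = 2
    calf_summer_mortality: float = 0.10
    pen_survival: float = 0.5
    pen_calving: float = 1.0
    ae_calf: float = 0.6
    ae_female: float = 1.0
    ae_male: float = 1.3
    winter_requirement_ae: float = 360.0  # kg lichen-equivalent per AE per winter

    def __post_init__(self) -> None:
        for name in ("survival", "calving_rate", "calf_summer_mortality"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def ae_vector(self) -> tuple[np.ndarray, np.ndarray]:
        ae_f = np.full(N_FEMALE_CLASSES, self.ae_female)
        ae_f[0] = self.ae_calf
        ae_m = np.full(N_MALE_CLASSES, self.ae_male)
        ae_m[0] = self.ae_calf
        return ae_f, ae_m


def recruitment(
    n_females_fertile: float, n_males_mature: float, config: DemographyConfig
) -> float:
    """Expected calves from a harmonic-mean mating system.

    ``calving_rate * n_f * sigma n_m / (sigma n_m + n_f)``: linear in
    females when males are plentiful, zero without sires.
    """
    if n_females_fertile < 0 or n_males_mature < 0:
        raise ValueError("counts must be >= 0")
    if n_females_fertile == 0 or n_males_mature == 0:
        return 0.0
    sm = config.sigma * n_males_mature
    return config.calving_rate * n_females_fertile * sm / (sm + n_females_fertile)


def winter_energy_balance(
    population: PopulationState,
    pasture_state,
    feed_kg_per_head: float,
    config: DemographyConfig,
    lichen_supply_frac: float | None = None,
    feed_sub: float = 0.8,
) -> tuple[dict, np.ndarray]:
    """Allocate winter energy sources and return per-class deficits.

    Requirement per class is its adult-equivalent weight times the
    per-AE winter requirement.  Ground lichen supplies the fraction
    ``z / (z + z_half)`` of the requirement (``lichen_supply_frac``
    overrides if given), the arboreal pool tops up proportionally, and
    supplementary feed contributes ``feed_sub`` lichen-equivalents per
    kg.  Deficit = requirement - supplied, floored at zero; supplied
    energy beyond the requirement is recorded as surplus, so
    ``supplied_capped + deficit == requirement`` holds exactly.
    """
    ae_f, ae_m = config.ae_vector()
    # per-head requirement per class (kg lichen-equivalent per winter)
    req = np.concatenate([ae_f, ae_m]) * config.winter_requirement_ae

    if lichen_supply_frac is None:
        z = pasture_state.z
        z_half = 300.0  # matches the default intake half-saturation
        lichen_supply_frac = z / (z + z_half) if z > 0 else 0.0
    lichen = req * lichen_supply_frac
    counts = np.concatenate([population.females, population.males])
    total_req = float(req @ counts)
    arboreal_total = min(
        getattr(pasture_state, "arboreal_pool", 0.0),
        max(0.0, total_req - float(lichen @ counts)),
    )
    arb_frac = arboreal_total / total_req if total_req > 0 else 0.0
    arboreal = req * arb_frac
    feed = np.full_like(req, feed_kg_per_head * feed_sub)
    supplied = lichen + arboreal + feed
    supplied_capped = np.minimum(supplied, req)
    deficit = req - supplied_capped
    ledger = {
        "requirement": req,
        "lichen": lichen,
        "arboreal": arboreal,
        "feed": feed,
        "supplied": supplied,
        "supplied_capped": supplied_capped,
        "surplus": supplied - supplied_capped,
        "total_requirement": total_req,
    }
    return ledger, deficit


def population_step(
    state: PopulationState,
    deficit: np.ndarray | float,
    harvest_by_class: tuple[np.ndarray, np.ndarray],
    config: DemographyConfig,
) -> PopulationState:
    """Advance the herd one year: harvest, overwinter, age, recruit.

    ``deficit`` is the winter energy deficit as a fraction of the
    requirement (scalar or per class, females then males).  Harvest is
    removed at the autumn round-up, survivors overwinter with the
    deficit-penalized survival, cohorts age one class (the oldest
    exit), and calves born to surviving fertile females enter class 0
    split evenly by sex after calf summer mortality.
    """
    h_f, h_m = harvest_by_class
    h_f = np.asarray(h_f, dtype=float)
    h_m = np.asarray(h_m, dtype=float)
    if np.any(h_f > state.females + 1e-9) or np.any(h_m > state.males + 1e-9):
        raise ValueError("harvest exceeds available animals in some class")
    d = np.asarray(deficit, dtype=float)
    if d.ndim == 0:
        d_f = np.full(N_FEMALE_CLASSES, float(d))
        d_m = np.full(N_MALE_CLASSES, float(d))
    else:
        d_f = d[:N_FEMALE_CLASSES]
        d_m = d[N_FEMALE_CLASSES:]
    if np.any(d_f < 0) or np.any(d_m < 0) or np.any(d_f > 1) or np.any(d_m > 1):
        raise ValueError("deficit fractions must lie in [0, 1]")

    surv_f = np.clip(config.survival * (1.0 - config.pen_survival * d_f), 0.0, 1.0)
    surv_m = np.clip(config.survival * (1.0 - config.pen_survival * d_m), 0.0, 1.0)
    post_f = (state.females - h_f) * surv_f
    post_m = (state.males - h_m) * surv_m
    if np.any(post_f < -1e-9) or np.any(post_m < -1e-9):
        raise ValueError("negative cohort after step")

    next_f = np.zeros(N_FEMALE_CLASSES)
    next_m = np.zeros(N_MALE_CLASSES)
    next_f[1:] = post_f[:-1]
    next_m[1:] = post_m[:-1]

    fertile = post_f[config.min_age_breeding_f :]
    calving_pen = 1.0 - config.pen_calving * d_f[config.min_age_breeding_f :]
    n_fertile_eff = float((fertile * np.clip(calving_pen, 0.0, 1.0)).sum())
    n_mature_m = float(post_m[config.min_age_breeding_m :].sum())
    calves = recruitment(n_fertile_eff, n_mature_m, config)
    calves *= 1.0 - config.calf_summer_mortality
    next_f[0] = 0.5 * calves
    next_m[0] = 0.5 * calves
    return PopulationState(females=next_f, males=next_m)
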