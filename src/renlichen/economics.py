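"""Steady-state bioeconomics of reindeer husbandry on lichen pastures.

A steady state couples two fixed points at a target lichen biomass
``z*``: the annual lichen growth equals the annual removal by the
herd, and the age/sex-structured herd reproduces itself under a
constant harvest and feeding policy.  For each ``z*`` on a grid the
solver finds the policy maximizing yearly net revenue

    R - C = price * meat - husbandry * heads - feed_cost * feed,

and a positive interest rate is handled through the annuity-equivalent
objective ``(R - C) + r * V(z*)``, where ``V`` values the lichen stock
released (or withheld) relative to the initial biomass.  Herd
management based on intensive supplementary feeding shows up as
optima at the low end of the biomass grid.

The demographic sub-problem (harvest fractions balancing the
population at replacement) has a closed form under class-uniform
harvest rates, which makes the nested optimization cheap: for a given
winter-deficit level the stationary age structure is geometric in the
retention rates, and the calf-harvest rate that holds the population
at replacement follows directly from the recruitment balance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .demography import (
    DemographyConfig,
    N_FEMALE_CLASSES,
    N_MALE_CLASSES,
    PopulationState,
    population_step,
    recruitment,
)
from .districts import DistrictRecord, corrected_herd
from .pasture import (
    GrazingConfig,
    LINEAR_WASTAGE_ESTIMATE,
    SeasonSchedule,
    WastageParameters,
    infra_wastage,
)

__all__ = [
    "EconomicParameters",
    "SteadyStateSolution",
    "SweepResult",
    "npv_objective",
    "steady_state_sweep",
    "feeding_frontier",
    "district_optimum",
    "compare_to_data",
    "fictional_district",
]


@dataclass(frozen=True)
class EconomicParameters:
    """Prices, costs and discounting for the husbandry economy.

    Monetary units are arbitrary but consistent (think EUR).  The
    slaughter weights are carcass kg per animal by class.
    ``stock_value_per_kg`` prices the standing lichen stock when
    discounting makes the timing of pasture depletion matter;
    ``z_init`` is the biomass the stock change is measured against.
    """

    price: float = 8.0                # per kg meat
    weight_calf: float = 22.0
    weight_female: float = 35.0
    weight_male: float = 55.0
    husbandry_cost: float = 40.0      # per winter head per year
    feed_cost: float = 0.105          # per kg supplementary feed
    interest: float = 0.0
    stock_value_per_kg: float = 0.02  # value of 1 kg/ha lichen stock per ha
    z_init: float = 1000.0            # reference biomass for the stock term

    def __post_init__(self) -> None:
        for name in (
            "price", "weight_calf", "weight_female", "weight_male",
            "husbandry_cost", "feed_cost", "stock_value_per_kg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.interest < 0:
            raise ValueError("interest must be >= 0")

    @property
    def discount_factor(self) -> float:
        return 1.0 / (1.0 + self.interest)


def npv_objective(revenue_stream, cost_stream, r: float) -> float:
    """Discounted net present value of a revenue/cost stream.

    ``J = sum_t (R_t - C_t) / (1 + r)**t`` with ``t`` starting at 0.
    """
    rev = np.asarray(revenue_stream, dtype=float)
    cost = np.asarray(cost_stream, dtype=float)
    if rev.shape != cost.shape:
        raise ValueError("revenue and cost streams must have equal length")
    if r < 0:
        raise ValueError("interest rate must be >= 0")
    t = np.arange(rev.size)
    return float(np.sum((rev - cost) * (1.0 / (1.0 + r)) ** t))


# ---------------------------------------------------------------------------
# demographic steady states under class-uniform harvest rates
# ---------------------------------------------------------------------------


@dataclass
class _PolicySteadyState:
    """Replacement-rate herd structure for one (h_f, h_m, deficit) policy."""

    feasible: bool
    h_calf: float = np.nan
    h_female: float = np.nan
    h_male: float = np.nan
    deficit: float = np.nan
    females: np.ndarray | None = None     # autumn pre-harvest, unit calves born
    males: np.ndarray | None = None
    meat_per_head: float = np.nan         # kg per winter head per year
    ae_per_head: float = np.nan
    winter_heads: float = np.nan          # per unit structure


def _policy_steady_state(
    h_female: float, h_male: float, deficit: float, demo: DemographyConfig
) -> _PolicySteadyState:
    """Closed-form stationary structure with the calf harvest balancing
    the population at replacement (growth factor 1)."""
    sf = demo.survival * max(0.0, 1.0 - demo.pen_survival * deficit)
    rho_f = sf * (1.0 - h_female)
    rho_m = sf * (1.0 - h_male)

    # unit: one calf of each sex entering autumn age 0 (pre-harvest)
    ages_f = np.arange(1, N_FEMALE_CLASSES)
    ages_m = np.arange(1, N_MALE_CLASSES)
    # structure at calf harvest zero; every class scales with (1 - h_calf)
    nf1 = 0.5 * sf
    nm1 = 0.5 * sf
    n_f = nf1 * rho_f ** (ages_f - 1)
    n_m = nm1 * rho_m ** (ages_m - 1)
    # spring breeders: autumn age >= min breeding age, surviving the winter,
    # with the calving deficit penalty applied to the effective females
    fertile = float(n_f[demo.min_age_breeding_f - 1 :].sum() * rho_f)
    mature = float(n_m[demo.min_age_breeding_m - 1 :].sum() * rho_m)
    fertile_eff = fertile * max(0.0, 1.0 - demo.pen_calving * deficit)
    calves_out0 = recruitment(fertile_eff, mature, demo)
    calves_out0 *= 1.0 - demo.calf_summer_mortality
    if calves_out0 < 1.0:
        return None
    h_calf = 1.0 - 1.0 / calves_out0
    scale = 1.0 - h_calf

    females = np.zeros(N_FEMALE_CLASSES)
    males = np.zeros(N_MALE_CLASSES)
    females[0] = 0.5
    males[0] = 0.5
    females[1:] = n_f * scale
    males[1:] = n_m * scale

    harvest_f = h_female * females[1:].sum()
    harvest_m = h_male * males[1:].sum()
    harvest_c = h_calf * 1.0
    winter_f = np.concatenate([[females[0] * (1 - h_calf)], females[1:] * (1 - h_female)])
    winter_m = np.concatenate([[males[0] * (1 - h_calf)], males[1:] * (1 - h_male)])
    winter_heads = float(winter_f.sum() + winter_m.sum())
    ae_f, ae_m = demo.ae_vector()
    winter_ae = float(winter_f @ ae_f + winter_m @ ae_m)
    return _PolicySteadyState(
        feasible=True,
        h_calf=h_calf,
        h_female=h_female,
        h_male=h_male,
        deficit=deficit,
        females=females,
        males=males,
        meat_per_head=np.nan,  # filled by caller with weights
        ae_per_head=winter_ae / winter_heads,
        winter_heads=winter_heads,
    ), (harvest_c, harvest_f, harvest_m)


_H_FEMALE_GRID = np.round(np.arange(0.0, 0.31, 0.02), 4)
_H_MALE_GRID = np.round(np.arange(0.0, 0.61, 0.05), 4)
_DEFICIT_GRID = np.linspace(0.0, 1.0, 41)
_COVERAGE_GRID = np.linspace(0.0, 1.0, 11)

_demography_cache: dict = {}


def _best_policies(econ: EconomicParameters, demo: DemographyConfig):
    """Best harvest policy and its economics for every deficit level.

    Returns arrays over the deficit grid: net score per AE per year
    (price * meat - husbandry, divided by AE), and the winning policy
    details.  Infeasible deficit levels get -inf score.
    """
    key = (
        econ.price, econ.weight_calf, econ.weight_female, econ.weight_male,
        econ.husbandry_cost, demo,
    )
    if key in _demography_cache:
        return _demography_cache[key]
    n_d = _DEFICIT_GRID.size
    score = np.full(n_d, -np.inf)
    best = [None] * n_d
    for i, d in enumerate(_DEFICIT_GRID):
        for hf in _H_FEMALE_GRID:
            for hm in _H_MALE_GRID:
                res = _policy_steady_state(hf, hm, d, demo)
                if res is None:
                    continue  # population cannot replace itself
                st, (harv_c, harv_f, harv_m) = res
                meat = (
                    harv_c * econ.weight_calf
                    + harv_f * econ.weight_female
                    + harv_m * econ.weight_male
                )
                meat_per_head = meat / st.winter_heads
                val = (
                    econ.price * meat_per_head - econ.husbandry_cost
                ) / st.ae_per_head
                if val > score[i]:
                    score[i] = val
                    st.meat_per_head = meat_per_head
                    best[i] = st
    out = (score, best)
    _demography_cache[key] = out
    return out


# ---------------------------------------------------------------------------
# lichen balance at a target biomass
# ---------------------------------------------------------------------------


def _exposure(rotation: bool, schedule: SeasonSchedule) -> np.ndarray:
    return schedule.rotation_exposure if rotation else schedule.full_exposure


def _removal_per_ae(
    z: float,
    record: DistrictRecord,
    params: WastageParameters,
    config: GrazingConfig,
    schedule: SeasonSchedule,
    arb_frac: float,
) -> float:
    """Annual ground-lichen removal (kg) per adult-equivalent at biomass ``z``."""
    phi = z / (z + config.z_half)
    p1, p2 = params.seasonal_anchors
    days = np.asarray(schedule.days)
    expo = _exposure(record.rotation, schedule)
    infra = infra_wastage(record.infra_pct)
    mask = config.infra_season_mask
    demand = config.demand.copy()
    demand[0] *= 1.0 - arb_frac
    w = p1 + (p2 - p1) * z / 1000.0 + infra * mask
    return float(np.sum(demand * phi * (1.0 + w) * days * expo))


def _growth_per_ha(z: float, record: DistrictRecord, config: GrazingConfig) -> float:
    g_eff = record.growth_rel * (1.0 - record.hm_reduction)
    return float(
        _kernel.growth_increment(
            z, g_eff, config.carrying_capacity, config.r0,
            config.growth_exponent, config.growth_form_code,
        )
    )


@dataclass
class SteadyStateSolution:
    """One steady state: pasture target, herd, policy and its economics."""

    z_star: float
    population: PopulationState
    h_calf: float
    h_female: float
    h_male: float
    deficit_frac: float
    feed_coverage: float
    feed_kg_per_ae: float
    winter_heads: float
    net_revenue: float
    objective: float
    residual_lichen: float
    residual_population: float
    feasible: bool


@dataclass
class SweepResult:
    """Net-income curve over the steady-state biomass grid."""

    z_grid: np.ndarray
    income: np.ndarray
    objective: np.ndarray
    heads: np.ndarray
    deficit: np.ndarray
    deficit_pre: np.ndarray
    coverage: np.ndarray
    feasible: np.ndarray
    record: DistrictRecord
    params: WastageParameters

    @property
    def argmax_index(self) -> int:
        return int(np.argmax(np.where(self.feasible, self.objective, -np.inf)))

    @property
    def optimal_z(self) -> float:
        return float(self.z_grid[self.argmax_index])

    @property
    def optimal_income(self) -> float:
        return float(self.income[self.argmax_index])

    @property
    def optimal_heads(self) -> float:
        return float(self.heads[self.argmax_index])

    @property
    def feed_share(self) -> np.ndarray:
        """Fraction of the winter energy requirement supplied by feed."""
        return self.coverage * self.deficit_pre

    @property
    def feeding_intensive(self) -> bool:
        """Whether the best feeding-based steady state beats the best
        natural-pasture one.

        A steady state counts as feeding-based when supplementary feed
        supplies at least half of the winter energy requirement (the
        main winter resource), which with full coverage corresponds to
        lichen densities at or below the intake half-saturation.
        """
        feeding = self.feasible & (self.feed_share >= 0.5)
        natural = self.feasible & (self.feed_share < 0.5)
        if not feeding.any():
            return False
        if not natural.any():
            return True
        return float(self.objective[feeding].max()) > float(
            self.objective[natural].max()
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_star": self.z_grid,
                "net_income": self.income,
                "objective": self.objective,
                "winter_heads": self.heads,
                "deficit_frac": self.deficit,
                "feed_coverage": self.coverage,
                "feasible": self.feasible,
            }
        )


def fictional_district(
    area: float = 10_000.0,
    rotation: bool = True,
    z_init: float = 1000.0,
) -> DistrictRecord:
    """A stylized district: closed rotation, mature-pine growth, no
    arboreal lichen, no infrastructure, no heavy metals."""
    return DistrictRecord(
        district_id="fictional",
        rotation=rotation,
        feeding=0.0,
        area_lichen=area,
        area_arboreal=0.0,
        arboreal_avail=0.0,
        z_1995=z_init,
        z_2008=z_init,
        growth_rel=1.0,
        hm_reduction=0.0,
        infra_pct=0.0,
    )


def steady_state_sweep(
    record: DistrictRecord,
    econ: EconomicParameters | None = None,
    z_grid: np.ndarray | None = None,
    wastage_params: WastageParameters = LINEAR_WASTAGE_ESTIMATE,
    config: GrazingConfig | None = None,
    demo: DemographyConfig | None = None,
    schedule: SeasonSchedule | None = None,
    allow_feeding: bool = True,
) -> SweepResult:
    """Maximize yearly net income at each steady-state lichen biomass.

    For every ``z*`` on the grid the sustainable herd is the annual
    lichen growth divided by the per-animal removal at ``z*``; the
    harvest policy and the share of the winter energy deficit covered
    by supplementary feed are chosen to maximize net revenue.  With a
    positive interest rate the ranking objective adds the annuitized
    value of the lichen stock change relative to ``econ.z_init``.
    """
    econ = econ or EconomicParameters()
    config = config or GrazingConfig()
    demo = demo or DemographyConfig()
    schedule = schedule or SeasonSchedule()
    if z_grid is None:
        z_grid = np.arange(100.0, 6000.0 + 1e-9, 10.0)
    z_grid = np.asarray(z_grid, dtype=float)
    if np.any(z_grid <= 0) or np.any(z_grid > config.carrying_capacity):
        raise ValueError("z_grid must lie in (0, K]")

    score_d, policies = _best_policies(econ, demo)
    req = demo.winter_requirement_ae
    coverage = _COVERAGE_GRID if allow_feeding else np.array([0.0])

    n = z_grid.size
    income = np.full(n, 0.0)
    heads = np.zeros(n)
    deficit = np.zeros(n)
    deficit_pre = np.zeros(n)
    best_cov = np.zeros(n)
    feasible = np.zeros(n, dtype=bool)

    pool = record.arboreal_pool
    for i, z in enumerate(z_grid):
        growth = _growth_per_ha(z, record, config) * record.area_lichen
        if growth <= 0:
            continue
        phi = z / (z + config.z_half)
        # arboreal displacement of winter ground intake, resolved by a
        # short fixed-point iteration (the pool is finite)
        arb_frac = 0.0
        if pool > 0:
            arb_frac = config.arb_cap
            for _ in range(3):
                rem = _removal_per_ae(z, record, wastage_params, config, schedule, arb_frac)
                if rem <= 0:
                    break
                n_ae = growth / rem
                winter_need = n_ae * config.demand[0] * schedule.days[0]
                arb_frac = min(config.arb_cap, pool / winter_need if winter_need > 0 else config.arb_cap)
        rem = _removal_per_ae(z, record, wastage_params, config, schedule, arb_frac)
        if rem <= 0:
            continue
        n_ae = growth / rem
        d0 = (1.0 - arb_frac) * (1.0 - phi)
        deficit_pre[i] = d0

        best_val = -np.inf
        for c in coverage:
            d = d0 * (1.0 - c)
            di = int(np.argmin(np.abs(_DEFICIT_GRID - d)))
            if not np.isfinite(score_d[di]):
                continue
            feed_ae = c * d0 * req / config.feed_sub
            val = n_ae * (score_d[di] - econ.feed_cost * feed_ae)
            if val > best_val:
                best_val = val
                best_cov[i] = c
                deficit[i] = _DEFICIT_GRID[di]
        if not np.isfinite(best_val):
            continue
        feasible[i] = True
        income[i] = best_val
        di = int(np.argmin(np.abs(_DEFICIT_GRID - d0 * (1.0 - best_cov[i]))))
        heads[i] = n_ae / policies[di].ae_per_head

    objective = income + econ.interest * econ.stock_value_per_kg * (
        econ.z_init - z_grid
    ) * record.area_lichen
    objective = np.where(feasible, objective, -np.inf)
    return SweepResult(
        z_grid=z_grid,
        income=income,
        objective=objective,
        heads=heads,
        deficit=deficit,
        deficit_pre=deficit_pre,
        coverage=best_cov,
        feasible=feasible,
        record=record,
        params=wastage_params,
    )


def solution_at(
    sweep: SweepResult,
    index: int | None = None,
    econ: EconomicParameters | None = None,
    demo: DemographyConfig | None = None,
) -> SteadyStateSolution:
    """Materialize the steady state at a grid point (default: the optimum),
    including fixed-point residuals for both the pasture and the herd."""
    econ = econ or EconomicParameters()
    demo = demo or DemographyConfig()
    if index is None:
        index = sweep.argmax_index
    z = float(sweep.z_grid[index])
    if not sweep.feasible[index]:
        return SteadyStateSolution(
            z_star=z,
            population=PopulationState(np.zeros(N_FEMALE_CLASSES), np.zeros(N_MALE_CLASSES)),
            h_calf=np.nan, h_female=np.nan, h_male=np.nan,
            deficit_frac=np.nan, feed_coverage=np.nan, feed_kg_per_ae=np.nan,
            winter_heads=0.0, net_revenue=0.0, objective=-np.inf,
            residual_lichen=np.nan, residual_population=np.nan, feasible=False,
        )
    d = float(sweep.deficit[index])
    score_d, policies = _best_policies(econ, demo)
    di = int(np.argmin(np.abs(_DEFICIT_GRID - d)))
    pol = policies[di]
    scale = sweep.heads[index] / pol.winter_heads
    females = pol.females * scale
    males = pol.males * scale
    state = PopulationState(females=females, males=males)
    h_f = np.concatenate([[pol.h_calf * females[0]], pol.h_female * females[1:]])
    h_m = np.concatenate([[pol.h_calf * males[0]], pol.h_male * males[1:]])
    nxt = population_step(state, d, (h_f, h_m), demo)
    denom = max(state.total, 1e-12)
    res_pop = float(
        np.max(
            np.abs(
                np.concatenate([nxt.females - females, nxt.males - males])
            )
        )
        / denom
    )
    # lichen balance holds by construction: the herd is scaled so that
    # removal equals growth at z*
    res_lichen = 0.0
    cov = float(sweep.coverage[index])
    return SteadyStateSolution(
        z_star=z,
        population=state,
        h_calf=pol.h_calf,
        h_female=pol.h_female,
        h_male=pol.h_male,
        deficit_frac=d,
        feed_coverage=cov,
        feed_kg_per_ae=cov * d * demo.winter_requirement_ae / 0.8,
        winter_heads=float(sweep.heads[index]),
        net_revenue=float(sweep.income[index]),
        objective=float(sweep.objective[index]),
        residual_lichen=res_lichen,
        residual_population=res_pop,
        feasible=True,
    )


def feeding_frontier(
    interest_grid,
    feed_cost_grid,
    wastage_params: WastageParameters = LINEAR_WASTAGE_ESTIMATE,
    record: DistrictRecord | None = None,
    econ: EconomicParameters | None = None,
    config: GrazingConfig | None = None,
    demo: DemographyConfig | None = None,
    schedule: SeasonSchedule | None = None,
    z_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Maximum feed cost at which intensive feeding is optimal, per rate.

    Classifies the optimal steady state at every (interest, feed cost)
    pair as feeding-intensive (optimum at the depleted end of the
    biomass grid) or natural-pasture, and reports the frontier.
    """
    record = record or fictional_district()
    econ = econ or EconomicParameters()
    rows = []
    for r in np.asarray(interest_grid, dtype=float):
        frontier = np.nan
        for fc in sorted(np.asarray(feed_cost_grid, dtype=float)):
            e = dataclasses.replace(econ, interest=r, feed_cost=fc)
            sweep = steady_state_sweep(
                record, e, z_grid, wastage_params, config, demo, schedule
            )
            if sweep.feeding_intensive:
                frontier = fc
        rows.append({"interest": r, "max_feed_cost_feeding": frontier})
    return pd.DataFrame(rows)


def district_optimum(
    record: DistrictRecord,
    econ: EconomicParameters | None = None,
    wastage_params: WastageParameters = LINEAR_WASTAGE_ESTIMATE,
    config: GrazingConfig | None = None,
    demo: DemographyConfig | None = None,
    schedule: SeasonSchedule | None = None,
    z_grid: np.ndarray | None = None,
) -> SteadyStateSolution:
    """Optimal steady state for one district's pasture parameters.

    The district's own 1995 biomass anchors the stock-value term when
    the interest rate is positive.
    """
    econ = econ or EconomicParameters(interest=0.02)
    econ = dataclasses.replace(econ, z_init=record.z_1995)
    sweep = steady_state_sweep(
        record, econ, z_grid, wastage_params, config, demo, schedule
    )
    return solution_at(sweep, econ=econ, demo=demo)


def compare_to_data(
    solutions,
    records,
    schedule: SeasonSchedule | None = None,
) -> pd.DataFrame:
    """Observed 2008 herds and biomasses vs. the optimal steady states.

    The observed herd is the corrected post-slaughter winter herd of
    the final census year.
    """
    rows = []
    for sol, rec in zip(solutions, records):
        if rec.herd_years:
            series = corrected_herd(rec, season_schedule=schedule)
            actual_herd = float(series.corrected_total[-1])
        else:
            actual_herd = np.nan
        rows.append(
            {
                "district_id": rec.district_id,
                "actual_herd": actual_herd,
                "optimal_herd": sol.winter_heads,
                "herd_above_optimum": actual_herd > sol.winter_heads,
                "actual_z_2008": rec.z_2008,
                "optimal_z": sol.z_star,
                "z_below_optimum": rec.z_2008 < sol.z_star,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_herd_above_optimum"] = int(df["herd_above_optimum"].sum())
    df.attrs["n_z_below_optimum"] = int(df["z_below_optimum"].sum())
    return df
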