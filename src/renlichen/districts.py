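"""District-level input data: pasture tables, herd bookkeeping, and corrections.

The observational unit is the reindeer herding district.  Each district
carries static pasture parameters (lichen area, arboreal availability,
relative growth rate, disturbance shares) together with an annual herd
series: autumn census counts by class, slaughter removals and reported
mortalities.  Two corrections turn the raw bookkeeping into grazing
pressure usable by the forward model:

* **Uncounted reindeer** -- part of the herd is always missed in the
  autumn gatherings.  Comparing the animals reportedly left alive after
  slaughter with the adults counted and slaughtered the next autumn
  (plus winter deaths) yields a minimum number of uncounted animals.
  The correction applies the larger of that data-implied share and a
  10% floor, uniformly across age and sex classes.
* **Predation under-reporting** -- roughly one third of predated
  reindeer are never found, so reported predation deaths are inflated
  by a factor of 1.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnualHerdCount",
    "DistrictRecord",
    "HerdSeries",
    "load_districts",
    "write_districts",
    "load_packaged_districts",
    "min_uncounted",
    "corrected_herd",
    "DEFAULT_UNCOUNTED_SHARE",
    "PREDATION_FACTOR",
]

#: Floor on the share of the true herd missed by the autumn census.
DEFAULT_UNCOUNTED_SHARE = 0.10

#: Reported predation deaths are multiplied by this factor (one third of
#: carcasses are assumed never found).
PREDATION_FACTOR = 1.5

_PACKAGED_TABLE = Path(__file__).parent / "data" / "districts_fi20.csv"

_TABLE_COLUMNS = [
    "district_id",
    "rotation",
    "feeding",
    "area_lichen",
    "area_arboreal",
    "arboreal_avail",
    "z_1995",
    "z_2008",
    "growth_rel",
    "hm_reduction_pct",
    "infra_pct",
]


@dataclass(frozen=True)
class AnnualHerdCount:
    """One year of herd bookkeeping for a district.

    Counts refer to the autumn round-up: animals left alive after
    slaughter, slaughter removals by class, and mortalities reported
    during the preceding year.
    """

    year: int
    calves_alive: float
    females_alive: float
    males_alive: float
    calves_slaughtered: float = 0.0
    females_slaughtered: float = 0.0
    males_slaughtered: float = 0.0
    traffic_deaths: float = 0.0
    predation_reported: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")

    @property
    def total_alive(self) -> float:
        return self.calves_alive + self.females_alive + self.males_alive

    @property
    def adults_alive(self) -> float:
        return self.females_alive + self.males_alive

    @property
    def adults_slaughtered(self) -> float:
        return self.females_slaughtered + self.males_slaughtered


@dataclass
class DistrictRecord:
    """Static pasture parameters for one herding district.

    Units: areas in ha, biomasses in kg/ha, feeding in kg of
    supplementary feed per reindeer per winter.  ``growth_rel`` is the
    lichen growth rate relative to mature/old pine forest,
    ``hm_reduction`` the fractional growth reduction from airborne
    heavy-metal deposition, and ``infra_pct`` the percentage of the
    district area under infrastructure-associated disturbance.
    """

    district_id: str
    rotation: bool
    feeding: float
    area_lichen: float
    area_arboreal: float
    arboreal_avail: float
    z_1995: float
    z_2008: float
    growth_rel: float
    hm_reduction: float
    infra_pct: float
    herd_years: list[AnnualHerdCount] = field(default_factory=list)

    def __post_init__(self) -> None:
        checks = [
            (self.area_lichen > 0, f"area_lichen must be > 0, got {self.area_lichen}"),
            (self.area_arboreal >= 0, f"area_arboreal must be >= 0, got {self.area_arboreal}"),
            (self.arboreal_avail >= 0, f"arboreal_avail must be >= 0, got {self.arboreal_avail}"),
            (self.z_1995 > 0, f"z_1995 must be > 0, got {self.z_1995}"),
            (self.z_2008 > 0, f"z_2008 must be > 0, got {self.z_2008}"),
            (0 < self.growth_rel <= 1, f"growth_rel must be in (0, 1], got {self.growth_rel}"),
            (0 <= self.hm_reduction < 1, f"hm_reduction must be in [0, 1), got {self.hm_reduction}"),
            (self.feeding >= 0, f"feeding must be >= 0, got {self.feeding}"),
            (0 <= self.infra_pct <= 100, f"infra_pct must be in [0, 100], got {self.infra_pct}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"district {self.district_id}: {msg}")

    @property
    def arboreal_pool(self) -> float:
        """Arboreal lichen available per winter (kg): q * A_Q."""
        return self.arboreal_avail * self.area_arboreal


@dataclass
class HerdSeries:
    """Corrected seasonal grazing pressure for one district.

    ``reindeer_days`` has shape (n_years, 4) in season order
    (winter, spring, summer, autumn) and already folds in the uncounted
    correction and within-winter attrition from mortality.
    """

    district_id: str
    years: np.ndarray
    corrected_calves: np.ndarray
    corrected_females: np.ndarray
    corrected_males: np.ndarray
    share_uncounted: np.ndarray
    winter_mortality: np.ndarray
    reindeer_days: np.ndarray

    @property
    def corrected_total(self) -> np.ndarray:
        return self.corrected_calves + self.corrected_females + self.corrected_males


def min_uncounted(
    alive_after_slaughter_t: float,
    adults_counted_t1: float,
    adults_slaughtered_t1: float,
    winter_deaths: float,
) -> float:
    """Minimum number of reindeer uncounted in autumn of year ``t``.

    Every animal alive after slaughter in autumn ``t`` is over one year
    old the next autumn, so it must appear among the adults counted or
    slaughtered in ``t+1`` or among the winter deaths.  Any excess of
    that balance over the reported survivors was uncounted in year
    ``t``.  The true number can only be higher (animals missed two
    years running never enter the balance).
    """
    for name, v in (
        ("alive_after_slaughter_t", alive_after_slaughter_t),
        ("adults_counted_t1", adults_counted_t1),
        ("adults_slaughtered_t1", adults_slaughtered_t1),
        ("winter_deaths", winter_deaths),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    balance = adults_counted_t1 + adults_slaughtered_t1 + winter_deaths - alive_after_slaughter_t
    return max(0.0, balance)


def corrected_herd(
    record: DistrictRecord,
    default_uncounted_share: float = DEFAULT_UNCOUNTED_SHARE,
    predation_factor: float = PREDATION_FACTOR,
    season_schedule=None,
) -> HerdSeries:
    """Turn raw census bookkeeping into corrected seasonal reindeer-days.

    Per year, the applied uncounted share is the maximum of the default
    floor and the share implied by :func:`min_uncounted` (the final
    year, lacking a successor, uses the floor).  The share is applied
    uniformly to all classes.  Winter reindeer-days are reduced by a
    single mid-winter mortality step; the post-winter herd drives the
    remaining seasons.
    """
    if not record.herd_years:
        raise ValueError(f"district {record.district_id}: empty herd series")
    if season_schedule is None:
        from .pasture import SeasonSchedule

        season_schedule = SeasonSchedule()

    years_sorted = sorted(record.herd_years, key=lambda h: h.year)
    n = len(years_sorted)
    years = np.array([h.year for h in years_sorted], dtype=int)

    shares = np.empty(n)
    mortality = np.empty(n)
    cal = np.empty(n)
    fem = np.empty(n)
    mal = np.empty(n)

    for i, h in enumerate(years_sorted):
        if i + 1 < n:
            nxt = years_sorted[i + 1]
            winter_deaths = nxt.traffic_deaths + predation_factor * nxt.predation_reported
            u = min_uncounted(
                h.total_alive, nxt.adults_alive, nxt.adults_slaughtered, winter_deaths
            )
            if h.total_alive <= 0 and u > 0:
                raise ValueError(
                    f"district {record.district_id}, year {h.year}: zero counted herd "
                    "with a positive uncounted balance (inconsistent data)"
                )
            implied = u / (h.total_alive + u) if (h.total_alive + u) > 0 else 0.0
        else:
            implied = 0.0
        share = max(default_uncounted_share, implied)
        if share >= 1.0:
            raise ValueError(
                f"district {record.district_id}, year {h.year}: implied uncounted "
                f"share {share:.3f} >= 1 (inconsistent data)"
            )
        shares[i] = share
        corr = 1.0 / (1.0 - share)
        cal[i] = h.calves_alive * corr
        fem[i] = h.females_alive * corr
        mal[i] = h.males_alive * corr
        total = cal[i] + fem[i] + mal[i]
        deaths = h.traffic_deaths + predation_factor * h.predation_reported
        mortality[i] = min(1.0, deaths / total) if total > 0 else 0.0

    days = season_schedule.days  # (wi, sp, su, au)
    totals = cal + fem + mal
    post_winter = totals * (1.0 - mortality)
    rd = np.empty((n, 4))
    # single mid-winter step: half the winter at the full herd, half at
    # the post-mortality herd
    rd[:, 0] = days[0] * 0.5 * (totals + post_winter)
    for s in (1, 2, 3):
        rd[:, s] = days[s] * post_winter
    return HerdSeries(
        district_id=record.district_id,
        years=years,
        corrected_calves=cal,
        corrected_females=fem,
        corrected_males=mal,
        share_uncounted=shares,
        winter_mortality=mortality,
        reindeer_days=rd,
    )


def _records_from_frame(df: pd.DataFrame, source: str) -> list[DistrictRecord]:
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{source}: no districts")
    records = []
    for idx, row in df.iterrows():
        rot_raw = str(row["rotation"]).strip().upper()
        if rot_raw in {"YES", "TRUE", "1"}:
            rotation = True
        elif rot_raw in {"NO", "FALSE", "0"}:
            rotation = False
        else:
            raise ValueError(f"{source}, row {idx}: bad rotation flag {row['rotation']!r}")
        numeric = {}
        for col in _TABLE_COLUMNS[2:]:
            try:
                numeric[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{source}, row {idx}, column {col}: non-numeric cell {row[col]!r}"
                ) from exc
        try:
            rec = DistrictRecord(
                district_id=str(row["district_id"]),
                rotation=rotation,
                feeding=numeric["feeding"],
                area_lichen=numeric["area_lichen"],
                area_arboreal=numeric["area_arboreal"],
                arboreal_avail=numeric["arboreal_avail"],
                z_1995=numeric["z_1995"],
                z_2008=numeric["z_2008"],
                growth_rel=numeric["growth_rel"],
                hm_reduction=numeric["hm_reduction_pct"] / 100.0,
                infra_pct=numeric["infra_pct"],
            )
        except ValueError as exc:
            raise ValueError(f"{source}, row {idx}: {exc}") from exc
        records.append(rec)
    return records


def load_districts(table_path: str | Path) -> list[DistrictRecord]:
    """Load a delimited district table (one row per district)."""
    path = Path(table_path)
    df = pd.read_csv(path, sep=None, engine="python")
    return _records_from_frame(df, str(path))


def load_packaged_districts() -> list[DistrictRecord]:
    """The packaged 20-district pasture table for northernmost Finland."""
    return load_districts(_PACKAGED_TABLE)


def write_districts(records: Sequence[DistrictRecord], table_path: str | Path) -> None:
    """Write district records back to CSV (inverse of :func:`load_districts`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "district_id": r.district_id,
                "rotation": "YES" if r.rotation else "NO",
                "feeding": r.feeding,
                "area_lichen": r.area_lichen,
                "area_arboreal": r.area_arboreal,
                "arboreal_avail": r.arboreal_avail,
                "z_1995": r.z_1995,
                "z_2008": r.z_2008,
                "growth_rel": r.growth_rel,
                "hm_reduction_pct": round(r.hm_reduction * 100.0, 10),
                "infra_pct": r.infra_pct,
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(table_path, index=False)


def herd_series_frame(series: Sequence[HerdSeries]) -> pd.DataFrame:
    """Long-format view of corrected herd series (one row per district-year)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "district_id": s.district_id,
                    "year": s.years,
                    "corrected_calves": s.corrected_calves,
                    "corrected_females": s.corrected_females,
                    "corrected_males": s.corrected_males,
                    "share_uncounted": s.share_uncounted,
                    "winter_mortality": s.winter_mortality,
                    "rd_winter": s.reindeer_days[:, 0],
                    "rd_spring": s.reindeer_days[:, 1],
                    "rd_summer": s.reindeer_days[:, 2],
                    "rd_autumn": s.reindeer_days[:, 3],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
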