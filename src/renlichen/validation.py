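"""Wastage estimation, cross-validated model validation, and ablations.

The agreement statistic is modeling efficiency,

    EF = 1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2),

a dimensionless measure equal to 1 for a perfect fit, 0 for the
mean-predictor baseline, and negative when the model does worse than
the mean (the Nash-Sutcliffe efficiency).  Seasonal wastage multipliers
are estimated by maximizing EF of predicted vs. observed end-of-period
lichen biomass across districts; validation uses leave-one-out
cross-validation so that each district is predicted with parameters
estimated without it.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .districts import DistrictRecord, corrected_herd
from .pasture import (
    DistrictBatch,
    GrazingConfig,
    SeasonSchedule,
    WastageParameters,
    pack_districts,
    predict_final_biomass,
)

__all__ = [
    "modeling_efficiency",
    "pearson_r",
    "OptimizerConfig",
    "estimate_wastage",
    "ValidationResult",
    "loocv",
    "AblationSpec",
    "run_ablation",
    "ablation_battery",
]


def modeling_efficiency(observed, predicted) -> float:
    """Nash-Sutcliffe-type modeling efficiency of predictions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are all identical (zero denominator)")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def pearson_r(observed, predicted) -> float:
    """Pearson product-moment correlation between observations and predictions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(obs, pred).statistic)


@dataclass(frozen=True)
class OptimizerConfig:
    """Deterministic multi-start simplex search for wastage parameters.

    A fixed lattice of candidate multipliers seeds the search; the best
    ``n_starts`` lattice points are refined with bounded Nelder-Mead.
    Ties break by first occurrence, so results are reproducible.
    """

    lattice: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    lattice_linear: tuple = (0.0, 0.5, 2.0, 8.0)
    n_starts: int = 8
    maxfev: int = 300
    upper_bound: float = 50.0
    fatol: float = 1e-8
    xatol: float = 1e-4


def _objective_factory(batch: DistrictBatch, form: str):
    obs = batch.observed_final

    def neg_ef(x):
        params = WastageParameters.from_free_vector(np.abs(x), form)
        pred = predict_final_biomass(batch, params)
        return -modeling_efficiency(obs, pred)

    return neg_ef


def estimate_wastage(
    districts,
    form: str = "linear",
    optimizer_config: OptimizerConfig | None = None,
    schedule: SeasonSchedule | None = None,
    config: GrazingConfig | None = None,
) -> tuple[WastageParameters, float]:
    """Best-fitting seasonal wastage multipliers for a set of districts.

    Maximizes the modeling efficiency of predicted vs. observed
    end-of-period lichen biomass over the non-negative winter and
    summer anchors (two free parameters for the constant form, four
    for the linear form).  Returns the parameters and the achieved EF.
    """
    if form not in ("constant", "linear"):
        raise ValueError(f"unknown wastage form {form!r}")
    oc = optimizer_config or OptimizerConfig()
    batch = districts if isinstance(districts, DistrictBatch) else pack_districts(
        districts, schedule=schedule, config=config
    )
    if len(batch) < 2:
        raise ValueError("need at least 2 districts for estimation")
    neg_ef = _objective_factory(batch, form)

    ndim = 2 if form == "constant" else 4
    values = oc.lattice if form == "constant" else oc.lattice_linear
    lattice_pts = np.array(list(itertools.product(values, repeat=ndim)), dtype=float)
    lattice_ef = np.array([neg_ef(x) for x in lattice_pts])
    order = np.argsort(lattice_ef, kind="stable")[: oc.n_starts]

    best_x = lattice_pts[order[0]]
    best_f = lattice_ef[order[0]]
    bounds = [(0.0, oc.upper_bound)] * ndim
    for idx in order:
        res = optimize.minimize(
            neg_ef,
            lattice_pts[idx],
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxfev": oc.maxfev, "fatol": oc.fatol, "xatol": oc.xatol},
        )
        if res.fun < best_f:
            best_f = res.fun
            best_x = np.abs(res.x)
    if not np.isfinite(best_f):
        raise RuntimeError("wastage estimation failed to produce a finite EF")
    return WastageParameters.from_free_vector(best_x, form), -best_f


@dataclass
class ValidationResult:
    """Leave-one-out cross-validation output.

    ``predicted`` holds each district's end-of-period biomass predicted
    with parameters estimated on the other districts; ``ef`` and the
    correlation coefficients aggregate those held-out predictions.
    """

    district_ids: list
    observed: np.ndarray
    predicted: np.ndarray
    observed_initial: np.ndarray
    fold_params: list
    fold_ef_train: list
    ef: float
    r_levels: float
    r_changes: float
    form: str

    @property
    def mean_params(self) -> WastageParameters:
        """Arithmetic mean of the fold estimates (the reported averages)."""
        x = np.mean([p.as_free_vector() for p in self.fold_params], axis=0)
        return WastageParameters.from_free_vector(x, self.form)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "district_id": self.district_ids,
                "observed": self.observed,
                "predicted": self.predicted,
                "observed_change": self.observed - self.observed_initial,
                "predicted_change": self.predicted - self.observed_initial,
            }
        )


def loocv(
    districts,
    form: str = "linear",
    optimizer_config: OptimizerConfig | None = None,
    schedule: SeasonSchedule | None = None,
    config: GrazingConfig | None = None,
) -> ValidationResult:
    """Leave-one-out cross-validation of the wastage-parameterized model.

    Each district is held out in turn, the wastage multipliers are
    re-estimated on the remaining districts, and the held-out
    district's end-of-period biomass is predicted with those
    parameters.
    """
    batch = districts if isinstance(districts, DistrictBatch) else pack_districts(
        districts, schedule=schedule, config=config
    )
    n = len(batch)
    if n < 3:
        raise ValueError("need at least 3 districts for cross-validation")
    predicted = np.empty(n)
    fold_params = []
    fold_ef = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        params, ef_train = estimate_wastage(
            batch.subset(mask), form=form, optimizer_config=optimizer_config
        )
        fold_params.append(params)
        fold_ef.append(ef_train)
        held = batch.subset(~mask)
        predicted[i] = predict_final_biomass(held, params)[0]
    obs = batch.observed_final
    return ValidationResult(
        district_ids=list(batch.district_ids),
        observed=obs.copy(),
        predicted=predicted,
        observed_initial=batch.observed_initial.copy(),
        fold_params=fold_params,
        fold_ef_train=fold_ef,
        ef=modeling_efficiency(obs, predicted),
        r_levels=pearson_r(obs, predicted),
        r_changes=pearson_r(obs - batch.observed_initial, predicted - batch.observed_initial),
        form=form,
    )


@dataclass(frozen=True)
class AblationSpec:
    """Structural model variant: extensions removed or rescaled one at a time."""

    no_feeding: bool = False
    no_arboreal: bool = False
    one_growth_rate: bool = False
    no_rotation: bool = False
    rotation_everywhere: bool = False
    no_infra: bool = False
    infra_scale: float = 1.0
    no_nickel: bool = False
    nickel_scale: float = 1.0
    wastage_form: str = "linear"

    def __post_init__(self) -> None:
        if self.no_rotation and self.rotation_everywhere:
            raise ValueError("no_rotation and rotation_everywhere are exclusive")
        if self.no_infra and self.infra_scale != 1.0:
            raise ValueError("no_infra excludes a non-unit infra_scale")
        if self.no_nickel and self.nickel_scale != 1.0:
            raise ValueError("no_nickel excludes a non-unit nickel_scale")
        if self.infra_scale < 0 or self.nickel_scale < 0:
            raise ValueError("scales must be >= 0")
        if self.wastage_form not in ("constant", "linear"):
            raise ValueError(f"unknown wastage form {self.wastage_form!r}")

    def apply(self, records) -> list[DistrictRecord]:
        out = []
        for r in records:
            changes = {}
            if self.no_feeding:
                changes["feeding"] = 0.0
            if self.no_arboreal:
                changes["area_arboreal"] = 0.0
            if self.one_growth_rate:
                changes["growth_rel"] = 1.0
            if self.no_rotation:
                changes["rotation"] = False
            if self.rotation_everywhere:
                changes["rotation"] = True
            if self.no_infra:
                changes["infra_pct"] = 0.0
            elif self.infra_scale != 1.0:
                changes["infra_pct"] = min(100.0, r.infra_pct * self.infra_scale)
            if self.no_nickel:
                changes["hm_reduction"] = 0.0
            elif self.nickel_scale != 1.0:
                changes["hm_reduction"] = min(0.95, r.hm_reduction * self.nickel_scale)
            out.append(dataclasses.replace(r, **changes) if changes else r)
        return out


def run_ablation(
    districts,
    ablation_spec: AblationSpec,
    optimizer_config: OptimizerConfig | None = None,
    schedule: SeasonSchedule | None = None,
    config: GrazingConfig | None = None,
) -> float:
    """Cross-validated EF of a structural model variant.

    Applies the spec's toggles to the district inputs, re-estimates the
    wastage multipliers within each fold, and returns the overall
    held-out modeling efficiency.
    """
    modified = ablation_spec.apply(districts)
    result = loocv(
        modified,
        form=ablation_spec.wastage_form,
        optimizer_config=optimizer_config,
        schedule=schedule,
        config=config,
    )
    return result.ef


#: The standard battery of structural variants (EF per variant).
STANDARD_VARIANTS = {
    "full_linear": AblationSpec(),
    "full_constant": AblationSpec(wastage_form="constant"),
    "no_feeding": AblationSpec(no_feeding=True),
    "no_arboreal": AblationSpec(no_arboreal=True),
    "one_growth_rate": AblationSpec(one_growth_rate=True),
    "none_above": AblationSpec(no_feeding=True, no_arboreal=True, one_growth_rate=True),
    "no_rotation": AblationSpec(no_rotation=True),
    "no_infra": AblationSpec(no_infra=True),
    "infra_50": AblationSpec(infra_scale=0.5),
    "infra_150": AblationSpec(infra_scale=1.5),
    "no_nickel": AblationSpec(no_nickel=True),
    "nickel_50": AblationSpec(nickel_scale=0.5),
    "nickel_150": AblationSpec(nickel_scale=1.5),
    "bare_no_rotation": AblationSpec(
        no_feeding=True, no_arboreal=True, one_growth_rate=True,
        no_infra=True, no_nickel=True, no_rotation=True,
    ),
    "bare_rotation_everywhere": AblationSpec(
        no_feeding=True, no_arboreal=True, one_growth_rate=True,
        no_infra=True, no_nickel=True, rotation_everywhere=True,
    ),
}


def ablation_battery(
    districts,
    variants: dict | None = None,
    optimizer_config: OptimizerConfig | None = None,
    schedule: SeasonSchedule | None = None,
    config: GrazingConfig | None = None,
) -> pd.Series:
    """EF for each named structural variant."""
    variants = variants or STANDARD_VARIANTS
    out = {}
    for name, spec in variants.items():
        out[name] = run_ablation(
            districts, spec, optimizer_config=optimizer_config,
            schedule=schedule, config=config,
        )
    return pd.Series(out, name="modeling_efficiency")
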