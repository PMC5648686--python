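"""Forward lichen dynamics: wastage forms, growth, seasonal consumption."""

import dataclasses

import numpy as np
import pytest

from renlichen.districts import corrected_herd
from renlichen.pasture import (
    GrazingConfig,
    PastureState,
    SeasonSchedule,
    WastageParameters,
    annual_growth,
    heavy_metal_multiplier,
    infra_wastage,
    pack_districts,
    predict_final_biomass,
    relative_wastage,
    seasonal_removal,
    simulate_lichen,
)


class TestRelativeWastage:
    @pytest.mark.parametrize(
        "z, expected",
        [(0.0, 5.7), (1000.0, 9.6), (500.0, 7.65)],
    )
    def test_linear_summer(self, z, expected):
        p = WastageParameters.linear(0.0, 0.7, 5.7, 9.6)
        assert relative_wastage(p, z, "su") == pytest.approx(expected)

    def test_spring_autumn_half_summer(self):
        p = WastageParameters.linear(0.0, 0.7, 5.7, 9.6)
        for z in (0.0, 400.0, 1500.0):
            assert relative_wastage(p, z, "sp") == pytest.approx(
                0.5 * relative_wastage(p, z, "su")
            )
            assert relative_wastage(p, z, "au") == relative_wastage(p, z, "sp")

    def test_constant_form_flat(self):
        p = WastageParameters.constant(0.5, 8.5)
        assert relative_wastage(p, 0, "wi") == relative_wastage(p, 1800, "wi") == 0.5

    def test_extrapolates_linearly_above_1000(self):
        p = WastageParameters.linear(0.0, 0.7, 5.7, 9.6)
        assert relative_wastage(p, 2000, "wi") == pytest.approx(1.4)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            relative_wastage(WastageParameters.constant(0.5, 8.5), -1.0, "wi")

    def test_constant_requires_equal_anchors(self):
        with pytest.raises(ValueError):
            WastageParameters("constant", 0.5, 0.6, 8.5, 8.5)


class TestInfraWastage:
    @pytest.mark.parametrize("pct, expected", [(25.0, 1.0), (27.2, 1.088), (2.5, 0.1)])
    def test_linear_rule(self, pct, expected):
        assert infra_wastage(pct) == pytest.approx(expected)

    @pytest.mark.parametrize("pct", [-1.0, 101.0])
    def test_out_of_range(self, pct):
        with pytest.raises(ValueError):
            infra_wastage(pct)


class TestHeavyMetal:
    @pytest.mark.parametrize(
        "band, expected",
        [("none", 1.0), ("3-6", 0.8), ("9-12", 0.6), (">15", 0.4),
         (0.0, 1.0), (4.5, 0.8), (10.0, 0.6), (20.0, 0.4)],
    )
    def test_band_mapping(self, band, expected):
        assert heavy_metal_multiplier(band) == expected

    def test_unknown_band_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            assert heavy_metal_multiplier("7-8ish") == 1.0


class TestAnnualGrowth:
    def test_zero_at_carrying_capacity(self):
        cfg = GrazingConfig()
        assert annual_growth(cfg.carrying_capacity, 1.0, 1.0, cfg) == 0.0

    def test_growth_scales_with_relative_rate(self):
        cfg = GrazingConfig()
        g1 = annual_growth(400.0, 1.0, 1.0, cfg)
        assert annual_growth(400.0, 0.5, 1.0, cfg) == pytest.approx(0.5 * g1)

    def test_heavy_metal_scales_growth(self):
        cfg = GrazingConfig()
        g1 = annual_growth(400.0, 0.8, 1.0, cfg)
        assert annual_growth(400.0, 0.8, 0.4, cfg) == pytest.approx(0.4 * g1)

    @pytest.mark.parametrize("form", ["logistic", "gompertz", "saturating"])
    def test_nonnegative_and_bounded(self, form):
        cfg = GrazingConfig(growth_form=form)
        for z in (0.0, 1.0, 500.0, 5999.0, 6000.0):
            inc = annual_growth(z, 1.0, 1.0, cfg)
            assert inc >= 0.0
            assert z + inc <= cfg.carrying_capacity + 1e-9


class TestSeasonalRemoval:
    def test_ledger_identity(self):
        cfg = GrazingConfig()
        state = PastureState(z=500.0)
        removal, led = seasonal_removal(
            state, reindeer_days=5e5, season="su",
            params=WastageParameters.linear(0.0, 0.7, 5.7, 9.6),
            infra_pct=10.0, config=cfg, area=20_000.0,
        )
        expected = led["intake_per_ha"] * (1.0 + led["wastage_multiplier"])
        assert removal == pytest.approx(expected, rel=1e-9)
        assert led["deficit"] == 0.0

    def test_consumption_is_intake_plus_wastage(self):
        # relative wastage exactly 1 doubles the removal
        cfg = GrazingConfig()
        state = PastureState(z=800.0)
        removal, led = seasonal_removal(
            state, 1e5, "wi", WastageParameters.constant(1.0, 2.0),
            infra_pct=0.0, config=cfg, area=50_000.0,
        )
        assert removal == pytest.approx(2.0 * led["intake_per_ha"], rel=1e-12)

    def test_nothing_to_graze(self):
        removal, led = seasonal_removal(
            PastureState(z=0.0), 1e5, "wi", WastageParameters.constant(0.5, 8.5),
            infra_pct=0.0, config=GrazingConfig(), area=10_000.0,
        )
        assert removal == 0.0
        assert led["intake_per_ha"] == 0.0

    def test_clamped_at_available_biomass(self):
        removal, led = seasonal_removal(
            PastureState(z=2.0), 1e7, "su", WastageParameters.constant(0.5, 8.5),
            infra_pct=0.0, config=GrazingConfig(), area=100.0,
        )
        assert removal == 2.0
        assert led["deficit"] > 0


class TestSimulate:
    def test_zero_reindeer_grows_toward_capacity(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        rec = dataclasses.replace(records[0], feeding=0.0)
        series = corrected_herd(rec)
        series.reindeer_days[:] = 0.0
        traj = simulate_lichen(rec, series, WastageParameters.constant(0.5, 8.5))
        assert np.all(np.diff(traj.values) > 0)
        assert traj.iloc[-1] <= GrazingConfig().carrying_capacity

    def test_constant_and_linear_forms_agree_when_anchors_equal(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        batch = pack_districts(records)
        z_const = predict_final_biomass(batch, WastageParameters.constant(0.5, 8.5))
        z_lin = predict_final_biomass(batch, WastageParameters.linear(0.5, 0.5, 8.5, 8.5))
        assert np.array_equal(z_const, z_lin)

    def test_rotation_shields_summer(self, synthetic_noisefree):
        records, _ = synthetic_noisefree
        rec = next(r for r in records if r.rotation)
        series = corrected_herd(rec)
        base = simulate_lichen(rec, series, WastageParameters.constant(0.5, 8.5))
        heavy = corrected_herd(rec)
        heavy.reindeer_days[:, 2] *= 100.0  # summer pressure is irrelevant
        again = simulate_lichen(rec, heavy, WastageParameters.constant(0.5, 8.5))
        assert np.array_equal(base.values, again.values)

    @pytest.mark.parametrize("param_index", [0, 1, 2, 3])
    def test_more_wastage_never_raises_biomass(self, synthetic_noisefree, param_index):
        records, _ = synthetic_noisefree
        batch = pack_districts(records)
        x = np.array([0.2, 0.7, 5.7, 9.6])
        lo = predict_final_biomass(batch, WastageParameters.from_free_vector(x, "linear"))
        x2 = x.copy()
        x2[param_index] += 2.0
        hi = predict_final_biomass(batch, WastageParameters.from_free_vector(x2, "linear"))
        assert np.all(hi <= lo + 1e-12)

    def test_packaged_district_bounded(self, packaged_districts, synthetic_noisefree):
        # drive a real pasture row with a synthetic herd series
        records, _ = synthetic_noisefree
        series = corrected_herd(records[0])
        rec = dataclasses.replace(packaged_districts[0], herd_years=records[0].herd_years)
        traj = simulate_lichen(rec, params=WastageParameters.linear(0.0, 0.7, 5.7, 9.6))
        assert np.all(traj.values >= 0)
        assert np.all(traj.values <= GrazingConfig().carrying_capacity)
        assert np.isfinite(traj.values).all()


class TestSeasonSchedule:
    def test_days_must_sum_to_365(self):
        with pytest.raises(ValueError):
            SeasonSchedule(days=(180.0, 60.0, 95.0, 40.0))

    def test_rotation_exposure(self):
        s = SeasonSchedule()
        assert s.rotation_exposure == pytest.approx([1.0, 28.0 / 60.0, 0.0, 0.0])
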