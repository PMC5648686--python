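"""District table loading and herd bookkeeping corrections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from renlichen.districts import (
    AnnualHerdCount,
    DistrictRecord,
    corrected_herd,
    load_districts,
    min_uncounted,
    write_districts,
)


class TestLoadDistricts:
    def test_packaged_table_shape_and_first_row(self, packaged_districts):
        recs = packaged_districts
        assert len(recs) == 20
        hd1 = recs[0]
        assert hd1.district_id == "1"
        assert hd1.rotation is False
        assert hd1.area_lichen == 78780
        assert hd1.z_1995 == 33
        assert hd1.z_2008 == 129
        assert hd1.growth_rel == 0.49
        assert hd1.hm_reduction == 0.2
        assert hd1.infra_pct == 3.4

    def test_row_order_preserved(self, packaged_districts):
        assert [r.district_id for r in packaged_districts] == [
            str(i) for i in range(1, 21)
        ]

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        pd.DataFrame(
            columns=[
                "district_id", "rotation", "feeding", "area_lichen",
                "area_arboreal", "arboreal_avail", "z_1995", "z_2008",
                "growth_rel", "hm_reduction_pct", "infra_pct",
            ]
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="no districts"):
            load_districts(p)

    def test_missing_column_identified(self, tmp_path, packaged_districts):
        p = tmp_path / "t.csv"
        write_districts(packaged_districts, p)
        df = pd.read_csv(p).drop(columns=["z_1995"])
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="z_1995"):
            load_districts(p)

    def test_negative_area_rejected_with_row(self, tmp_path, packaged_districts):
        p = tmp_path / "t.csv"
        write_districts(packaged_districts, p)
        df = pd.read_csv(p)
        df.loc[2, "area_lichen"] = -5
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="row 2"):
            load_districts(p)

    def test_non_numeric_cell_identified(self, tmp_path, packaged_districts):
        p = tmp_path / "t.csv"
        write_districts(packaged_districts, p)
        df = pd.read_csv(p).astype(object)
        df.loc[4, "feeding"] = "lots"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="feeding"):
            load_districts(p)

    def test_round_trip(self, tmp_path, packaged_districts):
        p = tmp_path / "round.csv"
        write_districts(packaged_districts, p)
        again = load_districts(p)
        assert again == packaged_districts


class TestMinUncounted:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1000, 950, 30, 30), 10),       # balance exceeds survivors by 10
            ((1000, 900, 50, 50), 0),        # deficit clamps at zero
            ((0, 100, 0, 0), 100),           # everyone next year was uncounted
        ],
    )
    def test_examples(self, args, expected):
        assert min_uncounted(*args) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            min_uncounted(-1, 0, 0, 0)

    @settings(max_examples=200, derandomize=True)
    @given(
        alive=st.floats(0, 1e5),
        counted=st.floats(0, 1e5),
        sl=st.floats(0, 1e4),
        deaths=st.floats(0, 1e4),
        bump=st.floats(0, 1e4),
    )
    def test_monotone(self, alive, counted, sl, deaths, bump):
        base = min_uncounted(alive, counted, sl, deaths)
        assert min_uncounted(alive, counted + bump, sl, deaths) >= base
        assert min_uncounted(alive, counted, sl, deaths + bump) >= base
        assert min_uncounted(alive + bump, counted, sl, deaths) <= base


def _record_with_years(years):
    return DistrictRecord(
        district_id="T",
        rotation=False,
        feeding=0.0,
        area_lichen=10_000.0,
        area_arboreal=0.0,
        arboreal_avail=0.0,
        z_1995=400.0,
        z_2008=300.0,
        growth_rel=0.8,
        hm_reduction=0.0,
        infra_pct=5.0,
        herd_years=years,
    )


def _year(year, alive, **kw):
    return AnnualHerdCount(
        year=year,
        calves_alive=0.2 * alive,
        females_alive=0.65 * alive,
        males_alive=0.15 * alive,
        **kw,
    )


class TestCorrectedHerd:
    def test_floor_applied_when_implied_share_low(self):
        # implied share 4%: balance exceeds survivors by 41.67 of 1041.67
        u = 1000 * 0.04 / 0.96
        rec = _record_with_years(
            [_year(1995, 1000), AnnualHerdCount(1996, 200, (1000 + u) * 0.8, (1000 + u) * 0.2)]
        )
        series = corrected_herd(rec)
        assert series.share_uncounted[0] == pytest.approx(0.10)

    def test_data_implied_share_above_floor_used(self):
        u = 1000 * 0.15 / 0.85
        rec = _record_with_years(
            [_year(1995, 1000), AnnualHerdCount(1996, 200, (1000 + u) * 0.8, (1000 + u) * 0.2)]
        )
        series = corrected_herd(rec)
        assert series.share_uncounted[0] == pytest.approx(0.15)

    def test_predation_inflated_by_factor(self):
        rec = _record_with_years(
            [
                _year(1995, 1000),
                _year(1996, 1000, predation_reported=100.0),
            ]
        )
        series = corrected_herd(rec)
        # winter mortality of year 1996 counts 150 effective predation deaths
        total_96 = series.corrected_total[1]
        assert series.winter_mortality[1] == pytest.approx(150.0 / total_96)

    def test_correction_never_below_census(self):
        rec = _record_with_years([_year(1995 + i, 800 + 10 * i) for i in range(5)])
        series = corrected_herd(rec)
        raw = np.array([h.total_alive for h in rec.herd_years])
        ratio = series.corrected_total / raw
        assert np.all(ratio >= 1.0 / 0.9 - 1e-12)

    def test_applied_uniformly_across_classes(self):
        rec = _record_with_years([_year(1995, 1000), _year(1996, 1000)])
        series = corrected_herd(rec)
        assert series.corrected_calves[0] / series.corrected_total[0] == pytest.approx(0.2)
        assert series.corrected_females[0] / series.corrected_total[0] == pytest.approx(0.65)

    def test_reindeer_days_follow_schedule(self):
        rec = _record_with_years([_year(1995, 900)])
        series = corrected_herd(rec)
        n = series.corrected_total[0]
        # no mortality: winter days = 180 * n, spring 60 * n, etc.
        assert series.reindeer_days[0] == pytest.approx(
            [180 * n, 60 * n, 95 * n, 30 * n]
        )

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            corrected_herd(_record_with_years([]))
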