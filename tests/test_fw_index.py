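import math

import numpy as np
import pandas as pd
import pytest

from fwaging import synthetic_data as sd
from fwaging.errors import ConfigurationError, FactorLookupError, UndefinedStatisticError
from fwaging.fw_index import (
    FWWeights,
    RegionalIndex,
    RegionalPanel,
    aggregate_zones,
    classify_trend,
    compute_factors,
    derive_weights,
    fw_score,
    indices_to_frame,
    load_zone_map,
    plot_indices,
    score_panel,
    trend_table,
)
from test_stepwise_model import make_fit


FINAL_ORS = {"X2": 1.554, "X3": 1.573, "X4": 0.663, "X6": 1.697, "X7": 0.497}


def final_fit():
    return make_fit({t: math.log(orr) for t, orr in FINAL_ORS.items()})


class TestDeriveWeights:
    def test_aging_weight_from_final_odds_ratio(self):
        w = derive_weights(final_fit(), precision=2)
        assert w.w1_aging == pytest.approx(0.44)

    def test_family_care_weight(self):
        w = derive_weights(final_fit(), precision=2)
        assert w.w4_family_care == pytest.approx(0.53)

    def test_urbanization_weight(self):
        w = derive_weights(final_fit(), precision=2)
        assert w.w2_urbanization == pytest.approx(0.45)

    def test_education_weight_blends_one_third_two_thirds(self):
        w = derive_weights(final_fit())
        expected = abs(math.log(0.663)) / 3 + abs(math.log(0.497)) * 2 / 3
        assert w.w3_education == pytest.approx(expected)

    def test_unit_odds_ratio_gives_zero_weight(self):
        fit = make_fit({"X2": 0.0, "X3": 0.2, "X4": 0.2, "X6": 0.2, "X7": 0.2})
        assert derive_weights(fit).w1_aging == pytest.approx(0.0)

    def test_magnitude_convention_for_protective_odds(self):
        w = derive_weights(final_fit())
        assert w.w3_education > 0  # |ln| of ORs below 1

    def test_signed_convention(self):
        w = derive_weights(make_fit({t: math.log(o) for t, o in FINAL_ORS.items() if o > 1} | {"X4": 0.1, "X7": 0.1}), signed=True)
        assert w.w1_aging == pytest.approx(math.log(1.554))

    def test_missing_term_raises(self):
        fit = make_fit({"X2": 0.4, "X3": 0.4})
        with pytest.raises(FactorLookupError):
            derive_weights(fit)


def panel_with_national(rows, national):
    frame = pd.DataFrame(rows)
    nat = pd.DataFrame(national).set_index("year")
    return RegionalPanel(frame, national=nat)


def _row(region, year, school=8.0, urb=0.5, hh=1e7, pop=3e7, dep=0.14):
    return {
        "region": region,
        "year": year,
        "mean_schooling_years": school,
        "urbanization_rate": urb,
        "households": hh,
        "population": pop,
        "old_age_dependency_ratio": dep,
    }


def _nat(year, school=8.0, urb=0.5, hh=1e7, pop=3e7, dep=0.14):
    return {
        "year": year,
        "mean_schooling_years": school,
        "urbanization_rate": urb,
        "households": hh,
        "population": pop,
        "old_age_dependency_ratio": dep,
    }


class TestComputeFactors:
    def test_region_at_national_average_is_all_ones(self):
        panel = panel_with_national([_row("A", 2005)], [_nat(2005)])
        assert compute_factors(panel, "A", 2005) == pytest.approx((1, 1, 1, 1))

    def test_half_dependency_ratio_doubles_aging_factor(self):
        panel = panel_with_national([_row("A", 2005, dep=0.07)], [_nat(2005, dep=0.14)])
        f1, *_ = compute_factors(panel, "A", 2005)
        assert f1 == pytest.approx(2.0)

    def test_random_panel_matches_ratio_oracle(self, rng):
        years = [2005, 2010, 2015]
        rows, nats = [], []
        for year in years:
            nats.append(
                _nat(
                    year,
                    school=rng.uniform(6, 10),
                    urb=rng.uniform(0.3, 0.7),
                    hh=rng.uniform(5e6, 2e7),
                    pop=rng.uniform(2e7, 6e7),
                    dep=rng.uniform(0.08, 0.25),
                )
            )
            for region in ("A", "B", "C"):
                rows.append(
                    _row(
                        region,
                        year,
                        school=rng.uniform(6, 10),
                        urb=rng.uniform(0.3, 0.7),
                        hh=rng.uniform(5e6, 2e7),
                        pop=rng.uniform(2e7, 6e7),
                        dep=rng.uniform(0.08, 0.25),
                    )
                )
        panel = panel_with_national(rows, nats)
        for region in ("A", "B", "C"):
            for year in years:
                row = panel.row(region, year)
                nat = panel.national(year)
                f1, f2, f3, f4 = compute_factors(panel, region, year)
                assert f1 == pytest.approx(
                    nat["old_age_dependency_ratio"] / row["old_age_dependency_ratio"], abs=1e-12
                )
                assert f2 == pytest.approx(
                    row["urbanization_rate"] / nat["urbanization_rate"], abs=1e-12
                )
                assert f3 == pytest.approx(
                    row["mean_schooling_years"] / nat["mean_schooling_years"], abs=1e-12
                )
                assert f4 == pytest.approx(
                    (row["population"] / row["households"])
                    / (nat["population"] / nat["households"]),
                    abs=1e-12,
                )

    def test_household_count_mode(self):
        panel = panel_with_national([_row("A", 2005, hh=2e7)], [_nat(2005, hh=1e7)])
        *_, f4 = compute_factors(panel, "A", 2005, household_mode="households")
        assert f4 == pytest.approx(2.0)

    def test_unknown_mode_rejected(self):
        panel = panel_with_national([_row("A", 2005)], [_nat(2005)])
        with pytest.raises(ConfigurationError):
            compute_factors(panel, "A", 2005, household_mode="bogus")

    def test_missing_region_raises(self):
        panel = panel_with_national([_row("A", 2005)], [_nat(2005)])
        with pytest.raises(FactorLookupError):
            compute_factors(panel, "B", 2005)


WEIGHTS = FWWeights(0.44, 0.45, 0.5967, 0.53)


class TestFwScore:
    def test_baseline_100(self):
        entry = fw_score((1, 1, 1, 1), WEIGHTS)
        assert entry.score_100 == pytest.approx(100.0)

    def test_hand_computed_example(self):
        entry = fw_score((2, 1, 1, 1), WEIGHTS)
        total = 0.44 + 0.45 + 0.5967 + 0.53
        raw = 2 * 0.44 + 0.45 + 0.5967 + 0.53
        assert entry.score_raw == pytest.approx(raw)
        assert entry.score_100 == pytest.approx(100 * raw / total)
        assert entry.score_100 == pytest.approx(121.82, abs=0.01)

    def test_homogeneity(self):
        one = fw_score((1.1, 0.9, 1.2, 0.8), WEIGHTS)
        two = fw_score((2.2, 1.8, 2.4, 1.6), WEIGHTS)
        assert two.score_raw == pytest.approx(2 * one.score_raw)
        assert two.score_100 == pytest.approx(2 * one.score_100)

    def test_weight_rescaling_invariance(self, rng):
        factors = tuple(rng.uniform(0.5, 2.0, size=4))
        scaled = FWWeights(*(3.7 * w for w in WEIGHTS.as_tuple()))
        assert fw_score(factors, scaled).score_100 == pytest.approx(
            fw_score(factors, WEIGHTS).score_100
        )

    def test_no_normalize_returns_raw(self):
        entry = fw_score((1, 1, 1, 1), WEIGHTS, normalize=False)
        assert entry.score_100 == pytest.approx(entry.score_raw)

    def test_zero_weights_raise(self):
        with pytest.raises(UndefinedStatisticError):
            fw_score((1, 1, 1, 1), FWWeights(0, 0, 0, 0))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            fw_score((0, 1, 1, 1), WEIGHTS)


class TestScorePanel:
    def test_identical_regions_all_score_100(self):
        panel = sd.generate_macro(
            sd.MacroGenConfig(n_regions=4, years=[2005, 2010, 2015], dispersion=0.0, seed=0)
        )
        indices = score_panel(panel, WEIGHTS)
        assert len(indices) == 12
        for ix in indices:
            assert ix.score_100 == pytest.approx(100.0)


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ((100, 110, 105), 1),
            ((110, 105, 100), 2),
            ((110, 100, 105), 3),
            ((100, 105, 110), 4),
        ],
    )
    def test_canonical_shapes(self, series, expected):
        assert classify_trend(series) == expected

    def test_flat_series_counts_as_down(self):
        assert classify_trend((100, 100, 100)) == 2

    def test_mapping_input_sorted_by_year(self):
        assert classify_trend({2015: 105, 2005: 100, 2010: 110}) == 1

    def test_wrong_length_raises(self):
        with pytest.raises(FactorLookupError):
            classify_trend((1, 2))

    def test_exhaustive_exclusive_on_random_series(self, rng):
        for _ in range(200):
            vals = tuple(rng.uniform(90, 110, size=3))
            assert classify_trend(vals) in (1, 2, 3, 4)


def make_index(region, year, score):
    return RegionalIndex(
        region=region,
        year=year,
        f1_aging=1.0,
        f2_urbanization=1.0,
        f3_education=1.0,
        f4_family_care=1.0,
        score_raw=score / 100 * WEIGHTS.total,
        score_100=score,
    )


class TestTrendTable:
    def test_per_region_types(self):
        indices = [
            make_index("A", y, s) for y, s in zip((2005, 2010, 2015), (100, 110, 105))
        ] + [make_index("B", y, s) for y, s in zip((2005, 2010, 2015), (100, 105, 110))]
        table = trend_table(indices)
        assert dict(zip(table["region"], table["trend_type"])) == {"A": 1, "B": 4}


class TestAggregateZones:
    def test_single_region_zone_passthrough(self):
        indices = [make_index("A", 2005, 104.0)]
        out = aggregate_zones(indices, {"A": "Z1"})
        assert out.loc[0, 2005] == pytest.approx(104.0)
        assert out.loc[0, "period_mean"] == pytest.approx(104.0)

    def test_two_region_mean(self):
        indices = [make_index("A", 2005, 100.0), make_index("B", 2005, 120.0)]
        out = aggregate_zones(indices, {"A": "Z", "B": "Z"})
        assert out.loc[0, 2005] == pytest.approx(110.0)

    def test_engineered_zone_means(self, rng):
        scores = {f"R{i}": rng.uniform(90, 110, size=3) for i in range(6)}
        indices = [
            make_index(r, y, s)
            for r, ser in scores.items()
            for y, s in zip((2005, 2010, 2015), ser)
        ]
        zone_map = {f"R{i}": ("east" if i < 3 else "west") for i in range(6)}
        out = aggregate_zones(indices, zone_map).set_index("zone")
        for zone, members in (("east", [0, 1, 2]), ("west", [3, 4, 5])):
            for k, year in enumerate((2005, 2010, 2015)):
                expected = np.mean([scores[f"R{i}"][k] for i in members])
                assert out.loc[zone, year] == pytest.approx(expected)

    def test_grand_mean_conserved_for_equal_zones(self, rng):
        indices = [make_index(f"R{i}", 2005, float(rng.uniform(90, 110))) for i in range(8)]
        zone_map = {f"R{i}": f"Z{i % 4}" for i in range(8)}  # 4 zones x 2 regions
        out = aggregate_zones(indices, zone_map)
        grand = np.mean([ix.score_100 for ix in indices])
        assert out[2005].mean() == pytest.approx(grand)

    def test_unmapped_region_raises(self):
        with pytest.raises(ConfigurationError):
            aggregate_zones([make_index("A", 2005, 100.0)], {"B": "Z"})


class TestZoneMapFile:
    def test_packaged_mapping_loads(self):
        zone_map = load_zone_map()
        assert zone_map["Beijing"] == "Beijing-Tianjin-Hebei"
        assert zone_map["Guangdong"] == "Pearl River Delta"
        assert zone_map["Shanghai"] == "Yangtze River Delta"
        # every region maps to exactly one zone by construction of the dict
        assert len(zone_map) >= 28


class TestPlotIndices:
    def test_files_written(self, tmp_path):
        indices = [
            make_index(r, y, 100 + i)
            for i, r in enumerate("ABC")
            for y in (2005, 2010, 2015)
        ]
        written = plot_indices(indices, tmp_path)
        assert len(written) == 2
        for p in written:
            assert p.exists() and p.stat().st_size > 0

    def test_empty_is_noop_with_warning(self, tmp_path):
        with pytest.warns(UserWarning):
            assert plot_indices([], tmp_path) == []

    def test_ranked_chart_order_non_increasing(self):
        indices = [
            make_index(r, y, s)
            for r, s in (("A", 95.0), ("B", 107.0), ("C", 101.0))
            for y in (2005, 2010, 2015)
        ]
        frame = indices_to_frame(indices)
        avg = frame.groupby("region")["score_100"].mean().sort_values(ascending=False)
        assert list(avg.index) == ["B", "C", "A"]
        assert all(x >= y for x, y in zip(avg, avg[1:]))
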