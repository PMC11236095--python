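"""Annual series, attributions, rankings, coverage, and regressions."""

import numpy as np
import pytest
from scipy import stats as sps

from twowaytrade.aggregation import (
    CountrySummary,
    annual_series,
    country_attribution,
    pair_ranking,
    percent_change,
    redundancy_regression,
    species_ranking,
    threatened_share,
    topk_coverage,
)
from twowaytrade.errors import UndefinedMetricError
from twowaytrade.records import IUCNCategory, IUCNTable, RegionMap
from twowaytrade.redundancy import RedundantFlow, compute_redundant_flows

from .conftest import (
    make_record,
    oracle_by_country,
    oracle_by_pair,
    oracle_by_species,
    oracle_by_year,
    oracle_redundant_cells,
    oracle_total,
    random_filtered_records,
)


def pipeline(records):
    return compute_redundant_flows(records)


def make_country(country, total=100.0, species=80.0, redundant=10.0, n_species=2,
                 trade=150.0):
    return CountrySummary(
        country=country,
        total_export_tonnes=total,
        species_level_export_tonnes=species,
        redundant_export_tonnes=redundant,
        n_redundant_species=n_species,
        total_trade_tonnes=trade,
    )


class TestAnnualSeries:
    def test_worked_example_share(self, worked_example_records):
        flows = pipeline(worked_example_records)
        series = annual_series(worked_example_records, flows)
        assert len(series) == 1
        row = series[0]
        assert row.total_tonnes == 15.0
        assert row.species_level_tonnes == 15.0
        assert row.redundant_tonnes == 10.0
        assert row.redundant_share_of_total == pytest.approx(10.0 / 15.0)

    def test_no_two_way_matches(self):
        records = [make_record("AAA", "BBB", 5.0, year=y) for y in (2000, 2001)]
        series = annual_series(records, pipeline(records))
        assert [s.redundant_tonnes for s in series] == [0.0, 0.0]

    def test_invariant_chain_and_oracle(self, rng):
        records = random_filtered_records(rng, n_rows=100)
        flows = pipeline(records)
        series = annual_series(records, flows)
        expected = oracle_by_year(oracle_redundant_cells(records))
        for row in series:
            assert row.redundant_tonnes <= row.species_level_tonnes <= row.total_tonnes
            assert row.redundant_tonnes == expected.get(row.year, 0.0)


class TestPercentChange:
    def test_no_change(self):
        assert percent_change({2000: 5.0, 2015: 5.0}, 2000, 2015) == 0.0

    def test_definition(self):
        assert percent_change({2000: 100.0, 2015: 143.4}, 2000, 2015) == pytest.approx(43.4)

    def test_decrease(self):
        assert percent_change({2000: 200.0, 2015: 150.0}, 2000, 2015) == pytest.approx(-25.0)

    def test_zero_baseline_undefined(self):
        with pytest.raises(UndefinedMetricError):
            percent_change({2000: 0.0, 2015: 5.0}, 2000, 2015)

    def test_missing_year_undefined(self):
        with pytest.raises(UndefinedMetricError):
            percent_change({2000: 1.0}, 2000, 2015)

    def test_accepts_annual_summaries(self, worked_example_records):
        records = worked_example_records + [
            make_record("AAA", "BBB", 20.0, year=2001),
            make_record("BBB", "AAA", 10.0, year=2001),
        ]
        series = annual_series(records, pipeline(records))
        assert percent_change(series, 2000, 2001) == pytest.approx(100.0)


class TestCountryAttribution:
    def test_worked_example_split(self, worked_example_records):
        flows = pipeline(worked_example_records)
        summaries = country_attribution(flows, worked_example_records)
        by_country = {s.country: s for s in summaries}
        assert by_country["AAA"].redundant_export_tonnes == 5.0
        assert by_country["BBB"].redundant_export_tonnes == 5.0
        assert sum(s.redundant_export_tonnes for s in summaries) == 10.0

    def test_one_way_country_zero(self):
        records = [make_record("AAA", "BBB", 5.0)]
        summaries = country_attribution(pipeline(records), records)
        for s in summaries:
            assert s.redundant_export_tonnes == 0.0
            assert s.redundancy_proportion() == 0.0

    def test_n_redundant_species_counts_distinct(self):
        records = [
            make_record("AAA", "BBB", 10.0, taxon="Gadus morhua"),
            make_record("BBB", "AAA", 5.0, taxon="Gadus morhua"),
            make_record("AAA", "BBB", 4.0, taxon="Clupea harengus"),
            make_record("BBB", "AAA", 4.0, taxon="Clupea harengus"),
        ]
        summaries = country_attribution(pipeline(records), records)
        assert {s.country: s.n_redundant_species for s in summaries} == {"AAA": 2, "BBB": 2}

    def test_proportion_bases(self, worked_example_records):
        flows = pipeline(worked_example_records)
        summaries = country_attribution(flows, worked_example_records)
        a = next(s for s in summaries if s.country == "AAA")
        # AAA exports 10, imports 5; avoidable exports 5
        assert a.redundancy_proportion("exports") == pytest.approx(0.5)
        assert a.redundancy_proportion("trade") == pytest.approx(5.0 / 15.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 7)
        records = random_filtered_records(rng, n_rows=60)
        summaries = country_attribution(pipeline(records), records)
        expected = oracle_by_country(oracle_redundant_cells(records))
        got = {s.country: s.redundant_export_tonnes for s in summaries
               if s.redundant_export_tonnes > 0}
        assert got == expected

    def test_conservation(self, rng):
        records = random_filtered_records(rng, n_rows=120)
        flows = pipeline(records)
        summaries = country_attribution(flows, records)
        total_flows = sum(f.redundant_tonnes for f in flows)
        total_countries = sum(s.redundant_export_tonnes for s in summaries)
        assert total_countries == pytest.approx(total_flows, rel=1e-9)


class TestPairRanking:
    def region_map(self):
        return RegionMap(
            continent={"AAA": "Europe", "BBB": "Europe", "CCC": "Asia", "DDD": "Asia"},
            subregion={"AAA": "Western Europe", "BBB": "Western Europe",
                       "CCC": "Eastern Asia", "DDD": "Southern Asia"},
        )

    def two_pair_flows(self):
        return [
            RedundantFlow(2000, "AAA", "BBB", "Gadus morhua", 10.0, 5.0),
            RedundantFlow(2000, "AAA", "CCC", "Gadus morhua", 4.0, 6.0),
        ]

    def test_half_same_continent_count_basis(self):
        _, overlap = pair_ranking(self.two_pair_flows(), self.region_map())
        assert overlap.same_continent_pair_fraction == pytest.approx(0.5)
        assert overlap.same_subregion_pair_fraction == pytest.approx(0.5)

    def test_all_in_one_subregion(self):
        flows = [RedundantFlow(2000, "AAA", "BBB", "Gadus morhua", 2.0, 2.0)]
        _, overlap = pair_ranking(flows, self.region_map())
        assert overlap.same_continent_pair_fraction == 1.0
        assert overlap.same_subregion_pair_fraction == 1.0
        assert overlap.same_continent_tonnage_fraction == 1.0

    def test_subregion_match_implies_continent_match(self, rng):
        records = random_filtered_records(rng, n_rows=80)
        countries = sorted({r.exporter for r in records} | {r.importer for r in records})
        regions = RegionMap(
            continent={c: f"Continent {i % 2}" for i, c in enumerate(countries)},
            subregion={c: f"Continent {i % 2} Sub {i % 4}" for i, c in enumerate(countries)},
        )
        summaries, _ = pair_ranking(pipeline(records), regions)
        for s in summaries:
            if s.same_subregion:
                assert s.same_continent

    def test_unknown_country_flagged_and_excluded(self):
        flows = self.two_pair_flows() + [
            RedundantFlow(2000, "CCC", "ZZZ", "Gadus morhua", 1.0, 1.0)]
        with pytest.warns(UserWarning, match="region map"):
            summaries, overlap = pair_ranking(flows, self.region_map())
        unknown = next(s for s in summaries if s.country_b == "ZZZ")
        assert unknown.same_continent is None
        assert overlap.n_pairs_known == 2
        assert overlap.same_continent_pair_fraction == pytest.approx(0.5)

    def test_shares_sum_to_one_and_sorted(self, rng):
        records = random_filtered_records(rng, n_rows=100)
        flows = pipeline(records)
        summaries, _ = pair_ranking(flows, None)
        if summaries:
            assert sum(s.share_of_global for s in summaries) == pytest.approx(1.0)
            tonnages = [s.redundant_tonnes for s in summaries]
            assert tonnages == sorted(tonnages, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 21)
        records = random_filtered_records(rng, n_rows=60)
        summaries, _ = pair_ranking(pipeline(records), None)
        expected = oracle_by_pair(oracle_redundant_cells(records))
        got = {(s.country_a, s.country_b): s.redundant_tonnes for s in summaries}
        assert got == expected


class TestSpeciesRanking:
    def test_single_species_share_one(self, worked_example_records):
        summaries = species_ranking(pipeline(worked_example_records))
        assert len(summaries) == 1
        assert summaries[0].share_of_global == 1.0
        assert summaries[0].partner_pairs[0][:2] == ("AAA", "BBB")

    def test_missing_iucn_is_na(self, worked_example_records):
        table = IUCNTable(category={"Clupea harengus": IUCNCategory.LC})
        summaries = species_ranking(pipeline(worked_example_records), table)
        assert summaries[0].iucn_category is IUCNCategory.NA

    def test_iucn_join(self, worked_example_records):
        table = IUCNTable(category={"Gadus morhua": IUCNCategory.VU})
        summaries = species_ranking(pipeline(worked_example_records), table)
        assert summaries[0].iucn_category is IUCNCategory.VU

    def test_partner_shares_sum_to_one(self, rng):
        records = random_filtered_records(rng, n_rows=100)
        for summary in species_ranking(pipeline(records)):
            assert sum(p[3] for p in summary.partner_pairs) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed + 42)
        records = random_filtered_records(rng, n_rows=60)
        summaries = species_ranking(pipeline(records))
        expected = oracle_by_species(oracle_redundant_cells(records))
        got = {s.species: s.redundant_tonnes for s in summaries}
        assert got == expected


class TestTopkCoverage:
    def test_hand_computed(self):
        assert topk_coverage([0.6, 0.3, 0.1], 0.9) == (2, pytest.approx(0.9))

    def test_threshold_one_counts_nonzero_shares(self):
        k, covered = topk_coverage([0.5, 0.3, 0.2, 0.0, 0.0], 1.0)
        assert k == 3
        assert covered == pytest.approx(1.0)

    def test_single_item(self):
        for threshold in (0.1, 0.5, 1.0):
            assert topk_coverage([1.0], threshold) == (1, 1.0)

    def test_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            topk_coverage([], 0.9)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            topk_coverage([1.0], 0.0)

    def test_monotone_in_threshold(self):
        shares = [0.4, 0.25, 0.15, 0.1, 0.05, 0.05]
        ks = [topk_coverage(shares, t)[0] for t in (0.3, 0.5, 0.7, 0.9, 1.0)]
        assert ks == sorted(ks)


class TestThreatenedShare:
    def summaries(self, flows, categories):
        table = IUCNTable(category=categories)
        return species_ranking(flows, table)

    def test_no_threatened_species(self, worked_example_records):
        flows = pipeline(worked_example_records)
        result = threatened_share(self.summaries(flows, {"Gadus morhua": IUCNCategory.LC}))
        assert result.fraction == 0.0

    def test_all_volume_in_one_vulnerable_species(self, worked_example_records):
        flows = pipeline(worked_example_records)
        result = threatened_share(self.summaries(flows, {"Gadus morhua": IUCNCategory.VU}))
        assert result.fraction == 1.0

    def test_mixed_weighted_fraction(self):
        records = [
            make_record("AAA", "BBB", 10.0, taxon="Gadus morhua"),      # VU, 20 t redundant
            make_record("BBB", "AAA", 10.0, taxon="Gadus morhua"),
            make_record("AAA", "BBB", 15.0, taxon="Clupea harengus"),   # LC, 30 t redundant
            make_record("BBB", "AAA", 15.0, taxon="Clupea harengus"),
            make_record("AAA", "BBB", 5.0, taxon="Solea solea"),        # EN, 10 t redundant
            make_record("BBB", "AAA", 5.0, taxon="Solea solea"),
        ]
        result = threatened_share(self.summaries(pipeline(records), {
            "Gadus morhua": IUCNCategory.VU,
            "Clupea harengus": IUCNCategory.LC,
            "Solea solea": IUCNCategory.EN,
        }))
        assert result.fraction == pytest.approx(30.0 / 60.0)
        assert result.category_counts == {"VU": 1, "LC": 1, "EN": 1}


class TestRedundancyRegression:
    def test_noiseless_line_slope_two(self):
        summaries = [make_country(f"C{i:02d}", total=float(10 * (i + 1)),
                                  redundant=float(20 * (i + 1)))
                     for i in range(10)]
        fit = redundancy_regression(summaries, "total_export_tonnes")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_r2_zero(self):
        summaries = [make_country(f"C{i:02d}", total=float(10 * (i + 1)), redundant=5.0)
                     for i in range(10)]
        fit = redundancy_regression(summaries, "total_export_tonnes")
        assert fit.r_squared == pytest.approx(0.0)

    def test_species_fraction_predictor(self):
        summaries = [make_country(f"C{i:02d}", total=100.0,
                                  species=10.0 * (i + 1),
                                  redundant=10.0 * (i + 1))
                     for i in range(5)]
        fit = redundancy_regression(summaries, "species_level_fraction")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(100.0)

    def test_nan_predictors_dropped(self):
        summaries = [make_country(f"C{i:02d}", total=float(10 * (i + 1)),
                                  redundant=float(20 * (i + 1)))
                     for i in range(5)]
        summaries.append(make_country("ZZZ", total=0.0, species=0.0, redundant=0.0))
        fit = redundancy_regression(summaries, "species_level_fraction")
        assert fit.n == 5

    def test_too_few_countries_undefined(self):
        summaries = [make_country("AAA"), make_country("BBB")]
        with pytest.raises(UndefinedMetricError):
            redundancy_regression(summaries)

    def test_degenerate_predictor_undefined(self):
        summaries = [make_country(f"C{i:02d}", total=50.0) for i in range(5)]
        with pytest.raises(UndefinedMetricError):
            redundancy_regression(summaries, "total_export_tonnes")

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            redundancy_regression([make_country("AAA")], "bogus_field")

    def test_noisy_slope_recovered_within_ci(self):
        # single draw sanity check; coverage is tested in the acceptance suite
        rng = np.random.default_rng(7)
        xs = rng.uniform(10, 1000, size=40)
        ys = 2.0 * xs + rng.normal(0, 25, size=40)
        summaries = [make_country(f"C{i:02d}", total=float(x), redundant=float(y))
                     for i, (x, y) in enumerate(zip(xs, ys))]
        fit = redundancy_regression(summaries, "total_export_tonnes")
        se = sps.linregress(xs, ys).stderr
        half_width = sps.t.ppf(0.9995, len(xs) - 2) * se
        assert abs(fit.slope - 2.0) < half_width


class TestGlobalConservation:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_aggregations_sum_to_global(self, seed):
        rng = np.random.default_rng(seed + 77)
        records = random_filtered_records(rng, n_rows=120)
        flows = pipeline(records)
        global_total = sum(f.redundant_tonnes for f in flows)

        series = annual_series(records, flows)
        countries = country_attribution(flows, records)
        pairs, _ = pair_ranking(flows, None)
        species = species_ranking(flows)

        assert sum(s.redundant_tonnes for s in series) == pytest.approx(
            global_total, rel=1e-9)
        assert sum(s.redundant_export_tonnes for s in countries) == pytest.approx(
            global_total, rel=1e-9)
        assert sum(s.redundant_tonnes for s in pairs) == pytest.approx(
            global_total, rel=1e-9)
        assert sum(s.redundant_tonnes for s in species) == pytest.approx(
            global_total, rel=1e-9)
        assert global_total == oracle_total(oracle_redundant_cells(records))
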