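"""Population projection, birth cohorts, age-band slicing, and the region
CSV schema."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutricost.demographics import (
    CohortTable,
    RegionDemographics,
    age_cohort_size,
    annual_births,
    build_cohorts,
    cohort_from_age_bands,
    project_population,
    read_regions_csv,
    write_regions_csv,
)
from nutricost.errors import (
    CoverageError,
    InvalidInputError,
    InvalidIntervalError,
    SchemaError,
)

from conftest import make_region


class TestProjection:
    def test_zero_growth_identity(self):
        assert project_population(1000, 0.0, 3) == 1000

    def test_one_step_closed_form(self):
        assert project_population(1000, 0.01, 1) == pytest.approx(1010)

    @pytest.mark.parametrize("bad", [(-1, 0.01, 1), (100, -1.0, 1), (100, 0.01, -1)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            project_population(*bad)

    @given(
        g1=st.floats(min_value=-0.05, max_value=0.05),
        g2=st.floats(min_value=-0.05, max_value=0.05),
        t=st.floats(min_value=0.5, max_value=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_growth(self, g1, g2, t):
        if abs(g1 - g2) < 1e-6:
            return
        lo, hi = sorted([g1, g2])
        assert project_population(1e6, lo, t) < project_population(1e6, hi, t)

    @given(
        g=st.floats(min_value=0.001, max_value=0.05),
        t1=st.floats(min_value=0, max_value=20),
        t2=st.floats(min_value=0, max_value=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_elapsed_for_positive_growth(self, g, t1, t2):
        if abs(t1 - t2) < 1e-6:
            return
        lo, hi = sorted([t1, t2])
        assert project_population(1e6, g, lo) < project_population(1e6, g, hi)


class TestBirths:
    @pytest.mark.parametrize(
        "pop,cbr,expected", [(1_000_000, 0, 0), (1_000_000, 20, 20_000)]
    )
    def test_closed_form(self, pop, cbr, expected):
        assert annual_births(pop, cbr) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            annual_births(-1, 20)
        with pytest.raises(InvalidInputError):
            annual_births(1, -20)


class TestAgeCohorts:
    def test_one_full_birth_cohort(self):
        assert age_cohort_size(12, 0, 12) == 12

    def test_half_cohort(self):
        assert age_cohort_size(28.19e6, 0, 6) == pytest.approx(14.095e6)

    def test_stationarity_five_birth_cohorts_under_five(self):
        b = 123456.0
        assert age_cohort_size(b, 0, 60) == pytest.approx(5 * b, rel=1e-12)

    def test_reversed_interval_rejected(self):
        with pytest.raises(InvalidIntervalError):
            age_cohort_size(10, 12, 6)


class TestBandSlicing:
    def test_full_band(self):
        bands = {(0.0, 5.0, "m"): 60.0, (0.0, 5.0, "f"): 40.0}
        assert cohort_from_age_bands(bands, 0, 5) == 100

    def test_uniform_interpolation(self):
        bands = {(10.0, 15.0, "m"): 100.0, (15.0, 20.0, "m"): 100.0}
        # [11, 18) takes 4/5 of the first band and 3/5 of the second.
        assert cohort_from_age_bands(bands, 11, 18) == pytest.approx(140)

    def test_outside_coverage_rejected(self):
        bands = {(0.0, 5.0, "m"): 10.0}
        with pytest.raises(CoverageError):
            cohort_from_age_bands(bands, 3, 8)

    @given(
        counts=st.lists(
            st.integers(min_value=0, max_value=50), min_size=4, max_size=4
        ),
        lo=st.integers(min_value=0, max_value=3),
        width=st.integers(min_value=1, max_value=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_aligned_requests_match_per_band_enumeration(self, counts, lo, width):
        """On band-aligned ranges the slice is an exact sum: the oracle just
        assigns every person to its band and counts bands inside the range."""
        hi = min(lo + width, 4)
        if hi <= lo:
            return
        bands = {(float(i), float(i + 1), "m"): float(c) for i, c in enumerate(counts)}
        oracle = sum(counts[i] for i in range(lo, hi))
        assert cohort_from_age_bands(bands, lo, hi) == pytest.approx(oracle)

    @given(
        counts=st.lists(
            st.integers(min_value=0, max_value=50), min_size=3, max_size=3
        ),
        split=st.floats(min_value=0.5, max_value=2.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_additive_over_adjacent_ranges(self, counts, split):
        bands = {(float(i), float(i + 1), "f"): float(c) for i, c in enumerate(counts)}
        left = cohort_from_age_bands(bands, 0, split)
        right = cohort_from_age_bands(bands, split, 3)
        assert left + right == pytest.approx(cohort_from_age_bands(bands, 0, 3))


class TestBuildCohorts:
    def test_nested_child_cohorts_are_monotone(self, toy_region):
        table = build_cohorts(toy_region, 2014)
        c = table.cohorts
        assert (
            c["children_6_12m"]
            <= c["children_6_36m"]
            <= c["children_6_59m"]
            <= c["children_0_59m"]
        )
        assert c["children_6_23m"] <= c["children_6_36m"]

    def test_derived_cohorts_follow_conventions(self, toy_region):
        table = build_cohorts(toy_region, 2014)
        pop = project_population(toy_region.total_population, 0.01, 3)
        births = pop * 20.0 / 1000.0
        assert table["pregnant_women"] == pytest.approx(births)
        assert table["lactating_mothers_0_6m"] <= table["pregnant_women"] * 1.0 + 1e-9
        assert table["households_with_u5"] == pytest.approx(
            table["children_0_59m"] / 2
        )
        assert table["general_population"] == pytest.approx(pop)

    def test_overrides_take_precedence(self, toy_region):
        table = build_cohorts(toy_region, 2014, overrides={"children_6_36m": 42.0})
        assert table["children_6_36m"] == 42.0

    def test_target_year_before_base_rejected(self, toy_region):
        with pytest.raises(InvalidInputError):
            build_cohorts(toy_region, 2005)

    def test_negative_cohort_rejected(self):
        with pytest.raises(InvalidInputError):
            CohortTable("x", 2014, {"pregnant_women": -1.0})


class TestRegionValidation:
    def test_severe_wasting_cannot_exceed_wasting(self):
        with pytest.raises(InvalidInputError):
            make_region(prev_whz_m3=0.2, prev_whz_m2=0.1)

    def test_bands_must_cover_0_100(self):
        with pytest.raises(InvalidInputError):
            RegionDemographics(
                region_id="gap",
                base_year=2011,
                population_by_band={(0.0, 50.0, "m"): 100.0},
                crude_birth_rate=20,
                growth_rate=0.01,
                prev_whz_lt_m3=0.05,
                prev_whz_lt_m2=0.15,
                prev_waz_lt_m3=0.08,
                frac_women_govt=0.03,
            )

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            make_region(prev_waz_m3=1.5)


class TestRegionsCsv:
    def test_round_trip(self, tmp_path, toy_region):
        path = tmp_path / "regions.csv"
        write_regions_csv([toy_region, make_region("other", endemic=True)], path)
        back = read_regions_csv(path)
        assert [r.region_id for r in back] == ["toy", "other"]
        assert back[0].total_population == pytest.approx(
            toy_region.total_population
        )
        assert back[1].malaria_endemic is True
        assert math.isclose(back[0].crude_birth_rate, 20.0)

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("region_id,base_year\n")
        with pytest.raises(SchemaError):
            read_regions_csv(path)

    def test_duplicate_region_id_is_schema_error(self, tmp_path, toy_region):
        path = tmp_path / "dupe.csv"
        write_regions_csv([toy_region, toy_region], path)
        with pytest.raises(SchemaError, match="duplicated"):
            read_regions_csv(path)

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("region_id,pop_m_0_100\na,1\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_regions_csv(path)
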