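import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from descurve.effort_stats import (
    AnnualSeries,
    annual_counts,
    author_careers,
    decade_summaries,
    family_completion_table,
    first_authors_per_year,
    lifetime_summary,
    moving_average,
    prolific_ranking,
    species_per_author,
)
from .conftest import make_record


class TestAnnualCounts:
    def test_counts_with_zero_filled_span(self):
        recs = [make_record(1814), make_record(1814), make_record(1814),
                make_record(1816)]
        s = annual_counts(recs)
        assert s.series.to_dict() == {1814: 3, 1815: 0, 1816: 1}

    def test_group_filter(self):
        recs = [make_record(1900, group="marine"),
                make_record(1900, group="terrestrial"),
                make_record(1901, group="marine")]
        s = annual_counts(recs, group_filter="marine")
        assert s.series.to_dict() == {1900: 1, 1901: 1}

    def test_subgroup_filters(self):
        recs = [make_record(1900, parasitic=True), make_record(1900),
                make_record(1901, subterranean=True)]
        assert annual_counts(recs, group_filter="parasitic").total == 1
        assert annual_counts(recs, group_filter="subterranean").total == 1

    def test_cumulative_view(self):
        s = AnnualSeries({1814: 3, 1816: 1})
        assert s.cumulative().to_dict() == {1814: 3, 1815: 3, 1816: 4}

    def test_totals_partition_by_group(self, small_records):
        records, _, _ = small_records
        total = annual_counts(records).total
        assert total == len(records)
        by_group = sum(
            annual_counts(records, group_filter=g).total
            for g in ("marine", "freshwater", "terrestrial")
        )
        assert by_group == total

    def test_cumulative_is_monotone(self, small_records):
        records, _, _ = small_records
        cum = annual_counts(records).cumulative().to_numpy()
        assert (np.diff(cum) >= 0).all()
        assert cum[-1] == len(records)


class TestMovingAverage:
    def test_window_one_is_identity(self):
        s = AnnualSeries({1900: 2, 1901: 7, 1902: 1})
        assert (moving_average(s, 1) == s.series).all()

    def test_hand_computed_center(self):
        s = AnnualSeries({1900: 0, 1901: 3, 1902: 6})
        ma = moving_average(s, 3)
        assert ma[1901] == pytest.approx(3.0)
        # edges shrink to the raw value
        assert ma[1900] == pytest.approx(0.0)
        assert ma[1902] == pytest.approx(6.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        c=st.integers(0, 50),
        n=st.integers(3, 40),
        window=st.integers(1, 10),
    )
    def test_constant_series_is_preserved(self, c, n, window):
        if window > n:
            window = n
        s = AnnualSeries({1900 + i: c for i in range(n)})
        assert np.allclose(moving_average(s, window), c)

    def test_window_longer_than_series_is_an_error(self):
        s = AnnualSeries({1900: 1, 1901: 2})
        with pytest.raises(ValueError):
            moving_average(s, 3)


class TestAuthorsAndProductivity:
    def test_one_author_many_species_counts_once(self):
        recs = [make_record(1814, "Leach") for _ in range(3)]
        assert first_authors_per_year(recs).series.to_dict() == {1814: 1}

    def test_two_authors_count_twice(self):
        recs = [make_record(1814, "Leach"), make_record(1814, "Brandt")]
        assert first_authors_per_year(recs).series[1814] == 2

    def test_author_active_in_two_years_counts_in_both(self):
        recs = [make_record(1814, "Leach"), make_record(1816, "Leach")]
        s = first_authors_per_year(recs)
        assert s.series[1814] == 1 and s.series[1816] == 1

    def test_species_per_author_ratio(self):
        recs = [make_record(1900, f"A{i % 2}") for i in range(10)]
        assert species_per_author(recs)[1900] == pytest.approx(5.0)

    def test_zero_year_is_undefined_marker(self):
        recs = [make_record(1900), make_record(1902)]
        ratio = species_per_author(recs)
        assert np.isnan(ratio[1901])
        assert ratio[1900] == pytest.approx(1.0)


class TestCareersAndLifetimes:
    def test_single_year_author_has_lifetime_one(self):
        recs = [make_record(1908, "Vanhöffen") for _ in range(5)]
        (career,) = author_careers(recs)
        assert career.lifetime == 1 and career.n_species == 5

    def test_inclusive_lifetime(self):
        recs = [make_record(1814, "Leach"), make_record(1818, "Leach")]
        (career,) = author_careers(recs)
        assert career.lifetime == 5

    def test_one_time_author(self):
        (career,) = author_careers([make_record(1900, "Solo")])
        assert career.lifetime == 1 and career.n_species == 1

    def test_career_totals_match_records(self, small_records):
        records, _, _ = small_records
        careers = author_careers(records)
        assert sum(c.n_species for c in careers) == len(records)
        assert len(careers) == len({r.first_author for r in records})

    def test_lifetime_summary_hand_example(self):
        recs = (
            [make_record(1900, "A")]
            + [make_record(1910, "B")]
            + [make_record(1900, "C"), make_record(1909, "C")]
        )
        out = lifetime_summary(author_careers(recs))
        assert out["mean_lifetime"] == pytest.approx(4.0)  # lifetimes 1, 1, 10
        assert out["share_above_mean"] == pytest.approx(1 / 3)

    def test_all_equal_lifetimes_share_zero(self):
        recs = [make_record(1900, "A"), make_record(1900, "B")]
        assert lifetime_summary(author_careers(recs))["share_above_mean"] == 0.0

    def test_exclusions_compose(self):
        recs = [
            make_record(1900, "Old"), make_record(1905, "Old"),
            make_record(2015, "New"), make_record(2020, "New"),
            make_record(1950, "OneTimer"),
        ]
        careers = author_careers(recs)
        out = lifetime_summary(
            careers, exclude_one_time=True, exclude_started_after=2010
        )
        assert out["n_authors"] == 1  # only "Old" survives both filters
        with pytest.raises(ValueError):
            lifetime_summary(careers, exclude_authors=["Old", "New", "OneTimer"])


class TestDecadeSummaries:
    def test_multi_author_proportion(self):
        recs = [make_record(2010 + i % 10, f"A{i}", n_authors=1) for i in range(3)]
        recs += [make_record(2010 + i % 10, f"B{i}", n_authors=3) for i in range(7)]
        (decade,) = decade_summaries(recs)
        assert decade.decade == "2010s"
        assert decade.n_single_author == 3 and decade.n_multi_author == 7
        assert decade.prop_multi_author == pytest.approx(0.7)

    def test_one_time_author_is_a_global_property(self):
        # "Busy" describes in two decades, so their 1950s description is not
        # a one-time contribution; "Solo" is a true one-time author.
        recs = [
            make_record(1950, "Busy"), make_record(1962, "Busy"),
            make_record(1955, "Solo"),
        ]
        decades = {d.decade: d for d in decade_summaries(recs)}
        assert decades["1950s"].n_one_time_author_descriptions == 1
        assert decades["1960s"].n_one_time_author_descriptions == 0

    def test_empty_decade_is_all_zero(self):
        recs = [make_record(1900), make_record(1920)]
        decades = {d.decade: d for d in decade_summaries(recs)}
        d = decades["1910s"]
        assert d.n_descriptions == 0 and d.prop_multi_author == 0.0

    def test_single_and_multi_partition(self, small_records):
        records, _, _ = small_records
        for d in decade_summaries(records):
            assert d.n_single_author + d.n_multi_author == d.n_descriptions


class TestProlificRanking:
    def test_combined_share(self):
        # 21 authors above the threshold jointly describing 4619 of 10687
        recs = []
        year = 1900
        for i in range(21):
            recs += [make_record(year, f"Top{i:02d}") for _ in range(219)]
        recs += [make_record(year, f"Rest{i}") for i in range(10687 - 21 * 219)]
        out = prolific_ranking(author_careers(recs), threshold=100)
        assert len(out["authors"]) == 21
        assert out["combined_species"] == 4599
        assert round(out["share_of_total"] * 100) == 43

    def test_threshold_above_max_gives_empty(self):
        recs = [make_record(1900, "A"), make_record(1900, "B")]
        out = prolific_ranking(author_careers(recs), threshold=5)
        assert out["authors"] == [] and out["share_of_total"] == 0.0

    def test_single_author_describes_everything(self):
        recs = [make_record(1900, "Only") for _ in range(4)]
        out = prolific_ranking(author_careers(recs), threshold=1)
        assert out["share_of_total"] == pytest.approx(1.0)

    def test_ranking_is_descending(self, small_records):
        records, _, _ = small_records
        out = prolific_ranking(author_careers(records), threshold=10)
        sizes = [c.n_species for c in out["authors"]]
        assert sizes == sorted(sizes, reverse=True)
        assert all(s > 10 for s in sizes)


class TestFamilyCompletion:
    def _family(self):
        # 10 species: 4 described by 1900, all by 1950
        years = [1850, 1860, 1880, 1900, 1910, 1920, 1930, 1940, 1945, 1950]
        return [make_record(y, family="Sphaeromatidae", genus=f"G{i % 3}")
                for i, y in enumerate(years)]

    def test_percentage_by_checkpoint(self):
        table = family_completion_table(self._family(), checkpoint_years=[1900])
        assert table.loc[0, "pct_by_1900"] == 40
        assert table.loc[0, "n_species"] == 10
        assert table.loc[0, "n_genera"] == 3

    def test_checkpoint_before_first_year_is_zero(self):
        table = family_completion_table(self._family(), checkpoint_years=[1800])
        assert table.loc[0, "pct_by_1800"] == 0

    def test_checkpoint_after_last_year_is_complete(self):
        table = family_completion_table(self._family(), checkpoint_years=[2000])
        assert table.loc[0, "pct_by_2000"] == 100

    def test_completion_is_monotone_in_checkpoint(self, small_records):
        records, _, _ = small_records
        checkpoints = [1900, 1950, 2000]
        table = family_completion_table(records, checkpoint_years=checkpoints)
        cols = [f"pct_by_{y}" for y in checkpoints]
        values = table[cols].to_numpy()
        assert (np.diff(values, axis=1) >= 0).all()
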