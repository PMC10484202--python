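"""Descriptive statistics of description rates and taxonomic effort.

Everything here works on cleaned :class:`~descurve.checklist_io.SpeciesRecord`
sequences: annual and cumulative description counts (optionally per
environment group), moving averages for the trend figures, first-author
activity, species-per-author productivity ratios, publication lifetimes,
decade summaries of sole vs multi-authorship and one-time authors, prolific
author rankings, and family completion tables.

The unit of taxonomic effort throughout is the *first* author of a
description; the publication lifetime of an author is counted inclusively,
so an author whose first and last descriptions fall in the same year has a
lifetime of one year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnualSeries",
    "AuthorCareer",
    "DecadeSummary",
    "annual_counts",
    "moving_average",
    "first_authors_per_year",
    "species_per_author",
    "author_careers",
    "lifetime_summary",
    "decade_summaries",
    "prolific_ranking",
    "family_completion_table",
]


class AnnualSeries:
    """Year-indexed non-negative counts over a contiguous span.

    Missing years inside the span are stored as zeros, so the cumulative
    view is well defined and monotone.
    """

    def __init__(self, counts: dict | pd.Series):
        if isinstance(counts, pd.Series):
            counts = counts.to_dict()
        if not counts:
            self.series = pd.Series(dtype=int)
            return
        years = sorted(int(y) for y in counts)
        full = range(years[0], years[-1] + 1)
        values = [int(counts.get(y, 0)) for y in full]
        if any(v < 0 for v in values):
            raise ValueError("annual counts must be non-negative")
        self.series = pd.Series(values, index=pd.Index(full, name="year"))

    def __len__(self) -> int:
        return len(self.series)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnualSeries) and self.series.equals(other.series)

    @property
    def first_year(self) -> int:
        return int(self.series.index[0])

    @property
    def last_year(self) -> int:
        return int(self.series.index[-1])

    @property
    def total(self) -> int:
        return int(self.series.sum())

    def cumulative(self) -> pd.Series:
        return self.series.cumsum()

    def to_frame(self, value_name: str = "count") -> pd.DataFrame:
        return self.series.rename(value_name).reset_index()

    def __repr__(self) -> str:  # pragma: no cover
        if len(self.series) == 0:
            return "AnnualSeries(empty)"
        return (
            f"AnnualSeries({self.first_year}-{self.last_year}, "
            f"total={self.total})"
        )


@dataclass(frozen=True)
class AuthorCareer:
    author: str
    first_year: int
    last_year: int
    lifetime: int
    n_species: int


@dataclass(frozen=True)
class DecadeSummary:
    decade: str
    start_year: int
    n_descriptions: int
    n_single_author: int
    n_multi_author: int
    n_one_time_author_descriptions: int
    prop_single_author: float
    prop_multi_author: float
    prop_one_time_author: float


def _filtered(records, group_filter: Optional[str]):
    if group_filter is None:
        return list(records)
    if group_filter in {"marine", "freshwater", "terrestrial"}:
        return [r for r in records if r.group == group_filter]
    if group_filter == "parasitic":
        return [r for r in records if r.is_parasitic]
    if group_filter == "subterranean":
        return [r for r in records if r.is_subterranean]
    raise ValueError(f"unknown group filter {group_filter!r}")


def annual_counts(records, group_filter: Optional[str] = None) -> AnnualSeries:
    """Number of species described per calendar year (zero-filled span).

    ``group_filter`` may be an environment group (``marine``, ``freshwater``,
    ``terrestrial``) or one of the subgroups ``parasitic`` / ``subterranean``.
    """
    recs = _filtered(records, group_filter)
    counts: dict = {}
    for r in recs:
        counts[r.year] = counts.get(r.year, 0) + 1
    return AnnualSeries(counts)


def moving_average(series: AnnualSeries, window: int) -> pd.Series:
    """Centered moving average with symmetric shrinkage at the edges.

    At position ``i`` the mean is taken over ``i ± h`` with
    ``h = min((window - 1) // 2, i, n - 1 - i)``, so the window shrinks
    symmetrically near the ends and ``window=1`` is the identity. Even
    windows use the same radius as the next-lower odd window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(series)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    values = series.series.to_numpy(dtype=float)
    radius = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        h = min(radius, i, n - 1 - i)
        out[i] = values[i - h: i + h + 1].mean()
    return pd.Series(out, index=series.series.index, name="moving_average")


def first_authors_per_year(records) -> AnnualSeries:
    """Distinct first authors with at least one description in each year."""
    per_year: dict = {}
    for r in records:
        per_year.setdefault(r.year, set()).add(r.first_author)
    return AnnualSeries({y: len(a) for y, a in per_year.items()})


def species_per_author(records) -> pd.Series:
    """Average number of species described per active author, by year.

    The denominator is the number of distinct first authors active in that
    same year. Years inside the span with no descriptions (hence no active
    authors) carry NaN as an undefined marker; callers decide whether to
    exclude them.
    """
    species = annual_counts(records)
    authors = first_authors_per_year(records)
    ratio = species.series / authors.series.replace(0, np.nan)
    return ratio.rename("species_per_author")


def author_careers(records) -> list:
    """One career per distinct first author (inclusive lifetime)."""
    first: dict = {}
    last: dict = {}
    count: dict = {}
    for r in records:
        a = r.first_author
        first[a] = min(first.get(a, r.year), r.year)
        last[a] = max(last.get(a, r.year), r.year)
        count[a] = count.get(a, 0) + 1
    return [
        AuthorCareer(
            author=a,
            first_year=first[a],
            last_year=last[a],
            lifetime=last[a] - first[a] + 1,
            n_species=count[a],
        )
        for a in sorted(first)
    ]


def lifetime_summary(
    careers: Sequence[AuthorCareer],
    exclude_one_time: bool = False,
    exclude_started_after: Optional[int] = None,
    exclude_authors: Iterable[str] = (),
) -> dict:
    """Mean publication lifetime and the share of authors above the mean.

    Exclusion filters compose: drop one-time authors (a single species),
    drop authors whose first description is after a cutoff year (their
    careers may still be open), and drop named authors.
    """
    excluded_names = set(exclude_authors)
    kept = [
        c for c in careers
        if not (exclude_one_time and c.n_species == 1)
        and not (exclude_started_after is not None
                 and c.first_year > exclude_started_after)
        and c.author not in excluded_names
    ]
    if not kept:
        raise ValueError("no careers left after exclusions")
    lifetimes = np.array([c.lifetime for c in kept], dtype=float)
    mean = float(lifetimes.mean())
    share_above = float((lifetimes > mean).mean())
    return {
        "n_authors": len(kept),
        "mean_lifetime": mean,
        "share_above_mean": share_above,
    }


def decade_summaries(records) -> list:
    """Sole vs multi-authored descriptions and one-time-author output per decade.

    Decades are calendar decades (``"1910s"`` = 1910-1919). One-time-author
    status is global: an author counts as one-time if they described exactly
    one species in the whole dataset, and that single description is charged
    to the decade it falls in.
    """
    records = list(records)
    if not records:
        return []
    careers = author_careers(records)
    one_timers = {c.author for c in careers if c.n_species == 1}
    first_decade = (min(r.year for r in records) // 10) * 10
    last_decade = (max(r.year for r in records) // 10) * 10
    out = []
    for start in range(first_decade, last_decade + 1, 10):
        decade_recs = [r for r in records if start <= r.year <= start + 9]
        n = len(decade_recs)
        n_single = sum(1 for r in decade_recs if r.n_authors == 1)
        n_multi = n - n_single
        n_ot = sum(1 for r in decade_recs if r.first_author in one_timers)
        out.append(
            DecadeSummary(
                decade=f"{start}s",
                start_year=start,
                n_descriptions=n,
                n_single_author=n_single,
                n_multi_author=n_multi,
                n_one_time_author_descriptions=n_ot,
                prop_single_author=n_single / n if n else 0.0,
                prop_multi_author=n_multi / n if n else 0.0,
                prop_one_time_author=n_ot / n if n else 0.0,
            )
        )
    return out


def prolific_ranking(
    careers: Sequence[AuthorCareer], threshold: int = 100
) -> dict:
    """Authors with more than ``threshold`` first-author species.

    Returns the ranking (descending by output) and their combined share of
    the total species count.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    total = sum(c.n_species for c in careers)
    top = sorted(
        (c for c in careers if c.n_species > threshold),
        key=lambda c: (-c.n_species, c.author),
    )
    combined = sum(c.n_species for c in top)
    return {
        "authors": top,
        "combined_species": combined,
        "share_of_total": combined / total if total else 0.0,
    }


def family_completion_table(
    records, checkpoint_years: Sequence[int] = (1850, 1900, 1950, 2000)
) -> pd.DataFrame:
    """Per-family discovery summary with completion percentages.

    For each family: number of genera and species, first and last
    description year, and for every checkpoint the percentage of the
    family's species described by that year (rounded to an integer).
    Families are ranked by species count (descending).
    """
    df = pd.DataFrame(
        {
            "family": [r.family for r in records],
            "genus": [r.genus for r in records],
            "year": [r.year for r in records],
        }
    )
    if df.empty:
        cols = ["family", "n_genera", "n_species", "first_year", "last_year"]
        cols += [f"pct_by_{y}" for y in checkpoint_years]
        return pd.DataFrame(columns=cols)
    g = df.groupby("family")
    out = pd.DataFrame(
        {
            "n_genera": g["genus"].nunique(),
            "n_species": g["year"].size(),
            "first_year": g["year"].min(),
            "last_year": g["year"].max(),
        }
    )
    for y in checkpoint_years:
        pct = g["year"].apply(lambda s, y=y: (s <= y).mean() * 100)
        out[f"pct_by_{y}"] = pct.round().astype(int)
    out = out.sort_values(
        ["n_species", "family"], ascending=[False, True]
    ).reset_index()
    return out
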