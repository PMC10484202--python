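import numpy as np
import pandas as pd
import pytest

from descurve.checklist_io import RawChecklistRow, SpeciesRecord
from descurve.synthetic_data import SyntheticConfig, build_checklist


def make_record(
    year,
    first_author="Leach",
    group="marine",
    n_authors=1,
    family="Cirolanidae",
    genus="Cirolana",
    parasitic=False,
    subterranean=False,
    species_id=None,
):
    coauthors = tuple(f"Coauthor{i}" for i in range(n_authors - 1))
    return SpeciesRecord(
        species_id=species_id or f"sp-{year}-{first_author}-{len(coauthors)}",
        canonical_name=f"{genus} testsp",
        genus=genus,
        family=family,
        first_author=first_author,
        all_authors=(first_author,) + coauthors,
        n_authors=n_authors,
        year=year,
        group=group,
        is_parasitic=parasitic,
        is_subterranean=subterranean,
    )


def make_raw_row(
    name="Cirolana alpha",
    authority="Leach, 1814",
    status="accepted",
    rank="Species",
    fossil=False,
    flags=("marine",),
    genus="Cirolana",
    family="Cirolanidae",
):
    return RawChecklistRow(
        scientific_name=name,
        authority_raw=authority,
        status=status,
        rank=rank,
        is_fossil=fossil,
        genus=genus,
        family=family,
        environment_flags=frozenset(flags),
        is_parasitic=False,
        is_subterranean=False,
    )


@pytest.fixture
def six_row_checklist():
    """1 fossil, 1 subspecies-rank, 1 unaccepted, 3 valid rows."""
    return [
        make_raw_row(name="Valid one"),
        make_raw_row(name="Fossil one", fossil=True),
        make_raw_row(name="Subspecies one", rank="Subspecies"),
        make_raw_row(name="Synonym one", status="unaccepted"),
        make_raw_row(name="Valid two", authority="(Wägele, 1981)", flags=("freshwater",)),
        make_raw_row(name="Valid three", authority="Nierstrasz & Brender à Brandis, 1923"),
    ]


# scaled-down generator conditions, reused by several test modules
SMALL_CONFIG = dict(
    N_total=1600.0,
    alpha=1950.0,
    beta=0.05,
    kappa=1.5,
    start_year=1850,
    end_year=2023,
    author_pool_size=1500,
)


@pytest.fixture(scope="session")
def small_checklist():
    config = SyntheticConfig(seed=11, misspelling_rate=0.02, **SMALL_CONFIG)
    frame, truth = build_checklist(config)
    return frame, truth


@pytest.fixture(scope="session")
def small_records(small_checklist, tmp_path_factory):
    from descurve.checklist_io import clean_checklist

    frame, truth = small_checklist
    path = tmp_path_factory.mktemp("chk") / "checklist.csv"
    frame.to_csv(path, index=False)
    records, drop_log = clean_checklist(path, variants=truth.variant_map)
    return records, drop_log, truth
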