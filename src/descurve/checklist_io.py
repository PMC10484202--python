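"""Reading and cleaning taxonomic checklists.

A checklist export (one row per name, in the dialect of a WoRMS download)
is turned into a set of clean :class:`SpeciesRecord` objects by

1. keeping only accepted, extant, species-rank names,
2. parsing the taxonomic authority string into authors and year,
3. canonicalizing author surnames against a user-supplied variant map, and
4. assigning each species to a single environment group
   (brackish records are grouped with the marine ones).

Only the first-listed author of a description is used as the unit of
taxonomic effort downstream, so the parse keeps author order.
"""

from __future__ import annotations

import datetime
import json
import re
import unicodedata
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "RawChecklistRow",
    "AuthorityParse",
    "SpeciesRecord",
    "AuthorityParseError",
    "GroupAssignmentError",
    "parse_authority",
    "canonicalize_authors",
    "apply_inclusion_filters",
    "assign_group",
    "clean_checklist",
    "read_checklist",
    "read_variant_map",
    "validate_variant_map",
    "format_authority",
    "records_to_frame",
    "write_clean_checklist",
    "suggest_variant_candidates",
]

#: Columns a checklist CSV is expected to carry (values are the defaults;
#: a YAML/CLI column mapping may rename any of them).
DEFAULT_COLUMNS = {
    "scientific_name": "scientific_name",
    "authority": "authority",
    "status": "status",
    "rank": "rank",
    "is_fossil": "is_fossil",
    "genus": "genus",
    "family": "family",
    "marine": "marine",
    "brackish": "brackish",
    "freshwater": "freshwater",
    "terrestrial": "terrestrial",
    "is_parasitic": "is_parasitic",
    "is_subterranean": "is_subterranean",
}

ENVIRONMENTS = ("marine", "brackish", "freshwater", "terrestrial")

FIRST_VALID_YEAR = 1758  # Systema Naturae, 10th edition


class AuthorityParseError(ValueError):
    """Raised when an authority string cannot be parsed."""


class GroupAssignmentError(ValueError):
    """Raised when a record carries no environment flag at all."""


@dataclass(frozen=True)
class RawChecklistRow:
    """One row of a raw checklist export, prior to any cleaning."""

    scientific_name: str
    authority_raw: str
    status: str
    rank: str
    is_fossil: bool
    genus: str
    family: str
    environment_flags: frozenset
    is_parasitic: bool
    is_subterranean: bool


@dataclass(frozen=True)
class AuthorityParse:
    """Parsed taxonomic authority: ordered authors, year, recombination flag."""

    authors: tuple
    year: int
    parenthesized: bool

    @property
    def first_author(self) -> str:
        return self.authors[0]


@dataclass(frozen=True)
class SpeciesRecord:
    """A cleaned checklist row ready for the effort / discovery analyses."""

    species_id: str
    canonical_name: str
    genus: str
    family: str
    first_author: str
    all_authors: tuple
    n_authors: int
    year: int
    group: str
    is_parasitic: bool
    is_subterranean: bool


_YEAR_RE = re.compile(r"(?<!\d)(\d{4})(?!\d)")
# delimiters between author names; ' in ' marks the publication author(s),
# the describing author(s) come before it
_IN_RE = re.compile(r"\s+in\s+", flags=re.IGNORECASE)
_SPLIT_RE = re.compile(r"\s*(?:,|&|\bet\b|\band\b)\s*")


def _current_year() -> int:
    return datetime.date.today().year


def parse_authority(authority_raw: str) -> AuthorityParse:
    """Parse an authority string such as ``"(Leach, 1814)"``.

    Parentheses wrapping the whole string mark a later recombination and are
    recorded, not discarded. Author names are split on ``","``, ``"&"`` and
    ``"and"``; diacritics and multi-part surnames with particles are kept
    intact. ``"A in B, 1900"`` attributes the name to the describing
    author(s) before ``in``. The trailing 4-digit token is the year; if
    several 4-digit tokens occur the last is used and a warning is emitted.
    """
    if authority_raw is None:
        raise AuthorityParseError("authority string is missing")
    text = str(authority_raw).strip()
    if not text:
        raise AuthorityParseError("authority string is empty")

    parenthesized = text.startswith("(") and text.endswith(")")
    if parenthesized:
        text = text[1:-1].strip()

    years = _YEAR_RE.findall(text)
    if not years:
        raise AuthorityParseError(
            f"no 4-digit year token in authority {authority_raw!r}"
        )
    if len(years) > 1:
        warnings.warn(
            f"multiple year tokens in authority {authority_raw!r}; using the last",
            stacklevel=2,
        )
    year = int(years[-1])
    if not (FIRST_VALID_YEAR <= year <= _current_year()):
        raise AuthorityParseError(
            f"year {year} out of range in authority {authority_raw!r}"
        )

    # strip the year token (last occurrence) from the author part
    idx = text.rfind(years[-1])
    author_part = text[:idx] + text[idx + 4:]
    # honour "in"-authorship: keep only the describing author(s)
    author_part = _IN_RE.split(author_part)[0]
    tokens = [t.strip() for t in _SPLIT_RE.split(author_part)]
    authors = tuple(t for t in tokens if any(ch.isalpha() for ch in t))
    if not authors:
        raise AuthorityParseError(
            f"no author name found in authority {authority_raw!r}"
        )
    return AuthorityParse(authors=authors, year=year, parenthesized=parenthesized)


def validate_variant_map(variants: Mapping[str, str]) -> None:
    """Check a surname variant map is idempotent.

    Every canonical value must map to itself if it appears as a key;
    a canonical value that is itself remapped elsewhere is an error.
    """
    for variant, canonical in variants.items():
        if canonical in variants and variants[canonical] != canonical:
            raise ValueError(
                f"variant map is not idempotent: {variant!r} -> {canonical!r} "
                f"but {canonical!r} -> {variants[canonical]!r}"
            )


def canonicalize_authors(
    parse: AuthorityParse, variants: Mapping[str, str]
) -> AuthorityParse:
    """Replace every surname by its canonical spelling.

    Unmapped names pass through unchanged; applying the map twice changes
    nothing (the map is required to be idempotent).
    """
    validate_variant_map(variants)
    authors = tuple(variants.get(a, a) for a in parse.authors)
    if authors == parse.authors:
        return parse
    return AuthorityParse(
        authors=authors, year=parse.year, parenthesized=parse.parenthesized
    )


def assign_group(environment_flags: Iterable[str], name: str = "") -> str:
    """Collapse environment flags to one group: marine, freshwater or terrestrial.

    Brackish is grouped with marine. When several groups are flagged the
    precedence marine > freshwater > terrestrial applies (with a warning);
    a record with no flags at all is an error.
    """
    flags = set(environment_flags)
    unknown = flags - set(ENVIRONMENTS)
    if unknown:
        raise GroupAssignmentError(
            f"unknown environment flags {sorted(unknown)} on record {name!r}"
        )
    if not flags:
        raise GroupAssignmentError(f"record {name!r} has no environment flag")
    groups = set()
    if flags & {"marine", "brackish"}:
        groups.add("marine")
    if "freshwater" in flags:
        groups.add("freshwater")
    if "terrestrial" in flags:
        groups.add("terrestrial")
    if len(groups) > 1:
        warnings.warn(
            f"record {name!r} flagged for {sorted(groups)}; "
            "using precedence marine > freshwater > terrestrial",
            stacklevel=2,
        )
    for g in ("marine", "freshwater", "terrestrial"):
        if g in groups:
            return g
    raise GroupAssignmentError(f"record {name!r} has no usable environment flag")


def apply_inclusion_filters(
    rows: Sequence[RawChecklistRow],
    variants: Optional[Mapping[str, str]] = None,
) -> tuple:
    """Keep accepted, extant, species-rank rows and build SpeciesRecords.

    Returns ``(records, drop_log)`` where ``drop_log`` counts dropped rows
    per reason (``status``, ``rank``, ``fossil``, ``authority``, ``group``).
    Reasons are checked in that order and a row is charged to the first
    failing one.
    """
    variants = variants or {}
    validate_variant_map(variants)
    records = []
    drop_log: dict = {}

    def _drop(reason: str) -> None:
        drop_log[reason] = drop_log.get(reason, 0) + 1

    for i, row in enumerate(rows):
        if str(row.status).strip().lower() != "accepted":
            _drop("status")
            continue
        if str(row.rank).strip().lower() != "species":
            _drop("rank")
            continue
        if row.is_fossil:
            _drop("fossil")
            continue
        try:
            parse = parse_authority(row.authority_raw)
        except AuthorityParseError:
            _drop("authority")
            continue
        parse = canonicalize_authors(parse, variants)
        try:
            group = assign_group(row.environment_flags, name=row.scientific_name)
        except GroupAssignmentError:
            _drop("group")
            continue
        records.append(
            SpeciesRecord(
                species_id=f"sp{i:06d}",
                canonical_name=row.scientific_name,
                genus=row.genus,
                family=row.family,
                first_author=parse.first_author,
                all_authors=parse.authors,
                n_authors=len(parse.authors),
                year=parse.year,
                group=group,
                is_parasitic=bool(row.is_parasitic),
                is_subterranean=bool(row.is_subterranean),
            )
        )
    return records, drop_log


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "t", "1", "yes", "y"}
    if pd.isna(value):
        return False
    return bool(value)


def read_checklist(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list:
    """Read a raw checklist CSV into :class:`RawChecklistRow` objects.

    ``column_map`` maps the logical names in :data:`DEFAULT_COLUMNS` to the
    actual column headers of the file.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"checklist is missing required column(s): {missing}")
    rows = []
    for _, r in df.iterrows():
        flags = frozenset(
            env for env in ENVIRONMENTS if _as_bool(r[cols[env]])
        )
        rows.append(
            RawChecklistRow(
                scientific_name=r[cols["scientific_name"]],
                authority_raw=r[cols["authority"]],
                status=r[cols["status"]],
                rank=r[cols["rank"]],
                is_fossil=_as_bool(r[cols["is_fossil"]]),
                genus=r[cols["genus"]],
                family=r[cols["family"]],
                environment_flags=flags,
                is_parasitic=_as_bool(r[cols["is_parasitic"]]),
                is_subterranean=_as_bool(r[cols["is_subterranean"]]),
            )
        )
    return rows


def read_variant_map(path) -> dict:
    """Read a two-column CSV ``variant,canonical`` into a validated map."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("variant map CSV needs columns: variant, canonical")
    variants = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    validate_variant_map(variants)
    return variants


def format_authority(authors: Sequence[str], year: int, parenthesized: bool = False) -> str:
    """Render an authority string: ``"A, B & C, 1923"`` (optionally in parens)."""
    authors = list(authors)
    if len(authors) == 1:
        core = f"{authors[0]}, {year}"
    else:
        core = f"{', '.join(authors[:-1])} & {authors[-1]}, {year}"
    return f"({core})" if parenthesized else core


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Tabulate SpeciesRecords.

    The frame carries both the derived columns (first author, year, group,
    authors joined by ``" | "``) and the raw checklist dialect (authority,
    status, rank, environment flags), so a cleaned CSV is itself a valid
    checklist and cleaning is idempotent.
    """
    out = []
    for r in records:
        d = asdict(r)
        d["all_authors"] = " | ".join(r.all_authors)
        d["scientific_name"] = r.canonical_name
        d["authority"] = format_authority(r.all_authors, r.year)
        d["status"] = "accepted"
        d["rank"] = "Species"
        d["is_fossil"] = False
        for env in ENVIRONMENTS:
            d[env] = env == r.group
        out.append(d)
    columns = [
        "species_id", "scientific_name", "canonical_name", "authority",
        "status", "rank", "is_fossil", "genus", "family", "first_author",
        "all_authors", "n_authors", "year", "group",
        "marine", "brackish", "freshwater", "terrestrial",
        "is_parasitic", "is_subterranean",
    ]
    return pd.DataFrame(out, columns=columns)


def write_clean_checklist(records, drop_log, csv_path, droplog_path=None) -> None:
    records_to_frame(records).to_csv(csv_path, index=False)
    if droplog_path is not None:
        with open(droplog_path, "w", encoding="utf-8") as fh:
            json.dump(drop_log, fh, indent=2, sort_keys=True)


def clean_checklist(
    path,
    variants: Optional[Mapping[str, str]] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple:
    """Read, filter, parse and canonicalize a checklist CSV in one call."""
    rows = read_checklist(path, column_map=column_map)
    return apply_inclusion_filters(rows, variants=variants)


# ---------------------------------------------------------------------------
# Near-duplicate surname report (never auto-applied)
# ---------------------------------------------------------------------------

def _strip_accents(s: str) -> str:
    return "".join(
        ch for ch in unicodedata.normalize("NFKD", s)
        if not unicodedata.combining(ch)
    )


def _levenshtein(a: str, b: str, cap: int) -> int:
    # small banded DP; strings here are surnames (tens of characters)
    if abs(len(a) - len(b)) > cap:
        return cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        best = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            best = min(best, cur[j])
        if best > cap:
            return cap + 1
        prev = cur
    return prev[-1]


def suggest_variant_candidates(
    names: Iterable[str], max_distance: int = 2
) -> list:
    """Report pairs of author names within ``max_distance`` edits.

    Accent-insensitive (``Wägele`` vs ``Waegele`` style pairs are caught by
    comparing accent-stripped forms too). This is a report for a human to
    turn into a variant map; nothing is applied automatically.
    """
    uniq = sorted(set(names))
    pairs = []
    folded = {n: _strip_accents(n).lower() for n in uniq}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            d = _levenshtein(folded[a], folded[b], max_distance)
            if d <= max_distance:
                pairs.append((a, b, d))
    return pairs
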