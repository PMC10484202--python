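"""Seeded synthetic checklists with known ground truth.

The generator emulates the salient features of a real taxonomic checklist
export: a logistic discovery trajectory realized through the renewal count
model, an author population with heavy-tailed (truncated power-law)
productivity and bounded, contiguous careers, a logistic rise of
multi-authored descriptions over time, environment/parasitic/subterranean
composition, and optional injected surname misspellings together with the
true variant map for round-trip testing.

Defaults are set to the study conditions of the isopod checklist the
package is built around: ~10,400 realized species over 1758-2023 out of an
asymptote of 11,000, peak description rate near 1960, marine /
terrestrial / freshwater shares of roughly 58/36/6%, ~14% parasitic and
~9% subterranean species, and a productivity law under which a few percent
of authors contribute around 40% of all descriptions.

Everything is driven by a single integer seed; the same seed reproduces the
checklist byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .checklist_io import format_authority
from .effort_stats import AnnualSeries
from .nhrp_model import LogisticParams, _annual_means, simulate_counts

__all__ = [
    "SyntheticConfig",
    "TruthBundle",
    "simulate_description_years",
    "assign_authors",
    "inject_variants",
    "build_checklist",
]


@dataclass
class SyntheticConfig:
    """Full generative truth for a synthetic checklist."""

    # discovery truth
    N_total: float = 11000.0
    alpha: float = 1960.0
    beta: float = 0.045
    kappa: float = 1.5
    start_year: int = 1758
    end_year: int = 2023
    # author model
    author_pool_size: int = 4000
    productivity_exponent: float = 1.6
    productivity_cap: int = 400
    career_length_mean: float = 15.5
    multi_author_midpoint: float = 2004.0
    multi_author_steepness: float = 0.12
    multi_author_max_proportion: float = 0.97
    # composition (defaults follow the marine/freshwater/terrestrial,
    # parasitic and subterranean shares of the real checklist)
    group_proportions: dict = field(
        default_factory=lambda: {
            "marine": 6151 / 10687,
            "freshwater": 696 / 10687,
            "terrestrial": 3840 / 10687,
        }
    )
    parasitic_proportion: float = 1486 / 10687
    subterranean_proportion: float = 994 / 10687
    misspelling_rate: float = 0.0
    n_families: int = 25
    seed: int = 0

    def __post_init__(self):
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        for name in ("parasitic_proportion", "subterranean_proportion",
                     "misspelling_rate", "multi_author_max_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def logistic_params(self) -> LogisticParams:
        return LogisticParams(self.N_total, self.alpha, self.beta)

    def productivity_pmf(self) -> np.ndarray:
        """Truncated power-law pmf over species-per-author k = 1..cap."""
        k = np.arange(1, self.productivity_cap + 1, dtype=float)
        w = k ** (-self.productivity_exponent)
        return w / w.sum()

    @property
    def one_time_target(self) -> float:
        """Configured probability that an author describes exactly one species."""
        return float(self.productivity_pmf()[0])

    def multi_author_probability(self, year) -> np.ndarray:
        """Probability that a description in ``year`` is multi-authored."""
        year = np.asarray(year, dtype=float)
        z = self.multi_author_steepness * (year - self.multi_author_midpoint)
        return self.multi_author_max_proportion / (1.0 + np.exp(-z))


@dataclass
class TruthBundle:
    """The configuration plus everything realized during generation."""

    config: SyntheticConfig
    annual_counts: dict
    careers: dict  # author -> {first_year, last_year, n_species}
    variant_map: dict  # injected misspelling -> canonical surname

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "annual_counts": {str(k): v for k, v in self.annual_counts.items()},
            "careers": self.careers,
            "variant_map": self.variant_map,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def simulate_description_years(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> AnnualSeries:
    """Draw yearly description counts from the renewal model truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    years = np.arange(config.start_year, config.end_year + 1, dtype=float)
    mus = _annual_means(years, config.logistic_params)
    counts = simulate_counts(mus, config.kappa, rng)
    return AnnualSeries(dict(zip(years.astype(int), counts.tolist())))


# ---------------------------------------------------------------------------
# Names
# ---------------------------------------------------------------------------

_SYLLABLES = [
    "ba", "bel", "cor", "dan", "dor", "fer", "gal", "gar", "hol", "jan",
    "kov", "lan", "mar", "mor", "nov", "ol", "pet", "ras", "ric", "san",
    "sch", "ser", "tor", "vak", "ver", "wag", "wil", "zan", "zim", "bro",
]
_ENDINGS = ["sen", "son", "ski", "mann", "er", "etti", "ez", "ini", "ov", "sz"]
_DIACRITIC_SWAPS = {"a": "ä", "o": "ö", "u": "ü", "e": "é"}
_PARTICLES = ["van ", "de ", "van der ", "di "]


def _make_surname(rng: np.random.Generator) -> str:
    parts = [rng.choice(_SYLLABLES) for _ in range(rng.integers(1, 3))]
    name = "".join(parts) + rng.choice(_ENDINGS)
    name = name.capitalize()
    r = rng.random()
    if r < 0.06:  # occasional diacritic
        for plain, marked in _DIACRITIC_SWAPS.items():
            if plain in name[1:]:
                i = name.index(plain, 1)
                name = name[:i] + marked + name[i + 1:]
                break
    elif r < 0.10:  # particle surname
        name = rng.choice(_PARTICLES) + name
    elif r < 0.14:  # initials to distinguish homonymous surnames
        initials = f"{chr(rng.integers(65, 91))}.{chr(rng.integers(65, 91))}."
        name = f"{initials} {name}"
    return name


def _surname_pool(rng: np.random.Generator, n: int) -> list:
    pool: list = []
    seen = set()
    while len(pool) < n:
        name = _make_surname(rng)
        if name not in seen:
            seen.add(name)
            pool.append(name)
    return pool


def _latin_word(rng: np.random.Generator) -> str:
    syl = ["a", "bo", "ca", "do", "el", "fu", "gi", "lo", "mi", "nu",
           "pa", "ra", "si", "to", "ve"]
    return "".join(rng.choice(syl) for _ in range(rng.integers(2, 5)))


# ---------------------------------------------------------------------------
# Author assignment
# ---------------------------------------------------------------------------

def assign_authors(
    series: AnnualSeries,
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Attribute every description in ``series`` to a first author.

    Authors are created on demand: each gets a productivity drawn from the
    truncated power law and a contiguous career window whose anchor year is
    sampled in proportion to remaining description intensity, then claims
    slots inside (or, when the window is too tight, adjacent to) the
    window. Multi-authorship is decided per description from the logistic
    trend. The result is one row per description with columns
    ``year, first_author, all_authors, n_authors``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    years = series.series.index.to_numpy()
    unassigned = series.series.to_numpy().astype(int).copy()
    total = int(unassigned.sum())
    pool = _surname_pool(rng, config.author_pool_size)
    pmf = config.productivity_pmf()
    ks = np.arange(1, config.productivity_cap + 1)

    assignments = []  # (year, author)
    author_idx = 0
    while total > 0:
        if author_idx >= len(pool):
            raise RuntimeError(
                "author pool exhausted; increase author_pool_size"
            )
        author = pool[author_idx]
        author_idx += 1
        k = int(min(rng.choice(ks, p=pmf), total))
        if k == 1:
            length = 1
        else:
            length = max(2, int(round(rng.exponential(config.career_length_mean))))
        # anchor in proportion to what is still to be described
        anchor = int(rng.choice(len(years), p=unassigned / unassigned.sum()))
        end = min(anchor + length - 1, len(years) - 1)
        window = np.arange(anchor, end + 1)
        avail = unassigned[window].copy()
        take = int(min(k, avail.sum()))
        picks = np.zeros(len(window), dtype=int)
        if take > 0:
            # anchor the career at the window's first and last open years so
            # the realized lifetime tracks the drawn career length
            open_idx = np.flatnonzero(avail)
            picks[open_idx[0]] += 1
            avail[open_idx[0]] -= 1
            if take > 1 and avail[open_idx[-1]] > 0 and open_idx[-1] != open_idx[0]:
                picks[open_idx[-1]] += 1
                avail[open_idx[-1]] -= 1
            # spread the rest across the window, weighted by open slots
            while picks.sum() < take:
                j = int(rng.choice(len(window), p=avail / avail.sum()))
                picks[j] += 1
                avail[j] -= 1
        for j in np.flatnonzero(picks):
            yr = int(years[window[j]])
            assignments.extend([(yr, author)] * int(picks[j]))
        unassigned[window] -= picks
        taken = take
        # window exhausted before k descriptions: grow forward, then backward
        i = end + 1
        while taken < k and i < len(years):
            grab = min(k - taken, unassigned[i])
            assignments.extend([(int(years[i]), author)] * grab)
            unassigned[i] -= grab
            taken += grab
            i += 1
        i = anchor - 1
        while taken < k and i >= 0:
            grab = min(k - taken, unassigned[i])
            assignments.extend([(int(years[i]), author)] * grab)
            unassigned[i] -= grab
            taken += grab
            i -= 1
        total -= taken

    assignments.sort(key=lambda t: t[0])
    yrs = np.array([a[0] for a in assignments])
    first_authors = [a[1] for a in assignments]

    # multi-authorship trend
    p_multi = config.multi_author_probability(yrs)
    is_multi = rng.random(len(yrs)) < p_multi
    n_authors = np.where(is_multi, 2 + rng.poisson(0.7, size=len(yrs)), 1)
    all_authors = []
    for fa, n in zip(first_authors, n_authors):
        co = []
        while len(co) < n - 1:
            cand = pool[int(rng.integers(0, len(pool)))]
            if cand != fa and cand not in co:
                co.append(cand)
        all_authors.append([fa] + co)

    return pd.DataFrame(
        {
            "year": yrs,
            "first_author": first_authors,
            "all_authors": all_authors,
            "n_authors": n_authors.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# Checklist assembly
# ---------------------------------------------------------------------------

def build_checklist(config: SyntheticConfig):
    """Generate a full synthetic checklist.

    Returns ``(frame, truth)``: a DataFrame in the CSV dialect that
    :mod:`descurve.checklist_io` reads, and the :class:`TruthBundle` with
    the realized annual counts, author careers and (if ``misspelling_rate``
    is positive) the injected variant map.
    """
    rng = np.random.default_rng(config.seed)
    series = simulate_description_years(config, rng)
    authored = assign_authors(series, config, rng)
    n = len(authored)

    # taxonomy scaffolding: families with power-law sizes, genera within
    fam_stems = set()
    while len(fam_stems) < config.n_families:
        fam_stems.add(_latin_word(rng).capitalize())
    families = [f"{s}idae" for s in sorted(fam_stems)]
    fam_w = np.arange(1, config.n_families + 1, dtype=float) ** -1.0
    fam_w /= fam_w.sum()
    genera_per_family = {
        f: max(1, int(rng.integers(1, 9))) for f in families
    }
    genus_names = {
        f: [f"{f[:-4].capitalize()}{_latin_word(rng)}".capitalize()
            for _ in range(genera_per_family[f])]
        for f in families
    }

    fam_idx = rng.choice(config.n_families, size=n, p=fam_w)
    groups = rng.choice(
        list(config.group_proportions),
        size=n,
        p=list(config.group_proportions.values()),
    )
    rows = []
    for i in range(n):
        fam = families[fam_idx[i]]
        genus = genus_names[fam][int(rng.integers(0, len(genus_names[fam])))]
        epithet = f"{_latin_word(rng)}{i}"
        authors = authored.all_authors.iloc[i]
        authority = format_authority(
            authors, int(authored.year.iloc[i]), rng.random() < 0.25
        )
        g = groups[i]
        marine = g == "marine"
        brackish = bool(marine and rng.random() < 0.08)
        if marine and rng.random() < 0.02:
            marine, brackish = False, True  # brackish-only record
        rows.append(
            {
                "scientific_name": f"{genus} {epithet}",
                "authority": authority,
                "status": "accepted",
                "rank": "Species",
                "is_fossil": False,
                "genus": genus,
                "family": fam,
                "marine": marine,
                "brackish": brackish,
                "freshwater": g == "freshwater",
                "terrestrial": g == "terrestrial",
                "is_parasitic": bool(rng.random() < config.parasitic_proportion),
                "is_subterranean": bool(
                    rng.random() < config.subterranean_proportion
                ),
            }
        )
    frame = pd.DataFrame(rows)

    careers: dict = {}
    for year, author in zip(authored.year, authored.first_author):
        c = careers.setdefault(
            author, {"first_year": int(year), "last_year": int(year), "n_species": 0}
        )
        c["first_year"] = min(c["first_year"], int(year))
        c["last_year"] = max(c["last_year"], int(year))
        c["n_species"] += 1

    variant_map: dict = {}
    if config.misspelling_rate > 0:
        frame, variant_map = inject_variants(
            frame, config.misspelling_rate, seed=config.seed + 2
        )

    truth = TruthBundle(
        config=config,
        annual_counts={int(y): int(c) for y, c in series.series.items()},
        careers=careers,
        variant_map=variant_map,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Misspelling injection
# ---------------------------------------------------------------------------

def _perturb(name: str, rng: np.random.Generator) -> str:
    """One small spelling perturbation (diacritic fold, swap, drop, double)."""
    for marked, plain in {"ä": "ae", "ö": "oe", "ü": "ue", "é": "e"}.items():
        if marked in name:
            return name.replace(marked, plain, 1)
    letters = [i for i, ch in enumerate(name) if ch.isalpha()]
    body = [i for i in letters if i > letters[0]] or letters
    move = rng.integers(0, 3)
    i = int(body[int(rng.integers(0, len(body)))])
    if move == 0 and i + 1 < len(name) and name[i + 1].isalpha():
        return name[:i] + name[i + 1] + name[i] + name[i + 2:]
    if move == 1 and len(body) > 2:
        return name[:i] + name[i + 1:]
    return name[:i] + name[i] + name[i:]


def inject_variants(frame: pd.DataFrame, rate: float, seed: int):
    """Misspell the first-author surname on a random fraction of rows.

    Returns the perturbed frame and the true variant map
    (misspelling -> canonical) whose application restores every original
    spelling exactly.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    frame = frame.copy()
    if rate == 0.0:
        return frame, {}
    rng = np.random.default_rng(seed)
    # canonical names present anywhere, to avoid colliding variants
    canonical = set()
    for auth in frame["authority"]:
        stripped = auth.strip("()")
        names = stripped.rsplit(",", 1)[0]
        for token in names.replace("&", ",").split(","):
            token = token.strip()
            if token:
                canonical.add(token)
    variant_map: dict = {}
    by_canonical: dict = {}
    hit = rng.random(len(frame)) < rate
    for i in np.flatnonzero(hit):
        auth = frame.at[frame.index[i], "authority"]
        stripped = auth.strip("()")
        first = stripped.replace("&", ",").split(",")[0].strip()
        if first in by_canonical:
            variant = by_canonical[first]
        else:
            variant = None
            for _ in range(20):
                cand = _perturb(first, rng)
                if cand != first and cand not in canonical and (
                    cand not in variant_map
                ):
                    variant = cand
                    break
            if variant is None:
                continue
            variant_map[variant] = first
            by_canonical[first] = variant
        frame.at[frame.index[i], "authority"] = auth.replace(first, variant, 1)
    return frame, variant_map
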