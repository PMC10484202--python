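# Methods

This note documents the statistical model, the conventions baked into the
descriptive statistics, the synthetic-data generator, and the numerical
choices — the decisions a maintainer or reviewer would want stated rather
than reverse-engineered from code.

## Checklist cleaning

A raw checklist row enters the analysis only if its status is `accepted`,
its rank is `species`, and it is not flagged fossil; every dropped row is
charged to the first failing reason (status, then rank, then fossil, then
unparseable authority, then missing environment flags) in a drop log whose
counts always sum to input − output.

Authority strings are parsed structurally: a fully parenthesized authority
marks a recombination; authors are split on `","`, `"&"` and `"and"`, which
keeps diacritics, hyphens, particles ("van der", "à") and
disambiguating initials ("E.H. Williams") intact; the trailing 4-digit
token is the publication year (several year tokens: the last wins, with a
warning; none: a parse error naming the row). `"A in B, 1900"` credits the
describing author(s) before `in`, matching the nomenclatural first-author
convention. Years are integers — the analysis works at annual grain.

Surname canonicalization is deliberately not automatic: the variant map
(misspelling → canonical spelling) is user-supplied and validated for
idempotence; the package only *reports* candidate near-duplicates (accent-
insensitive Levenshtein distance ≤ 2) for a curator to confirm. Automatic
merging would conflate genuinely distinct authors with similar names.

Environment flags collapse to one group per species: brackish counts as
marine; a multi-flagged record resolves by the precedence
marine > freshwater > terrestrial with a warning. Unique assignment is
required downstream (group counts must partition the total); the precedence
order is a package choice, made once, favouring the habitat that dominates
checklist coverage.

## Effort statistics

The unit of taxonomic effort is the *first* author of a description, a
deliberate lower bound that is robust to the growth of multi-authored
papers. Publication lifetime is inclusive (`last − first + 1`), so an
author who published everything in one year has lifetime 1. One-time-author
status is global — exactly one species in the whole dataset — not
per-decade. Decades are calendar decades ("1910s" = 1910–1919). Moving
averages are centered, with the window shrinking symmetrically at the
series edges (an even window uses the radius of the next-lower odd one);
a trailing variant can be had by shifting the input, but centered is the
default because the series are used for trend reading, not forecasting.
Species-per-author divides each year's descriptions by the number of
distinct first authors *active that same year*; description-free years have
no defined ratio and carry NaN, and the breakpoint regression exposes a
flag for excluding zero/undefined years since both treatments are
defensible.

## Breakpoint regression

The two-segment model is `y = b0 + b1 x + b2 max(0, x − ψ)` — continuous at
the breakpoint ψ by construction, with slopes `b1` and `b1 + b2`. For fixed
ψ the coefficients are linear least squares; ψ itself is profiled: every
interior observed x value with at least three points strictly on each side
is a grid candidate, the best few candidates are refined by golden-section
search between their neighbours, and ties go to the earliest ψ. Because the
basis nests the straight line, the segmented SSE can never exceed the OLS
SSE; an all-constant response is flagged degenerate and returned as a flat
fit with a warning. The test suite checks the optimizer against an exact
per-interval oracle (after projecting out {1, x}, the profiled SSE on each
inter-candidate interval is a rational function of ψ whose stationary point
is available in closed form).

OLS is the textbook closed form with a two-sided t-test on the slope
(n − 2 degrees of freedom, no small-sample corrections); it is
cross-checked against statsmodels in the tests rather than delegated to it,
because the segmented fit needs the same SSE machinery internally.

## The renewal discovery model

The cumulative mean is logistic, `Λ(t) = N / (1 + exp(−β(t − α)))`:
`N` (species) is the asymptotic richness, `α` (calendar year) the year of
the fastest description rate, `β` (per year) the overall rate. The defining
equation is conventionally printed with the cumulative count on the
left-hand side denoted by the same symbol as the year; it is read here as
"species described by year t", and the fit report records that reading.

The renewal structure makes inter-arrival gaps i.i.d. Gamma(κ, κ) in
operational time `u = Λ(t)`. The observation model is this package's
concrete realization: counts are observed in yearly bins and the renewal
clock restarts at each year boundary, which makes yearly counts independent
with pmf `P(K=k) = G(μ; kκ, κ) − G(μ; (k+1)κ, κ)` (G the gamma CDF,
`G(μ; 0, κ) ≡ 1`, `μ = Λ(t+1) − Λ(t)`). The restart discards the carry-over
of a partial inter-arrival interval across New Year's Eve — negligible at
μ ≫ 1 and a second-order effect elsewhere — and buys a closed-form
likelihood in which κ is directly interpretable: κ = 1 is exactly Poisson
(the tests verify equality of the likelihoods to 1e-12), κ > 1
under-dispersed, κ < 1 over-dispersed. Published uses of the model specify
only the mean function; κ and the binned likelihood are labelled as this
artifact's realization.

**Fitting.** Maximum likelihood on the transformed vector
`(η, α, log β, log κ)` with `N = S_obs (1 + e^η)`, which enforces
`N ≥ S_obs` (the asymptote cannot undercut the observed total), `β > 0`,
`κ > 0`. Initial values come from least squares of the logistic against the
cumulative curve with κ = 1; optimization is a derivative-free simplex
start polished by quasi-Newton (tolerances 1e-8). Degenerate inputs (span
< 10 years, fewer than two description years) and non-convergence return an
explicit failure object with diagnostics — never a silently bad fit.

**Uncertainty.** Default is the parametric bootstrap: simulate annual
counts from the fitted model, refit, keep the parameter vector; the fast
mode draws from a multivariate normal on the transformed scale using the
inverse observed information (finite-difference Hessian, eigenvalue-floored
if needed). Draw counts are controlled by the caller; the bootstrap is the
honest default because N is near a boundary when the curve is still rising.

**Prediction.** Additional species by a horizon year are simulated: each
replicate picks a parameter draw, simulates every future yearly count from
the renewal pmf, and accumulates; the per-replicate total is capped at
`N − S_obs` for that draw (the remaining pool — renewal counts are formally
unbounded, the species pool is not). Reported are the median and the
central interval at the requested level; everything is reproducible from an
explicit integer seed, and seeds are mandatory in the CLI (no clock seeds).

## Synthetic-data generator

The generator exists so that every pipeline stage, and above all the model
fit, can be tested against known truth. Its defaults are the study
conditions the package was built around, fixed once:

| parameter | default | meaning |
|---|---|---|
| `N_total, alpha, beta, kappa` | 11000, 1960, 0.045/yr, 1.5 | discovery truth: ~10,400 species realized over 1758–2023 |
| `start_year, end_year` | 1758, 2023 | observation window |
| `productivity_exponent, cap` | 1.6, 400 | truncated power law of species per author: ~45% one-time authors, ~2–4% of authors contributing ~40–45% of species |
| `career_length_mean` | 15.5 yr | mean career-window length for multi-species authors; with one-year careers for one-time authors and end-of-series clipping this realizes an overall mean publication lifetime ≈ 8.4 years with ~30% of authors above it |
| `multi_author_*` | midpoint 2004, steepness 0.12/yr, max 0.97 | logistic rise of multi-authored descriptions: ~75% in the 2010s, ~85–90% in the early 2020s |
| `group_proportions` | 0.576 / 0.065 / 0.359 | marine / freshwater / terrestrial shares |
| `parasitic, subterranean` | 0.139, 0.093 | independent Bernoulli flags |
| `misspelling_rate` | 0 (0.02 in the acceptance run) | fraction of rows with a perturbed first-author surname; the true variant map is returned |

Yearly counts are drawn from the renewal pmf itself (arrival-time
simulation). Authors are created on demand: productivity from the truncated
power law, a contiguous career window anchored at a year drawn in
proportion to remaining description intensity, descriptions spread across
the window (first and last open years claimed first so the realized
lifetime tracks the drawn window length). Multi-authorship is decided per
description from the logistic trend; coauthors are drawn from the surname
pool. Misspelling injection perturbs the first author's surname (diacritic
folding, adjacent swap, deletion, doubling) while guaranteeing no collision
with a real name, and returns the exact variant map so the
canonicalization round trip is testable.

What the generator does **not** emulate: synonymy and taxonomic revisions,
shelf-life delays between collection and description, gaps inside careers
(lifetimes depend only on endpoints, so nothing testable is lost),
correlation between parasitism/subterranean habit and environment, and any
effort covariate driving the description rate. Passing tests therefore
demonstrate correctness of the computations and internal consistency of the
model on data that *obey* the model; they do not validate the logistic
assumption against a real checklist.

## Scales used in the checks

The test suite fits the model on full-length series (266 years, ~10⁴
events) where a fit takes well under a second; interval-coverage checks run
200 replicates with 100 asymptotic draws and 500 prediction simulations
each, and parameter-recovery checks use 100 bootstrap refits. The
acceptance script runs one full pipeline (10⁴-row checklist, bootstrap
B = 100, 2,000 prediction simulations per horizon). These sizes were chosen
as the smallest at which the Monte-Carlo error is comfortably below the
tolerances being asserted.

## Known limitations

- The year-boundary renewal restart slightly understates inter-year
  dependence for very small μ; at the default conditions μ < 1 occurs only
  in the first decades, where counts are near zero anyway.
- The asymptotic-draws mode can understate uncertainty for N when the
  observed curve has not begun to flatten; use the bootstrap there.
- The breakpoint search assumes a single break; series with two regime
  changes will return the dominant one.
- Authority parsing targets the common checklist dialects; free-text
  authorities with embedded commas inside surnames would need a custom
  variant map.
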