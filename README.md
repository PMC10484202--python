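# descurve

Discovery-curve analysis for taxonomic checklists: how fast are new species
being described, how much taxonomic effort is behind that rate, and how many
species are still waiting for a name?

The package is built for analyses of checklist exports (one row per
scientific name with its authority string, taxonomic status, rank and
habitat flags, in the dialect of a WoRMS download). It was developed around
the global isopod (Crustacea: Peracarida) checklist, but nothing in it is
specific to isopods. It provides, as an importable library plus a thin CLI:

- **`checklist_io`** — inclusion filtering (accepted, extant, species-rank
  names only), authority-string parsing (`"(Leach, 1814)"` → first author,
  all authors, year, recombination flag), surname canonicalization against a
  user-supplied variant map, and a single environment group per species
  (brackish is grouped with marine).
- **`effort_stats`** — annual/cumulative description counts by group, moving
  averages, first authors active per year, species described per author per
  year, publication lifetimes (inclusive: a one-year career has lifetime 1),
  sole- vs multi-authorship per decade, one-time authors, prolific-author
  rankings, and family completion tables.
- **`regression`** — closed-form OLS with a slope t-test, and continuous
  two-segment (breakpoint) regression via SSE profiling with golden-section
  refinement, used to date the change in species-per-author productivity.
- **`nhrp_model`** — the inference core: a non-homogeneous renewal process
  with logistic cumulative mean, fitted to annual counts by maximum
  likelihood, with parametric-bootstrap (or asymptotic) uncertainty and
  simulation-based prediction intervals for future descriptions.
- **`synthetic_data`** — a seeded checklist generator with known ground
  truth (logistic discovery trajectory, heavy-tailed author productivity,
  bounded careers, rising multi-authorship, injected misspellings), so the
  whole pipeline is testable end to end without any download.

## The model

Let `Λ(t)` be the expected cumulative number of species described by year
`t`. The discovery curve is logistic,

```
Λ(t) = N / (1 + exp(−β (t − α)))
```

with `N` the total number of species that will ever be described (the
richness estimate), `α` the calendar year of the fastest description rate,
and `β` (per year) the overall rate of description — larger `β`, steeper
curve. Descriptions form a renewal process in operational time `u = Λ(t)`:
inter-arrival gaps are i.i.d. Gamma(κ, κ) (mean 1), so the yearly count in
`[t, t+1)` has the closed-form distribution

```
P(K = k) = G(μ_t; kκ, κ) − G(μ_t; (k+1)κ, κ),   μ_t = Λ(t+1) − Λ(t),
```

where `G` is the gamma CDF (shape, rate). `κ = 1` recovers the
non-homogeneous Poisson process exactly; `κ > 1` is under-dispersed,
`κ < 1` over-dispersed. All four parameters `(N, α, β, κ)` are estimated by
maximum likelihood; predictions of species still to be described by a
horizon year are medians and central intervals over simulated future yearly
counts, propagating parameter uncertainty through bootstrap draws.

## Worked example

```python
from descurve import (SyntheticConfig, fit_nhrp, predict_additional,
                      simulate_description_years)

truth = SyntheticConfig(seed=7)   # N=11000, alpha=1960, beta=0.045, kappa=1.5
series = simulate_description_years(truth)
fit = fit_nhrp(series, n_draws=100, draws_method="bootstrap", seed=1)
print(fit.params, fit.kappa)
for horizon in (2050, 2100):
    print(predict_additional(fit, horizon, level=0.95, n_sims=2000, seed=2))
```

prints (`examples/04_fit_and_predict.py`):

```
observed: 10444 species over 1758-2023
fitted: N=11070 species, peak year alpha=1960.1, rate beta=0.0453/yr, dispersion kappa=1.59
still undescribed under the fit: 626
additional species by 2050: 400 (95% interval 357-438)
additional species by 2100: 546 (95% interval 467-593)
```

That is: from 266 years of simulated annual counts the fit recovers the
generating asymptote within ~0.6%, dates the peak of description correctly,
and puts ~400 further species by 2050 and ~550 by 2100 — the gap between
what has been described (10,444) and the estimated total (11,070) closing
slowly as the curve flattens. Each `examples/*.py` script is a similar
short, narrative walk through one capability (cleaning, effort trends,
breakpoint dating, pipeline recovery).

The same operations are available from the shell:

```
descurve simulate --seed 5 --outdir run/
descurve clean run/synthetic_checklist.csv --outdir run/
descurve stats run/clean_checklist.csv --outdir run/
descurve predict run/series.csv --seed 1 --horizons 2050,2100 --outdir run/
```

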