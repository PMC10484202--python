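"""Fit the renewal discovery model and predict future descriptions.

Fits the non-homogeneous renewal process with logistic cumulative mean to
an annual description series by maximum likelihood, then simulates forward
to put a median and 95% interval on the number of species still to be
described by 2050 and 2100.
"""

from descurve import (
    SyntheticConfig,
    fit_nhrp,
    predict_additional,
    simulate_description_years,
)

# annual counts realized from a known logistic truth
truth = SyntheticConfig(seed=7)  # N=11000, alpha=1960, beta=0.045, kappa=1.5
series = simulate_description_years(truth)
print(f"observed: {series.total} species over "
      f"{series.first_year}-{series.last_year}")

fit = fit_nhrp(series, n_draws=100, draws_method="bootstrap", seed=1)
p = fit.params
print(f"fitted: N={p.N_total:.0f} species, peak year alpha={p.alpha:.1f}, "
      f"rate beta={p.beta:.4f}/yr, dispersion kappa={fit.kappa:.2f}")
print(f"still undescribed under the fit: {p.N_total - fit.s_obs:.0f}")

for horizon in (2050, 2100):
    pred = predict_additional(fit, horizon, level=0.95, n_sims=2000, seed=2)
    print(f"additional species by {horizon}: {pred.additional_median:.0f} "
          f"(95% interval {pred.ci_low:.0f}-{pred.ci_high:.0f})")
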