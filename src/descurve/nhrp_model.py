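"""Non-homogeneous renewal process (NHRP) with a logistic mean curve.

Model
-----
The cumulative number of species described by calendar year ``t`` is
modelled by the logistic curve

    Lambda(t) = N / (1 + exp(-beta * (t - alpha)))

where ``N`` is the total number of species that will ever be described,
``alpha`` the year of the maximum description rate and ``beta`` the overall
rate of description (per year; larger beta = faster discovery).

Descriptions form a renewal process on the operational time axis
``u = Lambda(t)``: inter-arrival intervals are i.i.d. gamma with mean 1 and
shape ``kappa`` (rate ``kappa``), so ``kappa = 1`` recovers the
non-homogeneous Poisson process, ``kappa > 1`` is under-dispersed and
``kappa < 1`` over-dispersed relative to Poisson. Observations are yearly
counts; the renewal clock is restarted at each year boundary, which makes
the yearly counts independent with the closed-form distribution of
:func:`count_pmf` and the likelihood a sum over years.

The observation model (yearly gamma-renewal bins with boundary restart) and
the dispersion parameter ``kappa`` are this package's concrete realization
of the NHRP; published uses of the model specify only the logistic mean.
The defining logistic equation is usually printed with the cumulative count
on the left-hand side written as ``t``; it is read here as "species
described by year t" (a year cannot equal a count) and this reading is
recorded in the fit report.

Fitting is by maximum likelihood on the transformed parameter vector
``(eta, alpha, log beta, log kappa)`` with ``N = S_obs * (1 + exp(eta))``,
which enforces ``N >= S_obs`` (the asymptote cannot undercut what has been
observed), ``beta > 0`` and ``kappa > 0``. Uncertainty is by parametric
bootstrap (simulate from the fitted model and refit) or, as a fast mode,
multivariate-normal draws on the transformed scale from the inverse
observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess1

from .effort_stats import AnnualSeries

__all__ = [
    "LogisticParams",
    "NHRPFit",
    "FitFailure",
    "PredictionResult",
    "logistic_mean",
    "count_pmf",
    "simulate_counts",
    "nhrp_loglik",
    "fit_nhrp",
    "predict_additional",
]

EQUATION_NOTE = (
    "logistic mean read as cumulative species described by year t: "
    "Lambda(t) = N / (1 + exp(-beta*(t - alpha)))"
)


@dataclass(frozen=True)
class LogisticParams:
    """Logistic discovery-curve parameters.

    N_total : asymptotic number of species (must cover what was observed)
    alpha   : calendar year of the maximum description rate
    beta    : overall description rate, per year (> 0)
    """

    N_total: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.N_total > 0 and np.isfinite(self.N_total)):
            raise ValueError("N_total must be a positive finite number")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError("beta must be positive")


@dataclass
class NHRPFit:
    params: LogisticParams
    kappa: float
    loglik: float
    converged: bool
    s_obs: int
    last_year: int
    first_year: int
    param_draws: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    draws_method: Optional[str] = None
    message: str = ""
    equation_note: str = EQUATION_NOTE

    def report(self) -> dict:
        """JSON-serializable fit summary."""
        out = {
            "N_total": self.params.N_total,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "kappa": self.kappa,
            "loglik": self.loglik,
            "converged": self.converged,
            "s_obs": self.s_obs,
            "first_year": self.first_year,
            "last_year": self.last_year,
            "n_param_draws": int(len(self.param_draws)),
            "draws_method": self.draws_method,
            "equation_note": self.equation_note,
        }
        if len(self.param_draws):
            se = self.param_draws.std(axis=0, ddof=1)
            out["se"] = dict(zip(["N_total", "alpha", "beta", "kappa"], se.tolist()))
        return out


@dataclass(frozen=True)
class FitFailure:
    """Explicit non-convergence / non-identifiability marker."""

    message: str
    diagnostics: dict


@dataclass(frozen=True)
class PredictionResult:
    target_year: int
    additional_median: float
    ci_low: float
    ci_high: float
    level: float
    n_sims: int
    seed: int


def logistic_mean(t, params: LogisticParams):
    """Expected cumulative described species by year ``t`` (vectorized)."""
    t = np.asarray(t, dtype=float)
    out = params.N_total * special.expit(params.beta * (t - params.alpha))
    return out if out.ndim else float(out)


def _annual_means(years: np.ndarray, params: LogisticParams) -> np.ndarray:
    """Expected count in year t = Lambda(t+1) - Lambda(t)."""
    return logistic_mean(years + 1.0, params) - logistic_mean(years, params)


def count_pmf(k, mu: float, kappa: float):
    """P(K = k) for the count of gamma-renewal arrivals in operational length mu.

    Inter-arrival intervals are gamma with shape ``kappa`` and rate ``kappa``
    (mean 1), so ``P(K = k) = G(mu; k*kappa, kappa) - G(mu; (k+1)*kappa, kappa)``
    with ``G`` the gamma distribution function and ``G(mu; 0, kappa) = 1``.
    ``kappa = 1`` gives exactly the Poisson(mu) pmf.
    """
    if not (np.isfinite(mu) and mu > 0):
        raise ValueError("mu must be positive and finite")
    if not (np.isfinite(kappa) and kappa > 0):
        raise ValueError("kappa must be positive and finite")
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("k must be non-negative integers")
    k = k.astype(float)
    x = kappa * mu
    # G(mu; k*kappa, kappa) = gammainc(k*kappa, kappa*mu); shape 0 -> 1.
    lower_k = np.where(k > 0, special.gammainc(np.maximum(k, 1e-300) * kappa, x), 1.0)
    lower_k1 = special.gammainc((k + 1.0) * kappa, x)
    diff = lower_k - lower_k1
    # when both CDFs are near 1 the complement form is better conditioned
    upper = special.gammaincc((k + 1.0) * kappa, x) - np.where(
        k > 0, special.gammaincc(np.maximum(k, 1e-300) * kappa, x), 0.0
    )
    out = np.where(lower_k1 > 0.5, upper, diff)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def simulate_counts(
    mus: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one count per operational length in ``mus`` (renewal restart each bin).

    Arrival times are cumulative sums of gamma(kappa, rate=kappa) intervals;
    the count is the number of arrivals not exceeding the bin length.
    """
    mus = np.asarray(mus, dtype=float)
    counts = np.zeros(mus.shape, dtype=int)
    positive = mus > 0
    if not positive.any():
        return counts
    mpos = mus[positive]
    # enough arrivals to exceed the bin with overwhelming probability
    kmax = int(np.ceil(mpos.max() + 8.0 * np.sqrt(mpos.max() / kappa + 1.0) + 20))
    gaps = rng.gamma(shape=kappa, scale=1.0 / kappa, size=(mpos.size, kmax))
    arrivals = np.cumsum(gaps, axis=1)
    counts[positive] = (arrivals <= mpos[:, None]).sum(axis=1)
    return counts


def nhrp_loglik(series: AnnualSeries, params: LogisticParams, kappa: float) -> float:
    """Log likelihood of yearly counts under the renewal model."""
    years = series.series.index.to_numpy(dtype=float)
    counts = series.series.to_numpy(dtype=float)
    mus = _annual_means(years, params)
    if np.any(mus <= 0):
        raise ValueError("non-positive annual mean; invalid parameters")
    p = _pmf_vector(counts, mus, kappa)
    return float(np.sum(np.log(np.maximum(p, 1e-300))))


def _pmf_vector(k: np.ndarray, mus: np.ndarray, kappa: float) -> np.ndarray:
    """count_pmf with a different mu per entry (vectorized over years)."""
    k = np.asarray(k, dtype=float)
    x = kappa * mus
    lower_k = np.where(k > 0, special.gammainc(np.maximum(k, 1e-300) * kappa, x), 1.0)
    lower_k1 = special.gammainc((k + 1.0) * kappa, x)
    upper = special.gammaincc((k + 1.0) * kappa, x) - np.where(
        k > 0, special.gammaincc(np.maximum(k, 1e-300) * kappa, x), 0.0
    )
    return np.clip(np.where(lower_k1 > 0.5, upper, lower_k - lower_k1), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, s_obs: float) -> tuple:
    eta, alpha, log_beta, log_kappa = theta
    N = s_obs * (1.0 + np.exp(eta))
    return LogisticParams(N_total=N, alpha=alpha, beta=np.exp(log_beta)), np.exp(log_kappa)


def _pack(params: LogisticParams, kappa: float, s_obs: float) -> np.ndarray:
    ratio = max(params.N_total / s_obs - 1.0, 1e-8)
    return np.array(
        [np.log(ratio), params.alpha, np.log(params.beta), np.log(kappa)]
    )


def _initial_guess(series: AnnualSeries) -> np.ndarray:
    """Least squares on the cumulative curve, kappa = 1."""
    years = series.series.index.to_numpy(dtype=float)
    cum = series.cumulative().to_numpy(dtype=float)
    s_obs = cum[-1]
    half = s_obs / 2.0
    alpha0 = float(years[np.searchsorted(cum, half)])
    # slope of logit(cum/N) vs t gives beta; crude but only a starting point
    N0 = 1.1 * s_obs

    def resid(p):
        N, a, b = p
        N = max(N, s_obs + 1.0)
        b = abs(b) + 1e-6
        return N * special.expit(b * (years + 1.0 - a)) - cum

    sol = optimize.least_squares(
        resid, x0=[N0, alpha0, 0.05], method="lm", max_nfev=2000
    )
    N, a, b = sol.x
    N = max(N, s_obs * 1.0001)
    b = min(max(abs(b), 1e-4), 2.0)
    return _pack(LogisticParams(N, a, b), 1.0, s_obs)


def fit_nhrp(
    series: AnnualSeries,
    n_draws: int = 200,
    draws_method: str = "bootstrap",
    seed: Optional[int] = None,
    _with_draws: bool = True,
):
    """Maximum-likelihood fit of the renewal model to an annual count series.

    Returns an :class:`NHRPFit`, or a :class:`FitFailure` for degenerate or
    non-convergent inputs (never a silently bad fit). ``draws_method`` is
    ``"bootstrap"`` (parametric bootstrap: simulate from the fitted model,
    refit, ``n_draws`` times) or ``"asymptotic"`` (multivariate-normal draws
    on the transformed scale from the inverse observed information).
    """
    if len(series) < 10:
        return FitFailure(
            message="series spans fewer than 10 years",
            diagnostics={"n_years": len(series)},
        )
    counts = series.series.to_numpy()
    if int((counts > 0).sum()) < 2:
        return FitFailure(
            message="fewer than 2 years with descriptions; "
            "logistic parameters are not identifiable",
            diagnostics={"nonzero_years": int((counts > 0).sum())},
        )
    s_obs = float(counts.sum())
    years = series.series.index.to_numpy(dtype=float)

    def nll(theta):
        if not np.all(np.isfinite(theta)):
            return 1e12
        # eta, log beta and log kappa live on a log-ish scale; alpha is a year
        if abs(theta[0]) > 50 or abs(theta[2]) > 50 or abs(theta[3]) > 50:
            return 1e12
        params, kappa = _unpack(theta, s_obs)
        mus = _annual_means(years, params)
        if np.any(mus <= 0):
            return 1e12
        p = _pmf_vector(counts, mus, kappa)
        return -float(np.sum(np.log(np.maximum(p, 1e-300))))

    try:
        theta0 = _initial_guess(series)
    except Exception as exc:  # pragma: no cover - defensive
        return FitFailure(message=f"initialization failed: {exc}", diagnostics={})

    # derivative-free simplex start, then quasi-Newton polish
    nm = optimize.minimize(
        nll, theta0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8},
    )
    polish = optimize.minimize(nll, nm.x, method="L-BFGS-B")
    best = polish if polish.fun <= nm.fun else nm
    converged = bool((nm.success or polish.success) and np.isfinite(best.fun))
    if not np.isfinite(best.fun) or best.fun >= 1e11:
        return FitFailure(
            message="optimizer did not reach a finite likelihood",
            diagnostics={"nelder_mead": nm.message, "polish": str(polish.message)},
        )

    params, kappa = _unpack(best.x, s_obs)
    fit = NHRPFit(
        params=params,
        kappa=float(kappa),
        loglik=-float(best.fun),
        converged=converged,
        s_obs=int(s_obs),
        last_year=int(years[-1]),
        first_year=int(years[0]),
        message=str(best.message),
    )
    if _with_draws and n_draws > 0:
        fit.param_draws = _parameter_draws(
            fit, series, n_draws, draws_method, seed, nll, best.x
        )
        fit.draws_method = draws_method
    return fit


def _parameter_draws(fit, series, n_draws, method, seed, nll, theta_hat):
    rng = np.random.default_rng(seed)
    if method == "asymptotic":
        hess = approx_hess1(theta_hat, nll)
        # guard a non-PD observed information with eigenvalue flooring
        w, v = np.linalg.eigh((hess + hess.T) / 2.0)
        w = np.maximum(w, 1e-8 * max(w.max(), 1.0))
        cov = (v / w) @ v.T
        thetas = rng.multivariate_normal(theta_hat, cov, size=n_draws)
    elif method == "bootstrap":
        years = series.series.index.to_numpy(dtype=float)
        thetas = []
        attempts = 0
        while len(thetas) < n_draws and attempts < 3 * n_draws:
            attempts += 1
            mus = _annual_means(years, fit.params)
            sim = simulate_counts(mus, fit.kappa, rng)
            refit = fit_nhrp(
                AnnualSeries(dict(zip(years.astype(int), sim))),
                _with_draws=False,
            )
            if isinstance(refit, NHRPFit) and refit.converged:
                thetas.append(
                    [refit.params.N_total, refit.params.alpha,
                     refit.params.beta, refit.kappa]
                )
        if len(thetas) < n_draws:
            warnings.warn(
                f"only {len(thetas)} of {n_draws} bootstrap refits converged",
                stacklevel=2,
            )
        return np.asarray(thetas, dtype=float).reshape(-1, 4)
    else:
        raise ValueError(f"unknown draws_method {method!r}")
    s_obs = float(fit.s_obs)
    thetas = np.asarray(thetas, dtype=float)
    for j in (0, 2, 3):  # transformed-scale coordinates; alpha is a year
        thetas[:, j] = np.clip(thetas[:, j], -50, 50)
    out = np.empty((n_draws, 4))
    for i, th in enumerate(thetas):
        p, kap = _unpack(th, s_obs)
        out[i] = [p.N_total, p.alpha, p.beta, kap]
    return out


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_additional(
    fit: NHRPFit,
    to_year: int,
    level: float = 0.95,
    n_sims: int = 2000,
    seed: Optional[int] = None,
) -> PredictionResult:
    """Simulate additional species described between the fit's last year and
    ``to_year`` and summarize the distribution.

    Each simulation picks one parameter draw (the point estimate when no
    draws are stored), simulates yearly renewal counts for every future
    year, and accumulates; the per-draw total is capped at ``N - S_obs``
    (the remaining pool under that draw). Reported are the median and the
    central ``level`` interval; fixed seeds give identical results.
    """
    if isinstance(fit, FitFailure):
        raise ValueError(f"cannot predict from a failed fit: {fit.message}")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if to_year <= fit.last_year:
        raise ValueError(
            f"to_year must be after the last observed year {fit.last_year}"
        )
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rng = np.random.default_rng(seed)
    future = np.arange(fit.last_year + 1, to_year + 1, dtype=float)

    if len(fit.param_draws):
        draw_idx = rng.integers(0, len(fit.param_draws), size=n_sims)
    else:
        draw_idx = np.full(n_sims, -1)

    totals = np.empty(n_sims)
    for s in range(n_sims):
        if draw_idx[s] >= 0:
            N, a, b, kap = fit.param_draws[draw_idx[s]]
            params = LogisticParams(N_total=float(N), alpha=float(a), beta=float(b))
        else:
            params, kap = fit.params, fit.kappa
        mus = np.maximum(_annual_means(future, params), 0.0)
        sim = simulate_counts(mus, float(kap), rng)
        pool = max(params.N_total - fit.s_obs, 0.0)
        totals[s] = min(float(sim.sum()), pool)

    half = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(totals, [half, 0.5, 1.0 - half])
    return PredictionResult(
        target_year=int(to_year),
        additional_median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        level=float(level),
        n_sims=int(n_sims),
        seed=-1 if seed is None else int(seed),
    )
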