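"""Hierarchical Bayesian fits of clone-count data.

Four fits mirror the study design:

* :func:`fit_ta_mutation_rate` — de novo mutation rate per mitosis from
  transit-amplifying clone counts per tissue block (binomial counts with a
  truncated-Gaussian experimental-error layer and a patient hierarchy);
* :func:`fit_wpc_accumulation` — age-linear accumulation of wholly
  populated crypts, per-patient slopes drawn from a population Gaussian
  (the population mean is Delta C_fix);
* :func:`fit_ppc_plateau` — age-constant partially-populated-crypt
  fraction (the population mean is C_part);
* :func:`fit_patch_multinomial` — crypt fission rate from relative patch
  sizes, chance-doublet corrected.

:func:`infer_n_lambda` then converts the continuous-labelling summaries
plus the mutation rate into the stem-cell number N and replacement rate
lambda, either through the closed-form moment relations
(slope = alpha*lambda, plateau = alpha*N(N-1)/2) or as a grid posterior
over (N, lambda) given per-patient counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from ._mcmc import FitResult, posterior_me, run_ensemble, summarize_chain
from .data import CohortObservation, TABlockCounts, patch_counts
from .drift import continuous_labelling
from .fission import doublet_correction
from .params import CryptDriftParams, MutationSupply

__all__ = [
    "fit_ta_mutation_rate",
    "fit_wpc_accumulation",
    "fit_ppc_plateau",
    "fit_patch_multinomial",
    "infer_n_lambda",
    "n_lambda_from_moments",
    "GridPosterior",
    "posterior_me",
]

_GAMMA_A = 1e-2  # shape and rate of the vague Gamma(1e-2, 1e-2) priors


def _log_gamma_prior(x):
    return (_GAMMA_A - 1.0) * np.log(x) - _GAMMA_A * x


def _log_beta_half(x):
    # Beta(1/2, 1/2) on (0, 1)
    return -0.5 * np.log(x) - 0.5 * np.log1p(-x)


def _binom_logpmf(k, n, p):
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


# ---------------------------------------------------------------------------
# TA-clone mutation rate
# ---------------------------------------------------------------------------

def fit_ta_mutation_rate(
    data: list[TABlockCounts],
    nsteps: int = 4000,
    seed: int = 0,
    nwalkers: int | None = None,
) -> FitResult:
    """Posterior for the de novo mutation rate per mitosis.

    Model: per block ``k ~ Binomial(G, q)`` with ``q ~ Normal(alpha_i,
    sigma_error)`` truncated to [0, 1]; per patient ``alpha_i ~
    Normal(mu_alpha, sigma_alpha)`` truncated to [0, 1]; Beta(1/2, 1/2)
    priors on ``mu_alpha``, ``sigma_alpha`` and ``sigma_error``. The latent
    ``q`` is integrated out by Gauss-Legendre quadrature over the
    (log-concave) product of the binomial and truncated-normal terms.
    """
    if not data:
        raise ValueError("no TA blocks supplied")
    patients = sorted({b.patient for b in data})
    pidx = np.array([patients.index(b.patient) for b in data])
    k = np.array([b.k for b in data], dtype=float)
    G = np.array([b.G for b in data], dtype=float)
    P, B = len(patients), len(data)

    # Gauss-Legendre nodes on [0, 1]
    nodes, weights = np.polynomial.legendre.leggauss(40)
    nodes = 0.5 * (nodes + 1.0)
    weights = 0.5 * weights

    # Gaussian proxy of the binomial-in-q factor, used only to window the
    # quadrature around the log-concave integrand's peak
    m1 = (k + 1.0) / (G + 2.0)
    s1 = np.sqrt(k + 1.0) / G

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu, sig_a, sig_e = theta[:, 0], theta[:, 1], theta[:, 2]
        alphas = theta[:, 3:]  # (W, P)
        lp = np.full(theta.shape[0], -np.inf)
        ok = (
            (mu > 0) & (mu < 1)
            & (sig_a > 0) & (sig_a < 1)
            & (sig_e > 0) & (sig_e < 1)
            & np.all((alphas >= 0) & (alphas <= 1), axis=1)
        )
        if not np.any(ok):
            return lp
        muo, sao, seo = mu[ok], sig_a[ok], sig_e[ok]
        ao = alphas[ok]
        prior = _log_beta_half(muo) + _log_beta_half(sao) + _log_beta_half(seo)
        # alpha_i ~ truncated Normal(mu, sig_a) on [0, 1]
        z = norm.cdf((1.0 - muo) / sao) - norm.cdf(-muo / sao)
        hier = np.sum(
            -0.5 * ((ao - muo[:, None]) / sao[:, None]) ** 2, axis=1
        ) - ao.shape[1] * (np.log(sao) + np.log(z))
        # marginal block likelihoods
        a_blk = ao[:, pidx]  # (w, B)
        se = seo[:, None]
        prec = 1.0 / s1**2 + 1.0 / se**2
        mstar = (m1 / s1**2 + a_blk / se**2) / prec
        sstar = np.sqrt(1.0 / prec)
        lo = np.clip(mstar - 10.0 * sstar, 0.0, 1.0)
        hi = np.clip(mstar + 10.0 * sstar, 0.0, 1.0)
        width = hi - lo
        q = lo[..., None] + width[..., None] * nodes  # (w, B, K)
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = (
                k[:, None] * np.log(q)
                + (G[:, None] - k[:, None]) * np.log1p(-q)
                - 0.5 * ((q - a_blk[..., None]) / se[..., None]) ** 2
                - np.log(se[..., None])
            )
        logf = np.where(np.isfinite(logf), logf, -np.inf)
        ze = norm.cdf((1.0 - a_blk) / se) - norm.cdf(-a_blk / se)
        log_int = (
            logsumexp(logf + np.log(weights), axis=-1)
            + np.log(width)
            - np.log(ze)
            - 0.5 * math.log(2 * math.pi)
        )
        lp[ok] = prior + hier + np.sum(log_int, axis=1)
        return lp

    rng = np.random.default_rng(seed)
    ndim = 3 + P
    nwalkers = nwalkers or max(2 * ndim + 2, 48)
    a_hat = np.zeros(P)
    for i in range(P):
        sel = pidx == i
        a_hat[i] = (k[sel].sum() + 0.5) / G[sel].sum()
    mu0 = a_hat.mean()
    sig0 = max(a_hat.std(), 0.3 * mu0) + 1e-9
    p0 = np.empty((nwalkers, ndim))
    p0[:, 0] = mu0 * rng.lognormal(0, 0.2, nwalkers)
    p0[:, 1] = sig0 * rng.lognormal(0, 0.3, nwalkers)
    p0[:, 2] = sig0 * rng.lognormal(0, 0.3, nwalkers)
    p0[:, 3:] = a_hat * rng.lognormal(0, 0.2, (nwalkers, P))
    names = ["mu_alpha", "sigma_alpha", "sigma_error"] + [
        f"alpha[{p}]" for p in patients
    ]
    chain, acc = run_ensemble(log_prob, p0, nsteps, seed)
    res = summarize_chain(chain, names)
    res.acceptance = acc
    return res


# ---------------------------------------------------------------------------
# WPC / PPC regressions
# ---------------------------------------------------------------------------

def _binomial_hierarchy_fit(
    counts: np.ndarray,
    crypts: np.ndarray,
    ages: np.ndarray,
    with_intercept: bool,
    hyper_names: tuple,
    unit_name: str,
    patients: list,
    nsteps: int,
    seed: int,
    nwalkers: int | None,
) -> FitResult:
    P = len(counts)
    n_hyper = 3 if with_intercept else 2

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu, sig = theta[:, 0], theta[:, 1]
        t0 = theta[:, 2] if with_intercept else np.zeros(theta.shape[0])
        coef = theta[:, n_hyper:]  # (W, P)
        lp = np.full(theta.shape[0], -np.inf)
        p = coef * (ages - t0[:, None]) if with_intercept else coef
        ok = (
            (mu > 0)
            & (sig > 0)
            & np.all((p >= 0) & (p <= 1), axis=1)
        )
        if with_intercept:
            ok &= np.abs(t0) < 60
        if not np.any(ok):
            return lp
        muo, sio, co, po = mu[ok], sig[ok], coef[ok], p[ok]
        prior = _log_gamma_prior(muo) + _log_gamma_prior(sio)
        if with_intercept:
            prior = prior - 0.5 * (t0[ok] / 10.0) ** 2
        hier = (
            np.sum(-0.5 * ((co - muo[:, None]) / sio[:, None]) ** 2, axis=1)
            - P * np.log(sio)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.sum(_binom_logpmf(counts, crypts, po), axis=1)
        ll = np.where(np.isfinite(ll), ll, -np.inf)
        lp[ok] = prior + hier + ll
        return lp

    rng = np.random.default_rng(seed)
    ndim = n_hyper + P
    nwalkers = nwalkers or max(2 * ndim + 2, 48)
    c_hat = (counts + 0.5) / (crypts * np.maximum(ages, 1.0)) if with_intercept else (
        counts + 0.5
    ) / crypts
    mu0 = max(c_hat.mean(), 1e-12)
    sig0 = max(c_hat.std(), 0.3 * mu0) + 1e-12
    p0 = np.empty((nwalkers, ndim))
    p0[:, 0] = mu0 * rng.lognormal(0, 0.2, nwalkers)
    p0[:, 1] = sig0 * rng.lognormal(0, 0.3, nwalkers)
    if with_intercept:
        p0[:, 2] = rng.normal(0, 0.5, nwalkers)
    p0[:, n_hyper:] = c_hat * rng.lognormal(0, 0.2, (nwalkers, P))
    names = list(hyper_names) + [f"{unit_name}[{p}]" for p in patients]
    chain, acc = run_ensemble(log_prob, p0, nsteps, seed)
    res = summarize_chain(chain, names)
    res.acceptance = acc
    return res


def fit_wpc_accumulation(
    data: list[CohortObservation],
    nsteps: int = 4000,
    seed: int = 0,
    nwalkers: int | None = None,
) -> FitResult:
    """Posterior for the WPC accumulation slope Delta C_fix.

    Model: ``wpc_i ~ Binomial(C_i, a_i * (t_i - t0))`` with per-patient
    slopes ``a_i ~ Normal(mu_a, sigma_a)``, vague Gamma(1e-2, 1e-2) priors
    on ``mu_a`` and ``sigma_a`` and ``t0 ~ Normal(0, 10)`` (the age-axis
    intercept may be negative if clones arise during development). The
    population mean ``mu_a`` is Delta C_fix. Probabilities outside [0, 1]
    are excluded by constraint during sampling, not by rejecting the fit.
    """
    if len(data) < 2:
        raise ValueError("need at least two patients")
    return _binomial_hierarchy_fit(
        counts=np.array([o.wpc for o in data], dtype=float),
        crypts=np.array([o.crypts for o in data], dtype=float),
        ages=np.array([o.age for o in data], dtype=float),
        with_intercept=True,
        hyper_names=("mu_a", "sigma_a", "t0"),
        unit_name="a",
        patients=[o.patient for o in data],
        nsteps=nsteps,
        seed=seed,
        nwalkers=nwalkers,
    )


def fit_ppc_plateau(
    data: list[CohortObservation],
    nsteps: int = 4000,
    seed: int = 0,
    nwalkers: int | None = None,
) -> FitResult:
    """Posterior for the PPC plateau C_part.

    Model: ``ppc_i ~ Binomial(C_i, b_i)`` with ``b_i ~ Normal(mu_b,
    sigma_b)`` and Gamma(1e-2, 1e-2) priors; there is no age term, the
    partial fraction being constant in the continuous-labelling steady
    state. The population mean ``mu_b`` is C_part.
    """
    if len(data) < 2:
        raise ValueError("need at least two patients")
    return _binomial_hierarchy_fit(
        counts=np.array([o.ppc for o in data], dtype=float),
        crypts=np.array([o.crypts for o in data], dtype=float),
        ages=np.array([o.age for o in data], dtype=float),
        with_intercept=False,
        hyper_names=("mu_b", "sigma_b"),
        unit_name="b",
        patients=[o.patient for o in data],
        nsteps=nsteps,
        seed=seed,
        nwalkers=nwalkers,
    )


# ---------------------------------------------------------------------------
# patch-size multinomial (crypt fission rate)
# ---------------------------------------------------------------------------

def fit_patch_multinomial(
    data: list[CohortObservation],
    nsteps: int = 4000,
    seed: int = 0,
    nwalkers: int | None = None,
    doublet_corrected: bool = True,
) -> FitResult:
    """Posterior for the crypt fission rate from relative patch sizes.

    Patients with no clones are filtered (the relative distribution carries
    no information about them). Model: per patient the vector of patch
    sizes ``g_i ~ Multinomial(f(rho_i, t_i))`` with
    ``f_n = (1 - e^{-rho t})^n / (rho n t)``, chance-doublet corrected
    (``D`` added to the size-2 class and subtracted from size-1);
    ``rho_i ~ Normal(mu_rho, sigma_rho)`` restricted to positive rates,
    Gamma(1e-2, 1e-2) priors on the population parameters.
    """
    used = [o for o in data if len(o.patch_sizes) >= 1]
    if len(used) < 2:
        raise ValueError("need at least two patients with clones")
    P = len(used)
    ages = np.array([o.age for o in used])
    count_list = [patch_counts(o) for o in used]
    D = np.zeros(P)
    if doublet_corrected:
        for i, o in enumerate(used):
            kclones = len(o.patch_sizes)
            if kclones > 1:
                D[i] = doublet_correction(o.delta, kclones, o.crypts).exact

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu, sig = theta[:, 0], theta[:, 1]
        rho = theta[:, 2:]  # (W, P)
        lp = np.full(theta.shape[0], -np.inf)
        ok = (mu > 0) & (sig > 0) & np.all(rho > 0, axis=1) & np.all(rho < 2, axis=1)
        if not np.any(ok):
            return lp
        muo, sio, ro = mu[ok], sig[ok], rho[ok]
        prior = _log_gamma_prior(muo) + _log_gamma_prior(sio)
        hier = (
            np.sum(-0.5 * ((ro - muo[:, None]) / sio[:, None]) ** 2, axis=1)
            - P * np.log(sio)
        )
        ll = np.zeros(ro.shape[0])
        good = np.ones(ro.shape[0], dtype=bool)
        for i in range(P):
            c = count_list[i]
            n = np.arange(1, c.size + 1)
            q = -np.expm1(-ro[:, i] * ages[i])  # (w,)
            f = q[:, None] ** n / (ro[:, i, None] * n * ages[i])
            f[:, 0] -= D[i]
            if c.size >= 2:
                f[:, 1] += D[i]
            elif D[i] > 0:
                f[:, 0] = f[:, 0]  # no size-2 class observed; correction only on f1
            good &= np.all(f[:, c > 0] > 0, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll += np.where(good, np.nansum(c * np.log(np.clip(f, 1e-300, None)), axis=1), -np.inf)
        lp[ok] = np.where(good, prior + hier + ll, -np.inf)
        return lp

    rng = np.random.default_rng(seed)
    ndim = 2 + P
    nwalkers = nwalkers or max(2 * ndim + 2, 48)
    # crude per-patient moment start: mean patch size 1/(1-q)-ish
    r_hat = np.empty(P)
    for i, o in enumerate(used):
        mean_size = np.mean(o.patch_sizes)
        q0 = min(1.0 - 1.0 / mean_size + 1e-3, 0.95)
        r_hat[i] = max(-math.log(1.0 - q0) / ages[i], 1e-4) if q0 > 0 else 1e-3
    mu0 = float(np.clip(np.mean(r_hat), 1e-4, 0.5))
    sig0 = max(float(np.std(r_hat)), 0.3 * mu0) + 1e-6
    p0 = np.empty((nwalkers, ndim))
    p0[:, 0] = mu0 * rng.lognormal(0, 0.2, nwalkers)
    p0[:, 1] = sig0 * rng.lognormal(0, 0.3, nwalkers)
    p0[:, 2:] = r_hat * rng.lognormal(0, 0.3, (nwalkers, P))
    names = ["mu_rho", "sigma_rho"] + [f"rho[{o.patient}]" for o in used]
    chain, acc = run_ensemble(log_prob, p0, nsteps, seed)
    res = summarize_chain(chain, names)
    res.acceptance = acc
    return res


# ---------------------------------------------------------------------------
# (N, lambda) inference
# ---------------------------------------------------------------------------

def n_lambda_from_moments(
    slope: float, plateau: float, alpha: float
) -> tuple[float, float]:
    """Solve the neutral moment relations for (N, lambda).

    ``slope = alpha * lambda`` and ``plateau = alpha * N(N-1)/2`` give
    ``lambda = slope/alpha`` and the positive root of
    ``N^2 - N - 2*plateau/alpha = 0``. Scaling ``alpha``, ``slope`` and
    ``plateau`` by a common factor leaves the solution unchanged.
    """
    if min(slope, plateau, alpha) <= 0:
        raise ValueError("slope, plateau and alpha must be positive")
    lam = slope / alpha
    nn = 2.0 * plateau / alpha
    n_stem = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * nn))
    return n_stem, lam


@dataclass(frozen=True)
class GridPosterior:
    """Normalized posterior mass over an (N, lambda) grid."""

    n_grid: np.ndarray
    lam_grid: np.ndarray
    mass: np.ndarray  # shape (len(n_grid), len(lam_grid))

    @property
    def mean_n(self) -> float:
        return float(np.sum(self.mass.sum(axis=1) * self.n_grid))

    @property
    def mean_lam(self) -> float:
        return float(np.sum(self.mass.sum(axis=0) * self.lam_grid))

    @property
    def map_estimate(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.mass), self.mass.shape)
        return float(self.n_grid[i]), float(self.lam_grid[j])

    def marginal_ci(self, which: str = "n", level: float = 0.95) -> tuple:
        axis, grid = (1, self.n_grid) if which == "n" else (0, self.lam_grid)
        marg = self.mass.sum(axis=axis)
        cum = np.cumsum(marg)
        lo = grid[np.searchsorted(cum, (1 - level) / 2)]
        hi = grid[min(np.searchsorted(cum, 1 - (1 - level) / 2), len(grid) - 1)]
        return float(lo), float(hi)


def infer_n_lambda(
    data: list[CohortObservation] | None,
    alpha,
    slope: float | None = None,
    plateau: float | None = None,
    n_grid=None,
    lam_grid=None,
) -> GridPosterior:
    """Grid posterior over stem-cell number N and replacement rate lambda.

    With per-patient counts (``data``), the likelihood of each (N, lambda)
    cell is the product of binomial likelihoods of the observed WPC and PPC
    counts under the continuous-labelling closed forms, with the mutation
    rate ``alpha`` integrated over its posterior draws (pass an array) or
    fixed (pass a float). Without counts, point summaries (``slope``,
    ``plateau``) are converted to the same grid through the moment
    relations, giving a sharply peaked mass around the closed-form solution
    (a warning-free fallback for summary-only inputs). Uniform prior over
    the grid; mass normalized to 1.
    """
    n_grid = np.arange(2, 21) if n_grid is None else np.asarray(n_grid)
    lam_grid = (
        np.round(np.arange(0.1, 5.0001, 0.05), 10) if lam_grid is None else np.asarray(lam_grid)
    )
    alphas = np.atleast_1d(np.asarray(alpha, dtype=float))
    logmass = np.full((n_grid.size, lam_grid.size), -np.inf)
    if data is not None:
        ages = np.array([o.age for o in data])
        crypts = np.array([o.crypts for o in data])
        wpc = np.array([o.wpc for o in data])
        ppc = np.array([o.ppc for o in data])
        for i, N in enumerate(n_grid):
            params = CryptDriftParams(int(N), 1.0)
            cp1, cm1 = continuous_labelling(params, MutationSupply(1.0), 1.0)
            for j, lam in enumerate(lam_grid):
                params_l = CryptDriftParams(int(N), float(lam))
                lls = np.empty(alphas.size)
                for s, a in enumerate(alphas):
                    cp, cm = continuous_labelling(
                        params_l, MutationSupply(float(a)), ages
                    )
                    cp = np.clip(cp, 1e-300, 1.0)
                    cm = np.clip(cm, 1e-300, 1.0)
                    lls[s] = np.sum(
                        _binom_logpmf(wpc, crypts, cm) + _binom_logpmf(ppc, crypts, cp)
                    )
                logmass[i, j] = logsumexp(lls) - math.log(alphas.size)
    else:
        if slope is None or plateau is None:
            raise ValueError("need either data or (slope, plateau)")
        # treat the summaries as exact moments: score each cell by how well
        # its implied (slope, plateau) matches, on the log scale
        for i, N in enumerate(n_grid):
            for j, lam in enumerate(lam_grid):
                lls = np.empty(alphas.size)
                for s, a in enumerate(alphas):
                    sl = a * lam
                    pl = a * N * (N - 1) / 2.0
                    lls[s] = -0.5 * (
                        (math.log(sl / slope)) ** 2 + (math.log(pl / plateau)) ** 2
                    ) / 0.05**2
                logmass[i, j] = logsumexp(lls) - math.log(alphas.size)
    logmass -= logmass.max()
    mass = np.exp(logmass)
    mass /= mass.sum()
    if mass.max() > 1 - 1e-9:
        pass  # single-cell mass: grid resolution limits the CI
    return GridPosterior(n_grid=n_grid, lam_grid=lam_grid, mass=mass)
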