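"""Closed-form clone-size dynamics within a colonic crypt.

A mutant clone of stem cells inside one crypt performs a birth-death random
walk on its size ``n`` in ``{0, ..., N}``: at each clone boundary the mutant
lineage replaces a wild-type neighbour at rate ``beta = 2*lam*p_r`` and is
replaced at rate ``gamma = 2*lam*(1-p_r)``; 0 (extinction) and ``N``
(monoclonal conversion, the clone fixed in the crypt) are absorbing. The
transient spectrum of this chain gives finite sine series for the clone-size
distribution, the continuous-labelling clone frequencies (partially and
wholly populated crypt fractions under a constant supply of new mutant
clones), and the fixation-time distribution.

All times are in years; ``lam`` is per stem cell per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .params import CryptDriftParams, MutationSupply

__all__ = [
    "LabelKinetics",
    "clone_size_pmf",
    "monoclonal_probability",
    "continuous_labelling",
    "label_kinetics",
    "fixation_probability",
    "fixation_time_quantiles",
    "mean_fixation_time",
    "conversion_time_quantiles",
]


# ---------------------------------------------------------------------------
# spectral building blocks
# ---------------------------------------------------------------------------

def _spectrum(params: CryptDriftParams) -> tuple[np.ndarray, float, float]:
    """Decay rates ``h_m`` of the transient clone-size chain, plus (beta, gamma).

    ``h_m = 4*sqrt(beta*gamma)*sin^2(pi*m/(2N)) + beta + gamma - 2*sqrt(beta*gamma)``
    for ``m = 1..N-1``; in the neutral case this reduces to
    ``4*lam*sin^2(pi*m/(2N))``.
    """
    N = params.n_stem
    beta, gamma = params.beta, params.gamma
    m = np.arange(1, N)
    root = math.sqrt(beta * gamma)
    h = 4.0 * root * np.sin(np.pi * m / (2 * N)) ** 2 + beta + gamma - 2.0 * root
    return h, beta, gamma


def _k(N: int, n: int) -> np.ndarray:
    """Spectral weights ``k_{m,n} = sin(pi*m/N) * sin(pi*m*n/N)``."""
    m = np.arange(1, N)
    return np.sin(np.pi * m / N) * np.sin(np.pi * m * n / N)


def _generator(params: CryptDriftParams) -> np.ndarray:
    """Full (N+1)-state generator of the clone-size chain, absorbing at 0, N."""
    N = params.n_stem
    Q = np.zeros((N + 1, N + 1))
    for n in range(1, N):
        Q[n, n + 1] = params.beta
        Q[n, n - 1] = params.gamma
        Q[n, n] = -(params.beta + params.gamma)
    return Q


# ---------------------------------------------------------------------------
# clone-size distributions
# ---------------------------------------------------------------------------

def clone_size_pmf(
    params: CryptDriftParams, t: float, method: str = "series"
) -> np.ndarray:
    """Distribution of clone size at time ``t`` for a clone born at size 1.

    Returns a vector ``p`` of length ``N+1``: ``p[0]`` is the extinct mass,
    ``p[N]`` the probability the crypt has become monoclonal, and ``p[n]``
    for ``0 < n < N`` the probability of a partial clone of ``n`` stem cells.

    ``method="series"`` evaluates the finite sine series (the default);
    ``method="expm"`` exponentiates the chain generator directly and serves
    as an independent numerical route. The boundary biases ``p_r in {0, 1}``
    (pure gain / pure loss) have vanishing ``sqrt(beta*gamma)`` terms and are
    always evaluated by the generator route.
    """
    if not math.isfinite(t) or t < 0:
        raise ValueError(f"t must be finite and >= 0, got {t}")
    N = params.n_stem
    if method == "expm" or params.p_r in (0.0, 1.0):
        p0 = np.zeros(N + 1)
        p0[1] = 1.0
        p = p0 @ expm(_generator(params) * t)
    elif method == "series":
        h, beta, gamma = _spectrum(params)
        ratio = beta / gamma
        decay = np.exp(-h * t)
        p = np.zeros(N + 1)
        for n in range(1, N):
            terms = _k(N, n) * decay
            p[n] = (2.0 / N) * ratio ** ((n - 1) / 2.0) * math.fsum(terms)
        terms_N = _k(N, N - 1) / h * (1.0 - decay)
        p[N] = (2.0 * beta / N) * ratio ** ((N - 2) / 2.0) * math.fsum(terms_N)
        p[0] = 1.0 - math.fsum(p[1:])
    else:
        raise ValueError(f"unknown method {method!r}")
    # tiny negative round-off from the alternating series is clamped
    if p.min() < -1e-12:
        raise RuntimeError(f"clone-size pmf lost precision: min {p.min()}")
    return np.clip(p, 0.0, 1.0)


def monoclonal_probability(params: CryptDriftParams, t: np.ndarray) -> np.ndarray:
    """Probability ``P_N(t)`` that a clone born at size 1 has fixed by ``t``."""
    t = np.asarray(t, dtype=float)
    h, beta, gamma = _spectrum(params)
    kN = _k(params.n_stem, params.n_stem - 1)
    pref = (2.0 * beta / params.n_stem) * (beta / gamma) ** ((params.n_stem - 2) / 2.0)
    return pref * np.sum(kN / h * (1.0 - np.exp(-np.multiply.outer(t, h))), axis=-1)


def fixation_probability(params: CryptDriftParams) -> float:
    """Probability a clone born at size 1 eventually fixes.

    ``1/N`` for neutral drift; ``(1 - r) / (1 - r^N)`` with ``r = gamma/beta``
    otherwise (the gambler's-ruin formula of the biased walk).
    """
    N = params.n_stem
    if params.p_r == 0.5:
        return 1.0 / N
    if params.p_r == 0.0:
        return 0.0
    if params.p_r == 1.0:
        return 1.0
    r = params.gamma / params.beta
    return (1.0 - r) / (1.0 - r**N)


# ---------------------------------------------------------------------------
# continuous labelling
# ---------------------------------------------------------------------------

def continuous_labelling(
    params: CryptDriftParams,
    supply: MutationSupply,
    t: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected partially and wholly populated crypt fractions at age ``t``.

    New mutant clones of size one stem cell appear in each crypt as a Poisson
    process at rate ``kappa = alpha*lam*N`` and then drift. Convolving the
    (approximately linear) arrival flux with the clone-size series gives
    closed forms: the wholly-populated fraction grows asymptotically linearly
    with slope ``kappa * P_fix`` and the partial fraction saturates at a
    plateau; for neutral drift these are ``alpha*lam*t`` and
    ``alpha*N*(N-1)/2``.

    Returns ``(c_partial, c_monoclonal)``, arrays broadcast over ``t``.
    The exponential terms all decay, so evaluation is stable at any age.
    """
    if params.p_r in (0.0, 1.0):
        raise ValueError(
            "continuous labelling requires p_r in (0, 1); the pure-gain/"
            "pure-loss boundaries have no partial-clone steady state in the "
            "series form - evaluate nearby p_r instead"
        )
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("ages must be finite and >= 0")
    N = params.n_stem
    h, beta, gamma = _spectrum(params)
    kappa = supply.kappa(params)
    ratio = beta / gamma

    grow = 1.0 - np.exp(-np.multiply.outer(t, h))  # (..., N-1)
    c_part = np.zeros(t.shape)
    for n in range(1, N):
        weights = ratio ** ((n - 1) / 2.0) * _k(N, n) / h
        c_part = c_part + (2.0 * kappa / N) * grow @ weights
    wN = ratio ** ((N - 2) / 2.0) * _k(N, N - 1) / h
    lag = np.multiply.outer(t, np.ones_like(h)) - grow / h
    c_mono = (2.0 * beta * kappa / N) * lag @ wN
    return np.clip(c_part, 0.0, None), np.clip(c_mono, 0.0, None)


@dataclass(frozen=True)
class LabelKinetics:
    """Asymptotic continuous-labelling summary.

    ``slope`` is the yearly gain in wholly-populated crypt fraction
    (Delta C_fix), ``plateau`` the asymptotic partial fraction (C_part),
    ``t0`` the age-axis intercept of the linear regime, and ``ratio`` the
    mutation-rate-independent diagnostic ``slope/plateau`` (per year);
    for neutral drift ``ratio = 2*lam/(N*(N-1))``.
    """

    slope: float
    plateau: float
    t0: float
    ratio: float


def label_kinetics(params: CryptDriftParams, supply: MutationSupply) -> LabelKinetics:
    """Slope, plateau and intercept of the continuous-labelling curves.

    The slope is ``kappa * P_fix`` exactly (arrival rate times fixation
    probability); the plateau and intercept come from the spectral sums.
    Doubling ``alpha`` doubles slope and plateau but leaves ``ratio``
    unchanged.
    """
    if params.p_r in (0.0, 1.0):
        raise ValueError("label kinetics requires p_r in (0, 1)")
    N = params.n_stem
    h, beta, gamma = _spectrum(params)
    kappa = supply.kappa(params)
    ratio_bg = beta / gamma

    slope = kappa * fixation_probability(params)
    plateau = 0.0
    for n in range(1, N):
        plateau += (2.0 * kappa / N) * ratio_bg ** ((n - 1) / 2.0) * math.fsum(
            _k(N, n) / h
        )
    wN = _k(N, N - 1) / h**2
    offset = (2.0 * beta * kappa / N) * ratio_bg ** ((N - 2) / 2.0) * math.fsum(wN)
    t0 = offset / slope if slope > 0 else math.nan
    return LabelKinetics(
        slope=slope,
        plateau=plateau,
        t0=t0,
        ratio=slope / plateau if plateau > 0 else math.inf,
    )


# ---------------------------------------------------------------------------
# fixation / conversion times
# ---------------------------------------------------------------------------

def _conditioned_subgenerator(params: CryptDriftParams) -> np.ndarray:
    """Sub-generator of the chain conditioned on absorption at ``N``.

    Doob h-transform with ``h(n)`` the fixation probability from size ``n``:
    conditioned up rate ``beta*h(n+1)/h(n)``, down rate ``gamma*h(n-1)/h(n)``
    (zero from size 1, since ``h(0)=0``). The absorption time at ``N`` of
    this chain from size 1 is the fixation time conditional on fixation,
    a phase-type distribution computed by linear algebra, not simulation.
    """
    N = params.n_stem
    if params.p_r == 0.0:
        raise ValueError("p_r=0 never fixes; conditional fixation time undefined")
    if params.p_r == 0.5:
        hvec = np.arange(N + 1) / N
    else:
        r = params.gamma / params.beta
        hvec = (1.0 - r ** np.arange(N + 1)) / (1.0 - r**N)
    T = np.zeros((N - 1, N - 1))
    for i, n in enumerate(range(1, N)):
        up = params.beta * hvec[n + 1] / hvec[n]
        down = params.gamma * hvec[n - 1] / hvec[n] if n > 1 else 0.0
        if n < N - 1:
            T[i, i + 1] = up
        if n > 1:
            T[i, i - 1] = down
        T[i, i] = -(up + down)
    return T


def mean_fixation_time(params: CryptDriftParams) -> float:
    """Mean time to monoclonal conversion, conditional on fixation.

    For neutral drift this equals ``(N^2 - 1) / (6 * lam)`` (the embedded
    symmetric walk takes ``(N^2-1)/3`` steps on average, each of mean
    duration ``1/(2*lam)``).
    """
    T = _conditioned_subgenerator(params)
    return float(-np.linalg.solve(T, np.ones(T.shape[0]))[0])


def fixation_time_quantiles(
    params: CryptDriftParams, quantiles
) -> np.ndarray:
    """Quantiles (years) of the conditional fixation-time distribution.

    The clone starts at one stem cell; times are conditional on reaching
    size ``N``. Quantiles are found by root-finding on the exact phase-type
    CDF ``1 - 1' expm(T t)`` of the conditioned chain.
    """
    qs = np.atleast_1d(np.asarray(quantiles, dtype=float))
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("quantiles must lie strictly in (0, 1)")
    T = _conditioned_subgenerator(params)

    def cdf(t: float) -> float:
        return 1.0 - expm(T * t)[0, :].sum()

    mean = -np.linalg.solve(T, np.ones(T.shape[0]))[0]
    out = np.empty_like(qs)
    for i, q in enumerate(qs):
        hi = mean
        while cdf(hi) < q:
            hi *= 2.0
        out[i] = brentq(lambda t: cdf(t) - q, 1e-12, hi)
    return out


def conversion_time_quantiles(
    params: CryptDriftParams, fractions
) -> np.ndarray:
    """Times (years) by which a given fraction of *surviving* clones are fixed.

    Among clones still present at age ``t`` (not extinct), the monoclonal
    fraction is ``P_N(t) / sum_{n>=1} P_n(t)``; this returns the ages at
    which that fraction crosses each requested value. This is the observable
    conversion statistic of a birth cohort of clones: the fraction of visible
    clones scored as wholly rather than partially populated. It differs from
    :func:`fixation_time_quantiles` (which conditions on eventual fixation,
    not on survival to ``t``) and is the quantity behind cohort-level
    "time to monoclonal conversion" summaries.
    """
    qs = np.atleast_1d(np.asarray(fractions, dtype=float))
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("fractions must lie strictly in (0, 1)")

    def frac_converted(t: float) -> float:
        p = clone_size_pmf(params, t)
        surv = p[1:].sum()
        return p[-1] / surv if surv > 0 else 1.0

    out = np.empty_like(qs)
    mean = mean_fixation_time(params)
    for i, q in enumerate(qs):
        hi = mean
        while frac_converted(hi) < q:
            hi *= 2.0
        out[i] = brentq(lambda t: frac_converted(t) - q, 1e-9, hi)
    return out
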