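"""Crypt-fission patch sizes, mutation burden and lifetime expansion.

Once a mutant clone has fixed in a crypt, the crypt can divide (fission) at
rate ``rho`` per crypt per year, expanding the clone into a patch of
neighbouring mutant crypts. Fission is modelled as a Yule-Furry pure-birth
process; convolving it with the linear accumulation of newly fixed clones
(slope ``Delta C_fix``) yields the cohort patch-size distribution, the
mutant burden per million crypts, and a mutation-rate-free relative
expansion coefficient for comparing marks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import comb

from .drift import fixation_probability, monoclonal_probability
from .params import CryptDriftParams, FissionParams, MutationSupply

__all__ = [
    "yule_patch_pmf",
    "cohort_patch_distribution",
    "cohort_patch_distribution_exact",
    "relative_patch_distribution",
    "doublet_correction",
    "DoubletCorrection",
    "burden",
    "BurdenResult",
    "expansion_coefficient",
]

_TINY_RHO = 1e-12


def yule_patch_pmf(fp: FissionParams, t: float, n) -> np.ndarray:
    """Probability a patch of initial size ``n0`` has ``n`` crypts at time ``t``.

    Pure-birth (Yule-Furry) law:
    ``C(n-1, n-n0) * exp(-rho*n0*t) * (1 - exp(-rho*t))^(n-n0)``.
    For ``n0 = 1`` this is geometric with success ``exp(-rho*t)`` and mean
    ``exp(rho*t)``. Sizes below ``n0`` have probability zero.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    n = np.atleast_1d(np.asarray(n))
    if np.any(n != np.floor(n)) or np.any(n < 1):
        raise ValueError("patch sizes must be integers >= 1")
    n = n.astype(int)
    n0, rho = fp.n0, fp.rho
    out = np.zeros(n.shape, dtype=float)
    ok = n >= n0
    if rho * t < _TINY_RHO:
        out[ok & (n == n0)] = 1.0
        return out
    q = -np.expm1(-rho * t)  # 1 - e^{-rho t}
    nn = n[ok]
    out[ok] = comb(nn - 1, nn - n0) * np.exp(-rho * n0 * t) * q ** (nn - n0)
    return out


def cohort_patch_distribution(
    slope: float, fp: FissionParams, t: float, n_max: int | None = None
) -> np.ndarray:
    """Expected patch-size frequencies ``F_n(t)`` per crypt, ``n = 1..n_max``.

    Fixed clones appear at rate ``slope`` (Delta C_fix) per crypt per year
    and then grow by fission, giving
    ``F_n(t) = slope * (1 - exp(-rho*t))^n / (rho * n)``
    (the exponential transient of the monoclonal curve is negligible and
    ignored, consistent with how the burden and patch fits use it).
    Requires ``n0 = 1``. Index 0 of the returned array is ``F_1``.
    """
    if fp.n0 != 1:
        raise ValueError("cohort patch distribution requires n0 = 1")
    if slope < 0:
        raise ValueError("slope must be >= 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    if n_max is None:
        n_max = _default_n_max(fp.rho, t)
    n = np.arange(1, n_max + 1)
    if t == 0 or slope == 0:
        return np.zeros(n_max)
    if fp.rho * t < _TINY_RHO:
        out = np.zeros(n_max)
        out[0] = slope * t
        return out
    q = -np.expm1(-fp.rho * t)
    return slope * q**n / (fp.rho * n)


def cohort_patch_distribution_exact(
    params: CryptDriftParams,
    supply: MutationSupply,
    fp: FissionParams,
    t: float,
    n_max: int = 12,
) -> np.ndarray:
    """Patch-size frequencies including the intra-crypt fixation transient.

    Clones seeded at rate ``kappa = alpha*lam*N`` per crypt fix with the
    time-dependent probability ``P_N``, so the rate of new fixation events
    at time ``u`` is ``kappa * P_N(u)`` and each patch then grows by Yule
    fission for the remaining ``t - u`` years:
    ``F_n(t) = integral_0^t kappa * P_N(u) * Yule(n; t-u) du``.
    :func:`cohort_patch_distribution` is the ``t >> fixation time`` limit of
    this convolution (with ``slope = kappa * P_fix``). Requires ``n0 = 1``.
    """
    if fp.n0 != 1:
        raise ValueError("cohort patch distribution requires n0 = 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    kappa = supply.kappa(params)
    out = np.zeros(n_max)
    if t == 0 or kappa == 0:
        return out
    for i in range(n_max):
        n = i + 1
        out[i], _ = quad(
            lambda u, n=n: kappa
            * monoclonal_probability(params, u)
            * float(yule_patch_pmf(fp, t - u, n)[0]),
            0.0,
            t,
            limit=200,
        )
    return out


def relative_patch_distribution(
    fp: FissionParams, t: float, n_max: int | None = None
) -> np.ndarray:
    """Relative patch-size distribution ``f_n(t) = (1-e^{-rho t})^n/(rho n t)``.

    Independent of the monoclonal slope (it cancels), so the crypt fission
    rate can be inferred from patch sizes alone. Sums to 1 over all ``n >= 1``
    exactly, since ``sum q^n/n = -ln(1-q)`` and ``-ln(e^{-rho t}) = rho*t``.
    """
    if t <= 0:
        raise ValueError("relative patch distribution requires t > 0")
    if fp.n0 != 1:
        raise ValueError("relative patch distribution requires n0 = 1")
    if n_max is None:
        n_max = _default_n_max(fp.rho, t)
    n = np.arange(1, n_max + 1)
    if fp.rho * t < _TINY_RHO:
        out = np.zeros(n_max)
        out[0] = 1.0
        return out
    q = -np.expm1(-fp.rho * t)
    return q**n / (fp.rho * n * t)


def _default_n_max(rho: float, t: float, tail: float = 1e-12) -> int:
    """Truncation bound capturing all but ``tail`` of the size-biased mass."""
    if rho * t < _TINY_RHO:
        return 4
    q = -math.expm1(-rho * t)
    # geometric tail of n*F_n ~ q^n: q^n < tail
    n = int(math.ceil(math.log(tail) / math.log(q))) if q < 1 else 10_000
    return max(4, min(n, 100_000))


@dataclass(frozen=True)
class DoubletCorrection:
    """Expected fraction of clones forming chance doublets.

    With ``k`` clones among ``C`` crypts, each crypt having ``delta``
    neighbours, unrelated clones occasionally land adjacent and are scored
    as a patch of two. ``exact`` is ``(1/k) * sum_{i=1}^{k-1} delta*i/(C-i)``;
    ``approx`` the small-``k`` form ``delta*(k-1)/(2C)``. Fitting code adds
    ``D`` to the size-2 class and subtracts it from size-1.
    """

    delta: int
    k: int
    C: int
    exact: float = field(init=False)
    approx: float = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.C <= self.k:
            raise ValueError("C must exceed k")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        i = np.arange(1, self.k)
        exact = float(np.sum(self.delta * i / (self.C - i)) / self.k)
        approx = self.delta * (self.k - 1) / (2.0 * self.C)
        object.__setattr__(self, "exact", min(exact, 1.0))
        object.__setattr__(self, "approx", min(approx, 1.0))


def doublet_correction(delta: int, k: int, C: int) -> DoubletCorrection:
    """Chance-doublet fraction for ``k`` clones in ``C`` crypts (``delta``
    neighbours per crypt, 6 for hexagonal packing)."""
    return DoubletCorrection(delta=delta, k=k, C=C)


@dataclass(frozen=True)
class BurdenResult:
    """Mutant burden at age ``t``: mutant crypts per million crypts."""

    t: float
    burden: float
    components: np.ndarray  # per-patch-size contributions 1e6 * n * F_n(t)


def _burden_total(slope: float, rho: float, t: float) -> float:
    if rho * t < _TINY_RHO:
        return 1e6 * slope * t
    return 1e6 * slope * math.expm1(rho * t) / rho


def burden(slope: float, fp: FissionParams, t: float) -> BurdenResult:
    """Mutant crypts per million at age ``t``.

    ``B(t) = 1e6 * sum_n n*F_n(t) = 1e6 * slope * (e^{rho t} - 1)/rho``
    (limit ``1e6 * slope * t`` as ``rho -> 0``). For biased marks pass the
    biased monoclonal slope. ``components`` holds the truncated per-size sum.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    total = _burden_total(slope, fp.rho, t)
    F = cohort_patch_distribution(slope, fp, t)
    comps = 1e6 * np.arange(1, F.size + 1) * F
    return BurdenResult(t=t, burden=total, components=comps)


def expansion_coefficient(
    mutant: tuple[CryptDriftParams, FissionParams],
    wild: tuple[CryptDriftParams, FissionParams],
    horizon: float = 100.0,
) -> float:
    """Relative lifetime expansion coefficient ``C_exp``.

    Ratio of lifetime-averaged burdens, mutant over wild-type, with the
    mutation rate fixed to a common value so it cancels exactly:
    ``C_exp = int_0^H B_mut(t) dt / int_0^H B_wt(t) dt``. The monoclonal
    slope per unit mutation rate is ``lam * N * P_fix``, so only the drift
    bias and fission rates enter. Equals 1 when mutant and wild-type
    parameters coincide.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")

    def avg_burden(dp: CryptDriftParams, fp: FissionParams) -> float:
        slope_per_alpha = dp.lam * dp.n_stem * fixation_probability(dp)
        val, _ = quad(
            lambda t: _burden_total(slope_per_alpha, fp.rho, t), 0.0, horizon, limit=200
        )
        return val / horizon

    return avg_burden(*mutant) / avg_burden(*wild)
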