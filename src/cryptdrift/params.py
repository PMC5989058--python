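"""Parameter containers for crypt clonal dynamics.

The model has three layers, each with a small parameter set:

* intra-crypt stem-cell drift (:class:`CryptDriftParams`) — ``N`` functional
  stem cells per crypt replacing each other at rate ``lam`` per stem cell per
  year, with a replacement probability ``p_r`` (0.5 = neutral drift);
* mutation supply (:class:`MutationSupply`) — mutations arise at rate
  ``alpha`` per mitosis, so whole crypts acquire a new mutant clone at rate
  ``kappa = alpha * lam * N`` per year;
* crypt fission (:class:`FissionParams`) — fixed mutant crypts divide at rate
  ``rho`` per crypt per year, expanding clones into multi-crypt patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CryptDriftParams", "MutationSupply", "FissionParams"]


@dataclass(frozen=True)
class CryptDriftParams:
    """Stem-cell replacement parameters of a single crypt.

    Parameters
    ----------
    n_stem:
        Number of functional stem cells ``N`` per crypt (>= 2).
    lam:
        Replacement rate per stem cell per year (lambda > 0).
    p_r:
        Probability that the mutant lineage wins a replacement event at a
        clone boundary; 0.5 is neutral drift. The clone-size birth-death
        chain has upward rate ``beta = 2*lam*p_r`` and downward rate
        ``gamma = 2*lam*(1 - p_r)``, so ``beta + gamma = 2*lam`` always.
    """

    n_stem: int
    lam: float
    p_r: float = 0.5

    def __post_init__(self) -> None:
        if not isinstance(self.n_stem, (int,)) or isinstance(self.n_stem, bool):
            raise ValueError("n_stem must be an integer")
        if self.n_stem < 2:
            raise ValueError(f"n_stem must be >= 2, got {self.n_stem}")
        if not math.isfinite(self.lam) or self.lam <= 0:
            raise ValueError(f"lam must be positive and finite, got {self.lam}")
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError(f"p_r must lie in [0, 1], got {self.p_r}")

    @property
    def beta(self) -> float:
        """Upward clone-boundary rate per year, ``2*lam*p_r``."""
        return 2.0 * self.lam * self.p_r

    @property
    def gamma(self) -> float:
        """Downward clone-boundary rate per year, ``2*lam*(1-p_r)``."""
        return 2.0 * self.lam * (1.0 - self.p_r)

    @property
    def is_neutral(self) -> bool:
        return self.p_r == 0.5


@dataclass(frozen=True)
class MutationSupply:
    """Mutation rate per mitosis (``alpha``).

    The crypt-level mutant-clone arrival rate is ``kappa = alpha * lam * N``
    per year: every stem-cell replacement is a mitosis, each of the ``N``
    stem cells undergoes them at rate ``lam``, and each mitosis mutates the
    mark with probability ``alpha``.
    """

    alpha: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be >= 0 and finite, got {self.alpha}")

    def kappa(self, params: CryptDriftParams) -> float:
        """Mutant-clone arrival rate per crypt per year, ``alpha*lam*N``."""
        return self.alpha * params.lam * params.n_stem


@dataclass(frozen=True)
class FissionParams:
    """Crypt fission as a Yule-Furry pure-birth process.

    ``rho`` is the per-crypt fission rate per year; ``n0`` the initial patch
    size in crypts (1 for a newly fixed clone).
    """

    rho: float
    n0: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.rho) or self.rho < 0:
            raise ValueError(f"rho must be >= 0 and finite, got {self.rho}")
        if not isinstance(self.n0, int) or isinstance(self.n0, bool) or self.n0 < 1:
            raise ValueError(f"n0 must be an integer >= 1, got {self.n0}")


#: Normal (wild-type) colonic crypt fission rate, per crypt per year.
NORMAL_FISSION_RATE = 0.007

#: Mark-specific fitted fission rates, per crypt per year.
FISSION_RATE_MPAS = 0.0068
FISSION_RATE_MAOA = 0.0072
FISSION_RATE_STAG2 = 0.0215
FISSION_RATE_KRAS = 0.07
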