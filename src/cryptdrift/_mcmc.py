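"""Shared ensemble-MCMC plumbing: sampling, seeding, posterior summaries.

All hierarchical fits in the package use an affine-invariant ensemble
sampler (emcee) behind a sampler-agnostic contract: a fit is accepted on
convergence diagnostics (split-R-hat across walkers and effective sample
size, via arviz), not on engine identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np

__all__ = ["PosteriorSummary", "FitResult", "posterior_me", "run_ensemble"]


@dataclass(frozen=True)
class PosteriorSummary:
    """Median, spread and convergence diagnostics for one parameter.

    ``me`` is the margin of error, defined as 1.96 times the posterior
    standard deviation; ``ci`` is the central 95% credible interval.
    Transformed parameters are summarised by applying the transform to
    every posterior sample, never to the summaries.
    """

    name: str
    median: float
    sd: float
    me: float
    ci: tuple
    rhat: float = float("nan")
    ess: float = float("nan")

    @property
    def converged(self) -> bool:
        return (np.isnan(self.rhat) or self.rhat <= 1.05) and (
            np.isnan(self.ess) or self.ess >= 400
        )


def posterior_me(samples, name: str = "param") -> PosteriorSummary:
    """Summarise posterior draws as median and ME = 1.96 * sd.

    ``samples`` may be flat ``(n,)`` or walker-shaped ``(chains, draws)``;
    in the latter case split-R-hat and bulk ESS are attached. Degenerate
    zero-variance chains yield ``me = 0`` (flagged by ``sd == 0``).
    """
    arr = np.asarray(samples, dtype=float)
    rhat = ess = float("nan")
    if arr.ndim == 2 and arr.shape[0] >= 2 and arr.shape[1] >= 4:
        if np.ptp(arr) > 0:
            ds = az.convert_to_dataset(arr[:, :, None])
            rhat = float(np.asarray(az.rhat(ds)["x"].values).reshape(-1)[0])
            ess = float(np.asarray(az.ess(ds)["x"].values).reshape(-1)[0])
        else:
            rhat, ess = 1.0, 0.0
    flat = arr.reshape(-1)
    if flat.size < 1:
        raise ValueError("no samples")
    sd = float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0
    lo, hi = np.percentile(flat, [2.5, 97.5])
    return PosteriorSummary(
        name=name,
        median=float(np.median(flat)),
        sd=sd,
        me=1.96 * sd,
        ci=(float(lo), float(hi)),
        rhat=rhat,
        ess=ess,
    )


@dataclass
class FitResult:
    """Posterior summaries plus raw walker chains for a hierarchical fit.

    ``chains`` maps parameter name -> array of shape (walkers, draws);
    ``summaries`` maps name -> :class:`PosteriorSummary`. ``converged`` is
    the R-hat/ESS gate over the hyperparameters (non-convergence is flagged,
    never silently accepted).
    """

    summaries: dict
    chains: dict
    acceptance: float

    def __getitem__(self, name: str) -> PosteriorSummary:
        return self.summaries[name]

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.summaries.values())

    def sample_matrix(self, names) -> np.ndarray:
        """Flat draws stacked column-wise for the given parameter names."""
        return np.column_stack([self.chains[n].reshape(-1) for n in names])


def run_ensemble(
    log_prob,
    p0: np.ndarray,
    nsteps: int,
    seed: int,
    burn: int | None = None,
    thin: int = 1,
) -> tuple[np.ndarray, float]:
    """Run the ensemble sampler from initial walkers ``p0``.

    ``log_prob`` must accept an array of shape (walkers, ndim) and return a
    vector of log posterior densities. Returns the post-burn chain with
    shape (walkers, draws, ndim) and the mean acceptance fraction.
    Identical seeds give identical chains.
    """
    nwalkers, ndim = p0.shape
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(seed % 2**31).get_state()
    sampler.run_mcmc(p0, nsteps, progress=False, skip_initial_state_check=True)
    burn = nsteps // 2 if burn is None else burn
    chain = sampler.get_chain(discard=burn, thin=thin)  # (draws, walkers, ndim)
    return np.moveaxis(chain, 0, 1), float(np.mean(sampler.acceptance_fraction))


def summarize_chain(chain: np.ndarray, names) -> FitResult:
    """Build a :class:`FitResult` from a (walkers, draws, ndim) chain."""
    summaries = {}
    chains = {}
    for j, name in enumerate(names):
        chains[name] = chain[:, :, j]
        summaries[name] = posterior_me(chain[:, :, j], name)
    return FitResult(summaries=summaries, chains=chains, acceptance=float("nan"))
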