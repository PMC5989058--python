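"""End-to-end orchestration: synthesize, fit, derive, report.

``run_pipeline`` ties the stages together on synthetic data: generate a
cohort and TA screen, fit the four hierarchical models, derive (N, lambda)
from the moment relations, evaluate fission burden and the lifetime
expansion coefficient, and write JSON metrics, TSV tables and summary
figures. ``fold_change_report`` computes the burden fold changes between
parameter sets with explicit baselines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .bayes import (
    fit_patch_multinomial,
    fit_ppc_plateau,
    fit_ta_mutation_rate,
    fit_wpc_accumulation,
    n_lambda_from_moments,
)
from .data import write_cohort_tsv, write_patches_tsv, write_ta_tsv
from .drift import fixation_probability
from .fission import burden, expansion_coefficient
from .params import (
    NORMAL_FISSION_RATE,
    CryptDriftParams,
    FissionParams,
)
from .synth import CohortConfig, generate_cohort, generate_ta_blocks

logger = logging.getLogger("cryptdrift")

__all__ = ["RunConfig", "run_pipeline", "fold_change_report", "burden_fold_change"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    ``nsteps`` trades sampler length for runtime; the seed governs both
    data generation and sampling and is logged with the package version.
    """

    out_dir: str
    seed: int = 0
    cohort: CohortConfig = None  # defaults derived from seed when None
    n_patients: int = 40
    nsteps: int = 4000
    horizon: float = 100.0
    fold_age: float = 60.0
    make_plots: bool = True

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return CohortConfig(seed=self.seed, n_patients=self.n_patients)


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(float(x), -int(floor(log10(abs(x)))) + sig - 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run synth -> fit -> derive -> burden -> report; return the metrics.

    Writes ``metrics.json`` (deterministic byte-for-byte for a fixed
    seed), the synthetic tables as TSV, and three figures (clone
    frequency vs age, patch-size distribution, burden vs age) into
    ``cfg.out_dir``. Every stage failure is reported with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed=%d version=%s", cfg.seed, __version__)

    stage = "synthesize"
    try:
        ccfg = cfg.resolved_cohort()
        cohort, truth = generate_cohort(ccfg)
        blocks, ta_truth = generate_ta_blocks(seed=cfg.seed + 1)
        write_cohort_tsv(cohort, out / "cohort.tsv")
        write_patches_tsv(cohort, out / "patches.tsv")
        write_ta_tsv(blocks, out / "ta_blocks.tsv")

        stage = "fit TA mutation rate"
        ta_fit = fit_ta_mutation_rate(blocks, nsteps=cfg.nsteps, seed=cfg.seed + 11)
        mu_alpha = ta_fit["mu_alpha"].median

        stage = "fit WPC accumulation"
        wpc_fit = fit_wpc_accumulation(cohort, nsteps=cfg.nsteps, seed=cfg.seed + 12)
        delta_c_fix = wpc_fit["mu_a"].median

        stage = "fit PPC plateau"
        ppc_fit = fit_ppc_plateau(cohort, nsteps=cfg.nsteps, seed=cfg.seed + 13)
        c_part = ppc_fit["mu_b"].median

        stage = "fit patch multinomial"
        patch_fit = fit_patch_multinomial(cohort, nsteps=cfg.nsteps, seed=cfg.seed + 14)
        rho = patch_fit["mu_rho"].median

        stage = "derive (N, lambda)"
        n_stem, lam = n_lambda_from_moments(delta_c_fix, c_part, mu_alpha)

        stage = "burden and expansion"
        fp = FissionParams(rho)
        b60 = burden(delta_c_fix, fp, cfg.fold_age).burden
        dp = CryptDriftParams(max(int(round(n_stem)), 2), lam)
        c_exp = expansion_coefficient(
            (dp, fp), (dp, FissionParams(NORMAL_FISSION_RATE)), horizon=cfg.horizon
        )

        stage = "report"
        metrics = {
            "seed": cfg.seed,
            "version": __version__,
            "mu_alpha": _round_sig(mu_alpha),
            "delta_c_fix": _round_sig(delta_c_fix),
            "c_part": _round_sig(c_part),
            "ratio": _round_sig(delta_c_fix / c_part),
            "n_stem": _round_sig(n_stem),
            "lam": _round_sig(lam),
            "rho": _round_sig(rho),
            "burden_at_fold_age": _round_sig(b60),
            "c_exp": _round_sig(c_exp),
            "converged": {
                "ta": ta_fit["mu_alpha"].converged,
                "wpc": wpc_fit["mu_a"].converged,
                "ppc": ppc_fit["mu_b"].converged,
                "patch": patch_fit["mu_rho"].converged,
            },
            "truth": {
                "alpha": truth["alpha"],
                "n_stem": truth["n_stem"],
                "lam": truth["lam"],
                "rho": truth["rho"],
            },
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if cfg.make_plots:
            _plots(cohort, metrics, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc
    return metrics


def _plots(cohort, metrics: dict, out: Path) -> None:
    ages = np.array([o.age for o in cohort])
    wpcf = np.array([o.wpc / o.crypts for o in cohort])
    ppcf = np.array([o.ppc / o.crypts for o in cohort])

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ages, wpcf * 1e4, "o", label="WPC per 10^4 crypts")
    ax.plot(ages, ppcf * 1e4, "s", label="PPC per 10^4 crypts", alpha=0.6)
    tt = np.linspace(0, ages.max(), 50)
    ax.plot(tt, metrics["delta_c_fix"] * tt * 1e4, "-", label="fitted slope")
    ax.axhline(metrics["c_part"] * 1e4, ls="--", label="fitted plateau")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("clones per 10^4 crypts")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "clone_frequency_vs_age.png", dpi=120)
    plt.close(fig)

    sizes = [g for o in cohort for g in o.patch_sizes]
    fig, ax = plt.subplots(figsize=(5, 4))
    if sizes:
        ax.hist(sizes, bins=np.arange(0.5, max(sizes) + 1.5), density=True)
    ax.set_xlabel("patch size (crypts)")
    ax.set_ylabel("relative frequency")
    fig.tight_layout()
    fig.savefig(out / "patch_size_distribution.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    tt = np.linspace(0, 90, 60)
    fp = FissionParams(metrics["rho"])
    ax.plot(tt, [burden(metrics["delta_c_fix"], fp, t).burden for t in tt])
    ax.set_xlabel("age (years)")
    ax.set_ylabel("mutant crypts per million")
    fig.tight_layout()
    fig.savefig(out / "burden_vs_age.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# fold-change reporting
# ---------------------------------------------------------------------------

def burden_fold_change(
    mutant: tuple[CryptDriftParams, FissionParams],
    baseline: tuple[CryptDriftParams, FissionParams],
    age: float = 60.0,
) -> float:
    """Burden ratio mutant/baseline at a given age, mutation rate cancelled.

    The monoclonal slope per unit mutation rate is ``lam * N * P_fix``,
    so only drift bias and fission rate matter. The baseline is explicit;
    a mark compared against itself gives exactly 1.
    """
    def total(dp: CryptDriftParams, fp: FissionParams) -> float:
        slope = dp.lam * dp.n_stem * fixation_probability(dp)
        return burden(slope, fp, age).burden

    return total(*mutant) / total(*baseline)


def fold_change_report(
    marks: dict,
    baseline: tuple[CryptDriftParams, FissionParams],
    age: float = 60.0,
    horizon: float = 100.0,
) -> pd.DataFrame:
    """Fold changes and lifetime expansion coefficients per mark.

    ``marks`` maps name -> (CryptDriftParams, FissionParams). Each row
    reports the burden fold over the stated baseline at ``age`` and the
    lifetime expansion coefficient over the same baseline at ``horizon``.
    The baseline convention is carried in the output so no fold is
    reported without its reference.
    """
    rows = []
    base_desc = (
        f"N={baseline[0].n_stem}, lam={baseline[0].lam}, "
        f"p_r={baseline[0].p_r}, rho={baseline[1].rho}"
    )
    for name, (dp, fp) in marks.items():
        rows.append(
            {
                "mark": name,
                "p_r": dp.p_r,
                "rho": fp.rho,
                "fold_at_age": burden_fold_change((dp, fp), baseline, age),
                "c_exp": expansion_coefficient((dp, fp), baseline, horizon=horizon),
                "baseline": base_desc,
                "age": age,
            }
        )
    return pd.DataFrame(rows)
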