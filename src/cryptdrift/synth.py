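"""Synthetic study-shaped data with known ground truth.

Every generator is a generative twin of one fitting stage and returns a
ground-truth sidecar so recovery tests can compare posterior against
truth. All generators are deterministic in their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .data import CohortObservation, TABlockCounts
from .drift import continuous_labelling
from .fission import doublet_correction, relative_patch_distribution
from .kras import MAFObservation, largest_undetectable_patch
from .params import CryptDriftParams, FissionParams, MutationSupply

__all__ = [
    "CohortConfig",
    "AmpliconRunConfig",
    "KRAS_REFERENCE",
    "KRAS_CODON12_START",
    "generate_cohort",
    "generate_ta_blocks",
    "generate_goblet_calibration",
    "fit_goblet_mapping",
    "generate_amplicon_run",
    "generate_amplicon_reads",
    "generate_maf_observations",
]


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters and sampling plan for a synthetic cohort.

    Ages uniform over 8-93 years (the study's range); crypts per patient
    log-uniform over 7,000-100,000, respecting the >7,000-crypt inclusion
    rule. The seed is mandatory.
    """

    params: CryptDriftParams = CryptDriftParams(7, 1.3)
    supply: MutationSupply = MutationSupply(4.44e-6)
    fission: FissionParams = FissionParams(0.007)
    n_patients: int = 40
    age_range: tuple = (8.0, 93.0)
    crypt_range: tuple = (7_000, 100_000)
    delta: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] < 0:
            raise ValueError("invalid age range")
        if self.crypt_range[0] < 7_000:
            raise ValueError("crypt range must respect the >7000 inclusion rule")


def generate_cohort(cfg: CohortConfig):
    """Draw a cohort of patients from the labelling + fission model.

    Per patient: ``WPC ~ Binomial(C, C_monoclonal(t))``, ``PPC ~
    Binomial(C, C_partial(t))`` (biased closed forms when ``p_r != 0.5``);
    the number of mutant patches is ``Poisson(C * slope * t)`` (``sum_n F_n
    = slope*t``) with sizes iid from the relative distribution ``f_n(t)``;
    chance doublets are planted by promoting singleton clones to scored
    size-2 patches with the doublet probability ``D(delta, k, C)``, the
    same convention the multinomial fit corrects for.

    Returns ``(cohort, truth)`` where ``truth`` records the generator
    parameters and per-patient latent probabilities.
    """
    rng = np.random.default_rng(cfg.seed)
    slope = None
    cohort = []
    latents = []
    for i in range(cfg.n_patients):
        age = float(rng.uniform(*cfg.age_range))
        crypts = int(
            math.exp(rng.uniform(math.log(cfg.crypt_range[0]), math.log(cfg.crypt_range[1])))
        )
        c_part, c_mono = continuous_labelling(cfg.params, cfg.supply, age)
        wpc = int(rng.binomial(crypts, min(c_mono, 1.0)))
        ppc = int(rng.binomial(crypts, min(c_part, 1.0)))
        if slope is None:
            # asymptotic monoclonal slope kappa * P_fix
            c1 = continuous_labelling(cfg.params, cfg.supply, 200.0)[1]
            c2 = continuous_labelling(cfg.params, cfg.supply, 201.0)[1]
            slope = c2 - c1
        k = int(rng.poisson(crypts * slope * age))
        sizes: list[int] = []
        if k > 0:
            f = relative_patch_distribution(cfg.fission, age)
            f = f / f.sum()
            sizes = list(rng.choice(np.arange(1, f.size + 1), size=k, p=f))
            if k > 1:
                D = doublet_correction(cfg.delta, k, crypts).exact
                singles = [j for j, g in enumerate(sizes) if g == 1]
                n_promote = rng.binomial(len(singles), D)
                for j in singles[:n_promote]:
                    sizes[j] = 2
        cohort.append(
            CohortObservation(
                patient=f"S{i:03d}",
                age=age,
                crypts=crypts,
                wpc=wpc,
                ppc=ppc,
                patch_sizes=[int(g) for g in sizes],
                delta=cfg.delta,
            )
        )
        latents.append({"patient": f"S{i:03d}", "c_part": c_part, "c_mono": c_mono})
    truth = {
        "n_stem": cfg.params.n_stem,
        "lam": cfg.params.lam,
        "p_r": cfg.params.p_r,
        "alpha": cfg.supply.alpha,
        "rho": cfg.fission.rho,
        "slope": slope,
        "seed": cfg.seed,
        "patients": latents,
    }
    return cohort, truth


def generate_ta_blocks(
    mu_alpha: float = 4.44e-6,
    sigma_alpha: float = 1.0e-6,
    sigma_error: float = 1.0e-6,
    n_patients: int = 9,
    blocks_per_patient: int = 3,
    goblet_mean: float = 1.5e6,
    seed: int = 0,
):
    """Transit-amplifying clone counts per tissue block.

    Per patient ``alpha_i ~ Normal(mu_alpha, sigma_alpha)`` truncated at 0;
    per block the realized rate ``q ~ Normal(alpha_i, sigma_error)``
    truncated at 0, goblet totals lognormal around ``goblet_mean``, and
    ``k ~ Binomial(G, q)``. Defaults size the screen like the study's
    (9 patients, ~26 blocks, about 2 million crypts, E[k] about 6.7 per
    block at the default rate). Returns ``(blocks, truth)``.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    alphas = []
    for i in range(n_patients):
        a_i = max(float(rng.normal(mu_alpha, sigma_alpha)), 0.0)
        alphas.append(a_i)
        for b in range(blocks_per_patient):
            G = int(goblet_mean * rng.lognormal(0.0, 0.25))
            q = max(float(rng.normal(a_i, sigma_error)), 0.0)
            k = int(rng.binomial(G, min(q, 1.0)))
            blocks.append(TABlockCounts(f"T{i}", f"B{b}", k, G))
    truth = {
        "mu_alpha": mu_alpha,
        "sigma_alpha": sigma_alpha,
        "sigma_error": sigma_error,
        "alphas": alphas,
        "seed": seed,
    }
    return blocks, truth


def generate_goblet_calibration(
    n_rows: int = 274,
    coefficient: float = 0.9,
    exponent: float = 0.8,
    noise_sd: float = 0.15,
    area_range: tuple = (500.0, 20_000.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Crypt area vs goblet count calibration table.

    Monotone power law ``count = coefficient * area**exponent`` with
    multiplicative lognormal noise; 274 rows by default. Columns:
    ``crypt_area``, ``goblet_count``, ``true_count``.
    """
    rng = np.random.default_rng(seed)
    area = np.exp(rng.uniform(math.log(area_range[0]), math.log(area_range[1]), n_rows))
    area.sort()
    true = coefficient * area**exponent
    noisy = true * rng.lognormal(0.0, noise_sd, n_rows)
    return pd.DataFrame(
        {"crypt_area": area, "goblet_count": noisy, "true_count": true}
    )


def fit_goblet_mapping(table: pd.DataFrame):
    """Monotone regression of goblet count on crypt area.

    Returns a callable area -> predicted count that is non-decreasing by
    construction (isotonic regression, linear interpolation between knots).
    """
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(table["crypt_area"].to_numpy(), table["goblet_count"].to_numpy())
    return lambda area: iso.predict(np.atleast_1d(np.asarray(area, dtype=float)))


# ---------------------------------------------------------------------------
# amplicon runs
# ---------------------------------------------------------------------------

# Synthetic 159-base stand-in for the KRAS amplicon; positions 34-39 play
# the role of codons 12 and 13 (GGT GGC).
KRAS_CODON12_START = 34
KRAS_REFERENCE = (
    "ATGACTGAATATAAACTTGTGGTAGTTGGAGCTGGTGGCGTAGGCAAGAGTGCCTTGACG"
    "ATACAGCTAATTCAGAATCATTTTGTGGACGAATATGATCCAACAATAGAGGTAAATCTT"
    "GTTTTAATATGCATATTACTGGTGCAGGACCATTCTTTG"
)
assert len(KRAS_REFERENCE) == 159


@dataclass(frozen=True)
class AmpliconRunConfig:
    """Plan for one synthetic sequencing run.

    ``spikes`` maps sample index -> list of ``(position, alt_base,
    maf)`` planted in both replicates; unspiked samples are pure
    background. Background error rates are beta-distributed across the
    run per position/base and shared by all samples on the run.
    """

    n_samples: int = 8
    depth: int = 10_000
    error_mean: float = 3e-4
    error_concentration: float = 30.0
    spikes: dict = field(default_factory=dict)
    run: str = "run1"
    seed: int = 0


def generate_amplicon_run(cfg: AmpliconRunConfig):
    """Duplicate per-sample nucleotide count tables with planted variants.

    Returns ``(samples, truth)`` where ``samples`` maps sample id ->
    {replicate -> count table} (the schema :func:`~cryptdrift.kras.
    compute_run_background` and :func:`~cryptdrift.kras.call_mutations`
    consume) and ``truth`` lists the planted ``(sample, position, alt,
    maf)`` tuples and the run error field.
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(KRAS_REFERENCE)
    bases = "ACGT"
    ref_idx = np.array([bases.index(b) for b in KRAS_REFERENCE])
    a = cfg.error_concentration * cfg.error_mean
    b = cfg.error_concentration * (1.0 - cfg.error_mean)
    err = rng.beta(a, b, size=(L, 4))
    err[np.arange(L), ref_idx] = 0.0
    samples: dict = {}
    planted = []
    for s in range(cfg.n_samples):
        name = f"{cfg.run}-sample{s}"
        spikes = cfg.spikes.get(s, [])
        for pos, alt, maf in spikes:
            planted.append((name, pos, alt, maf))
        reps = {}
        for rep in (1, 2):
            counts = np.zeros((L, 4), dtype=np.int64)
            for i in range(L):
                p = err[i].copy()
                for pos, alt, maf in spikes:
                    if pos - 1 == i:
                        p[bases.index(alt)] += maf
                p[ref_idx[i]] = max(1.0 - p.sum() + p[ref_idx[i]], 0.0)
                counts[i] = rng.multinomial(cfg.depth, p / p.sum())
            df = pd.DataFrame(counts, columns=list(bases))
            df.insert(0, "position", np.arange(1, L + 1))
            df["N"] = 0
            df["depth"] = df[list(bases)].sum(axis=1)
            reps[rep] = df
        samples[name] = reps
    truth = {"planted": planted, "error_mean": cfg.error_mean, "seed": cfg.seed}
    return samples, truth


def generate_amplicon_reads(
    n_reads: int,
    fwd_primer: str = "ATGACTGAATATAAACTTGTGGTA",
    rev_tail: int = 24,
    n_bad: int = 0,
    seed: int = 0,
):
    """Merged reads for exercising the filter/count path.

    Good reads are the full 159-base reference (which begins with
    ``fwd_primer``); ``n_bad`` reads are corrupted (wrong primer or
    overlong) and must be removed by the filter. Returns ``(reads,
    fwd_primer, rev_primer)`` with the reverse primer given 5'->3' on the
    opposite strand, as a protocol would list it.
    """
    from Bio.Seq import Seq

    if not KRAS_REFERENCE.startswith(fwd_primer):
        raise ValueError("forward primer must prefix the reference")
    rng = np.random.default_rng(seed)
    rev_primer = str(Seq(KRAS_REFERENCE[-rev_tail:]).reverse_complement())
    reads = [KRAS_REFERENCE] * n_reads
    for _ in range(n_bad):
        kind = rng.integers(3)
        if kind == 0:
            reads.append(KRAS_REFERENCE + "ACGTACG")  # 166 bases: overlong
        elif kind == 1:
            reads.append("T" + KRAS_REFERENCE[1:])  # broken forward primer
        else:
            reads.append(KRAS_REFERENCE[:-1] + "A")  # broken reverse end
    return reads, fwd_primer, rev_primer


def generate_maf_observations(
    rho: float = 0.07,
    delta_c_fix: float = 8e-5,
    n_patients: int = 100,
    crypts: int = 5_000,
    n_mutations: int = 12,
    detection_threshold: float = 1e-4,
    age_range: tuple = (50.0, 90.0),
    seed: int = 0,
):
    """Patient MAF observations drawn from the patch-size model itself.

    Per patient the sample-level categorical ``(F_0, F_1, F_2, ...)`` is
    sampled (it sums to one exactly since ``sum_n F_n = slope*t``); patch
    sizes at or below the largest undetectable size report MAF 0. Returns
    ``(observations, truth)``.
    """
    rng = np.random.default_rng(seed)
    slope = n_mutations * delta_c_fix
    nlim = largest_undetectable_patch(crypts, detection_threshold)
    obs = []
    latent_sizes = []
    for i in range(n_patients):
        t = float(rng.uniform(*age_range))
        if slope * t > 1:
            raise ValueError("slope * age exceeds 1; model assumptions violated")
        q = -math.expm1(-rho * t)
        n_max = max(int(math.log(1e-12) / math.log(q)) if 0 < q < 1 else 4, 4)
        n = np.arange(1, n_max + 1)
        F = slope * q**n / (max(rho, 1e-12) * n)
        p = np.concatenate([[1.0 - slope * t], F])
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        size = int(rng.choice(n_max + 1, p=p))
        latent_sizes.append(size)
        f = size / (2.0 * crypts) if size > nlim else 0.0
        obs.append(
            MAFObservation(
                patient=f"K{i:03d}",
                age=t,
                f_allele=min(f, 0.5),
                crypts=crypts,
                n_mutations=n_mutations,
                detection_threshold=detection_threshold,
            )
        )
    truth = {
        "rho": rho,
        "delta_c_fix": delta_c_fix,
        "n_limit": nlim,
        "sizes": latent_sizes,
        "seed": seed,
    }
    return obs, truth
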