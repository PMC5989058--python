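"""KRAS amplicon processing and detection-limited patch-size inference.

The wet-lab design this mirrors: a 159-bp KRAS amplicon is PCR-amplified
in duplicate per sample, sequenced deeply, and variant nucleotides are
called against a per-run background of all samples. A called, corrected
mutant-allele frequency (MAF) converts to an implied mutant patch size
``m = 2*C*f_allele`` (``C`` crypts per section; one allele of two per
cell, so the allele frequency is half the crypt burden; cells per crypt
cancel exactly). A three-category multinomial over {no detectable clone,
the observed patch, remainder} then yields a joint posterior for the
fission rate ``rho`` and the monoclonal accumulation rate ``Delta C_fix``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._mcmc import FitResult, run_ensemble, summarize_chain

__all__ = [
    "AmpliconSet",
    "VariantCall",
    "MAFObservation",
    "KrasPosterior",
    "AMPLICON_LENGTH",
    "MAX_READ_LENGTH",
    "CALL_FOLD",
    "CALL_Z",
    "CALL_MIN_READS",
    "filter_amplicons",
    "count_nucleotides",
    "compute_run_background",
    "call_mutations",
    "calls_to_frame",
    "maf_to_patch",
    "largest_undetectable_patch",
    "fit_kras_model",
]

AMPLICON_LENGTH = 159  # bases of KRAS sequence in the amplicon
MAX_READ_LENGTH = 164  # merged reads longer than this are discarded
CALL_FOLD = 4.0  # raw frequency must exceed fold * background mean ...
CALL_Z = 3.209  # ... or background mean + z * background sd
CALL_MIN_READS = 10  # absolute variant-read floor
_BASES = ("A", "C", "G", "T")


@dataclass
class AmpliconSet:
    """Merged consensus reads for one sample replicate.

    ``sequences`` are merged read strings; ``run`` identifies the
    sequencing run whose samples share a background model. Two replicate
    PCRs per sample are required for a sample to be callable.
    """

    sample: str
    replicate: int
    run: str
    sequences: list
    fwd_primer: str
    rev_primer: str  # given 5'->3' on the opposite strand, as ordered


def filter_amplicons(raw: AmpliconSet) -> AmpliconSet:
    """Keep reads that start with the forward primer, end with the
    reverse-complement of the reverse primer, and are <= 164 bases."""
    if not raw.fwd_primer or not raw.rev_primer:
        raise ValueError("primer strings must be non-empty")
    fwd = raw.fwd_primer.upper()
    rev_rc = str(Seq(raw.rev_primer.upper()).reverse_complement())
    kept = [
        s
        for s in raw.sequences
        if len(s) <= MAX_READ_LENGTH
        and s.upper().startswith(fwd)
        and s.upper().endswith(rev_rc)
    ]
    return AmpliconSet(
        sample=raw.sample,
        replicate=raw.replicate,
        run=raw.run,
        sequences=kept,
        fwd_primer=raw.fwd_primer,
        rev_primer=raw.rev_primer,
    )


def count_nucleotides(reads, length: int | None = None) -> pd.DataFrame:
    """Per-position base counts for anchored reads.

    Returns a frame with 1-based ``position``, columns A/C/G/T, an ``N``
    column collecting ambiguous bases (excluded from frequencies), and
    ``depth`` (A+C+G+T). Reads are anchored at position 1; positions past
    a read's end simply receive no count from it.
    """
    reads = [r.upper() for r in reads]
    if length is None:
        length = max((len(r) for r in reads), default=0)
    counts = np.zeros((length, 5), dtype=np.int64)
    idx = {b: j for j, b in enumerate(_BASES)}
    for r in reads:
        for i, ch in enumerate(r[:length]):
            counts[i, idx.get(ch, 4)] += 1
    df = pd.DataFrame(counts, columns=list(_BASES) + ["N"])
    df.insert(0, "position", np.arange(1, length + 1))
    df["depth"] = df[list(_BASES)].sum(axis=1)
    return df


def _frequencies(table: pd.DataFrame) -> np.ndarray:
    depth = table["depth"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = table[list(_BASES)].to_numpy(dtype=float) / depth[:, None]
    return np.nan_to_num(f)


def compute_run_background(tables: dict) -> pd.DataFrame:
    """Per position/base mean and sd of base frequency across a run.

    ``tables`` maps ``(sample, replicate) -> count table``; all entries must
    belong to the same sequencing run. Returns a frame with 1-based
    ``position``, ``base``, ``bg_mean``, ``bg_sd``.
    """
    if not tables:
        raise ValueError("no samples in run")
    freqs = np.stack([_frequencies(t) for t in tables.values()])  # (S, L, 4)
    mean = freqs.mean(axis=0)
    sd = freqs.std(axis=0, ddof=1) if freqs.shape[0] > 1 else np.zeros_like(mean)
    L = mean.shape[0]
    return pd.DataFrame(
        {
            "position": np.repeat(np.arange(1, L + 1), 4),
            "base": list(_BASES) * L,
            "bg_mean": mean.reshape(-1),
            "bg_sd": sd.reshape(-1),
        }
    )


@dataclass(frozen=True)
class VariantCall:
    """One candidate variant at a position, with all threshold flags.

    ``called`` requires, in both replicates: raw frequency at least
    ``CALL_FOLD`` times the run background mean OR at least the mean plus
    ``CALL_Z`` standard deviations, with at least ``CALL_MIN_READS``
    variant reads. ``corrected_maf`` is the replicate-mean raw frequency
    minus the background mean, floored at zero.
    """

    sample: str
    position: int
    ref: str
    alt: str
    raw_freq: float
    bg_mean: float
    bg_sd: float
    reads: int
    pass_fold: bool
    pass_sd: bool
    pass_reads: bool
    pass_concordance: bool
    called: bool
    corrected_maf: float


def _replicate_pass(freq: float, reads: int, mu: float, sd: float):
    pass_fold = freq >= CALL_FOLD * mu and freq > 0
    pass_sd = freq >= mu + CALL_Z * sd and freq > 0
    pass_reads = reads >= CALL_MIN_READS
    return pass_fold, pass_sd, pass_reads, (pass_fold or pass_sd) and pass_reads


def call_mutations(
    samples: dict, background: pd.DataFrame, reference: str
) -> list[VariantCall]:
    """Call variants for every sample with two replicates on a run.

    ``samples`` maps sample id -> {replicate id -> count table};
    ``background`` comes from :func:`compute_run_background` on the same
    run; ``reference`` is the amplicon reference sequence. Samples without
    exactly two replicates are excluded with a warning. Only positions/bases
    passing all thresholds in both replicates yield ``called=True``; other
    above-zero candidates are reported with their failing flags when they
    pass in at least one replicate.
    """
    ref = reference.upper()
    bg = background.set_index(["position", "base"])
    calls: list[VariantCall] = []
    for sample, reps in samples.items():
        if len(reps) != 2:
            warnings.warn(
                f"sample {sample!r} has {len(reps)} replicates; "
                "two are required, sample excluded",
                stacklevel=2,
            )
            continue
        tables = list(reps.values())
        fs = [_frequencies(t) for t in tables]
        counts = [t[list(_BASES)].to_numpy() for t in tables]
        L = min(f.shape[0] for f in fs + [np.empty((len(ref), 0))])
        for pos in range(1, L + 1):
            for j, base in enumerate(_BASES):
                if base == ref[pos - 1]:
                    continue
                mu = float(bg.loc[(pos, base), "bg_mean"])
                sd = float(bg.loc[(pos, base), "bg_sd"])
                verdicts = [
                    _replicate_pass(float(f[pos - 1, j]), int(c[pos - 1, j]), mu, sd)
                    for f, c in zip(fs, counts)
                ]
                if not any(v[3] for v in verdicts):
                    continue
                concordant = all(v[3] for v in verdicts)
                raw = float(np.mean([f[pos - 1, j] for f in fs]))
                calls.append(
                    VariantCall(
                        sample=sample,
                        position=pos,
                        ref=ref[pos - 1],
                        alt=base,
                        raw_freq=raw,
                        bg_mean=mu,
                        bg_sd=sd,
                        reads=int(sum(c[pos - 1, j] for c in counts)),
                        pass_fold=all(v[0] for v in verdicts),
                        pass_sd=all(v[1] for v in verdicts),
                        pass_reads=all(v[2] for v in verdicts),
                        pass_concordance=concordant,
                        called=concordant,
                        corrected_maf=max(raw - mu, 0.0) if concordant else 0.0,
                    )
                )
    return calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """VCF-like tabular view of variant calls (one row per candidate)."""
    cols = [
        "sample",
        "pos",
        "ref",
        "alt",
        "raw_freq",
        "bg_mean",
        "bg_sd",
        "reads",
        "called",
        "corrected_maf",
    ]
    rows = [
        {
            "sample": c.sample,
            "pos": c.position,
            "ref": c.ref,
            "alt": c.alt,
            "raw_freq": c.raw_freq,
            "bg_mean": c.bg_mean,
            "bg_sd": c.bg_sd,
            "reads": c.reads,
            "called": c.called,
            "corrected_maf": c.corrected_maf,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# MAF -> patch size and the three-category multinomial model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MAFObservation:
    """One patient sample for the patch-size model.

    ``f_allele`` is the corrected MAF (0 when no variant was called);
    ``crypts`` is ``C``, the crypt count represented in the sequenced DNA;
    ``n_mutations`` the number of distinct target mutations the assay
    scores (12 for the codon 12/13 panel, 1 for a single-allele assay);
    ``detection_threshold`` the smallest callable MAF. The implied mutant
    patch size is ``m = 2*C*f_allele``; cells per crypt cancel.
    """

    patient: str
    age: float
    f_allele: float
    crypts: int
    n_mutations: int = 12
    detection_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.f_allele < 0:
            raise ValueError("f_allele must be >= 0")
        if self.f_allele > 0.5:
            raise ValueError("f_allele > 0.5 would imply more mutant crypts than crypts")
        if self.crypts <= 0 or self.n_mutations < 1:
            raise ValueError("crypts and n_mutations must be positive")
        if self.age <= 0:
            raise ValueError("age must be positive")

    @property
    def m(self) -> float:
        return 2.0 * self.crypts * self.f_allele


def maf_to_patch(obs: MAFObservation) -> int:
    """Implied mutant patch size, rounded half-up to the nearest integer.

    The real-valued ``m = 2*C*f_allele`` is kept inside the likelihood;
    rounding is only used to assign the detected/undetected category.
    """
    return int(math.floor(obs.m + 0.5))


def largest_undetectable_patch(crypts: int, detection_threshold: float) -> int:
    """Largest patch size whose MAF stays below the detection threshold.

    A patch of ``n`` crypts in ``C`` produces MAF ``n/(2C)``, so patches
    with ``n < 2*C*threshold`` are invisible:
    ``n_limit = ceil(2*C*threshold) - 1`` (0 when the threshold is 0, in
    which case only the no-fixed-clone state is undetectable).
    """
    if detection_threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    return max(int(math.ceil(2.0 * crypts * detection_threshold)) - 1, 0)


@dataclass
class KrasPosterior:
    """Joint posterior for the fission rate and monoclonal slope.

    ``fit`` carries the chains and convergence diagnostics for ``rho`` and
    ``delta_c_fix``; ``flagged_prior_like`` marks the all-zero-MAF case in
    which the slope posterior collapses onto the truncated prior near 0.
    """

    fit: FitResult
    n_limits: dict = field(default_factory=dict)
    flagged_prior_like: bool = False

    def __getitem__(self, name: str):
        return self.fit[name]

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def q_vector(self, rho: float, delta_c_fix: float, obs: MAFObservation):
        """Category probabilities (q0, q1, q2) for one observation.

        q0: no detectable clone (no fixed clone, or a patch at or below the
        detection limit); q1: the observed patch (0 for undetected
        patients); q2: remainder. Sums to 1 by construction.
        """
        q0, q1 = _q01(
            np.array([rho]), np.array([delta_c_fix]), obs, obs.m if obs.m > 0 else None
        )
        q0, q1 = float(q0[0]), float(q1[0])
        return q0, q1, 1.0 - q0 - q1

    def predictive_detection_probability(
        self, age: float, crypts: int, n_mutations: int, maf: float, n_draws: int = 400
    ) -> float:
        """Posterior-predictive probability a sample shows MAF >= ``maf``.

        Under the sample-level categorical the probability of a patch of
        size ``n >= 2*C*maf`` is ``sum_n F_n(age)``, computed through the
        tail of ``-log(1-q)``; averaged over thinned posterior draws.
        """
        mat = self.fit.sample_matrix(["rho", "delta_c_fix"])
        step = max(mat.shape[0] // n_draws, 1)
        draws = mat[::step]
        m_min = max(int(math.ceil(2.0 * crypts * maf)), 1)
        probs = []
        for rho, dc in draws:
            rho = max(rho, 1e-12)
            slope = n_mutations * dc
            q = -math.expm1(-rho * age)
            # sum_{n>=m_min} q^n/n via the tail of -log(1-q)
            n = np.arange(1, m_min)
            head = float(np.sum(q**n / n)) if m_min > 1 else 0.0
            tail = max(-math.log1p(-q) - head, 0.0) if q < 1 else math.inf
            probs.append(min(slope * tail / rho, 1.0))
        return float(np.mean(probs))


def _q01(rho, dc, obs: MAFObservation, m_real):
    """Vectorized (q0, q1) over walkers for one observation.

    ``F_0 = 1 - n_mutations*dc*t``; ``F_n = n_mutations*dc*q^n/(rho*n)``
    with ``q = 1 - e^{-rho t}``; ``q0 = F_0 + sum_{n=1}^{n_limit} F_n``;
    ``q1 = F_m`` at the real-valued observed ``m`` (None when undetected).
    """
    t = obs.age
    slope = obs.n_mutations * dc
    rho_safe = np.maximum(rho, 1e-12)
    qe = -np.expm1(-rho_safe * t)
    nlim = largest_undetectable_patch(obs.crypts, obs.detection_threshold)
    f0 = 1.0 - slope * t
    q0 = f0.copy()
    if nlim >= 1:
        n = np.arange(1, nlim + 1)
        q0 = q0 + slope / rho_safe * np.sum(qe[:, None] ** n / n, axis=1)
    if m_real is None:
        q1 = np.zeros_like(q0)
    else:
        m = max(m_real, 1.0)
        with np.errstate(invalid="ignore"):
            q1 = slope / rho_safe * np.exp(m * np.log(qe)) / m
    return q0, q1


def fit_kras_model(
    observations: list[MAFObservation],
    nsteps: int = 3000,
    seed: int = 0,
    nwalkers: int = 32,
) -> KrasPosterior:
    """Sample (rho, Delta C_fix) under the three-category multinomial.

    Each patient contributes ``log q0`` if no variant was called and
    ``log q1 = log F_m(t)`` at their implied real-valued patch size if one
    was. Priors as printed: ``rho ~ half-normal(0, 0.5)``,
    ``Delta C_fix ~ half-normal(0, 1e-4)``; the slope in the likelihood is
    ``n_mutations * Delta C_fix`` (the panel scores 12 possible mutations).
    Zero-MAF patients stay in (they inform q0); an all-zero cohort is fit
    but flagged, its slope posterior being essentially the truncated prior.
    """
    if not observations:
        raise ValueError("no observations")
    detected = [(o, o.m) for o in observations if o.f_allele > 0]
    all_zero = not detected

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        rho, dc = theta[:, 0], theta[:, 1]
        lp = np.full(theta.shape[0], -np.inf)
        ok = (rho > 0) & (rho < 5) & (dc > 0)
        if not np.any(ok):
            return lp
        r, d = rho[ok], dc[ok]
        val = -0.5 * (r / 0.5) ** 2 - 0.5 * (d / 1e-4) ** 2
        good = np.ones(r.shape[0], dtype=bool)
        for o in observations:
            m_real = o.m if o.f_allele > 0 else None
            q0, q1 = _q01(r, d, o, m_real)
            term = q1 if m_real is not None else q0
            good &= (term > 0) & (q0 >= 0) & (q0 + q1 <= 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                val = val + np.where(good, np.log(np.clip(term, 1e-300, None)), 0.0)
        lp[ok] = np.where(good, val, -np.inf)
        return lp

    rng = np.random.default_rng(seed)
    p0 = np.column_stack(
        [
            np.exp(rng.uniform(math.log(0.005), math.log(0.3), nwalkers)),
            np.exp(rng.uniform(math.log(1e-8), math.log(5e-5), nwalkers)),
        ]
    )
    chain, acc = run_ensemble(log_prob, p0, nsteps, seed)
    fit = summarize_chain(chain, ["rho", "delta_c_fix"])
    fit.acceptance = acc
    n_limits = {
        o.patient: largest_undetectable_patch(o.crypts, o.detection_threshold)
        for o in observations
    }
    return KrasPosterior(fit=fit, n_limits=n_limits, flagged_prior_like=all_zero)
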