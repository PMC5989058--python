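"""Event-driven (Gillespie) simulators of crypt clonal dynamics.

These serve two roles: independent stochastic oracles for the closed-form
results in :mod:`cryptdrift.drift` and :mod:`cryptdrift.fission`, and
scenario engines for the two questions the analytic model cannot answer —
the effect of crypt fusion on patch sizes (spatial) and of sequential
double hits on apparent clone dynamics (per-cell mutation tracking).

All simulations are exact in the Gillespie sense: inter-event times are
exponential with the current total rate, and identical seeds reproduce
identical event streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import CryptDriftParams, FissionParams, MutationSupply

__all__ = [
    "SimConfig",
    "DoubleHitConfig",
    "CryptLattice",
    "simulate_crypt_drift",
    "simulate_fixation_times",
    "simulate_continuous_labelling",
    "simulate_fission_fusion",
    "simulate_double_hit",
]


@dataclass(frozen=True)
class SimConfig:
    """Replication settings; a seed is mandatory for reproducibility."""

    seed: int
    replicates: int = 10_000
    t_max: float = 10.0
    report_times: tuple = ()

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        times = tuple(float(t) for t in self.report_times) or (self.t_max,)
        if any(t < 0 for t in times):
            raise ValueError("report times must be >= 0")
        object.__setattr__(self, "report_times", tuple(sorted(times)))


# ---------------------------------------------------------------------------
# single-crypt clone-size drift
# ---------------------------------------------------------------------------

@njit(cache=True)
def _drift_kernel(N, beta, gamma, report_times, reps, seed):  # pragma: no cover
    np.random.seed(seed)
    R = report_times.shape[0]
    counts = np.zeros((R, N + 1), dtype=np.int64)
    total = beta + gamma
    p_up = beta / total
    for _ in range(reps):
        n = 1
        t = 0.0
        idx = 0
        while True:
            if n == 0 or n == N:
                for j in range(idx, R):
                    counts[j, n] += 1
                break
            dt = np.random.exponential(1.0 / total)
            t_new = t + dt
            while idx < R and report_times[idx] <= t_new:
                counts[idx, n] += 1
                idx += 1
            if idx == R:
                break
            t = t_new
            if np.random.random() < p_up:
                n += 1
            else:
                n -= 1
    return counts


def simulate_crypt_drift(params: CryptDriftParams, cfg: SimConfig) -> dict:
    """Empirical clone-size distributions of the drift chain.

    Simulates ``cfg.replicates`` clones starting from one stem cell and
    returns, per report time, the empirical pmf over sizes ``0..N`` with
    binomial Monte-Carlo standard errors.
    """
    times = np.asarray(cfg.report_times, dtype=float)
    counts = _drift_kernel(
        params.n_stem, params.beta, params.gamma, times, cfg.replicates, cfg.seed
    )
    pmf = counts / cfg.replicates
    se = np.sqrt(pmf * (1.0 - pmf) / cfg.replicates)
    return {"t": times, "counts": counts, "pmf": pmf, "se": se}


@njit(cache=True)
def _fixation_kernel(N, beta, gamma, reps, seed):  # pragma: no cover
    np.random.seed(seed)
    out = np.empty(reps)
    total = beta + gamma
    p_up = beta / total
    m = 0
    for _ in range(reps):
        n = 1
        t = 0.0
        while 0 < n < N:
            t += np.random.exponential(1.0 / total)
            if np.random.random() < p_up:
                n += 1
            else:
                n -= 1
        if n == N:
            out[m] = t
            m += 1
    return out[:m]


def simulate_fixation_times(params: CryptDriftParams, cfg: SimConfig) -> np.ndarray:
    """Fixation times of clones that reached size ``N`` (others discarded)."""
    return _fixation_kernel(
        params.n_stem, params.beta, params.gamma, cfg.replicates, cfg.seed
    )


# ---------------------------------------------------------------------------
# cohort continuous labelling with fission
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cohort_kernel(N, beta, gamma, kappa, rho, age, crypts, seed):  # pragma: no cover
    np.random.seed(seed)
    n_clones = np.random.poisson(crypts * kappa * age)
    wpc = 0
    ppc = 0
    patch_sizes = np.empty(n_clones, dtype=np.int64)
    n_patches = 0
    total = beta + gamma
    p_up = beta / total
    for _ in range(n_clones):
        tau = np.random.random() * age  # uniform birth time (kappa*t flux)
        t = tau
        n = 1
        while 0 < n < N and t < age:
            t += np.random.exponential(1.0 / total)
            if t >= age:
                break
            if np.random.random() < p_up:
                n += 1
            else:
                n -= 1
        if n == N and t < age:
            # fixed at time t; Yule fission for the remaining age - t years
            size = 1
            tf = t
            while True:
                tf += np.random.exponential(1.0 / (rho * size)) if rho > 0 else age
                if tf >= age:
                    break
                size += 1
            patch_sizes[n_patches] = size
            n_patches += 1
            wpc += size
        elif 0 < n < N:
            ppc += 1
    return wpc, ppc, patch_sizes[:n_patches]


def simulate_continuous_labelling(
    params: CryptDriftParams,
    supply: MutationSupply,
    fp: FissionParams,
    ages,
    crypts_per_patient,
    cfg: SimConfig,
) -> list[dict]:
    """Generative twin of the continuous-labelling + fission model.

    Per patient, mutant clones arise as a Poisson process at rate
    ``kappa = alpha*lam*N`` per crypt, drift to extinction or fixation, and
    fixed clones then expand by Yule fission. Returns one dict per patient
    with WPC count (mutant crypts in fixed patches), PPC count and the
    per-patch sizes.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    crypts = np.atleast_1d(np.asarray(crypts_per_patient, dtype=np.int64))
    if ages.shape != crypts.shape:
        raise ValueError("ages and crypts_per_patient must have equal length")
    kappa = supply.kappa(params)
    out = []
    for i, (age, C) in enumerate(zip(ages, crypts)):
        wpc, ppc, sizes = _cohort_kernel(
            params.n_stem,
            params.beta,
            params.gamma,
            kappa,
            fp.rho,
            age,
            C,
            (cfg.seed + 7919 * i) % 2**31,
        )
        out.append(
            {"age": float(age), "crypts": int(C), "wpc": int(wpc), "ppc": int(ppc),
             "patch_sizes": np.asarray(sizes)}
        )
    return out


# ---------------------------------------------------------------------------
# spatial fission-fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CryptLattice:
    """Local toroidal grid on which each mutant patch grows.

    ``dims`` bounds a single patch's footprint; wild-type crypts form the
    (implicit) background. 4-neighbour adjacency with toroidal wrap.
    """

    dims: tuple = (64, 64)

    def __post_init__(self) -> None:
        if len(self.dims) != 2 or min(self.dims) < 4:
            raise ValueError("lattice dims must be a 2-tuple, each >= 4")


_DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1))


class _Patch:
    """One mutant patch: full mutant crypts as occupied cells, plus partial
    crypts (mutant stem-cell fraction mid-drift) created by fusion."""

    __slots__ = ("cells", "partials", "dims")

    def __init__(self, dims):
        self.dims = dims
        c = (dims[0] // 2, dims[1] // 2)
        self.cells = {c}
        self.partials = {}  # cell -> clone size (stem cells) in 1..N-1

    def free_neighbour(self, cell, rng, placement):
        gx, gy = self.dims
        d = _DIRS[rng.integers(4)]
        if placement == "walk":
            # march along the chosen direction to the first free cell
            x, y = cell
            for _ in range(gx * gy):
                x, y = (x + d[0]) % gx, (y + d[1]) % gy
                if (x, y) not in self.cells and (x, y) not in self.partials:
                    return (x, y)
            return None
        # placement == "scan": first free cell among shuffled neighbours,
        # falling back to a ring search around the parent
        order = rng.permutation(4)
        for j in order:
            dx, dy = _DIRS[j]
            cand = ((cell[0] + dx) % gx, (cell[1] + dy) % gy)
            if cand not in self.cells and cand not in self.partials:
                return cand
        for radius in range(2, max(gx, gy)):
            ring = []
            for dx in range(-radius, radius + 1):
                for dy in range(-radius, radius + 1):
                    if max(abs(dx), abs(dy)) == radius:
                        cand = ((cell[0] + dx) % gx, (cell[1] + dy) % gy)
                        if cand not in self.cells and cand not in self.partials:
                            ring.append(cand)
            if ring:
                return ring[rng.integers(len(ring))]
        return None


def simulate_fission_fusion(
    lattice: CryptLattice,
    rho_fission: float,
    rho_fusion: float,
    slope: float,
    cfg: SimConfig,
    params: CryptDriftParams | None = None,
    placement: str = "walk",
) -> dict:
    """Patch-size distribution under crypt fission and fusion.

    Monoclonal mutant crypts appear at rate ``slope`` per field per year
    (``cfg.replicates`` is reinterpreted as the expected number of patch
    seeding events over ``cfg.t_max``; each seeds an independent patch at a
    uniform random time). Each full mutant crypt fissions at ``rho_fission``
    (daughter placed on an adjacent cell of the patch's local lattice) and
    undergoes fusion attempts at ``rho_fusion``: a random lattice neighbour
    is drawn; if it is mutant the two crypts merge (patch size - 1), if
    wild-type the mutant crypt becomes a partially populated crypt whose
    merged stem-cell pool starts at half mutant and resolves by continued
    drift (rejoining the patch on re-fixation, leaving it on extinction).

    Returns the relative patch-size distribution at ``cfg.t_max`` over
    patches with at least one full mutant crypt.
    """
    if params is None:
        params = CryptDriftParams(n_stem=7, lam=1.3)
    if placement not in ("walk", "scan"):
        raise ValueError("placement must be 'walk' or 'scan'")
    N = params.n_stem
    beta, gamma = params.beta, params.gamma
    rng = np.random.default_rng(cfg.seed)
    T = cfg.t_max
    n_seeds = rng.poisson(cfg.replicates)
    birth_times = np.sort(rng.uniform(0.0, T, n_seeds))

    sizes = []
    capacity = lattice.dims[0] * lattice.dims[1]
    for tb in birth_times:
        patch = _Patch(lattice.dims)
        t = tb
        while True:
            n_full = len(patch.cells)
            n_part = len(patch.partials)
            r_fis = rho_fission * n_full
            r_fus = rho_fusion * n_full
            r_drift = (beta + gamma) * n_part
            total = r_fis + r_fus + r_drift
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= T:
                break
            u = rng.uniform(0, total)
            cells = list(patch.cells)
            if u < r_fis:
                if n_full >= capacity - 1:
                    raise RuntimeError(
                        "patch outgrew the lattice; enlarge CryptLattice.dims"
                    )
                parent = cells[rng.integers(n_full)]
                target = patch.free_neighbour(parent, rng, placement)
                if target is not None:
                    patch.cells.add(target)
            elif u < r_fis + r_fus:
                crypt = cells[rng.integers(n_full)]
                d = _DIRS[rng.integers(4)]
                nb = ((crypt[0] + d[0]) % lattice.dims[0],
                      (crypt[1] + d[1]) % lattice.dims[1])
                if nb in patch.cells:
                    # mutant-mutant fusion: two crypts merge into one
                    patch.cells.discard(crypt)
                elif nb in patch.partials:
                    pass  # merging with a transient partial: ignore (rare)
                else:
                    # mutant-wild fusion: merged pool is half mutant
                    patch.cells.discard(crypt)
                    patch.partials[crypt] = max(1, N // 2)
            else:
                cell = list(patch.partials)[rng.integers(n_part)]
                n = patch.partials[cell]
                if rng.random() < beta / (beta + gamma):
                    n += 1
                else:
                    n -= 1
                if n == N:
                    del patch.partials[cell]
                    patch.cells.add(cell)
                elif n == 0:
                    del patch.partials[cell]
                else:
                    patch.partials[cell] = n
        if patch.cells:
            sizes.append(len(patch.cells))
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0:
        return {"sizes": sizes, "relative": np.zeros(0)}
    dist = np.bincount(sizes)[1:]
    return {"sizes": sizes, "relative": dist / dist.sum()}


# ---------------------------------------------------------------------------
# sequential double hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleHitConfig:
    """First-hit mutation rate, second-hit rate multiplier and its bias.

    The first mutation is neutral and arises at ``alpha1`` per mitosis; in
    cells already carrying it, a second mutation arises at ``alpha1 * fold``
    per mitosis and biases replacement with probability ``pr2``.
    """

    alpha1: float
    fold: float
    pr2: float

    def __post_init__(self) -> None:
        if self.alpha1 < 0:
            raise ValueError("alpha1 must be >= 0")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if not 0.5 <= self.pr2 <= 1.0:
            raise ValueError("pr2 must lie in [0.5, 1]")


@njit(cache=True)
def _double_hit_kernel(
    N, lam, alpha1, alpha2, pr2, report_times, reps, seed
):  # pragma: no cover
    np.random.seed(seed)
    R = report_times.shape[0]
    # per report time: partial1, mono1, partial2, mono2, mono1_with_mono2
    stats = np.zeros((R, 5), dtype=np.int64)
    for _ in range(reps):
        geno = np.zeros(N, dtype=np.int8)
        t = 0.0
        idx = 0
        total = N * lam  # one conflict per ring pair at rate lam
        while idx < R:
            dt = np.random.exponential(1.0 / total)
            t_new = t + dt
            while idx < R and report_times[idx] <= t_new:
                c1 = 0
                c2 = 0
                for i in range(N):
                    if geno[i] >= 1:
                        c1 += 1
                    if geno[i] == 2:
                        c2 += 1
                if c1 == N:
                    stats[idx, 1] += 1
                elif c1 > 0:
                    stats[idx, 0] += 1
                if c2 == N:
                    stats[idx, 3] += 1
                elif c2 > 0:
                    stats[idx, 2] += 1
                if c1 == N and c2 == N:
                    stats[idx, 4] += 1
                idx += 1
            if idx == R:
                break
            t = t_new
            i = np.random.randint(N)
            j = (i + 1) % N
            gi, gj = geno[i], geno[j]
            # winner of the neighbour conflict; genotype 2 wins with pr2
            if gi == gj:
                p_i = 0.5
            elif gi == 2:
                p_i = pr2
            elif gj == 2:
                p_i = 1.0 - pr2
            else:
                p_i = 0.5  # 1 vs 0: first hit is neutral
            if np.random.random() < p_i:
                daughter, loser = gi, j
            else:
                daughter, loser = gj, i
            # the daughter placed in the loser's position may mutate
            if daughter == 0:
                if np.random.random() < alpha1:
                    daughter = 1
            elif daughter == 1:
                if np.random.random() < alpha2:
                    daughter = 2
            geno[loser] = daughter
    return stats


def simulate_double_hit(
    params: CryptDriftParams, cfg2: DoubleHitConfig, cfg: SimConfig
) -> dict:
    """Sequential-mutation simulation of a single crypt's stem-cell ring.

    ``N`` stem cells on a ring start unmutated; neighbour conflicts
    (mitoses) occur at rate ``lam`` per pair. A neutral first mutation
    arises at ``alpha1`` per mitosis; cells carrying it acquire a second,
    drift-biasing mutation at ``alpha1*fold`` per mitosis. Two tracks are
    scored at each report time across replicate crypts: crypts partial or
    monoclonal for mutation 1 (regardless of mutation 2 — what a
    single-antibody stain measures) and for the double mutant.
    """
    times = np.asarray(cfg.report_times, dtype=float)
    stats = _double_hit_kernel(
        params.n_stem,
        params.lam,
        cfg2.alpha1,
        min(1.0, cfg2.alpha1 * cfg2.fold),
        cfg2.pr2,
        times,
        cfg.replicates,
        cfg.seed,
    )
    frac = stats / cfg.replicates
    with np.errstate(invalid="ignore", divide="ignore"):
        double_given_fixed = np.where(stats[:, 1] > 0, stats[:, 4] / stats[:, 1], np.nan)
    return {
        "t": times,
        "partial1": frac[:, 0],
        "mono1": frac[:, 1],
        "partial2": frac[:, 2],
        "mono2": frac[:, 3],
        "frac_fixed1_with_mut2": double_given_fixed,
        "counts": stats,
    }
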