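# Methods

Notation: `N` functional stem cells per crypt, `lambda` stem-cell
replacement rate (per stem cell per year), `P_R` probability that a mutant
wins a replacement event (0.5 = neutral), `alpha` mutation rate per
mitosis, `rho` crypt fission rate per year, `t` age in years.

## 1. Intra-crypt drift (`cryptdrift.drift`)

A mutant clone of size `m` in a crypt of `N` stem cells evolves as a
birth–death chain on {0, …, N} with rates

```
m -> m+1 at beta  * m * (N - m) / N,   beta  = 2 * lambda * P_R / N-normalised form
m -> m-1 at gamma * m * (N - m) / N,   gamma = 2 * lambda * (1 - P_R)
```

States 0 (loss) and N (fixation, i.e. monoclonal conversion) are
absorbing. The transient dynamics are computed from the exact spectral
(sine-series) solution of the tridiagonal generator; eigenvalues are

```
h_m = 4*sqrt(beta*gamma)*sin^2(pi*m / (2N)) + beta + gamma - 2*sqrt(beta*gamma)
```

The series implementation is validated in the tests against a dense
`scipy.linalg.expm` oracle of the full generator to 1e-12.

### Fixation probability

With bias ratio `r = gamma/beta = (1-P_R)/P_R`,

```
P_fix = (1 - r) / (1 - r^N)      (biased),      P_fix = 1/N  (neutral).
```

### Fixation times

Conditioned on eventual fixation, the chain is Doob h-transformed with
`h(m) = P_fix(m)`; the conditional hitting time of `N` from 1 is
phase-type with the transformed sub-generator, giving exact mean,
variance and quantiles. For neutral drift the conditional mean is
`(N^2 - 1) / (6 * lambda)`.

A second, population-level notion of "conversion time" conditions on
clone survival at time `t` rather than on eventual fixation: the quantile
is the `t` at which `P_N(t) / sum_{m>=1} P_m(t)` crosses the requested
level. Both are implemented (`fixation_time_quantiles` vs
`conversion_time_quantiles`); the survival-conditioned version matches
reported epidemiological median/90th-percentile conversion ages and is
the one used for reporting.

## 2. Continuous labelling

New clones arrive in each crypt as a Poisson process of rate
`kappa = alpha * lambda * N` (mutations per crypt per year). Because
clone fates are independent and almost all clones are lost quickly, the
expected fractions of partially and wholly populated crypts are

```
C_part(t)  = kappa * integral of sum_{0<m<N} P_m(u) du   -> plateau alpha*N*(N-1)/2  (neutral)
C_mono(t)  = kappa * integral of P_N(u) du               -> slope  Delta C_fix = kappa * P_fix
```

Neutral slope `= alpha * lambda`; the slope/plateau ratio
`2*lambda / (N*(N-1))` removes `alpha`. Given measured `alpha`, the pair
(slope, plateau) inverts in closed form to `(N, lambda)`
(`n_lambda_from_moments`); the grid posterior (`infer_n_lambda`)
performs the same inversion with full binomial likelihoods over an
`(N, lambda)` grid, optionally integrating over posterior draws of
`alpha`.

## 3. Crypt fission, patches and burden (`cryptdrift.fission`)

A fixed mutant crypt founds a patch that grows by fission as a Yule
process: a patch founded a time `s` ago has size `n` with probability
`e^{-rho s} (1 - e^{-rho s})^{n-1}`. With monoclonal crypts appearing at
constant rate `slope` per crypt per year, the expected fraction of crypts
in patches of size `n` at age `t` is

```
F_n(t) = slope * (1 - e^{-rho t})^n / (rho * n)
```

so that `sum_n F_n(t) = slope * t` exactly, and the normalised patch-size
distribution is `f_n = (1 - e^{-rho t})^n / (rho * n * t)`. The expected
mutant burden per 10^6 crypts is

```
B(t) = 1e6 * slope * (e^{rho t} - 1) / rho
```

The lifetime expansion coefficient `(e^{rho t} - 1)/(rho t)` compares a
fissioning mark against a fission-free mark of equal slope; fold changes
between marks multiply the `P_fix` ratio by this coefficient.

An exact patch distribution that accounts for the fixation lag is also
provided (`cohort_patch_distribution_exact`): it convolves the
monoclonal-conversion density `kappa * P_N(u)` with the Yule kernel over
founding times. The closed form above is this convolution with the lag
collapsed to a point mass; they agree to a few percent for human
parameter values.

### Doublet correction

Adjacent same-mark singletons can abut by chance and masquerade as
2-patches. For a patient with `k` observed clones among `C` crypts the
expected number of chance doublets is `D = (1/k) * sum_i delta_i/(C-i)`
with neighbourhood size `delta`; the small-`k` approximation is
`delta*(k-1)/(2C)`. The patch-size likelihood optionally moves mass `D`
from size-1 to size-2 counts before fitting.

## 4. Stochastic simulators (`cryptdrift.simulate`)

Exact Gillespie implementations serve as oracles for every analytic
result: the single-clone drift chain, the continuously labelled crypt
population, patch growth by fission, a spatial fission–fusion model on a
1-D crypt array (fusion merges adjacent crypts; placement rules for the
fused product are compared against pure fission by distributional
distance), and a sequential double-hit simulator in which a second
mutation can only arise at mitoses of the first clone's lineage — used to
quantify how strongly background drift gates the accumulation of second
hits and how a fold-increase in the second-hit supply or bias propagates
to double-mutant crypts.

## 5. Hierarchical Bayesian inference (`cryptdrift.bayes`)

All models share one machinery: an emcee `EnsembleSampler` with a 0.8/0.2
mixture of differential-evolution and DE-snooker moves (these mix far
better than stretch moves in the correlated, funnel-shaped hierarchies),
walkers initialised from the prior near a data-informed centre, split
R-hat ≤ 1.05 and bulk ESS ≥ 400 (arviz) as convergence gates, and
`PosteriorSummary` objects carrying median, 95 % CI, margin of error and
diagnostics.

* **TA mutation rate**: per-block mutant goblet counts `k ~ Binomial(G, q)`
  with `q ~ TruncNormal(alpha_i, sigma_error)` marginalised by 40-node
  Gauss–Legendre quadrature on an adaptively chosen window;
  `alpha_i ~ N(mu_alpha, sigma_alpha)` across patients.
* **WPC accumulation**: `WPC_i ~ Binomial(C_i, a_i * (t_i - t0))` with
  patient slopes `a_i ~ N(mu_a, sigma_a)` and a shared onset offset `t0`.
* **PPC plateau**: `PPC_i ~ Binomial(C_i, b_i)`, `b_i ~ N(mu_b, sigma_b)`.
* **Patch sizes**: per-patient multinomial over `f_n(t_i; rho_i)` with
  `rho_i ~ N(mu_rho, sigma_rho)`, optional doublet correction.

Scale parameters carry weak Gamma priors; all positivity constraints are
enforced in the log-posterior. Twenty-replicate simulation-based
calibration suites in `tests/test_acceptance.py` check that the 95 % CIs
cover the generating truth at the nominal rate for every model.

## 6. KRAS amplicon pipeline (`cryptdrift.kras`)

Merged reads are kept when they start with the forward primer, end with
the reverse-complement of the reverse primer, and are at most 164 bp
(amplicon length 159 bp). Nucleotide counts per position feed a
run-level background (mean and SD of non-reference fractions across all
samples in the run). A variant is **called** when, in *both* technical
replicates, the raw non-reference fraction is at least 4x the background
mean *or* exceeds `background mean + 3.209 * SD`, with at least 10
variant reads. Corrected MAF = mean raw fraction − background mean.

A corrected allele fraction `f` in a biopsy of `C` crypts implies a
mutant patch of `m = 2*C*f` crypts (heterozygous mutation); patches below
the detection threshold `theta` are censored at
`n_limit = ceil(2*C*theta) - 1`.

The cohort model is a per-sample categorical over patch size: with
`slope = n_mutations * Delta C_fix` the probabilities are
`F_0 = 1 - slope*t` (no detectable mutation) and `F_n` from the fission
closed form, which sum to one exactly. `rho` and `Delta C_fix` carry
half-normal priors; the posterior-predictive detection probability for a
future sample sums the `F_n` tail above its detection limit using the
series identity `sum_n x^n/n = -log(1-x)`.

## 7. Synthetic cohorts and the pipeline (`cryptdrift.synth`, `cryptdrift.pipeline`)

Every generator is the exact probabilistic twin of the model fitted to
its output (ages uniform on 8–93 y, crypt counts log-uniform 7e3–1e5,
binomial WPC/PPC, Poisson patch counts with iid Yule sizes and planted
chance doublets, beta-distributed sequencing background with multinomial
counts, power-law goblet-area calibration fit by isotonic regression).

`run_pipeline` chains generation → four fits → `(N, lambda)` inversion →
burden and lifetime-expansion report, writes `metrics.json` (6
significant figures, sorted keys — reruns are byte-identical), TSV
tables and figures, and wraps each stage so a failure reports the stage
name. `fold_change_report` states its baseline explicitly for each
comparison (bias-only: `P_fix` ratio; fission-only: expansion coefficient
vs a fission-free mark of equal slope; combined: their product).
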