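"""Hierarchical inference: from synthetic cohort to (N, lambda).

Generates a study-shaped cohort with known ground truth, fits the four
hierarchical models (TA mutation rate, WPC slope, PPC plateau, patch-size
fission rate) and derives the stem-cell number and replacement rate from
the moment relations and the grid posterior. Sampler lengths are reduced
for a quick demonstration; increase nsteps for production-quality chains.
"""

from cryptdrift import (
    CohortConfig,
    fit_patch_multinomial,
    fit_ppc_plateau,
    fit_ta_mutation_rate,
    fit_wpc_accumulation,
    generate_cohort,
    generate_ta_blocks,
    infer_n_lambda,
    n_lambda_from_moments,
)

NSTEPS = 1500

cohort, truth = generate_cohort(CohortConfig(seed=42, n_patients=25))
blocks, ta_truth = generate_ta_blocks(seed=43)
print(f"cohort: {len(cohort)} patients; truth N={truth['n_stem']}, "
      f"lam={truth['lam']}, alpha={truth['alpha']:.2e}, rho={truth['rho']}")

ta = fit_ta_mutation_rate(blocks, nsteps=NSTEPS, seed=1)
s = ta["mu_alpha"]
print(f"\nTA mutation rate: {s.median:.3e} +/- {s.me:.1e} "
      f"(truth {ta_truth['mu_alpha']:.2e}; rhat {s.rhat:.2f})")

wpc = fit_wpc_accumulation(cohort, nsteps=NSTEPS, seed=2)
s = wpc["mu_a"]
print(f"WPC slope Delta C_fix: {s.median:.3e} +/- {s.me:.1e} "
      f"(truth {truth['slope']:.2e}; rhat {s.rhat:.2f})")

ppc = fit_ppc_plateau(cohort, nsteps=NSTEPS, seed=3)
s = ppc["mu_b"]
print(f"PPC plateau C_part: {s.median:.3e} +/- {s.me:.1e} (rhat {s.rhat:.2f})")

patch = fit_patch_multinomial(cohort, nsteps=NSTEPS, seed=4)
s = patch["mu_rho"]
print(f"fission rate rho: {s.median:.4f} +/- {s.me:.4f} "
      f"(truth {truth['rho']}; rhat {s.rhat:.2f})")

n_stem, lam = n_lambda_from_moments(
    wpc["mu_a"].median, ppc["mu_b"].median, ta["mu_alpha"].median
)
print(f"\nmoment relations: N = {n_stem:.2f}, lambda = {lam:.2f}")

grid = infer_n_lambda(cohort, ta.chains["mu_alpha"].reshape(-1)[::50])
n_map, lam_map = grid.map_estimate
print(f"grid posterior: MAP N = {n_map:.0f}, lambda = {lam_map:.2f}; "
      f"95% CI lambda {grid.marginal_ci('lam')}")
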