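"""Gillespie simulators: oracles, fusion geometry and sequential hits.

Three stochastic engines: the single-crypt drift simulator (checked here
against the analytic clone-size series), the spatial fission-fusion
simulator (how much does crypt fusion distort patch sizes?), and the
double-hit simulator (when does a second mutation ride on the first?).
"""

import numpy as np

from cryptdrift import (
    CryptDriftParams,
    CryptLattice,
    DoubleHitConfig,
    FissionParams,
    SimConfig,
    clone_size_pmf,
    relative_patch_distribution,
    simulate_crypt_drift,
    simulate_double_hit,
    simulate_fission_fusion,
)

params = CryptDriftParams(7, 1.3)

res = simulate_crypt_drift(params, SimConfig(seed=1, replicates=50_000, t_max=5.0))
analytic = clone_size_pmf(params, 5.0)
print("clone-size pmf at t=5 y: simulated vs analytic")
for n in range(8):
    print(f"  n={n}: {res['pmf'][0][n]:.4f} vs {analytic[n]:.4f}")

print("\nfission-fusion (rho_fission=0.05/y, t=40 y):")
cfg = SimConfig(seed=2, replicates=4_000, t_max=40.0)
no_fusion = simulate_fission_fusion(CryptLattice(), 0.05, 0.0, 0.0, cfg)
with_fusion = simulate_fission_fusion(CryptLattice(), 0.05, 0.05, 0.0, cfg)
f = relative_patch_distribution(FissionParams(0.05), 40.0)
print("  size   analytic   fusion=0   fusion=fission")
for n in range(5):
    a = f[n] if n < f.size else 0.0
    b = no_fusion["relative"][n] if n < no_fusion["relative"].size else 0.0
    c = with_fusion["relative"][n] if n < with_fusion["relative"].size else 0.0
    print(f"  {n + 1:4d}   {a:8.4f}   {b:8.4f}   {c:8.4f}")

print("\ndouble hit (alpha1=2e-4/mitosis, 30 y, 20,000 crypts):")
cfg = SimConfig(seed=3, replicates=20_000, t_max=30.0, report_times=(30.0,))
for fold in (1e2, 1e4, 1e5):
    r = simulate_double_hit(params, DoubleHitConfig(2e-4, fold, 0.95), cfg)
    frac = r["frac_fixed1_with_mut2"][0]
    print(f"  fold {fold:8.0f}: mono1 {r['mono1'][0]:.4f}, "
          f"fixed clones carrying hit 2: {np.nan_to_num(frac):.2f}")
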