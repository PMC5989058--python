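"""Crypt fission: patch sizes, mutant burden and lifetime expansion.

Once fixed, a mutant crypt fissions at rate rho per year and the clone
spreads into a patch. This script evaluates the Yule patch-size law, the
cohort patch distribution, the chance-doublet correction applied before
fitting fission rates, burden growth with age, and the fold-change /
expansion-coefficient comparisons between marks.
"""

from cryptdrift import (
    CryptDriftParams,
    FissionParams,
    burden,
    doublet_correction,
    fold_change_report,
    relative_patch_distribution,
    yule_patch_pmf,
)
from cryptdrift.params import (
    FISSION_RATE_KRAS,
    FISSION_RATE_MPAS,
    FISSION_RATE_STAG2,
    NORMAL_FISSION_RATE,
)

fp = FissionParams(NORMAL_FISSION_RATE)
print(f"Yule patch-size pmf at rho={fp.rho}/y, t=60 y (single founder):")
print("  sizes 1-5:", [round(float(x), 4) for x in yule_patch_pmf(fp, 60.0, range(1, 6))])

f = relative_patch_distribution(fp, 60.0)
print("relative patch distribution f_n(60), sizes 1-5:",
      [round(float(x), 4) for x in f[:5]], f"(sums to {f.sum():.6f})")

d = doublet_correction(delta=6, k=40, C=30_000)
print(f"\nchance-doublet fraction for 40 clones in 30,000 crypts: "
      f"exact {d.exact:.5f}, approx {d.approx:.5f}")

print("\nmutant burden per million crypts (slope 5.85e-6/crypt/y):")
for age in (20, 40, 60, 80):
    print(f"  age {age}: {burden(5.85e-6, fp, age).burden:8.1f}")

neutral = CryptDriftParams(7, 1.3)
biased = CryptDriftParams(7, 1.3, p_r=0.99)
marks = {
    "neutral, no fission": (neutral, FissionParams(0.0)),
    "P_R=0.99 only": (biased, FissionParams(0.0)),
    "3x fission only": (neutral, FissionParams(3 * FISSION_RATE_MPAS)),
    "combined": (biased, FissionParams(3 * FISSION_RATE_MPAS)),
    "STAG2-like": (biased, FissionParams(FISSION_RATE_STAG2)),
    "KRAS-like": (biased, FissionParams(FISSION_RATE_KRAS)),
}
# fold changes at age 60 against the neutral fission-free baseline;
# expansion coefficients (c_exp column) against the same baseline
report = fold_change_report(marks, (neutral, FissionParams(0.0)), age=60.0)
print("\n" + report[["mark", "p_r", "rho", "fold_at_age", "c_exp"]].to_string(index=False))
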