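import numpy as np
import pytest

from cryptdrift import (
    CohortConfig,
    CryptDriftParams,
    FissionParams,
    MutationSupply,
    fit_goblet_mapping,
    generate_cohort,
    generate_goblet_calibration,
    generate_maf_observations,
    generate_ta_blocks,
)


def test_zero_mutation_rate_gives_zero_counts():
    cfg = CohortConfig(supply=MutationSupply(0.0), n_patients=10, seed=1)
    cohort, _ = generate_cohort(cfg)
    assert all(o.wpc == 0 and o.ppc == 0 and not o.patch_sizes for o in cohort)


def test_cohort_determinism_and_independence():
    cfg = CohortConfig(seed=2, n_patients=10)
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(cfg)
    assert [(o.age, o.wpc, o.ppc) for o in a] == [(o.age, o.wpc, o.ppc) for o in b]
    c, _ = generate_cohort(CohortConfig(seed=3, n_patients=10))
    assert [o.age for o in a] != [o.age for o in c]


def test_cohort_inclusion_rule_and_ranges():
    cohort, _ = generate_cohort(CohortConfig(seed=4, n_patients=50))
    for o in cohort:
        assert o.crypts >= 7_000
        assert 8.0 <= o.age <= 93.0
    with pytest.raises(ValueError):
        CohortConfig(crypt_range=(1_000, 5_000))


def test_cohort_regression_recovers_slope():
    """WPC fraction vs age over 200 patients recovers the generator slope
    within 2 standard errors (weighted least squares through the lag)."""
    cfg = CohortConfig(seed=5, n_patients=200)
    cohort, truth = generate_cohort(cfg)
    ages = np.array([o.age for o in cohort])
    y = np.array([o.wpc / o.crypts for o in cohort])
    w = np.array([o.crypts for o in cohort], dtype=float)
    X = np.column_stack([np.ones_like(ages), ages])
    W = np.diag(w)
    beta, cov = np.linalg.solve(X.T @ W @ X, X.T @ W @ y), None
    resid = y - X @ beta
    s2 = (w * resid**2).sum() / (len(y) - 2)
    cov = s2 * np.linalg.inv(X.T @ W @ X)
    se = np.sqrt(cov[1, 1])
    assert abs(beta[1] - truth["slope"]) < 2 * se + 0.05 * truth["slope"]


def test_cohort_default_scales_match_study_orders():
    """Defaults give WPC fractions of order 1e-4 at age ~60 and PPC near
    the 1e-4 plateau."""
    cohort, _ = generate_cohort(CohortConfig(seed=6, n_patients=300))
    mid = [o for o in cohort if 50 <= o.age <= 70]
    wpc = np.mean([o.wpc / o.crypts for o in mid])
    ppc = np.mean([o.ppc / o.crypts for o in mid])
    assert 1e-4 < wpc < 1e-3
    assert 3e-5 < ppc < 3e-4


def test_ta_blocks_expected_count():
    blocks, truth = generate_ta_blocks(
        sigma_alpha=1e-7, sigma_error=1e-7, n_patients=30, blocks_per_patient=5, seed=7
    )
    mean_k = np.mean([b.k for b in blocks])
    # E[k] = mu_alpha * E[G] ~ 4.44e-6 * 1.5e6 * exp(0.25^2/2)
    expect = 4.44e-6 * 1.5e6 * np.exp(0.25**2 / 2)
    assert mean_k == pytest.approx(expect, rel=0.2)
    assert len(blocks) == 150
    assert truth["mu_alpha"] == 4.44e-6


def test_ta_blocks_default_screen_size():
    blocks, _ = generate_ta_blocks(seed=8)
    assert len(blocks) == 27  # 9 patients, ~26 blocks as in the screen


def test_goblet_calibration_monotone_fit():
    table = generate_goblet_calibration(seed=9)
    assert len(table) == 274
    fit = fit_goblet_mapping(table)
    grid = np.linspace(table.crypt_area.min(), table.crypt_area.max(), 200)
    pred = fit(grid)
    assert np.all(np.diff(pred) >= 0)  # monotone non-decreasing
    # totals from fitted vs true mapping differ < 5% at default noise
    tot_fit = fit(table.crypt_area).sum()
    tot_true = table.true_count.sum()
    assert abs(tot_fit - tot_true) / tot_true < 0.05


def test_goblet_zero_noise_interpolates():
    table = generate_goblet_calibration(noise_sd=0.0, seed=10)
    fit = fit_goblet_mapping(table)
    pred = fit(table.crypt_area)
    rel = np.abs(pred - table.true_count) / table.true_count
    assert rel.max() < 0.01


def test_maf_observations_determinism_and_truth():
    a, ta = generate_maf_observations(seed=11)
    b, _ = generate_maf_observations(seed=11)
    assert [o.f_allele for o in a] == [o.f_allele for o in b]
    assert ta["rho"] == 0.07
    detected = [o for o in a if o.f_allele > 0]
    for o in detected:
        assert o.m > ta["n_limit"]


def test_cohort_patch_doublets_present():
    """With many clones per patient some chance doublets get planted."""
    cfg = CohortConfig(
        supply=MutationSupply(5e-4), fission=FissionParams(0.0), seed=12, n_patients=20
    )
    cohort, _ = generate_cohort(cfg)
    sizes = [g for o in cohort for g in o.patch_sizes]
    assert sizes, "expected clones at elevated mutation rate"
    assert any(g == 2 for g in sizes)  # fission is off: only chance doublets
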