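import math

import numpy as np
import pytest

from cryptdrift import (
    CryptDriftParams,
    FissionParams,
    MutationSupply,
    burden,
    cohort_patch_distribution,
    cohort_patch_distribution_exact,
    doublet_correction,
    expansion_coefficient,
    relative_patch_distribution,
    yule_patch_pmf,
)
from cryptdrift.drift import label_kinetics, mean_fixation_time
from cryptdrift.params import FISSION_RATE_STAG2, NORMAL_FISSION_RATE

FP = FissionParams(0.007)


def test_yule_pmf_normalizes_and_mean():
    n = np.arange(1, 400)
    for rho, t in ((0.007, 60), (0.07, 40), (0.2, 10)):
        fp = FissionParams(rho)
        p = yule_patch_pmf(fp, t, n)
        assert p.sum() == pytest.approx(1.0, abs=1e-8)
        assert float(np.sum(n * p)) == pytest.approx(math.exp(rho * t), rel=1e-6)


def test_yule_pmf_geometric_for_single_founder():
    fp = FissionParams(0.05)
    t = 10.0
    q = 1 - math.exp(-0.05 * t)
    p = yule_patch_pmf(fp, t, [1, 2, 5])
    assert p[0] == pytest.approx(1 - q)
    assert p[1] == pytest.approx((1 - q) * q)
    assert p[2] == pytest.approx((1 - q) * q**4)


def test_yule_pmf_larger_founder():
    fp = FissionParams(0.05, n0=3)
    p = yule_patch_pmf(fp, 5.0, [1, 2, 3, 4])
    assert p[0] == 0.0 and p[1] == 0.0
    assert p[2] == pytest.approx(math.exp(-3 * 0.05 * 5.0))
    assert p[3] > 0


def test_yule_pmf_zero_time_is_point_mass():
    p = yule_patch_pmf(FP, 0.0, [1, 2, 3])
    np.testing.assert_allclose(p, [1.0, 0.0, 0.0])


def test_relative_distribution_sums_to_one():
    for rho, t in ((0.007, 60), (0.0215, 70), (0.07, 80)):
        f = relative_patch_distribution(FissionParams(rho), t)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(f) < 0)  # strictly decreasing in n


def test_cohort_distribution_closed_form():
    slope, t = 5.85e-6, 60.0
    F = cohort_patch_distribution(slope, FP, t, n_max=5)
    q = 1 - math.exp(-FP.rho * t)
    for i in range(5):
        assert F[i] == pytest.approx(slope * q ** (i + 1) / (FP.rho * (i + 1)))
    # total patches per crypt equals slope * t exactly
    full = cohort_patch_distribution(slope, FP, t)
    assert full.sum() == pytest.approx(slope * t, rel=1e-9)


def test_cohort_distribution_zero_fission_limit():
    slope, t = 5.85e-6, 60.0
    F = cohort_patch_distribution(slope, FissionParams(0.0), t, n_max=3)
    np.testing.assert_allclose(F, [slope * t, 0.0, 0.0], rtol=1e-9)


def test_burden_closed_form_and_components():
    slope, t = 5.85e-6, 60.0
    b = burden(slope, FP, t)
    assert b.burden == pytest.approx(1e6 * slope * math.expm1(FP.rho * t) / FP.rho)
    # truncated component sum converges to the closed form
    assert b.components.sum() == pytest.approx(b.burden, rel=1e-9)
    b0 = burden(slope, FissionParams(0.0), t)
    assert b0.burden == pytest.approx(1e6 * slope * t)


def test_exact_patch_distribution_matches_lagged_closed_form():
    """The convolution over fixation times equals the closed form shifted
    by the mean fixation lag, to a few percent at adult ages."""
    params = CryptDriftParams(7, 1.3)
    supply = MutationSupply(1e-4)
    lk = label_kinetics(params, supply)
    t0 = mean_fixation_time(params)
    for t in (40.0, 70.0):
        exact = cohort_patch_distribution_exact(params, supply, FP, t, n_max=4)
        lagged = cohort_patch_distribution(lk.slope, FP, t - t0, n_max=4)
        np.testing.assert_allclose(exact, lagged, rtol=0.08)
        naive = cohort_patch_distribution(lk.slope, FP, t, n_max=4)
        assert naive[0] > exact[0]  # ignoring the lag overestimates


def test_doublet_correction_exact_vs_approx():
    d = doublet_correction(6, 40, 30_000)
    # exact (1/k) sum delta*i/(C-i) vs approx delta*(k-1)/(2C)
    i = np.arange(1, 40)
    assert d.exact == pytest.approx(float(np.sum(6 * i / (30_000 - i))) / 40)
    assert d.approx == pytest.approx(6 * 39 / 60_000)
    assert d.exact == pytest.approx(d.approx, rel=2e-3)
    with pytest.raises(ValueError):
        doublet_correction(6, 0, 100)
    with pytest.raises(ValueError):
        doublet_correction(6, 100, 100)


def test_expansion_coefficient_identity_and_frozen_value():
    neutral = CryptDriftParams(7, 1.3)
    same = (neutral, FissionParams(NORMAL_FISSION_RATE))
    assert expansion_coefficient(same, same) == pytest.approx(1.0, rel=1e-9)
    stag2 = (CryptDriftParams(7, 1.3, p_r=0.99), FissionParams(FISSION_RATE_STAG2))
    c_exp = expansion_coefficient(stag2, same, horizon=100.0)
    assert c_exp == pytest.approx(12.72, abs=0.02)  # frozen oracle value
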