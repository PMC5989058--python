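import numpy as np
import pytest

from cryptdrift import (
    CryptDriftParams,
    MutationSupply,
    clone_size_pmf,
    continuous_labelling,
    conversion_time_quantiles,
    fixation_probability,
    fixation_time_quantiles,
    label_kinetics,
    mean_fixation_time,
    monoclonal_probability,
)

NEUTRAL = CryptDriftParams(7, 1.3)
SUPPLY = MutationSupply(4.44e-6)


@pytest.mark.parametrize("n_stem", [2, 3, 5, 7, 10])
@pytest.mark.parametrize("p_r", [0.5, 0.3, 0.8])
@pytest.mark.parametrize("t", [0.1, 1.0, 5.0, 30.0])
def test_series_matches_generator_exponential(n_stem, p_r, t):
    p = CryptDriftParams(n_stem, 1.3, p_r=p_r)
    series = clone_size_pmf(p, t, method="series")
    exact = clone_size_pmf(p, t, method="expm")
    np.testing.assert_allclose(series, exact, atol=1e-10)


def test_pmf_normalized_and_boundaries():
    for t in (0.0, 2.0, 100.0):
        p = clone_size_pmf(NEUTRAL, t)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)
    p0 = clone_size_pmf(NEUTRAL, 0.0)
    assert p0[1] == pytest.approx(1.0, abs=1e-9)
    p_inf = clone_size_pmf(NEUTRAL, 1e4)
    assert p_inf[-1] == pytest.approx(1.0 / 7, abs=1e-9)
    assert p_inf[0] == pytest.approx(6.0 / 7, abs=1e-9)


def test_pure_boundary_biases_use_generator_route():
    up = CryptDriftParams(5, 1.0, p_r=1.0)
    p = clone_size_pmf(up, 50.0)
    assert p[-1] == pytest.approx(1.0, abs=1e-9)
    down = CryptDriftParams(5, 1.0, p_r=0.0)
    p = clone_size_pmf(down, 50.0)
    assert p[0] == pytest.approx(1.0, abs=1e-9)


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        clone_size_pmf(NEUTRAL, -0.1)


def test_fixation_probability_formulas():
    assert fixation_probability(NEUTRAL) == pytest.approx(1.0 / 7)
    biased = CryptDriftParams(7, 1.3, p_r=0.99)
    r = biased.gamma / biased.beta
    assert fixation_probability(biased) == pytest.approx((1 - r) / (1 - r**7))
    # long-time pmf agrees with the formula
    p = clone_size_pmf(biased, 1e3)
    assert p[-1] == pytest.approx(fixation_probability(biased), abs=1e-9)
    assert fixation_probability(CryptDriftParams(7, 1.3, p_r=0.0)) == 0.0
    assert fixation_probability(CryptDriftParams(7, 1.3, p_r=1.0)) == 1.0


def test_monoclonal_probability_matches_pmf():
    ts = np.array([0.5, 3.0, 10.0])
    pN = monoclonal_probability(NEUTRAL, ts)
    expected = [clone_size_pmf(NEUTRAL, t)[-1] for t in ts]
    np.testing.assert_allclose(pN, expected, atol=1e-12)


def test_continuous_labelling_neutral_kinetics():
    lk = label_kinetics(NEUTRAL, SUPPLY)
    # slope = alpha*lam, plateau = alpha*N(N-1)/2 for neutral drift
    assert lk.slope == pytest.approx(4.44e-6 * 1.3, rel=1e-12)
    assert lk.plateau == pytest.approx(4.44e-6 * 21.0, rel=1e-9)
    assert lk.ratio == pytest.approx(2 * 1.3 / 42.0, rel=1e-9)
    # large-t curve approaches slope*(t - t0) and the plateau
    t = 300.0
    c_part, c_mono = continuous_labelling(NEUTRAL, SUPPLY, t)
    assert c_part == pytest.approx(lk.plateau, rel=1e-9)
    assert c_mono == pytest.approx(lk.slope * (t - lk.t0), rel=1e-9)


def test_continuous_labelling_quadrature_oracle():
    """C_partial and C_mono are Poisson-arrival convolutions of the pmf."""
    from scipy.integrate import quad

    kappa = SUPPLY.kappa(NEUTRAL)
    for t in (2.0, 20.0):
        part_q = kappa * quad(
            lambda s: clone_size_pmf(NEUTRAL, s)[1:-1].sum(), 0, t, limit=200
        )[0]
        mono_q = kappa * quad(
            lambda s: clone_size_pmf(NEUTRAL, s)[-1], 0, t, limit=200
        )[0]
        c_part, c_mono = continuous_labelling(NEUTRAL, SUPPLY, t)
        assert c_part == pytest.approx(part_q, rel=1e-8)
        assert c_mono == pytest.approx(mono_q, rel=1e-8)


def test_continuous_labelling_scales_linearly_in_alpha():
    c1 = continuous_labelling(NEUTRAL, MutationSupply(1e-6), 40.0)
    c2 = continuous_labelling(NEUTRAL, MutationSupply(2e-6), 40.0)
    assert c2[0] == pytest.approx(2 * c1[0])
    assert c2[1] == pytest.approx(2 * c1[1])


def test_continuous_labelling_rejects_boundary_bias():
    with pytest.raises(ValueError):
        continuous_labelling(CryptDriftParams(7, 1.3, p_r=1.0), SUPPLY, 10.0)


def test_mean_fixation_time_neutral_closed_form():
    # (N^2 - 1) / (6 lam)
    assert mean_fixation_time(NEUTRAL) == pytest.approx(48 / 7.8, rel=1e-9)
    assert mean_fixation_time(CryptDriftParams(5, 2.0)) == pytest.approx(
        24 / 12.0, rel=1e-9
    )


def test_fixation_time_quantiles_frozen_and_monotone():
    q = fixation_time_quantiles(NEUTRAL, (0.25, 0.5, 0.9))
    assert np.all(np.diff(q) > 0)
    # frozen values of the conditioned-chain phase-type quantiles
    assert q[1] == pytest.approx(5.10, abs=0.02)
    assert q[2] == pytest.approx(11.44, abs=0.02)
    with pytest.raises(ValueError):
        fixation_time_quantiles(NEUTRAL, (0.0,))


def test_conversion_time_quantiles_frozen():
    t50, t90 = conversion_time_quantiles(NEUTRAL, (0.5, 0.9))
    assert t50 == pytest.approx(6.75, abs=0.02)
    assert t90 == pytest.approx(13.93, abs=0.02)
    # scaling lam rescales times inversely
    fast = CryptDriftParams(7, 2.6)
    t50f, _ = conversion_time_quantiles(fast, (0.5, 0.9))
    assert t50f == pytest.approx(t50 / 2.0, rel=1e-6)
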