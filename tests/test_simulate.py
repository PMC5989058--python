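import numpy as np
import pytest
from scipy import stats

from cryptdrift import (
    CryptDriftParams,
    CryptLattice,
    DoubleHitConfig,
    FissionParams,
    MutationSupply,
    SimConfig,
    clone_size_pmf,
    continuous_labelling,
    relative_patch_distribution,
    simulate_continuous_labelling,
    simulate_crypt_drift,
    simulate_double_hit,
    simulate_fission_fusion,
    simulate_fixation_times,
)
from cryptdrift.drift import fixation_probability, mean_fixation_time

NEUTRAL = CryptDriftParams(7, 1.3)


def _gof_pvalue(counts, probs):
    """Chi-square GOF with low-expectation categories pooled."""
    n = counts.sum()
    expected = probs * n
    order = np.argsort(expected)
    counts, expected = counts[order].astype(float), expected[order]
    while expected.size > 2 and expected[0] < 5:
        expected[1] += expected[0]
        counts[1] += counts[0]
        expected, counts = expected[1:], counts[1:]
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return stats.chi2.sf(chi2, df=expected.size - 1)


def test_drift_simulation_matches_series():
    cfg = SimConfig(seed=11, replicates=40_000, t_max=5.0, report_times=(1.0, 5.0))
    res = simulate_crypt_drift(NEUTRAL, cfg)
    for i, t in enumerate(res["t"]):
        p = clone_size_pmf(NEUTRAL, t)
        assert _gof_pvalue(res["counts"][i], p) > 1e-3


def test_drift_simulation_biased():
    biased = CryptDriftParams(5, 1.0, p_r=0.8)
    cfg = SimConfig(seed=12, replicates=40_000, t_max=3.0)
    res = simulate_crypt_drift(biased, cfg)
    p = clone_size_pmf(biased, 3.0)
    assert _gof_pvalue(res["counts"][0], p) > 1e-3


def test_simulation_deterministic_in_seed():
    cfg = SimConfig(seed=13, replicates=2_000, t_max=2.0)
    a = simulate_crypt_drift(NEUTRAL, cfg)
    b = simulate_crypt_drift(NEUTRAL, cfg)
    np.testing.assert_array_equal(a["counts"], b["counts"])
    c = simulate_crypt_drift(NEUTRAL, SimConfig(seed=14, replicates=2_000, t_max=2.0))
    assert not np.array_equal(a["counts"], c["counts"])


def test_fixation_times_match_conditioned_chain():
    cfg = SimConfig(seed=15, replicates=60_000)
    times = simulate_fixation_times(NEUTRAL, cfg)
    # fixation fraction ~ 1/N
    frac = times.size / cfg.replicates
    se = np.sqrt((1 / 7) * (6 / 7) / cfg.replicates)
    assert frac == pytest.approx(fixation_probability(NEUTRAL), abs=4 * se)
    # conditional mean ~ (N^2-1)/(6 lam)
    mean = mean_fixation_time(NEUTRAL)
    assert times.mean() == pytest.approx(mean, abs=4 * times.std() / np.sqrt(times.size))


def test_cohort_simulation_matches_closed_forms():
    supply = MutationSupply(2e-4)
    fp = FissionParams(0.0)
    ages = [60.0] * 8
    crypts = [50_000] * 8
    cfg = SimConfig(seed=16, replicates=1)
    sims = simulate_continuous_labelling(NEUTRAL, supply, fp, ages, crypts, cfg)
    c_part, c_mono = continuous_labelling(NEUTRAL, supply, 60.0)
    tot_c = sum(s["crypts"] for s in sims)
    ppc = sum(s["ppc"] for s in sims) / tot_c
    wpc = sum(s["wpc"] for s in sims) / tot_c
    assert ppc == pytest.approx(c_part, rel=0.15)
    assert wpc == pytest.approx(c_mono, rel=0.15)


def test_fusion_free_patches_match_relative_distribution():
    fp = FissionParams(0.05)
    t = 40.0
    cfg = SimConfig(seed=17, replicates=3_000, t_max=t)
    res = simulate_fission_fusion(CryptLattice(), fp.rho, 0.0, slope=0.0, cfg=cfg)
    f = relative_patch_distribution(fp, t)
    nmax = res["relative"].size
    counts = np.round(res["relative"] * res["sizes"].size).astype(int)
    probs = np.append(f[: nmax - 1], f[nmax - 1 :].sum())
    assert _gof_pvalue(counts, probs[:nmax] / probs[:nmax].sum()) > 1e-3


def test_fission_fusion_placement_rules_agree():
    cfg = SimConfig(seed=18, replicates=4_000, t_max=40.0)
    a = simulate_fission_fusion(CryptLattice(), 0.05, 0.05, 0.0, cfg, placement="walk")
    b = simulate_fission_fusion(CryptLattice(), 0.05, 0.05, 0.0, cfg, placement="scan")
    # the two geometry conventions give statistically indistinguishable
    # patch-size distributions (two-sample chi-square, sizes pooled at >=4)
    nmax = 4
    ca = np.bincount(np.minimum(a["sizes"], nmax), minlength=nmax + 1)[1:]
    cb = np.bincount(np.minimum(b["sizes"], nmax), minlength=nmax + 1)[1:]
    _, p, _, _ = stats.chi2_contingency(np.array([ca, cb]))
    assert p > 1e-3
    with pytest.raises(ValueError):
        simulate_fission_fusion(CryptLattice(), 0.05, 0.0, 0.0, cfg, placement="spiral")


def test_double_hit_smoke_and_tracks_order():
    cfg2 = DoubleHitConfig(alpha1=5e-3, fold=10.0, pr2=0.95)
    cfg = SimConfig(seed=19, replicates=3_000, t_max=30.0, report_times=(10.0, 30.0))
    res = simulate_double_hit(NEUTRAL, cfg2, cfg)
    # mutation-1 staining sees at least as many crypts as the double mutant
    assert np.all(res["mono1"] >= res["mono2"])
    assert res["mono1"][-1] > 0
    # determinism
    res2 = simulate_double_hit(NEUTRAL, cfg2, cfg)
    np.testing.assert_array_equal(res["counts"], res2["counts"])


def test_double_hit_config_validation():
    with pytest.raises(ValueError):
        DoubleHitConfig(alpha1=-1e-6, fold=10, pr2=0.9)
    with pytest.raises(ValueError):
        DoubleHitConfig(alpha1=1e-6, fold=0.5, pr2=0.9)
    with pytest.raises(ValueError):
        DoubleHitConfig(alpha1=1e-6, fold=10, pr2=0.3)
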