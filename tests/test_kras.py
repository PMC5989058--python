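import numpy as np
import pandas as pd
import pytest

from cryptdrift.kras import (
    AmpliconSet,
    MAFObservation,
    call_mutations,
    calls_to_frame,
    compute_run_background,
    count_nucleotides,
    filter_amplicons,
    fit_kras_model,
    largest_undetectable_patch,
    maf_to_patch,
)
from cryptdrift.synth import (
    KRAS_REFERENCE,
    AmpliconRunConfig,
    generate_amplicon_reads,
    generate_amplicon_run,
    generate_maf_observations,
)


def _aset(sequences):
    reads, fwd, rev = generate_amplicon_reads(0)
    return AmpliconSet("s", 1, "r", sequences, fwd, rev)


def test_filter_length_and_primers():
    good = KRAS_REFERENCE  # 159 bases, correct primers
    overlong = KRAS_REFERENCE + "ACGTACG"  # 166 bases
    missing_primer = "T" + KRAS_REFERENCE[1:]
    kept = filter_amplicons(_aset([good, overlong, missing_primer])).sequences
    assert kept == [good]


def test_filter_accepts_up_to_164():
    padded = KRAS_REFERENCE[:-24] + KRAS_REFERENCE[-24:]  # still 159
    assert len(padded) == 159
    kept = filter_amplicons(_aset([padded])).sequences
    assert kept == [padded]


def test_filter_empty_primer_errors():
    aset = _aset([KRAS_REFERENCE])
    aset.fwd_primer = ""
    with pytest.raises(ValueError):
        filter_amplicons(aset)


def test_count_identical_reads():
    table = count_nucleotides(["ACGT"] * 10)
    assert (table["depth"] == 10).all()
    assert table.loc[0, "A"] == 10 and table.loc[1, "C"] == 10
    assert table.loc[2, "G"] == 10 and table.loc[3, "T"] == 10


def test_count_planted_variant_frequency():
    reads = ["AAAA"] * 9_950 + ["ACAA"] * 50
    table = count_nucleotides(reads)
    freq = table.loc[1, "C"] / table.loc[1, "depth"]
    assert freq == pytest.approx(0.005)
    # column sums equal retained read count at every position
    assert (table[list("ACGT")].sum(axis=1) == 10_000).all()


def test_count_ambiguous_bases_discarded():
    table = count_nucleotides(["ANGT", "ACGT"])
    assert table.loc[1, "N"] == 1
    assert table.loc[1, "depth"] == 1  # ambiguous base excluded from depth


def _toy_tables(freq_c, depth, L=4):
    """Two replicate tables, all-A reference, C variant at position 2."""
    out = {}
    for rep in (1, 2):
        c = int(round(freq_c * depth))
        counts = np.zeros((L, 4), dtype=int)
        counts[:, 0] = depth
        counts[1, 0] = depth - c
        counts[1, 1] = c
        df = pd.DataFrame(counts, columns=list("ACGT"))
        df.insert(0, "position", np.arange(1, L + 1))
        df["N"] = 0
        df["depth"] = depth
        out[rep] = df
    return out


def _toy_background(mean_c=0.001, sd_c=0.0002, L=4):
    rows = []
    for pos in range(1, L + 1):
        for base in "ACGT":
            mu = mean_c if (pos == 2 and base == "C") else 0.0
            sd = sd_c if (pos == 2 and base == "C") else 0.0
            rows.append({"position": pos, "base": base, "bg_mean": mu, "bg_sd": sd})
    return pd.DataFrame(rows)


def test_call_rule_derived_example():
    # background mean 0.001, sd 0.0002; raw 0.005 at depth 10^4 in both reps
    calls = call_mutations({"s1": _toy_tables(0.005, 10_000)}, _toy_background(), "AAAA")
    called = [c for c in calls if c.called]
    assert len(called) == 1
    c = called[0]
    assert (c.position, c.alt) == (2, "C")
    assert c.corrected_maf == pytest.approx(0.004)
    assert c.pass_fold  # 0.005 >= 4 * 0.001


def test_call_requires_ten_reads():
    # raw 0.005 but only 9 variant reads (depth 1800)
    calls = call_mutations({"s1": _toy_tables(0.005, 1_800)}, _toy_background(), "AAAA")
    assert not any(c.called for c in calls)


def test_zero_variant_reads_not_called():
    calls = call_mutations({"s1": _toy_tables(0.0, 10_000)}, _toy_background(), "AAAA")
    assert calls == []


def test_call_depth_scaling_invariance_except_read_floor():
    bg = _toy_background()
    # frequencies unchanged under common depth scaling: 0.005 at 10^4 and 10^5
    for depth in (10_000, 100_000):
        calls = call_mutations({"s1": _toy_tables(0.005, depth)}, bg, "AAAA")
        assert any(c.called for c in calls)
    # same frequency at depth 1800 fails only through the absolute floor
    calls = call_mutations({"s1": _toy_tables(0.005, 1_800)}, bg, "AAAA")
    assert not any(c.called for c in calls)


def test_single_replicate_excluded_with_warning():
    tables = _toy_tables(0.005, 10_000)
    with pytest.warns(UserWarning):
        calls = call_mutations({"s1": {1: tables[1]}}, _toy_background(), "AAAA")
    assert calls == []


def test_replicate_discordance_blocks_call():
    tables = _toy_tables(0.005, 10_000)
    tables[2] = _toy_tables(0.0, 10_000)[2]
    calls = call_mutations({"s1": tables}, _toy_background(), "AAAA")
    assert not any(c.called for c in calls)


def test_calls_to_frame_schema():
    calls = call_mutations({"s1": _toy_tables(0.005, 10_000)}, _toy_background(), "AAAA")
    df = calls_to_frame(calls)
    assert list(df.columns) == [
        "sample", "pos", "ref", "alt", "raw_freq", "bg_mean", "bg_sd",
        "reads", "called", "corrected_maf",
    ]


def test_end_to_end_planted_runs():
    """Planted above-threshold variants: zero false negatives; pure
    background: zero calls, across seeded runs."""
    misses, false_calls = 0, 0
    for seed in range(10):
        cfg = AmpliconRunConfig(
            seed=seed, spikes={1: [(34, "A", 0.005)], 4: [(35, "T", 0.008)]}
        )
        samples, truth = generate_amplicon_run(cfg)
        bg = compute_run_background(
            {(s, r): t for s, reps in samples.items() for r, t in reps.items()}
        )
        calls = call_mutations(samples, bg, KRAS_REFERENCE)
        hits = {
            (c.sample, c.position, c.alt) for c in calls if c.called
        }
        for sample, pos, alt, _maf in truth["planted"]:
            if (sample, pos, alt) not in hits:
                misses += 1
        false_calls += sum(
            1
            for c in calls
            if c.called
            and (c.sample, c.position, c.alt)
            not in {(s, p, a) for s, p, a, _ in truth["planted"]}
        )
    assert misses == 0
    assert false_calls == 0


def test_maf_to_patch_examples():
    zero = MAFObservation("p", 60.0, 0.0, 150_000)
    assert maf_to_patch(zero) == 0
    obs = MAFObservation("p", 60.0, 1.44e-4, 150_000)
    assert maf_to_patch(obs) == 43
    assert obs.m == pytest.approx(2 * 150_000 * 1.44e-4)
    with pytest.raises(ValueError):
        MAFObservation("p", 60.0, 0.6, 150_000)


def test_largest_undetectable_patch():
    assert largest_undetectable_patch(150_000, 0.0) == 0
    assert largest_undetectable_patch(150_000, 1e-3) == 299
    assert largest_undetectable_patch(5_000, 1e-4) == 0


def test_q_vector_sums_to_one():
    obs, _ = generate_maf_observations(seed=0, n_patients=5)
    post = fit_kras_model(obs, nsteps=200, seed=0)
    for o in obs:
        for rho, dc in [(0.007, 1e-6), (0.07, 8e-5), (0.3, 2e-4)]:
            q = post.q_vector(rho, dc, o)
            assert sum(q) == pytest.approx(1.0, abs=1e-12)
            assert q[0] >= 0


def test_all_zero_cohort_flagged():
    obs = [MAFObservation(f"z{i}", 60.0, 0.0, 5_000) for i in range(5)]
    post = fit_kras_model(obs, nsteps=400, seed=1)
    assert post.flagged_prior_like
    # slope posterior hugs the truncated prior near zero
    assert post["delta_c_fix"].median < 1e-4


def test_kras_fit_recovers_rho():
    obs, truth = generate_maf_observations(seed=5)
    post = fit_kras_model(obs, nsteps=1500, seed=5)
    s = post["rho"]
    assert s.ci[0] < truth["rho"] < s.ci[1]
    s2 = post["delta_c_fix"]
    assert s2.ci[0] < truth["delta_c_fix"] < s2.ci[1]


def test_neutral_fission_predictive_cannot_reach_high_maf():
    """With rho fixed near the normal fission rate, the posterior
    predictive assigns <1% to MAFs at 10x the detection threshold."""
    obs, _ = generate_maf_observations(
        rho=0.007, delta_c_fix=8e-5, seed=6, n_patients=80
    )
    post = fit_kras_model(obs, nsteps=1500, seed=6)
    p = post.predictive_detection_probability(
        age=70.0, crypts=5_000, n_mutations=12, maf=10 * 1e-4
    )
    assert p < 0.01
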