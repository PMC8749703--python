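import numpy as np
import pytest

from conftest import fixed, quiet_profile

from turnkin import GroupProfile, TruncNormal, generate_cohort, generate_trial
from turnkin.preprocess import cumulative_rotation


def test_same_seed_reproduces_identically():
    prof = GroupProfile.for_group("SS")
    a = generate_trial(prof, 7)
    b = generate_trial(prof, 7)
    for p in a.traces:
        np.testing.assert_array_equal(a.traces[p].gyro, b.traces[p].gyro)
        np.testing.assert_array_equal(a.traces[p].angle, b.traces[p].angle)
    assert a.ground_truth.to_dict() == b.ground_truth.to_dict()


def test_hi_cycle_count_within_truncation():
    """HI cycle counts follow a truncated normal around 3.5 (SD 0.94)."""
    trial = generate_trial(GroupProfile.for_group("HI"), 1)
    assert trial.ground_truth.n_cycles in range(2, 7)


def test_minimal_constructive_trial():
    """Two noise-free pulses at stance fraction 0.5 occupy half of each cycle."""
    prof = quiet_profile(
        "SS", n_cycles=fixed(2.0), turn_duration_s=fixed(3.0),
        stance_fraction=fixed(0.5), swing_peak_velocity=fixed(5.0))
    trial = generate_trial(prof, 0)
    gt = trial.ground_truth
    assert gt.n_cycles == 2
    # P = D/(n - f) = 3/1.5 = 2 s; pulse width w = 0.5 P = 1 s
    assert gt.cycle_period == pytest.approx(2.0)
    assert gt.pulse_width == pytest.approx(1.0)
    assert gt.stance_fraction == [0.5]
    g = trial.leading_shank.channel("gyro", "flexext")
    t = trial.leading_shank.t
    in_pulse = g > 1e-9
    # support of the two pulses totals 2 x 1 s of the 3 s turn
    assert np.sum(in_pulse) * (t[1] - t[0]) == pytest.approx(2.0, abs=0.1)
    assert g.max() == pytest.approx(5.0, abs=1e-9)


def test_ground_truth_stance_identity():
    """Ground-truth stance fraction is exactly 1 - pulse_width/cycle_period."""
    for seed in range(5):
        gt = generate_trial(GroupProfile.for_group("HI"), seed).ground_truth
        assert gt.stance_fraction[0] == pytest.approx(
            1.0 - gt.pulse_width / gt.cycle_period, rel=1e-12)


def test_trailing_rotation_monotone_and_total(quiet_trial):
    gt = quiet_trial.ground_truth
    rot = cumulative_rotation(
        quiet_trial.trailing_shank.channel("angle", "rotation"),
        quiet_trial.turn_direction)
    assert np.all(np.diff(rot) >= -1e-9)
    assert rot[-1] == pytest.approx(abs(gt.total_rotation), abs=1e-6)


def test_zero_noise_mean_abs_velocity_matches_ground_truth(quiet_trial):
    """Sampled mean |angular velocity| over the turn matches the analytic
    construction recorded in the ground truth."""
    gt = quiet_trial.ground_truth
    fs = quiet_trial.fs
    i0 = int(round(gt.turn_start_t * fs))
    i1 = int(round((gt.turn_start_t + gt.turn_duration) * fs))
    for seg, trace in [("sternum", quiet_trial.traces["sternum"]),
                       ("sacrum", quiet_trial.traces["sacrum"])]:
        for d in ("flexext", "lateral", "rotation"):
            got = np.mean(np.abs(trace.channel("gyro", d)[i0:i1]))
            assert got == pytest.approx(gt.segment_av[(seg, d)], rel=1e-2)
    lead = np.mean(np.abs(
        quiet_trial.leading_shank.channel("gyro", "flexext")[i0:i1]))
    assert lead == pytest.approx(
        gt.segment_av[("shank_leading", "flexext")], rel=1e-2)


def test_cohort_counts_and_ids():
    trials = generate_cohort(3, 2, seed=42)
    assert len(trials) == 5
    assert sum(t.group == "SS" for t in trials) == 3
    assert len({t.participant_id for t in trials}) == 5


def test_cohort_cycle_mean_matches_sampler():
    """Monte-Carlo: cohort ground-truth cycle counts agree with an
    independent rejection sampler of the same truncated normal."""
    prof = GroupProfile.for_group("SS")
    trials = [generate_trial(prof, s) for s in range(200)]
    counts = np.array([t.ground_truth.n_cycles for t in trials], dtype=float)

    rng = np.random.default_rng(123456)
    draws = []
    while len(draws) < 20000:
        x = rng.normal(prof.n_cycles.mean, prof.n_cycles.sd)
        if prof.n_cycles.low <= x <= prof.n_cycles.high:
            draws.append(max(2, round(x)))
    oracle_mean = np.mean(draws)
    se = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - oracle_mean) < 3 * se


def test_inconsistent_profile_rejected():
    with pytest.raises(ValueError):
        TruncNormal(5.0, 1.0, 6.0, 8.0)  # mean outside bounds
    prof = GroupProfile.for_group("SS")
    prof.stance_fraction = TruncNormal(0.5, 0.1, 0.01, 0.94)
    with pytest.raises(ValueError, match="stance"):
        generate_trial(prof, 0)
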