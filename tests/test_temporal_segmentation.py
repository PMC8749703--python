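import numpy as np
import pytest

from conftest import FS, bell_pulse, fixed, quiet_profile

from turnkin import (
    DetectionParams,
    GaitEvents,
    NoSwingsError,
    detect_swings,
    generate_trial,
    n_cycles,
    stance_fraction,
    turn_duration,
)
from turnkin.temporal_segmentation import bell_base_scale


def pulse_train(n, period, width, amp=5.0, pad=1.0):
    total = 2 * pad + (n - 1) * period + width
    t = np.arange(int(round(total * FS)) + 1) / FS
    g = np.zeros_like(t)
    centers = []
    for i in range(n):
        s = pad + i * period
        g += bell_pulse(t, s, width, amp)
        centers.append(s + width / 2)
    return t, g, centers


def test_mid_swings_found_at_pulse_centers():
    t, g, centers = pulse_train(5, period=1.2, width=0.6)
    ev = detect_swings(g, FS)
    assert ev.n_swings == 5
    for idx, c in zip(ev.mid_swing_idx, centers):
        assert abs(idx - c * FS) <= 1


def test_raw_crossings_at_analytic_ten_percent_height():
    """Without bell correction, toe-off/heel-strike sit at the 10%-height
    crossings of the raised cosine: w*arccos(0.8)/(2*pi) inside each edge."""
    t, g, _ = pulse_train(1, period=2.0, width=1.0)
    ev = detect_swings(g, FS, DetectionParams(bell_correction=False))
    inset = 1.0 * np.arccos(1 - 2 * 0.1) / (2 * np.pi)  # s
    assert ev.toe_off_idx[0] == pytest.approx((1.0 + inset) * FS, abs=1)
    assert ev.heel_strike_idx[0] == pytest.approx((2.0 - inset) * FS, abs=1)


def test_bell_correction_recovers_pulse_support():
    """With bell correction the events extrapolate to the pulse base."""
    t, g, _ = pulse_train(1, period=2.0, width=1.0)
    ev = detect_swings(g, FS)
    assert ev.toe_off_idx[0] == pytest.approx(1.0 * FS, abs=2)
    assert ev.heel_strike_idx[0] == pytest.approx(2.0 * FS, abs=2)


def test_bell_base_scale_closed_form():
    # q = 0.5 -> crossing at quarter width -> scale 2
    assert bell_base_scale(0.5) == pytest.approx(2.0)
    assert bell_base_scale(0.1) == pytest.approx(
        1.0 / (1.0 - np.arccos(0.8) / np.pi))


def test_negative_polarity_normalized():
    t, g, _ = pulse_train(3, period=1.2, width=0.6)
    ev = detect_swings(-g, FS)
    assert ev.n_swings == 3


def test_no_swings_raises():
    with pytest.raises(NoSwingsError):
        detect_swings(np.zeros(600) - 1e-6, FS)


def test_event_ordering_invariant_on_noisy_trials():
    from turnkin import GroupProfile, lowpass
    for seed in range(8):
        trial = generate_trial(GroupProfile.for_group("HI"), seed)
        g = lowpass(trial.leading_shank.channel("gyro", "flexext"), trial.fs)
        ev = detect_swings(g, trial.fs)  # GaitEvents validates ordering
        assert ev.n_swings >= 2


def test_scalar_summaries():
    """Cycle count, duration and stance from hand-built events."""
    ev = GaitEvents(mid_swing_idx=[75, 135, 195],
                    toe_off_idx=[60, 120, 180],
                    heel_strike_idx=[90, 150, 210], fs=FS)
    assert n_cycles(ev) == 3
    # swing 0.5 s inside a 1.0 s cycle -> 50% stance
    fracs, mean = stance_fraction(ev)
    assert fracs == pytest.approx([50.0, 50.0])
    assert mean == pytest.approx(50.0)


def test_turn_duration_published_magnitude():
    """First toe-off 1.0 s, last heel-strike 8.67 s -> 7.67 s."""
    ev = GaitEvents(mid_swing_idx=[90, 500], toe_off_idx=[60, 460],
                    heel_strike_idx=[120, 520], fs=FS)
    assert turn_duration(ev) == pytest.approx((520 - 60) / FS)
    ev2 = GaitEvents(mid_swing_idx=[int(1.3 * FS), int(8.3 * FS)],
                     toe_off_idx=[int(1.0 * FS), int(8.0 * FS)],
                     heel_strike_idx=[int(1.6 * FS), int(8.67 * FS)], fs=FS)
    assert turn_duration(ev2) == pytest.approx(7.67, abs=1 / FS)


def test_invalid_event_order_rejected():
    with pytest.raises(ValueError, match="toe_off < mid_swing"):
        GaitEvents(mid_swing_idx=[50], toe_off_idx=[60],
                   heel_strike_idx=[70], fs=FS)


def test_recovered_stance_monotone_in_generated_stance():
    """Raising the generator's stance fraction never lowers the recovered
    mean stance (same seeds, all else fixed)."""
    recovered = []
    for f in (0.30, 0.45, 0.60, 0.75):
        prof = quiet_profile("SS", stance_fraction=fixed(f),
                             n_cycles=fixed(5.0), turn_duration_s=fixed(7.0))
        means = []
        for seed in range(3):
            trial = generate_trial(prof, seed)
            from turnkin import lowpass
            g = lowpass(trial.leading_shank.channel("gyro", "flexext"),
                        trial.fs)
            means.append(stance_fraction(detect_swings(g, trial.fs))[1])
        recovered.append(np.mean(means))
    assert all(b >= a for a, b in zip(recovered, recovered[1:]))


def test_zero_noise_recovery_matches_ground_truth(quiet_trial, analyzed_quiet):
    events, _, _ = analyzed_quiet
    gt = quiet_trial.ground_truth
    assert n_cycles(events) == gt.n_cycles
    assert turn_duration(events) == pytest.approx(gt.turn_duration,
                                                  abs=3 / FS)
    assert stance_fraction(events)[1] == pytest.approx(
        gt.stance_fraction[0] * 100.0, abs=2.0)
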