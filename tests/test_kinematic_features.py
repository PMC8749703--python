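import numpy as np
import pytest

from conftest import FS

from turnkin import (
    extract_all,
    leg_ratio,
    mean_abs_angular_velocity,
    range_of_motion,
    relative_trace,
)
from turnkin.io_ingest import SensorTrace


def make_trace(gyro_col, angle_col, placement="sternum"):
    n = gyro_col.size
    z = np.zeros(n)
    return SensorTrace(placement=placement, fs=FS, t=np.arange(n) / FS,
                       gyro=np.column_stack([gyro_col, z, z]),
                       angle=np.column_stack([angle_col, z, z]))


class TestMeanAbsAngularVelocity:
    def test_constant(self):
        assert mean_abs_angular_velocity(np.full(100, 2.0), (10, 60)) == 2.0

    def test_sine_whole_periods(self):
        """Mean |A sin| over whole periods is 2A/pi."""
        t = np.arange(0, 4.0, 1 / 600.0)  # fine grid, 4 whole 1-Hz periods
        x = 3.0 * np.sin(2 * np.pi * t)
        got = mean_abs_angular_velocity(x, (0, t.size))
        assert got == pytest.approx(2 * 3.0 / np.pi, rel=1e-3)

    def test_empty_interval_fatal(self):
        with pytest.raises(ValueError):
            mean_abs_angular_velocity(np.ones(10), (5, 5))


class TestRangeOfMotion:
    def test_constant_angle_zero(self):
        assert range_of_motion(np.full(50, 7.0), (0, 50)) == 0.0

    def test_ramp_magnitude(self):
        x = np.linspace(3.0, 14.51, 200)
        assert range_of_motion(x, (0, 200)) == pytest.approx(11.51)

    def test_monotone_under_interval_inclusion(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        inner = range_of_motion(x, (100, 200))
        outer = range_of_motion(x, (50, 250))
        union = range_of_motion(x, (50, 250))
        assert outer >= inner
        assert union >= max(range_of_motion(x, (50, 150)),
                            range_of_motion(x, (150, 250)))


class TestRelativeTrace:
    def test_identical_traces_cancel(self):
        a = make_trace(np.sin(np.arange(100.0)), np.ones(100))
        rel = relative_trace(a, a)
        assert mean_abs_angular_velocity(rel.channel("gyro", "flexext"),
                                         (0, 100)) == 0.0
        assert range_of_motion(rel.channel("angle", "flexext"), (0, 100)) == 0.0

    def test_antiphase_sines_double(self):
        t = np.arange(0, 2.0, 1 / FS)
        s = np.sin(2 * np.pi * t)
        a = make_trace(s, s, "sternum")
        b = make_trace(-s, -s, "sacrum")
        rel = relative_trace(a, b)
        assert np.max(np.abs(rel.channel("gyro", "flexext"))) == \
            pytest.approx(2.0, rel=1e-3)

    def test_length_mismatch_fatal(self):
        a = make_trace(np.zeros(100), np.zeros(100))
        b = make_trace(np.zeros(99), np.zeros(99))
        with pytest.raises(ValueError, match="align"):
            relative_trace(a, b)


class TestLegRatio:
    def test_equal_values_unity(self):
        assert leg_ratio(1.3, 1.3) == pytest.approx(1.0)

    def test_published_scale(self):
        assert leg_ratio(0.95 * 1.2, 1.2) == pytest.approx(0.95)

    def test_reciprocity(self):
        assert leg_ratio(2.0, 3.0) * leg_ratio(3.0, 2.0) == pytest.approx(1.0)

    def test_tiny_denominator_flagged_nan(self):
        assert np.isnan(leg_ratio(1.0, 0.0))


class TestExtractAll:
    # full parameter set: 3 whole-turn scalars + 27 interval parameters,
    # repeated per spatial partition (enumeration frozen once)
    N_TEMPORAL = 30
    N_PER_PARTITION = 27

    def test_record_count_enumeration(self, quiet_trial, analyzed_quiet):
        events, partitions, _ = analyzed_quiet
        recs = extract_all(quiet_trial, events,
                           {2: partitions[2]})
        assert len(recs) == self.N_TEMPORAL + 2 * self.N_PER_PARTITION  # 84
        keys = {(r.parameter, r.placement, r.direction, r.scheme,
                 r.partition_index) for r in recs}
        assert len(keys) == len(recs)

    def test_zero_noise_records_match_ground_truth(self, quiet_trial,
                                                   analyzed_quiet):
        _, _, recs = analyzed_quiet
        gt = quiet_trial.ground_truth
        by_key = {(r.parameter, r.placement, r.direction, r.scheme,
                   r.partition_index): r.value for r in recs}
        for seg in ("sternum", "sacrum"):
            for d in ("flexext", "lateral", "rotation"):
                assert by_key[("angular_velocity", seg, d, "temporal", -1)] \
                    == pytest.approx(gt.segment_av[(seg, d)], rel=0.02)
                assert by_key[("rom", seg, d, "temporal", -1)] == \
                    pytest.approx(gt.segment_rom[(seg, d)], rel=0.02)
        assert by_key[("n_cycles", "shank_leading", "", "temporal", -1)] == \
            gt.n_cycles
        assert by_key[("turn_duration", "shank_leading", "", "temporal", -1)] \
            == pytest.approx(gt.turn_duration, rel=0.02)
        assert by_key[("rom", "shank_trailing", "flexext", "temporal", -1)] \
            == pytest.approx(gt.segment_rom[("shank_trailing", "flexext")],
                             rel=0.05)

    def test_partition_means_recompose_whole(self, quiet_trial,
                                             analyzed_quiet):
        """k=2 angular-velocity records average (duration-weighted) to the
        value over the union of both partitions."""
        events, partitions, recs = analyzed_quiet
        ps = partitions[2]
        ivs = ps.intervals()
        weights = [i1 - i0 for i0, i1 in ivs]
        trace = quiet_trial.traces["sternum"]
        # recompute the channel used by extract_all (filtered trial)
        from turnkin import FilterSpec, preprocess_trial
        proc = preprocess_trial(quiet_trial, FilterSpec())
        chan = proc.traces["sternum"].channel("gyro", "flexext")
        vals = [r.value for r in recs
                if (r.parameter, r.placement, r.direction, r.scheme) ==
                ("angular_velocity", "sternum", "flexext", "spatial_k2")]
        whole = mean_abs_angular_velocity(chan, (ivs[0][0], ivs[-1][1]))
        weighted = sum(v * w for v, w in zip(vals, weights)) / sum(weights)
        assert weighted == pytest.approx(whole, abs=1e-9)

    def test_nonnegative_invariants(self, analyzed_quiet):
        _, _, recs = analyzed_quiet
        for r in recs:
            if r.parameter in ("angular_velocity", "rom") and \
                    "over" not in r.placement:
                assert r.value >= 0.0
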