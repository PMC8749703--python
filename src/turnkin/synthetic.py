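"""Seedable synthetic turning trials with exact ground truth.

Real recordings of the turning task are not publicly available, so this
module constructs trials that reproduce the movement structure the
segmentation stages assume:

* the leading shank's flexion–extension angular velocity is a train of
  raised-cosine ("bell") swing pulses separated by stance intervals;
* the trailing shank's axial-rotation angle is a monotone smoothstep ramp
  covering ~360°, flat during the quiet-standing padding;
* sternum and sacrum angles oscillate at low frequency with group-specific
  range of motion.

Group profiles for stroke survivors (SS) and healthy individuals (HI) are
anchored to published whole-turn group means (see
:mod:`turnkin.reference_values`): cycle counts, turn duration, stance
fraction, and trunk range of motion are drawn from truncated normals with
those means/SDs.  Every constructed quantity is recorded exactly in
:class:`GroundTruth`, which is what recovery tests compare against.

Construction details
--------------------
With ``n`` swing cycles, turn duration ``D`` and stance fraction ``f``,
the cycle period is ``P = D / (n - f)`` and the swing (pulse) width
``w = (1 - f) P``; swing ``i`` of the leading shank occupies
``[t0 + iP, t0 + iP + w]``, so the turn — first toe-off to last
heel-strike — lasts exactly ``D`` and every toe-off→toe-off cycle has
stance fraction exactly ``f``.  The trailing shank swings in the ``n - 1``
stance gaps of the leading shank (offset ``P/2``).

Trunk channels honor the drawn range of motion ``R`` exactly: the angle is
``(R/2)·cos(mπ(t-t0)/D)`` with an integer number ``m`` of half-periods
inside the turn, chosen as ``m = max(1, round(V·D/R))`` for a drawn target
mean |angular velocity| ``V``; the achieved mean |angular velocity|
``m·R/D`` is what the ground truth records (the published whole-turn means
of range, velocity and duration are not mutually consistent for a single
smooth oscillation, so range and duration take precedence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import reference_values as ref
from .io_ingest import DIRECTIONS, SensorTrace, TurnTrial


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to [low, high] by rejection."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.low <= self.mean <= self.high:
            raise ValueError(
                f"mean {self.mean} outside truncation [{self.low}, {self.high}]")

    def sample(self, rng: np.random.Generator, max_tries: int = 1000) -> float:
        for _ in range(max_tries):
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return float(x)
        raise RuntimeError(
            f"truncated normal (mean={self.mean}, sd={self.sd}, "
            f"bounds=[{self.low}, {self.high}]) rejected {max_tries} draws; "
            "profile inconsistent")


def _trunk_defaults(group: str) -> dict:
    """Trunk ROM / angular-velocity-target distributions per direction.

    Flexion–extension and lateral bending take the published whole-turn
    means/SDs; the axial-rotation oscillation amplitude is not reported as
    a whole-turn range, so a plausible default of 12 (4)° is used for both
    groups with the published rotation angular-velocity scale as target.
    """
    rom = {}
    av = {}
    for seg in ("sternum", "sacrum"):
        for direction in ("flexext", "lateral"):
            m, s = [r[group] for r in ref.TEMPORAL_SUMMARY
                    if r["parameter"] == "rom" and r["placement"] == seg
                    and r["direction"] == direction][0]
            rom[(seg, direction)] = TruncNormal(m, s, max(0.5, m - 3 * s), m + 4 * s)
        rom[(seg, "rotation")] = TruncNormal(12.0, 4.0, 2.0, 30.0)
        fe = [r[group] for r in ref.TEMPORAL_SUMMARY
              if r["parameter"] == "angular_velocity" and r["placement"] == seg
              and r["direction"] == "flexext"][0]
        av[(seg, "flexext")] = TruncNormal(fe[0], fe[1], 0.05, fe[0] + 4 * fe[1])
        av[(seg, "lateral")] = TruncNormal(0.12, 0.08, 0.02, 0.6)
        av[(seg, "rotation")] = TruncNormal(0.25, 0.15, 0.02, 1.0)
    return {"rom": rom, "av": av}


@dataclass
class GroupProfile:
    """Sampling distributions defining one group's synthetic trials.

    Defaults come from :func:`for_group`; all angular quantities are in
    degrees and °/s, durations in seconds, stance fraction dimensionless.
    """

    group: str
    n_cycles: TruncNormal
    turn_duration_s: TruncNormal
    stance_fraction: TruncNormal
    swing_peak_velocity: TruncNormal
    trunk_rom: dict
    trunk_av_target: dict
    total_rotation_range: tuple = (340.0, 380.0)
    gyro_noise_sd: float = 0.1   # °/s per channel
    angle_noise_sd: float = 0.1  # ° per channel
    pad_s: float = 1.0           # quiet standing before/after the turn
    fs: float = 60.0

    @classmethod
    def for_group(cls, group: str) -> "GroupProfile":
        if group not in ("SS", "HI"):
            raise ValueError(f"unknown group {group!r}")
        nc = ref.temporal_mean("n_cycles", "shank_leading", "", group), \
            [r[group][1] for r in ref.TEMPORAL_SUMMARY
             if r["parameter"] == "n_cycles"][0]
        dur = [r[group] for r in ref.TEMPORAL_SUMMARY
               if r["parameter"] == "turn_duration"][0]
        st = [r[group] for r in ref.TEMPORAL_SUMMARY
              if r["parameter"] == "stance_pct"][0]
        trunk = _trunk_defaults(group)
        return cls(
            group=group,
            n_cycles=TruncNormal(nc[0], nc[1], 2.0, 12.0),
            turn_duration_s=TruncNormal(dur[0], dur[1], 1.5, 20.0),
            stance_fraction=TruncNormal(st[0] / 100.0, st[1] / 100.0, 0.15, 0.85),
            # chosen so the whole-turn mean |angular velocity| of the pulse
            # train lands near the published leading-shank values for both
            # groups' cycle structure
            swing_peak_velocity=TruncNormal(6.6, 1.0, 3.0, 12.0),
            trunk_rom=trunk["rom"],
            trunk_av_target=trunk["av"],
        )

    def validate(self) -> "GroupProfile":
        if not (0.05 < self.stance_fraction.low
                and self.stance_fraction.high < 0.95):
            raise ValueError("stance fraction truncation must stay in (0.05, 0.95)")
        if self.n_cycles.low < 1.5:  # draws are rounded, then clamped to >= 2
            raise ValueError("n_cycles truncation must keep draws >= 2")
        if self.turn_duration_s.low <= 0:
            raise ValueError("turn duration must stay positive")
        return self


@dataclass
class GroundTruth:
    """Exact construction parameters of one synthetic trial."""

    n_cycles: int
    swing_intervals: list          # leading shank (toe_off_t, heel_strike_t)
    trailing_swing_intervals: list
    turn_start_t: float
    turn_duration: float           # s, first toe-off to last heel-strike
    cycle_period: float            # s, toe-off to toe-off
    pulse_width: float             # s, swing duration
    stance_fraction: list          # per toe-off→toe-off cycle, in (0,1)
    total_rotation: float          # ° signed, trailing shank
    leading_total_rotation: float  # ° signed
    swing_peaks_leading: list      # °/s per pulse
    swing_peaks_trailing: list
    segment_rom: dict              # {(placement, direction): °}
    segment_av: dict               # {(placement, direction): °/s}
    trunk_half_periods: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_cycles != len(self.swing_intervals):
            raise ValueError("n_cycles != number of swing intervals")
        prev_end = -np.inf
        for a, b in self.swing_intervals:
            if not (a < b and a >= prev_end):
                raise ValueError("swing intervals must be disjoint and increasing")
            prev_end = b
        if not all(0.0 < f < 1.0 for f in self.stance_fraction):
            raise ValueError("stance fractions must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segment_rom"] = {f"{p}:{dr}": v
                            for (p, dr), v in self.segment_rom.items()}
        d["segment_av"] = {f"{p}:{dr}": v
                           for (p, dr), v in self.segment_av.items()}
        d["trunk_half_periods"] = {f"{p}:{dr}": v for (p, dr), v
                                   in self.trunk_half_periods.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        for key in ("segment_rom", "segment_av", "trunk_half_periods"):
            d[key] = {tuple(k.split(":")): v for k, v in d[key].items()}
        d["swing_intervals"] = [tuple(x) for x in d["swing_intervals"]]
        d["trailing_swing_intervals"] = [tuple(x) for x in
                                         d["trailing_swing_intervals"]]
        return cls(**d)


def _bell_train(t: np.ndarray, starts, width: float, amps) -> np.ndarray:
    """Sum of raised-cosine pulses: amp/2 · (1 − cos(2π(t−s)/w)) on support."""
    g = np.zeros_like(t)
    for s, a in zip(starts, amps):
        m = (t >= s) & (t <= s + width)
        g[m] += a * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - s) / width))
    return g


def _bell_train_integral(t: np.ndarray, starts, width: float, amps) -> np.ndarray:
    """Closed-form running integral of :func:`_bell_train` (an angle in °)."""
    g = np.zeros_like(t)
    for s, a in zip(starts, amps):
        tau = np.clip(t - s, 0.0, width)
        g += a * 0.5 * (tau - width / (2.0 * np.pi)
                        * np.sin(2.0 * np.pi * tau / width))
    return g


def _smoothstep_ramp(t: np.ndarray, t0: float, duration: float,
                     total: float) -> tuple[np.ndarray, np.ndarray]:
    """Monotone C¹ ramp 0→total over [t0, t0+duration]; returns (angle, rate)."""
    u = np.clip((t - t0) / duration, 0.0, 1.0)
    angle = total * u * u * (3.0 - 2.0 * u)
    rate = total / duration * 6.0 * u * (1.0 - u)
    return angle, rate


def smoothstep_crossing_time(fraction: float) -> float:
    """Inverse of the smoothstep ramp: u with 3u² − 2u³ = fraction ∈ [0, 1].

    Closed form via the trigonometric cubic solution; used by tests to
    predict partition-boundary times analytically.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return float(0.5 - np.sin(np.arcsin(1.0 - 2.0 * fraction) / 3.0))


def _wrap180(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (−180, 180]."""
    return -((-x + 180.0) % 360.0 - 180.0)


def generate_trial(profile: GroupProfile, seed: int,
                   participant_id: Optional[str] = None) -> TurnTrial:
    """Generate one synthetic turning trial with exact ground truth.

    The same ``(profile, seed)`` pair always yields a byte-identical trial.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    fs = profile.fs

    n = max(2, int(round(profile.n_cycles.sample(rng))))
    duration = profile.turn_duration_s.sample(rng)
    f_stance = profile.stance_fraction.sample(rng)
    period = duration / (n - f_stance)
    width = (1.0 - f_stance) * period

    leading_side = "left" if rng.random() < 0.5 else "right"
    turn_direction = "ccw" if rng.random() < 0.5 else "cw"
    sign = 1.0 if turn_direction == "ccw" else -1.0
    total_trail = sign * rng.uniform(*profile.total_rotation_range)
    total_lead = sign * rng.uniform(*profile.total_rotation_range)

    t0 = profile.pad_s
    n_samp = int(round((duration + 2.0 * profile.pad_s) * fs)) + 1
    t = np.arange(n_samp) / fs

    amps_lead = [profile.swing_peak_velocity.sample(rng) for _ in range(n)]
    amps_trail = [profile.swing_peak_velocity.sample(rng) for _ in range(n - 1)]
    starts_lead = [t0 + i * period for i in range(n)]
    starts_trail = [t0 + (i + 0.5) * period for i in range(n - 1)]

    segment_rom: dict = {}
    segment_av: dict = {}
    half_periods: dict = {}

    # --- trunk traces -----------------------------------------------------
    trunk_signals = {}
    for seg in ("sternum", "sacrum"):
        gyro = np.zeros((n_samp, 3))
        angle = np.zeros((n_samp, 3))
        for j, direction in enumerate(DIRECTIONS):
            rom = profile.trunk_rom[(seg, direction)].sample(rng)
            v_target = profile.trunk_av_target[(seg, direction)].sample(rng)
            m = max(1, int(round(v_target * duration / rom)))
            amp = rom / 2.0
            omega = m * np.pi / duration
            phase = np.clip(t - t0, 0.0, duration)
            angle[:, j] = amp * np.cos(omega * phase)
            inside = (t >= t0) & (t <= t0 + duration)
            gyro[inside, j] = -amp * omega * np.sin(omega * (t[inside] - t0))
            segment_rom[(seg, direction)] = rom
            segment_av[(seg, direction)] = m * rom / duration
            half_periods[(seg, direction)] = m
        trunk_signals[seg] = (gyro, angle)

    # --- shank traces -----------------------------------------------------
    def shank(starts, amps, total_rot):
        gyro = np.zeros((n_samp, 3))
        angle = np.zeros((n_samp, 3))
        gyro[:, 0] = _bell_train(t, starts, width, amps)
        angle[:, 0] = _bell_train_integral(t, starts, width, amps)
        rot, rate = _smoothstep_ramp(t, t0, duration, total_rot)
        angle[:, 2] = _wrap180(rot)
        gyro[:, 2] = rate
        return gyro, angle

    lead_gyro, lead_angle = shank(starts_lead, amps_lead, total_lead)
    trail_gyro, trail_angle = shank(starts_trail, amps_trail, total_trail)

    segment_rom[("shank_leading", "flexext")] = sum(amps_lead) * width / 2.0
    segment_av[("shank_leading", "flexext")] = \
        segment_rom[("shank_leading", "flexext")] / duration
    segment_rom[("shank_trailing", "flexext")] = sum(amps_trail) * width / 2.0
    segment_av[("shank_trailing", "flexext")] = \
        segment_rom[("shank_trailing", "flexext")] / duration
    segment_rom[("shank_leading", "rotation")] = abs(total_lead)
    segment_av[("shank_leading", "rotation")] = abs(total_lead) / duration
    segment_rom[("shank_trailing", "rotation")] = abs(total_trail)
    segment_av[("shank_trailing", "rotation")] = abs(total_trail) / duration
    # lateral shank channels are pure noise
    for seg in ("shank_leading", "shank_trailing"):
        segment_rom[(seg, "lateral")] = 0.0
        segment_av[(seg, "lateral")] = 0.0

    placements = {
        "sternum": trunk_signals["sternum"],
        "sacrum": trunk_signals["sacrum"],
        ("shank_left" if leading_side == "left" else "shank_right"):
            (lead_gyro, lead_angle),
        ("shank_right" if leading_side == "left" else "shank_left"):
            (trail_gyro, trail_angle),
    }
    traces = {}
    for placement, (gyro, angle) in placements.items():
        gyro = gyro + rng.normal(0.0, profile.gyro_noise_sd, gyro.shape)
        angle = angle + rng.normal(0.0, profile.angle_noise_sd, angle.shape)
        traces[placement] = SensorTrace(
            placement=placement, fs=fs, t=t.copy(), gyro=gyro, angle=angle)

    gt = GroundTruth(
        n_cycles=n,
        swing_intervals=[(s, s + width) for s in starts_lead],
        trailing_swing_intervals=[(s, s + width) for s in starts_trail],
        turn_start_t=t0,
        turn_duration=duration,
        cycle_period=period,
        pulse_width=width,
        stance_fraction=[f_stance] * (n - 1),
        total_rotation=total_trail,
        leading_total_rotation=total_lead,
        swing_peaks_leading=amps_lead,
        swing_peaks_trailing=amps_trail,
        segment_rom=segment_rom,
        segment_av=segment_av,
        trunk_half_periods=half_periods,
    )
    if participant_id is None:
        participant_id = f"{profile.group}-{seed}"
    return TurnTrial(
        participant_id=participant_id, group=profile.group,
        leading_side=leading_side, turn_direction=turn_direction,
        traces=traces, ground_truth=gt).validate()


def generate_cohort(n_ss: int, n_hi: int, seed: int,
                    profiles: Optional[dict] = None) -> list:
    """Generate a two-group cohort with per-trial seeds derived from *seed*.

    Trials are independent; participant ids are ``SS01…`` / ``HI01…``.
    """
    if n_ss < 1 or n_hi < 1:
        raise ValueError("need at least one trial per group")
    if profiles is None:
        profiles = {g: GroupProfile.for_group(g) for g in ("SS", "HI")}
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_ss + n_hi)
    trials = []
    for i in range(n_ss):
        trials.append(generate_trial(
            profiles["SS"], int(child_seeds[i]), participant_id=f"SS{i + 1:02d}"))
    for i in range(n_hi):
        trials.append(generate_trial(
            profiles["HI"], int(child_seeds[n_ss + i]),
            participant_id=f"HI{i + 1:02d}"))
    return trials
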