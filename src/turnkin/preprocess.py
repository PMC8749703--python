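"""Signal conditioning for turning trials.

Three operations feed the segmentation stages: a low-pass Butterworth
filter (default 4th order, 5 Hz cutoff, applied zero-phase so event times
are not lag-shifted), unwrapping of the shank axial-rotation angle into a
cumulative turn angle, and the anatomical axis relabeling applied at
ingest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .io_ingest import DIRECTIONS, SensorTrace, TurnTrial


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings.

    ``zero_phase=True`` applies the filter forward and backward
    (``filtfilt``): no group delay, at the price of doubling the effective
    attenuation (the magnitude response is squared).
    """

    order: int = 4
    cutoff: float = 5.0  # Hz
    zero_phase: bool = True

    def validate(self, fs: float) -> "FilterSpec":
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff < fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff} Hz must lie in (0, Nyquist={fs / 2} Hz)")
        return self


def lowpass(x, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass filter one channel.

    With ``zero_phase`` the time index of a symmetric pulse's maximum is
    preserved exactly; single-pass filtering retains the filter's group
    delay and is provided for completeness.
    """
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * spec.order:
        raise ValueError(
            f"signal too short to filter: {x.size} samples")
    b, a = _sig.butter(spec.order, spec.cutoff / (fs / 2), btype="low")
    if spec.zero_phase:
        return _sig.filtfilt(b, a, x)
    return _sig.lfilter(b, a, x)


class NoTurnError(ValueError):
    """Raised when the rotation trace does not contain a ≥ 90° turn."""


def cumulative_rotation(angle_rotation, turn_direction: str | None = None,
                        wrap_period: float = 360.0) -> np.ndarray:
    """Unwrap an axial-rotation angle into a cumulative turn angle.

    Jumps larger than half the wrap period between consecutive samples are
    treated as wrap-arounds of the ±180° representation.  The initial value
    is subtracted and the sign flipped, if necessary, so that the turn is
    positive regardless of turning clockwise or counter-clockwise: with
    ``turn_direction`` ``"cw"`` the series is negated; when it is omitted
    the sign of the net rotation decides.
    """
    x = np.unwrap(np.asarray(angle_rotation, dtype=float),
                  period=wrap_period)
    x = x - x[0]
    if turn_direction == "cw":
        x = -x
    elif turn_direction is None and x[-1] < 0:
        x = -x
    return x


def axis_map(placement: str, raw: np.ndarray,
             mapping: dict | None = None) -> np.ndarray:
    """Relabel raw device axes to anatomical directions.

    ``mapping[placement]`` maps each anatomical direction to a raw column
    spec: an index 0–2 or one of ``"x"/"y"/"z"``, optionally prefixed with
    ``-`` to flip the sign (e.g. ``{"flexext": "y", "lateral": "-x",
    "rotation": "z"}``).  With no mapping the identity is used — the
    convention of the synthetic generator.
    """
    from .io_ingest import PLACEMENTS

    if placement not in PLACEMENTS:
        raise ValueError(f"unknown placement {placement!r}")
    raw = np.asarray(raw, dtype=float)
    if mapping is None or placement not in mapping:
        return raw.copy()
    table = mapping[placement]
    axis_names = {"x": 0, "y": 1, "z": 2}
    out = np.empty_like(raw)
    for j, direction in enumerate(DIRECTIONS):
        spec = table[direction]
        sign = 1.0
        if isinstance(spec, str):
            spec = spec.strip()
            if spec.startswith("-"):
                sign = -1.0
                spec = spec[1:]
            col = axis_names.get(spec.lower())
            if col is None:
                col = int(spec)
        else:
            col = int(spec)
            if col < 0:
                raise ValueError("use string '-x' style for sign flips")
        out[:, j] = sign * raw[:, col]
    return out


def preprocess_trial(trial: TurnTrial,
                     spec: FilterSpec = FilterSpec()) -> TurnTrial:
    """Return a filtered copy of *trial* ready for segmentation.

    All angular-velocity channels and the flexion–extension / lateral
    orientation channels are low-pass filtered.  The axial-rotation angle of
    every placement is replaced by its unwrapped cumulative form (initial
    value subtracted, direction sign left untouched) so range-of-motion and
    partitioning never see ±180° wrap discontinuities.
    """
    out_traces = {}
    for placement, tr in trial.traces.items():
        gyro = np.column_stack(
            [lowpass(tr.gyro[:, j], tr.fs, spec) for j in range(3)])
        ang_fe = lowpass(tr.angle[:, 0], tr.fs, spec)
        ang_lat = lowpass(tr.angle[:, 1], tr.fs, spec)
        rot = np.unwrap(tr.angle[:, 2], period=360.0)
        rot = rot - rot[0]
        angle = np.column_stack([ang_fe, ang_lat, rot])
        out_traces[placement] = SensorTrace(
            placement=placement, fs=tr.fs, t=tr.t.copy(),
            gyro=gyro, angle=angle)
    return TurnTrial(
        participant_id=trial.participant_id, group=trial.group,
        leading_side=trial.leading_side, turn_direction=trial.turn_direction,
        traces=out_traces, ground_truth=trial.ground_truth)
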