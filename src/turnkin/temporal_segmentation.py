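"""Gait-event detection on the leading shank during the turn.

Each swing of the leading leg appears in the flexion–extension
angular-velocity channel as a bell-shaped pulse: the signal rises to a
maximum at mid-swing and falls back to baseline during stance.  Repetition
of this pattern yields the mid-swing, toe-off and heel-strike events from
which the cycle count, turn duration and per-cycle stance fraction are
derived.  The trailing shank is never used temporally — in stroke
survivors it belongs to the affected side and shows no clear pattern.

Detection operates on the filtered signal: mid-swings are local maxima
with a minimum prominence (relative to the global maximum) and minimum
separation; toe-off and heel-strike start from the samples where the
signal falls below ``onset_frac`` of the peak height on either side.
Because a fractional-height crossing always sits inside the pulse's true
support, the crossings are extrapolated to the pulse base assuming the
bell is a raised cosine, for which the half-width up to the
``q``-height crossing is a fixed fraction ``1 − arccos(1 − 2q)/π`` of the
full half-width (``bell_correction``, on by default; switch off to keep
the raw crossings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)


class NoSwingsError(ValueError):
    """Raised when no swing pulses are found in the signal."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the swing detector.

    prominence_frac : minimum peak prominence as a fraction of the global
        maximum of the (sign-normalized) signal.
    onset_frac : fraction of a peak's height defining the toe-off /
        heel-strike crossing on each side.
    min_separation_s : minimum time between consecutive mid-swings.
    bell_correction : extrapolate the onset crossings to the pulse base
        assuming a raised-cosine swing pulse.
    """

    prominence_frac: float = 0.3
    onset_frac: float = 0.1
    min_separation_s: float = 0.3
    bell_correction: bool = True


@dataclass
class GaitEvents:
    """Detected gait events, all as sample indices into the input signal."""

    mid_swing_idx: list
    toe_off_idx: list
    heel_strike_idx: list
    fs: float
    excluded_cycles: list = field(default_factory=list)

    def __post_init__(self):
        ms, to, hs = self.mid_swing_idx, self.toe_off_idx, self.heel_strike_idx
        if not len(ms) == len(to) == len(hs):
            raise ValueError("event lists must have equal length")
        for i in range(len(ms)):
            if not to[i] < ms[i] < hs[i]:
                raise ValueError(
                    f"cycle {i}: require toe_off < mid_swing < heel_strike, "
                    f"got {to[i]}, {ms[i]}, {hs[i]}")
            if i and not (ms[i] > ms[i - 1] and to[i] > to[i - 1]
                          and hs[i] > hs[i - 1]):
                raise ValueError(f"events not strictly increasing at cycle {i}")

    @property
    def n_swings(self) -> int:
        return len(self.mid_swing_idx)

    @property
    def cycle_bounds(self) -> list:
        """Toe-off→toe-off cycle boundaries (n_swings − 1 cycles)."""
        to = self.toe_off_idx
        return [(to[i], to[i + 1]) for i in range(len(to) - 1)]

    def turn_interval(self) -> tuple:
        """Half-open sample interval from first toe-off to last heel-strike."""
        return (self.toe_off_idx[0], self.heel_strike_idx[-1] + 1)

    def to_dict(self) -> dict:
        return {
            "mid_swing_idx": [int(i) for i in self.mid_swing_idx],
            "toe_off_idx": [int(i) for i in self.toe_off_idx],
            "heel_strike_idx": [int(i) for i in self.heel_strike_idx],
            "fs": self.fs,
        }


def bell_base_scale(onset_frac: float) -> float:
    """Half-width ratio from the ``q``-height crossing to the bell base.

    For a raised-cosine pulse of width *w*, the crossing of ``q`` times the
    peak height lies ``w·arccos(1 − 2q)/(2π)`` inside each edge, so the
    measured peak-to-crossing half-width underestimates the true half-width
    by the factor ``1 − arccos(1 − 2q)/π``.
    """
    if not 0.0 < onset_frac < 1.0:
        raise ValueError("onset_frac must lie in (0, 1)")
    return 1.0 / (1.0 - np.arccos(1.0 - 2.0 * onset_frac) / np.pi)


def detect_swings(gyro_flexext, fs: float,
                  params: DetectionParams = DetectionParams()) -> GaitEvents:
    """Detect mid-swing, toe-off and heel-strike events.

    *gyro_flexext* must already be low-pass filtered.  The signal's sign is
    normalized so that swing pulses are positive maxima.
    """
    x = np.asarray(gyro_flexext, dtype=float)
    if np.abs(x.min()) > np.abs(x.max()):
        x = -x
    if x.max() <= 0:
        raise NoSwingsError("no swings detected: signal has no positive peaks")
    peaks, _ = find_peaks(
        x, prominence=params.prominence_frac * x.max(),
        distance=max(1, int(round(params.min_separation_s * fs))))
    if peaks.size == 0:
        raise NoSwingsError("no swings detected")
    if peaks.size < 2:
        logger.warning("only one swing detected; stance fraction undefined")

    scale = bell_base_scale(params.onset_frac) if params.bell_correction else 1.0
    toe_off, heel_strike = [], []
    for p in peaks:
        thresh = params.onset_frac * x[p]
        i = p
        while i > 0 and x[i] > thresh:
            i -= 1
        j = p
        while j < x.size - 1 and x[j] > thresh:
            j += 1
        toe_off.append(int(round(p - (p - i) * scale)))
        heel_strike.append(int(round(p + (j - p) * scale)))

    # midpoint rule: adjacent swings may not claim overlapping support
    for i in range(1, len(peaks)):
        if toe_off[i] <= heel_strike[i - 1]:
            mid = int((peaks[i - 1] + peaks[i]) // 2)
            heel_strike[i - 1] = mid
            toe_off[i] = mid + 1
    toe_off = [max(0, i) for i in toe_off]
    heel_strike = [min(x.size - 1, i) for i in heel_strike]
    return GaitEvents(
        mid_swing_idx=[int(p) for p in peaks], toe_off_idx=toe_off,
        heel_strike_idx=heel_strike, fs=fs)


def n_cycles(events: GaitEvents) -> int:
    """Number of swing cycles in the turning task (= mid-swing count)."""
    return events.n_swings


def turn_duration(events: GaitEvents, fs: float | None = None) -> float:
    """Turn duration in seconds: first toe-off to last heel-strike."""
    fs = events.fs if fs is None else fs
    return (events.heel_strike_idx[-1] - events.toe_off_idx[0]) / fs


def stance_fraction(events: GaitEvents) -> tuple[list, float]:
    """Per-cycle stance percentage and its mean.

    A cycle runs toe-off→toe-off; its stance phase is heel-strike of that
    swing to the next toe-off, so ``n`` swings yield ``n − 1`` stance
    values.  Cycles where the detected heel-strike does not precede the
    next toe-off are excluded (and logged on the events object).
    """
    if events.n_swings < 2:
        raise ValueError("stance fraction requires at least 2 swings")
    fracs = []
    for i in range(events.n_swings - 1):
        to_i, to_next = events.toe_off_idx[i], events.toe_off_idx[i + 1]
        hs_i = events.heel_strike_idx[i]
        if hs_i >= to_next:
            logger.warning("cycle %d invalid (heel-strike >= next toe-off); "
                           "excluded", i)
            events.excluded_cycles.append(i)
            continue
        fracs.append((to_next - hs_i) / (to_next - to_i) * 100.0)
    if not fracs:
        raise ValueError("no valid cycles for stance fraction")
    return fracs, float(np.mean(fracs))
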