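"""Per-trial kinematic parameters over the whole turn and per partition.

The parameter set covers, per body segment and anatomical direction, the
mean absolute angular velocity and the range of motion; for the shanks it
adds the cycle count, turn duration and stance percentage (temporal path
only) plus leading/trailing ratios; and for the trunk the sternum-relative-
to-sacrum channels, computed as per-sample difference signals before any
summary (differencing summaries instead would discard within-trial
covariance).

Angular velocity is summarized as the mean of the absolute value: the
published group values are all positive, and a signed mean would cancel
the oscillatory trunk motion to ~0.  Range of motion is max − min of the
angle over the interval.  Intervals are half-open ``(start, stop)`` sample
index pairs, so a partition set tiles the turn exactly and a
duration-weighted average of per-partition means reproduces the
whole-interval mean to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_ingest import DIRECTIONS, SensorTrace, TurnTrial
from .temporal_segmentation import GaitEvents, stance_fraction, turn_duration

logger = logging.getLogger(__name__)

#: placements carrying angular-velocity / ROM records
SEGMENT_PLACEMENTS = ("sternum", "sacrum", "shank_leading", "shank_trailing")

#: (parameter, placement, direction) triples emitted per interval
_INTERVAL_PARAMS = (
    [("angular_velocity", p, d) for p in ("sternum", "sacrum")
     for d in DIRECTIONS]
    + [("rom", p, d) for p in ("sternum", "sacrum") for d in DIRECTIONS]
    + [("angular_velocity", p, d)
       for p in ("shank_leading", "shank_trailing")
       for d in ("flexext", "rotation")]
    + [("rom", p, "flexext") for p in ("shank_leading", "shank_trailing")]
    + [("angular_velocity", "sternum_minus_sacrum", d) for d in DIRECTIONS]
    + [("rom", "sternum_minus_sacrum", d) for d in DIRECTIONS]
    + [("angular_velocity", "leading_over_trailing", d)
       for d in ("flexext", "rotation")]
    + [("rom", "leading_over_trailing", "flexext")]
)

RATIO_EPS = 1e-9


@dataclass(frozen=True)
class FeatureRecord:
    """One extracted parameter value for one participant.

    ``partition_index`` is −1 for whole-turn values and 0-based otherwise;
    ``scheme`` is ``"temporal"`` or ``"spatial_k<k>"``.
    """

    participant_id: str
    group: str
    parameter: str
    placement: str
    direction: str
    scheme: str
    partition_index: int
    value: float


def mean_abs_angular_velocity(gyro, interval) -> float:
    """Mean of |angular velocity| (°/s) over a half-open sample interval."""
    i0, i1 = interval
    if i1 <= i0:
        raise ValueError(f"empty interval {interval}")
    return float(np.mean(np.abs(np.asarray(gyro, dtype=float)[i0:i1])))


def range_of_motion(angle, interval) -> float:
    """Max − min of an angle channel (°) over a half-open sample interval."""
    i0, i1 = interval
    if i1 <= i0:
        raise ValueError(f"empty interval {interval}")
    seg = np.asarray(angle, dtype=float)[i0:i1]
    return float(seg.max() - seg.min())


def relative_trace(sternum: SensorTrace, sacrum: SensorTrace) -> SensorTrace:
    """Per-sample sternum − sacrum difference as a derived trace."""
    if sternum.n_samples != sacrum.n_samples:
        raise ValueError("traces are not time-aligned (length mismatch)")
    return SensorTrace(
        placement="sternum_minus_sacrum", fs=sternum.fs, t=sternum.t.copy(),
        gyro=sternum.gyro - sacrum.gyro, angle=sternum.angle - sacrum.angle)


def leg_ratio(leading: float, trailing: float) -> float:
    """Leading/trailing ratio; NaN (flagged undefined) for tiny denominators."""
    if abs(trailing) <= RATIO_EPS:
        logger.warning("leg ratio undefined: trailing value %g ~ 0", trailing)
        return float("nan")
    return leading / trailing


def _interval_value(parameter: str, placement: str, direction: str,
                    channels: dict, interval) -> float:
    if placement == "leading_over_trailing":
        num = _interval_value(parameter, "shank_leading", direction,
                              channels, interval)
        den = _interval_value(parameter, "shank_trailing", direction,
                              channels, interval)
        return leg_ratio(num, den)
    trace = channels[placement]
    if parameter == "angular_velocity":
        return mean_abs_angular_velocity(trace.channel("gyro", direction),
                                         interval)
    if parameter == "rom":
        return range_of_motion(trace.channel("angle", direction), interval)
    raise ValueError(f"unknown parameter {parameter!r}")


def extract_all(trial: TurnTrial, events: GaitEvents,
                partitions: dict | None = None) -> list:
    """Extract the full parameter set for one (preprocessed) trial.

    Parameters
    ----------
    trial : TurnTrial
        Filtered trial (see :func:`turnkin.preprocess.preprocess_trial`).
    events : GaitEvents
        Leading-shank gait events; define the temporal whole-turn interval.
    partitions : dict, optional
        Mapping ``k -> PartitionSet`` from the trailing shank's cumulative
        rotation; one ``spatial_k<k>`` scheme is emitted per entry.
    """
    channels = {
        "sternum": trial.traces["sternum"],
        "sacrum": trial.traces["sacrum"],
        "shank_leading": trial.leading_shank,
        "shank_trailing": trial.trailing_shank,
    }
    channels["sternum_minus_sacrum"] = relative_trace(
        channels["sternum"], channels["sacrum"])

    def rec(parameter, placement, direction, scheme, part_idx, value):
        return FeatureRecord(
            participant_id=trial.participant_id, group=trial.group,
            parameter=parameter, placement=placement, direction=direction,
            scheme=scheme, partition_index=part_idx, value=value)

    records = []
    # temporal path: whole-turn scalars + per-segment summaries
    fracs, mean_stance = stance_fraction(events)
    records.append(rec("n_cycles", "shank_leading", "", "temporal", -1,
                       float(events.n_swings)))
    records.append(rec("turn_duration", "shank_leading", "", "temporal", -1,
                       turn_duration(events)))
    records.append(rec("stance_pct", "shank_leading", "", "temporal", -1,
                       mean_stance))
    turn_iv = events.turn_interval()
    for parameter, placement, direction in _INTERVAL_PARAMS:
        records.append(rec(parameter, placement, direction, "temporal", -1,
                           _interval_value(parameter, placement, direction,
                                           channels, turn_iv)))
    # spatial path: per-partition summaries
    for k, pset in sorted((partitions or {}).items()):
        scheme = f"spatial_k{k}"
        for j, interval in enumerate(pset.intervals()):
            for parameter, placement, direction in _INTERVAL_PARAMS:
                records.append(rec(
                    parameter, placement, direction, scheme, j,
                    _interval_value(parameter, placement, direction,
                                    channels, interval)))
    return records
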