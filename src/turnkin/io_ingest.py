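"""Reading and writing turning-trial recordings and feature tables.

A trial is one participant performing an on-spot 360° turn while wearing
four inertial sensors (sternum, sacrum, left and right shank).  Each sensor
contributes a synchronized 3-axis angular-velocity and 3-axis orientation
time series, stored on disk as one CSV per placement plus a metadata
sidecar.  Channels are labeled anatomically (flexion–extension, lateral
bending, axial rotation) rather than by device axes; the relabeling happens
at ingest via :func:`turnkin.preprocess.axis_map` so everything downstream
is placement-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

PLACEMENTS = ("sternum", "sacrum", "shank_left", "shank_right")
DIRECTIONS = ("flexext", "lateral", "rotation")
GROUPS = ("SS", "HI")

#: column order of a trial CSV
TRIAL_COLUMNS = (
    "time",
    "gyro_flexext", "gyro_lateral", "gyro_rotation",
    "ang_flexext", "ang_lateral", "ang_rotation",
)

#: column order of a long-format feature CSV; the first six form the key
FEATURE_COLUMNS = (
    "participant_id", "parameter", "placement", "direction",
    "scheme", "partition_index", "group", "value",
)


class TrialValidationError(ValueError):
    """Raised when a trial or trace violates its structural invariants."""


@dataclass
class SensorTrace:
    """One placement's synchronized angular-velocity and orientation channels.

    Parameters
    ----------
    placement : str
        One of :data:`PLACEMENTS` (or a derived label such as
        ``"sternum_minus_sacrum"`` for relative channels).
    fs : float
        Sampling rate in Hz.
    t : ndarray, shape (n,)
        Time vector in seconds, strictly increasing with spacing ≈ 1/fs.
    gyro : ndarray, shape (n, 3)
        Angular velocity in °/s; columns are flexext, lateral, rotation.
    angle : ndarray, shape (n, 3)
        Orientation angles in °, same column order.
    """

    placement: str
    fs: float
    t: np.ndarray
    gyro: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    def channel(self, kind: str, direction: str) -> np.ndarray:
        """Return one channel; *kind* is ``"gyro"`` or ``"angle"``."""
        j = DIRECTIONS.index(direction)
        return (self.gyro if kind == "gyro" else self.angle)[:, j]

    def validate(self, *, dt_tol: float = 0.01) -> "SensorTrace":
        n = self.t.shape[0]
        if n < 2:
            raise TrialValidationError(
                f"{self.placement}: need at least 2 samples, got {n}")
        for name, arr in (("gyro", self.gyro), ("angle", self.angle)):
            if arr.shape != (n, 3):
                raise TrialValidationError(
                    f"{self.placement}: {name} shape {arr.shape} != ({n}, 3)")
            bad = np.argwhere(~np.isfinite(arr))
            if bad.size:
                raise TrialValidationError(
                    f"{self.placement}: non-finite {name} value at row "
                    f"{int(bad[0, 0])}")
        if not self.fs > 0:
            raise TrialValidationError(f"{self.placement}: fs must be > 0")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise TrialValidationError(
                f"{self.placement}: time not strictly increasing at row {i + 1}")
        expected = 1.0 / self.fs
        if np.any(np.abs(dt - expected) > dt_tol * expected):
            i = int(np.argmax(np.abs(dt - expected) > dt_tol * expected))
            raise TrialValidationError(
                f"{self.placement}: sample spacing {dt[i]:.6g} s at row {i + 1} "
                f"deviates from 1/fs = {expected:.6g} s by more than {dt_tol:.0%}")
        return self


@dataclass
class TurnTrial:
    """A participant's four sensor traces plus trial metadata.

    ``ground_truth`` is populated only for synthetic trials and holds the
    generator's exact construction parameters
    (:class:`turnkin.synthetic.GroundTruth`).
    """

    participant_id: str
    group: str
    leading_side: str
    turn_direction: str
    traces: dict = field(default_factory=dict)
    ground_truth: Optional[object] = None

    @property
    def fs(self) -> float:
        return next(iter(self.traces.values())).fs

    @property
    def leading_shank(self) -> SensorTrace:
        return self.traces["shank_left" if self.leading_side == "left"
                           else "shank_right"]

    @property
    def trailing_shank(self) -> SensorTrace:
        return self.traces["shank_right" if self.leading_side == "left"
                           else "shank_left"]

    def validate(self) -> "TurnTrial":
        if self.group not in GROUPS:
            raise TrialValidationError(f"unknown group {self.group!r}")
        if self.leading_side not in ("left", "right"):
            raise TrialValidationError(
                f"unknown leading side {self.leading_side!r}")
        if self.turn_direction not in ("cw", "ccw"):
            raise TrialValidationError(
                f"unknown turn direction {self.turn_direction!r}")
        missing = [p for p in PLACEMENTS if p not in self.traces]
        if missing:
            raise TrialValidationError(
                f"trial {self.participant_id}: missing placement(s) "
                f"{', '.join(missing)}")
        ref = self.traces[PLACEMENTS[0]]
        for p in PLACEMENTS:
            tr = self.traces[p].validate()
            if tr.fs != ref.fs or tr.n_samples != ref.n_samples or \
                    not np.allclose(tr.t, ref.t):
                raise TrialValidationError(
                    f"trial {self.participant_id}: trace {p} is not on the "
                    f"shared time base")
        return self

    def meta(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "group": self.group,
            "leading_side": self.leading_side,
            "turn_direction": self.turn_direction,
            "fs": self.fs,
        }


# ---------------------------------------------------------------------------
# trial round-trip

def write_trial(trial: TurnTrial, directory) -> Path:
    """Write one CSV per placement plus ``meta.yaml`` (and ground truth JSON).

    The dialect is UTF-8, '.' decimal, comma-separated, with the header
    ``time,gyro_flexext,...,ang_rotation``.  Float values are written with
    :func:`repr` precision so that ``read_trial(write_trial(x)) == x`` to
    float round-trip accuracy.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trial.validate()
    for placement, tr in trial.traces.items():
        df = pd.DataFrame(
            np.column_stack([tr.t, tr.gyro, tr.angle]),
            columns=list(TRIAL_COLUMNS))
        df.to_csv(directory / f"{placement}.csv", index=False)
    with open(directory / "meta.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(trial.meta(), fh, sort_keys=True)
    if trial.ground_truth is not None:
        with open(directory / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(trial.ground_truth.to_dict(), fh, indent=1, sort_keys=True)
    return directory


def read_trial(directory, meta: Optional[dict] = None,
               axis_maps: Optional[dict] = None) -> TurnTrial:
    """Read a trial from *directory*.

    Parameters
    ----------
    directory : path
        Directory containing one ``<placement>.csv`` per placement.
    meta : dict, optional
        Trial metadata (participant_id, group, leading_side, turn_direction,
        fs).  When omitted, the ``meta.yaml`` sidecar is read instead.
    axis_maps : dict, optional
        Per-placement axis relabeling passed to
        :func:`turnkin.preprocess.axis_map`; identity when omitted.
    """
    from .preprocess import axis_map  # local import to avoid a cycle

    directory = Path(directory)
    if meta is None:
        meta_path = directory / "meta.yaml"
        if not meta_path.exists():
            raise TrialValidationError(f"no metadata given and {meta_path} absent")
        with open(meta_path, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
    fs = float(meta["fs"])
    traces = {}
    for placement in PLACEMENTS:
        path = directory / f"{placement}.csv"
        if not path.exists():
            raise TrialValidationError(
                f"missing placement file for {placement}: {path}")
        df = pd.read_csv(path)
        if list(df.columns) != list(TRIAL_COLUMNS):
            raise TrialValidationError(
                f"{path}: expected columns {TRIAL_COLUMNS}, got "
                f"{tuple(df.columns)}")
        bad = np.argwhere(df.isna().to_numpy())
        if bad.size:
            raise TrialValidationError(
                f"{path}: NaN cell at data row {int(bad[0, 0])}")
        gyro = df[["gyro_flexext", "gyro_lateral", "gyro_rotation"]].to_numpy()
        angle = df[["ang_flexext", "ang_lateral", "ang_rotation"]].to_numpy()
        if axis_maps is not None and placement in axis_maps:
            gyro = axis_map(placement, gyro, axis_maps)
            angle = axis_map(placement, angle, axis_maps)
        traces[placement] = SensorTrace(
            placement=placement, fs=fs, t=df["time"].to_numpy(),
            gyro=gyro, angle=angle)
    ground_truth = None
    gt_path = directory / "ground_truth.json"
    if gt_path.exists():
        from .synthetic import GroundTruth
        with open(gt_path, encoding="utf-8") as fh:
            ground_truth = GroundTruth.from_dict(json.load(fh))
    trial = TurnTrial(
        participant_id=str(meta["participant_id"]), group=meta["group"],
        leading_side=meta["leading_side"], turn_direction=meta["turn_direction"],
        traces=traces, ground_truth=ground_truth)
    return trial.validate()


# ---------------------------------------------------------------------------
# feature tables

def features_to_frame(records) -> pd.DataFrame:
    """Convert FeatureRecords to a long-format frame sorted by key."""
    rows = [
        {
            "participant_id": r.participant_id,
            "parameter": r.parameter,
            "placement": r.placement,
            "direction": r.direction,
            "scheme": r.scheme,
            "partition_index": r.partition_index,
            "group": r.group,
            "value": r.value,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no feature records to write")
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    key = list(FEATURE_COLUMNS[:6])
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate feature key "
            + repr(tuple(first[k] for k in key)))
    return df.sort_values(key, kind="mergesort").reset_index(drop=True)


def write_features(records, path) -> Path:
    """Write FeatureRecords as a deterministic long-format CSV.

    One row per (participant, parameter, placement, direction, scheme,
    partition_index); rows sorted by the full key, stable column order.
    Writing the result of :func:`read_features` again is byte-identical.
    """
    path = Path(path)
    features_to_frame(records).to_csv(path, index=False)
    return path


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"participant_id": str, "direction": str})
    # undefined values (e.g. flagged leg ratios) round-trip as empty cells
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def frame_to_records(df: pd.DataFrame):
    """Inverse of :func:`features_to_frame`."""
    from .kinematic_features import FeatureRecord
    return [
        FeatureRecord(
            participant_id=row.participant_id, group=row.group,
            parameter=row.parameter, placement=row.placement,
            direction=row.direction, scheme=row.scheme,
            partition_index=int(row.partition_index), value=float(row.value))
        for row in df.itertuples()
    ]
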