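"""Angular partitioning of the turn from the trailing shank's rotation.

Temporal segmentation needs a repeating pattern; the trailing (affected)
shank rarely shows one.  Spatial segmentation sidesteps this: the
cumulative axial-rotation angle of the trailing shank rises monotonically
from 0 to the total covered angle (~360°), and dividing that angle into
``k`` equal parts yields time boundaries that are pattern-free.  All
``k ∈ {2,…,7}`` are supported; published comparisons use the half-turn
(k=2) and quarter-turn (k=4) partitions.

The total rotation is measured per trial — the actually covered angle —
rather than assumed to be exactly 360°.  Small noise dips are absorbed by
taking the running maximum of the rotation series before crossing
detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NoTurnError

K_RANGE = range(2, 8)


@dataclass
class PartitionSet:
    """Time-index boundaries dividing the turn into k equal angular parts."""

    k: int
    boundaries_idx: list    # k+1 sample indices: start, crossings, end
    boundary_angles: list   # cumulative rotation (°) at those indices
    total_rotation: float   # ° covered between start and end

    def __post_init__(self):
        if len(self.boundaries_idx) != self.k + 1:
            raise ValueError(f"need k+1 = {self.k + 1} boundaries, got "
                             f"{len(self.boundaries_idx)}")
        if any(b <= a for a, b in zip(self.boundaries_idx,
                                      self.boundaries_idx[1:])):
            raise ValueError("boundaries must be strictly increasing")

    def intervals(self) -> list:
        """Half-open sample intervals tiling the turn without overlap.

        Partition ``j < k−1`` covers ``[b_j, b_{j+1})``; the last covers
        ``[b_{k−1}, b_k]`` so the union is exactly the turn interval.
        """
        b = self.boundaries_idx
        out = [(b[j], b[j + 1]) for j in range(self.k - 1)]
        out.append((b[self.k - 1], b[self.k] + 1))
        return out

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "boundaries_idx": [int(i) for i in self.boundaries_idx],
            "boundary_angles": [float(a) for a in self.boundary_angles],
            "total_rotation": float(self.total_rotation),
        }


def partition_turn(rotation, k: int, fs: float | None = None,
                   angle_eps: float = 2.0,
                   backtrack_tol: float = 10.0) -> PartitionSet:
    """Divide a cumulative rotation series into *k* equal angular parts.

    Parameters
    ----------
    rotation : array
        Cumulative rotation in °, non-decreasing during the turn apart from
        noise, starting near 0 (see
        :func:`turnkin.preprocess.cumulative_rotation`).
    k : int
        Number of partitions, 2–7.
    angle_eps : float
        Angle tolerance (°) for locating the start of the turn and the
        final plateau.
    backtrack_tol : float
        Maximum tolerated dip below the running maximum before the series
        is declared non-monotone.

    Internal boundary ``j`` is the sample whose running-maximum rotation is
    nearest the crossing of ``j × total / k`` (never past the next
    boundary); the start is the first sample above ``angle_eps`` and the
    end the first sample within ``angle_eps`` of the total covered angle.
    """
    if k not in K_RANGE:
        raise ValueError(f"k must be in {list(K_RANGE)}, got {k}")
    x = np.asarray(rotation, dtype=float)
    run = np.maximum.accumulate(x)
    backtrack = float(np.max(run - x))
    if backtrack > backtrack_tol:
        raise ValueError(
            f"rotation series non-monotone beyond tolerance: max backtrack "
            f"{backtrack:.2f}° > {backtrack_tol}°")
    total = float(run[-1])
    if total < 90.0:
        raise NoTurnError(
            f"no turn detected: total rotation {total:.1f}° < 90°")

    start = int(np.argmax(run >= angle_eps))
    end = int(np.argmax(run >= total - angle_eps))
    boundaries = [start]
    for j in range(1, k):
        target = j * total / k
        idx = int(np.argmax(run >= target))
        # nearest-sample crossing: halves the quantization error on fast turns
        if idx > 0 and target - run[idx - 1] < run[idx] - target:
            idx -= 1
        boundaries.append(idx)
    boundaries.append(end)
    # guard against duplicate indices on extremely steep ramps
    for i in range(1, len(boundaries)):
        if boundaries[i] <= boundaries[i - 1]:
            boundaries[i] = boundaries[i - 1] + 1
    return PartitionSet(
        k=k, boundaries_idx=boundaries,
        boundary_angles=[float(run[min(i, run.size - 1)]) for i in boundaries],
        total_rotation=total)


def partition_all(rotation, ks=tuple(K_RANGE), **kwargs) -> dict:
    """Compute :func:`partition_turn` for every requested k."""
    return {k: partition_turn(rotation, k, **kwargs) for k in ks}
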