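"""Floor calibration from empty-scene depth frames.

The board is treated as a single flat reference at one distance (no tilt
fit): the floor distance is the median across frames of the per-frame
median depth over a central region, and the dispersion is the median
absolute deviation of those per-frame medians.  A known-height object can
then be measured to verify the rig end to end.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .bundle import INVALID_DEPTH

Region = Tuple[int, int, int, int]   # (row0, row1, col0, col1), half-open


@dataclass(frozen=True)
class FloorEstimate:
    floor_distance_cm: float
    dispersion_cm: float          # MAD of the per-frame medians
    n_frames: int
    region: Region

    def __post_init__(self) -> None:
        if self.floor_distance_cm <= 0:
            raise ValueError("floor_distance_cm must be positive")
        if self.dispersion_cm < 0:
            raise ValueError("dispersion_cm must be non-negative")


def central_region(shape: Tuple[int, int], fraction: float = 0.5) -> Region:
    """Central ``fraction`` of rows and columns (edges of the board and the
    pen walls are unreliable, so the default excludes them)."""
    rows, cols = shape
    dr, dc = int(rows * fraction / 2), int(cols * fraction / 2)
    r0, c0 = rows // 2 - dr, cols // 2 - dc
    return (r0, r0 + 2 * dr, c0, c0 + 2 * dc)


def estimate_floor_distance(
    frames: Sequence[np.ndarray],
    region: Optional[Region] = None,
) -> FloorEstimate:
    """Median-of-medians floor distance over empty-scene frames.

    Invalid (zero) pixels are excluded; a frame whose region is entirely
    invalid raises.  Robust to dropout and, by the median, to moderate
    contamination of the region.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    if region is None:
        region = central_region(frames.shape[1:])
    r0, r1, c0, c1 = region
    rows, cols = frames.shape[1:]
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"region {region} outside frame bounds {(rows, cols)}")

    medians = []
    for i, f in enumerate(frames):
        patch = f[r0:r1, c0:c1]
        valid = patch[patch != INVALID_DEPTH]
        if valid.size == 0:
            raise ValueError(f"frame {i}: calibration region contains no valid pixels")
        medians.append(np.median(valid))
    medians = np.asarray(medians)
    floor = float(np.median(medians))
    mad = 0.0 if medians.size == 1 else float(stats.median_abs_deviation(medians))
    return FloorEstimate(floor, mad, int(frames.shape[0]), region)


def verify_known_object(
    frames: Sequence[np.ndarray],
    floor: FloorEstimate,
    true_height_cm: float,
) -> float:
    """Signed error (cm) of the rig on an object of known height.

    The measured height is ``floor_distance - min valid depth`` over all
    frames; the return value is ``measured - true``.  What error is
    acceptable is a deployment decision, so only the signed error is
    reported.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    valid = frames[frames != INVALID_DEPTH]
    if valid.size == 0:
        raise ValueError("no valid pixels in verification frames")
    measured = floor.floor_distance_cm - float(valid.min())
    if measured <= max(3.0 * floor.dispersion_cm, 1.0):
        warnings.warn(
            "verification scene is degenerate: nothing detectably above the floor "
            f"(measured {measured:.2f} cm)")
    return measured - true_height_cm
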