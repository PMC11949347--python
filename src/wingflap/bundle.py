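"""In-memory containers for paired depth/RGB recordings.

Depth frames are 2-D float arrays in centimetres with ``0.0`` encoding an
invalid pixel (no sensor return).  Valid depths are quantised to 0.1 cm, the
storage resolution of the on-disk container.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: storage resolution of depth values, cm per stored unit
DEPTH_SCALE_CM = 0.1
#: pixel value marking "no sensor return"
INVALID_DEPTH = 0.0


def quantize_depth(depth_cm: np.ndarray) -> np.ndarray:
    """Snap depths to the 0.1 cm container resolution (invalid stays 0)."""
    return np.round(np.asarray(depth_cm, dtype=np.float64) / DEPTH_SCALE_CM) * DEPTH_SCALE_CM


@dataclass
class GroundTruth:
    """Per-depth-frame true maximum surface height for a synthetic bout."""

    max_height_cm: np.ndarray      # (n_depth_frames,) true max height per frame
    peak_frame_index: int          # frame attaining the bout maximum

    def __post_init__(self) -> None:
        self.max_height_cm = np.asarray(self.max_height_cm, dtype=float)
        if self.max_height_cm.ndim != 1 or self.max_height_cm.size == 0:
            raise ValueError("max_height_cm must be a non-empty 1-D array")
        if not (0 <= self.peak_frame_index < self.max_height_cm.size):
            raise ValueError("peak_frame_index out of range")

    @property
    def bout_max(self) -> float:
        return float(self.max_height_cm.max())


@dataclass
class SequenceBundle:
    """One recording: depth stream + RGB stream + rig metadata.

    Invariants (checked on construction): timestamps strictly increase
    within each stream and frame counts match timestamp counts.
    """

    depth_frames: np.ndarray       # (n, rows, cols) float cm, 0 = invalid
    depth_timestamps: np.ndarray   # (n,) seconds
    rgb_frames: np.ndarray         # (m, rows, cols, 3) uint8
    rgb_timestamps: np.ndarray     # (m,) seconds
    rig: "CameraRig"
    ground_truth: Optional[GroundTruth] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth_frames = np.asarray(self.depth_frames)
        self.rgb_frames = np.asarray(self.rgb_frames)
        self.depth_timestamps = np.asarray(self.depth_timestamps, dtype=float)
        self.rgb_timestamps = np.asarray(self.rgb_timestamps, dtype=float)
        if self.depth_frames.shape[0] != self.depth_timestamps.shape[0]:
            raise ValueError("depth frame count does not match timestamp count")
        if self.rgb_frames.shape[0] != self.rgb_timestamps.shape[0]:
            raise ValueError("rgb frame count does not match timestamp count")
        for name, ts in (("depth", self.depth_timestamps), ("rgb", self.rgb_timestamps)):
            if ts.size > 1 and not np.all(np.diff(ts) > 0):
                raise ValueError(f"{name} timestamps must be strictly increasing")
        if self.ground_truth is not None:
            if self.ground_truth.max_height_cm.size != self.depth_frames.shape[0]:
                raise ValueError("ground truth length does not match depth stream")

    @property
    def n_depth(self) -> int:
        return int(self.depth_frames.shape[0])

    @property
    def n_rgb(self) -> int:
        return int(self.rgb_frames.shape[0])


from .rig import CameraRig  # noqa: E402  (type used above by name)
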