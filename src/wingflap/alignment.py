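"""Pairing the fast depth stream with the slower RGB stream, and mapping
RGB frames onto depth-pixel coordinates.

Pairing is nearest-timestamp selection, one pair per RGB frame — not
triplet averaging, which would bias the depth minima the height analysis
depends on.  Height extraction itself runs on *all* depth frames; the
pairing exists so that masks and peak markers can be overlaid on colour
frames for visual verification.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

from .rig import CameraRig


@dataclass(frozen=True)
class PairedFrame:
    rgb_index: int
    depth_index: int
    gap_s: float

    def __post_init__(self) -> None:
        if self.gap_s < 0:
            raise ValueError("gap_s must be non-negative")


@dataclass(frozen=True)
class RegistrationMap:
    """Crop-then-scale map from RGB coordinates to depth coordinates.

    ``scale`` is depth pixels per RGB pixel; ``crop`` is the RGB-frame
    window (row0, row1, col0, col1), half-open, that maps onto the full
    depth frame.
    """

    scale: float
    crop: Tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        r0, r1, c0, c1 = self.crop
        if not (r0 < r1 and c0 < c1):
            raise ValueError("crop window must be non-empty")

    @property
    def row_offset(self) -> int:
        return self.crop[0]

    @property
    def col_offset(self) -> int:
        return self.crop[2]


def ground_truth_registration(rig: CameraRig) -> RegistrationMap:
    """The exact registration map for synthetic bundles, where the RGB
    render is the depth field of view uniformly rescaled and centred."""
    drows, dcols = rig.depth_resolution
    rrows, rcols = rig.rgb_resolution
    k = rrows / drows                      # RGB px per depth px
    out_w = int(round(dcols * k))
    off = (rcols - out_w) // 2
    return RegistrationMap(scale=1.0 / k, crop=(0, rrows, off, off + out_w))


def pair_streams(
    depth_timestamps: Sequence[float],
    rgb_timestamps: Sequence[float],
) -> List[PairedFrame]:
    """Pair each RGB frame with the depth frame of minimal |dt|.

    Ties are broken toward the earlier depth frame.  Depth indices across
    successive pairs are non-decreasing by construction.
    """
    dts = np.asarray(depth_timestamps, dtype=float)
    rts = np.asarray(rgb_timestamps, dtype=float)
    if dts.size == 0:
        raise ValueError("depth stream is empty")
    if np.any(np.diff(dts) < 0) or np.any(np.diff(rts) < 0):
        raise ValueError("timestamps must be sorted")
    if rts.size == 0:
        return []
    pos = np.searchsorted(dts, rts)
    pairs = []
    for j, t in enumerate(rts):
        lo = max(int(pos[j]) - 1, 0)
        hi = min(int(pos[j]), dts.size - 1)
        # earlier frame wins ties because it is checked first with <=
        i = lo if abs(dts[lo] - t) <= abs(dts[hi] - t) else hi
        while i > 0 and abs(dts[i - 1] - t) == abs(dts[i] - t):
            i -= 1          # duplicate timestamps: keep the earliest
        pairs.append(PairedFrame(j, i, float(abs(dts[i] - t))))
    return pairs


def pairing_table(pairs: Sequence[PairedFrame]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.rgb_index, p.depth_index, p.gap_s) for p in pairs],
        columns=["rgb_index", "depth_index", "gap_s"],
    )


def write_pairing_table(pairs: Sequence[PairedFrame], path: Union[str, Path]) -> Path:
    path = Path(path)
    pairing_table(pairs).to_csv(path, index=False)
    return path


def register_rgb(
    rgb_frame: np.ndarray,
    reg: RegistrationMap,
    depth_resolution: Tuple[int, int],
) -> np.ndarray:
    """Crop an RGB frame and rescale it to the depth-frame geometry."""
    rgb_frame = np.asarray(rgb_frame)
    r0, r1, c0, c1 = reg.crop
    if not (0 <= r0 < r1 <= rgb_frame.shape[0] and 0 <= c0 < c1 <= rgb_frame.shape[1]):
        raise ValueError(f"crop {reg.crop} outside frame of shape {rgb_frame.shape[:2]}")
    sub = rgb_frame[r0:r1, c0:c1]
    rows, cols = depth_resolution
    if sub.shape[:2] == (rows, cols):
        return sub.copy()
    return np.asarray(Image.fromarray(sub).resize((cols, rows), Image.NEAREST))
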