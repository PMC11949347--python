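"""Core measurement: segment the bird against the floor and extract the
maximum vertical height per frame and per bout.

The chain mirrors a fixed overhead-camera protocol: pixels whose depth
falls strictly below a floor threshold (floor distance minus a clearance,
5 cm by default, i.e. 245 cm for a 250 cm camera) form the foreground mask;
the frame's maximum height is ``camera_height - min(masked depth)`` with
the minimising pixel recorded as the "peak pixel"; and a bout reduces to
the maximum over its frames.

Two speckle-handling modes exist.  The faithful default takes the raw
minimum (no prefilter, ``min_component_px=1``).  The robust mode adds a
3x3 median prefilter and drops 8-connected components smaller than
``min_component_px``, because a single hot pixel otherwise sets the
height.  Which mode produced a number is always recorded alongside it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .bundle import INVALID_DEPTH

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class HenMask:
    """Binary foreground mask aligned to a depth frame."""

    mask: np.ndarray

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return not self.mask.any()


@dataclass(frozen=True)
class FrameHeight:
    frame_index: int
    max_height_cm: Optional[float]
    peak_pixel: Optional[Tuple[int, int]]
    n_foreground: int
    empty: bool

    @classmethod
    def empty_frame(cls, frame_index: int) -> "FrameHeight":
        return cls(frame_index, None, None, 0, True)


@dataclass(frozen=True)
class BoutResult:
    hen_id: str
    max_height_cm: float
    frame_index: int
    n_frames: int
    n_nonempty: int


def floor_threshold(floor_distance_cm: float, clearance_cm: float = 5.0) -> float:
    """Depth cutoff separating bird pixels from the floor.

    ``threshold = floor_distance - clearance``; e.g. (250, 5) -> 245 cm.
    """
    if not (0 < clearance_cm < floor_distance_cm):
        raise ValueError("need 0 < clearance < floor distance")
    return floor_distance_cm - clearance_cm


def segment_hen(
    frame: np.ndarray,
    threshold_cm: float,
    min_component_px: int = 1,
    prefilter: bool = False,
) -> HenMask:
    """Threshold a depth frame into a foreground mask.

    Foreground pixels have valid depth strictly below the threshold, so the
    floor itself can never enter the mask under exact arithmetic.  With
    ``prefilter`` a 3x3 median of the depth must also clear the threshold
    (isolated hot pixels fail this); components smaller than
    ``min_component_px`` (8-connectivity) are then removed.  An empty mask
    is a valid result.
    """
    frame = np.asarray(frame, dtype=float)
    valid = frame != INVALID_DEPTH
    mask = valid & (frame < threshold_cm)
    if prefilter and mask.any():
        # invalid pixels must not drag the median down: treat them as far
        filled = np.where(valid, frame, np.inf)
        med = ndimage.median_filter(filled, size=3, mode="nearest")
        mask &= med < threshold_cm
    if min_component_px > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=_EIGHT)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_component_px
            keep[0] = False
            mask = keep[labels]
    return HenMask(mask)


def frame_max_height(
    frame: np.ndarray,
    mask: HenMask,
    camera_height_cm: float,
    frame_index: int = 0,
) -> FrameHeight:
    """Maximum height in one frame: ``camera_height - min(masked depth)``.

    The peak pixel is the location of the minimising depth; ties break to
    the first pixel in row-major order.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != mask.mask.shape:
        raise ValueError("mask and frame shapes differ")
    if mask.empty:
        return FrameHeight.empty_frame(frame_index)
    d = np.where(mask.mask, frame, np.inf)
    flat = int(np.argmin(d))            # argmin returns the first minimum
    r, c = np.unravel_index(flat, d.shape)
    return FrameHeight(
        frame_index=frame_index,
        max_height_cm=float(camera_height_cm - d[r, c]),
        peak_pixel=(int(r), int(c)),
        n_foreground=mask.n_foreground,
        empty=False,
    )


def extract_frame_heights(
    frames: Sequence[np.ndarray],
    threshold_cm: float,
    camera_height_cm: float,
    min_component_px: int = 1,
    prefilter: bool = False,
) -> List[FrameHeight]:
    """Segment and measure every frame of a bout."""
    out = []
    for i, f in enumerate(frames):
        m = segment_hen(f, threshold_cm, min_component_px, prefilter)
        out.append(frame_max_height(f, m, camera_height_cm, i))
    return out


def bout_max_height(heights: Sequence[FrameHeight], hen_id: str) -> BoutResult:
    """Across-frame maximum-height reduction for one bout.

    Ties go to the earliest frame; a bout in which the bird never rose
    above the threshold is an error, not a silent zero.
    """
    nonempty = [h for h in heights if not h.empty]
    if not nonempty:
        raise ValueError(f"hen {hen_id}: no frame has foreground above the threshold")
    best = nonempty[0]
    for h in nonempty[1:]:
        if h.max_height_cm > best.max_height_cm:
            best = h
    return BoutResult(
        hen_id=hen_id,
        max_height_cm=float(best.max_height_cm),
        frame_index=int(best.frame_index),
        n_frames=len(heights),
        n_nonempty=len(nonempty),
    )


def render_overlay(
    rgb_registered: np.ndarray,
    mask: HenMask,
    peak_pixel: Optional[Tuple[int, int]],
    dot_radius: int = 4,
) -> np.ndarray:
    """Tint the mask and mark the peak pixel with a red disc (on a copy)."""
    img = np.asarray(rgb_registered)
    if img.shape[:2] != mask.mask.shape:
        raise ValueError("overlay image and mask shapes differ")
    out = img.copy()
    if mask.mask.any():
        tint = np.array([255, 255, 0], dtype=float)     # translucent yellow
        out[mask.mask] = (0.5 * out[mask.mask] + 0.5 * tint).astype(out.dtype)
    if peak_pixel is not None:
        r, c = peak_pixel
        rows, cols = out.shape[:2]
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"peak pixel {peak_pixel} outside image {(rows, cols)}")
        yy, xx = np.ogrid[:rows, :cols]
        disc = (yy - r) ** 2 + (xx - c) ** 2 <= dot_radius ** 2
        out[disc] = np.array([255, 0, 0], dtype=out.dtype)
    return out
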