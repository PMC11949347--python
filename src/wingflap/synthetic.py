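"""Synthetic top-down depth/RGB scenes of a standing, wing-flapping hen.

The study geometry this emulates: a depth camera faces straight down at a
flat board 250 cm below; a white hen stands on the black board and flaps her
wings while stationary, and the sensor records 90 depth frames per second
(with a slower colour stream alongside).  Real recordings of this kind are
rarely shareable, so this module produces physically plausible stand-ins
with exact per-frame ground truth.

Geometry model
--------------
The scene is a heightfield ``h(x, y)`` over the floor plane and the camera
is orthographic along its axis: every pixel reads
``depth = camera_height - h`` at its floor position.  The hen is

* a half-ellipsoid body resting on the floor, and
* two planar wing panels hinged at shoulder height that sweep upward with
  elevation angle ``theta(t)``, a rectified sinusoid between the rest and
  peak angles.

The highest point of the scene is therefore known in closed form,
``shoulder_height + wing_length * sin(theta)`` (or the body apex when the
wings are low), which is what makes the renders usable as ground truth for
the measurement pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from PIL import Image

from .bundle import DEPTH_SCALE_CM, INVALID_DEPTH, GroundTruth, SequenceBundle, quantize_depth
from .rig import CameraRig, FlapConfig

__all__ = [
    "Pose",
    "PoseSequence",
    "flap_pose_trajectory",
    "render_heightfield",
    "render_depth_frame",
    "render_rgb_frame",
    "apply_sensor_noise",
    "generate_sequence",
    "render_floor_frames",
    "render_block_frame",
]


@dataclass(frozen=True)
class Pose:
    """Scene state at one instant: the body geometry plus wing elevation."""

    theta_deg: float
    config: FlapConfig

    @property
    def tip_height(self) -> float:
        """Analytic wing-tip height (cm) at this elevation."""
        return self.config.shoulder_height + self.config.wing_length * math.sin(
            math.radians(self.theta_deg))

    @property
    def max_surface_height(self) -> float:
        """True maximum height of any surface point (tip or body apex)."""
        return max(self.tip_height, self.config.standing_height)


@dataclass
class PoseSequence:
    """One pose per depth-frame timestamp of a bout."""

    timestamps: np.ndarray     # (n,) seconds
    theta_deg: np.ndarray      # (n,) wing elevation
    tip_height: np.ndarray     # (n,) analytic wing-tip height, cm
    config: FlapConfig
    rig: CameraRig

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def pose(self, i: int) -> Pose:
        return Pose(float(self.theta_deg[i]), self.config)


def _theta_at(t: np.ndarray, config: FlapConfig) -> np.ndarray:
    """Rectified-sinusoid elevation: wings oscillate above the rest angle.

    ``theta(t) = rest + (peak - rest) * |sin(pi * f * t)|`` gives exactly
    ``f`` peaks per second and never dips below the rest angle, matching a
    stationary flap in which the wings are repeatedly thrown upward.
    """
    amp = config.peak_angle - config.rest_angle
    return config.rest_angle + amp * np.abs(np.sin(np.pi * config.flap_frequency * t))


def flap_pose_trajectory(config: FlapConfig, rig: CameraRig) -> PoseSequence:
    """Sample the wing-elevation trajectory at the depth-frame rate."""
    n = int(round(config.duration * rig.depth_fps))
    if n < 1:
        raise ValueError("duration too short for a single depth frame")
    t = np.arange(n, dtype=float) / rig.depth_fps
    theta = _theta_at(t, config)
    tip = config.shoulder_height + config.wing_length * np.sin(np.radians(theta))
    return PoseSequence(t, theta, tip, config, rig)


def _grid_coords(rig: CameraRig) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = rig.depth_resolution
    y = (np.arange(rows) - (rows - 1) / 2.0) * rig.pixel_pitch
    x = (np.arange(cols) - (cols - 1) / 2.0) * rig.pixel_pitch
    return y, x


def render_heightfield(pose: Pose, rig: CameraRig) -> np.ndarray:
    """Rasterise the hen surface into a per-pixel height map (cm).

    The body ellipsoid is evaluated analytically on the grid; the wing
    panels are scatter-sampled at sub-pixel spacing and combined with a
    max-reduction, which is the orthographic equivalent of z-buffering
    (the surface nearest the overhead camera is the highest one).
    """
    cfg = pose.config
    if pose.max_surface_height >= rig.camera_height:
        raise ValueError("scene geometry reaches the camera plane")
    rows, cols = rig.depth_resolution
    pitch = rig.pixel_pitch
    H = np.zeros((rows, cols), dtype=np.float64)
    yc, xc = _grid_coords(rig)

    # body: half-ellipsoid, long axis along x (columns); only its bounding
    # box needs evaluating
    a, b, c = cfg.body_length / 2.0, cfg.body_width / 2.0, cfg.standing_height
    rsel = np.flatnonzero(np.abs(yc) <= b)
    csel = np.flatnonzero(np.abs(xc) <= a)
    if rsel.size and csel.size:
        r0, r1 = rsel[0], rsel[-1] + 1
        c0, c1 = csel[0], csel[-1] + 1
        q = 1.0 - (xc[None, c0:c1] / a) ** 2 - (yc[r0:r1, None] / b) ** 2
        body = np.where(q > 0.0, c * np.sqrt(np.clip(q, 0.0, None)), 0.0)
        np.maximum(H[r0:r1, c0:c1], body, out=H[r0:r1, c0:c1])

    # wings: planar panels hinged at +/- y0, chord along x
    theta = math.radians(pose.theta_deg)
    chord = 0.55 * cfg.body_length
    y0 = 0.4 * cfg.body_width
    ds = pitch / 3.0
    s = np.linspace(0.0, cfg.wing_length, max(2, int(math.ceil(cfg.wing_length / ds)) + 1))
    u = np.linspace(-chord / 2.0, chord / 2.0, max(2, int(math.ceil(chord / ds)) + 1))
    wy = y0 + s * math.cos(theta)          # lateral reach of each span sample
    wh = cfg.shoulder_height + s * math.sin(theta)
    # scatter both wings; row index from +/- wy, column from chord position
    for sign in (1.0, -1.0):
        rr = np.rint(sign * wy / pitch + (rows - 1) / 2.0).astype(int)
        cc = np.rint(u / pitch + (cols - 1) / 2.0).astype(int)
        R = np.repeat(rr, cc.size)
        C = np.tile(cc, rr.size)
        V = np.repeat(wh, cc.size)
        ok = (R >= 0) & (R < rows) & (C >= 0) & (C < cols)
        np.maximum.at(H, (R[ok], C[ok]), V[ok])
    return H


def render_depth_frame(pose: Pose, rig: CameraRig) -> np.ndarray:
    """Orthographic depth render: ``depth = camera_height - height``."""
    H = render_heightfield(pose, rig)
    return rig.camera_height - H


def render_rgb_frame(pose: Pose, rig: CameraRig) -> np.ndarray:
    """Shaded colour render on the RGB canvas: white hen on a black board.

    The depth-geometry shade image is uniformly rescaled and centred on the
    (wider) RGB canvas, so the crop-and-scale map back to depth pixels is
    known exactly.
    """
    H = render_heightfield(pose, rig)
    rows, cols = rig.depth_resolution
    yc, xc = _grid_coords(rig)
    on_board = (np.abs(yc[:, None]) <= rig.board_side / 2.0) & (
        np.abs(xc[None, :]) <= rig.board_side / 2.0)
    shade = np.where(on_board, 25.0, 90.0)
    hen = H > 0.0
    if hen.any():
        hmax = max(float(H.max()), 1.0)
        shade = np.where(hen, 215.0 + 40.0 * H / hmax, shade)
    shade8 = np.clip(shade, 0, 255).astype(np.uint8)

    rgb_rows, rgb_cols = rig.rgb_resolution
    k = rgb_rows / rows
    out_w = int(round(cols * k))
    if out_w > rgb_cols:
        raise ValueError("RGB canvas narrower than the scaled depth field of view")
    scaled = np.asarray(Image.fromarray(shade8).resize((out_w, rgb_rows), Image.NEAREST))
    canvas = np.full((rgb_rows, rgb_cols), 10, dtype=np.uint8)
    off = (rgb_cols - out_w) // 2
    canvas[:, off:off + out_w] = scaled
    return np.repeat(canvas[:, :, None], 3, axis=2)


def apply_sensor_noise(
    frame: np.ndarray,
    noise_sigma: float,
    dropout_rate: float,
    seed: Union[int, np.random.Generator, None] = 0,
) -> np.ndarray:
    """Add Gaussian depth noise and random pixel dropout.

    Noise is zero-mean with SD ``noise_sigma`` (cm) on valid pixels only;
    a ``dropout_rate`` fraction of pixels is then set to the invalid code.
    Deterministic for a given seed (or pass a Generator to share a stream).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if not (0.0 <= dropout_rate <= 1.0):
        raise ValueError("dropout_rate must be in [0, 1]")
    frame = np.asarray(frame, dtype=np.float64)
    out = frame.copy()
    if noise_sigma == 0 and dropout_rate == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    valid = frame != INVALID_DEPTH
    if noise_sigma > 0:
        out[valid] += rng.normal(0.0, noise_sigma, int(valid.sum()))
        # noise may not push a return through the floor of representable depth
        np.clip(out, DEPTH_SCALE_CM, None, out=out)
        out[~valid] = INVALID_DEPTH
    if dropout_rate > 0:
        drop = rng.random(frame.shape) < dropout_rate
        out[drop] = INVALID_DEPTH
    return out


def generate_sequence(
    config: FlapConfig,
    rig: Optional[CameraRig] = None,
    hen_id: str = "synthetic",
) -> SequenceBundle:
    """Simulate one full bout: depth at ``depth_fps``, RGB at ``rgb_fps``.

    Returns a :class:`SequenceBundle` whose ``ground_truth`` holds the
    analytic per-frame maximum surface height — computed from the pose
    closed form, independently of the renderer — and the index of the frame
    attaining the bout maximum.  Bit-reproducible for a given
    ``(config, rig)`` including ``config.seed``.
    """
    rig = rig or CameraRig()
    poses = flap_pose_trajectory(config, rig)
    if config.peak_tip_height >= rig.camera_height:
        raise ValueError("peak wing-tip height reaches the camera plane")
    rng = np.random.default_rng(config.seed)

    depth = np.empty((len(poses),) + tuple(rig.depth_resolution), dtype=np.float64)
    truth = np.empty(len(poses))
    for i in range(len(poses)):
        p = poses.pose(i)
        d = render_depth_frame(p, rig)
        d = apply_sensor_noise(d, config.noise_sigma, config.dropout_rate, rng)
        depth[i] = quantize_depth(d)
        truth[i] = p.max_surface_height

    m = int(round(config.duration * rig.rgb_fps))
    rgb_ts = np.arange(m, dtype=float) / rig.rgb_fps
    theta_rgb = _theta_at(rgb_ts, config)
    rgb = np.empty((m,) + tuple(rig.rgb_resolution) + (3,), dtype=np.uint8)
    for j in range(m):
        rgb[j] = render_rgb_frame(Pose(float(theta_rgb[j]), config), rig)

    gt = GroundTruth(truth, int(np.argmax(truth)))
    return SequenceBundle(
        depth_frames=depth,
        depth_timestamps=poses.timestamps,
        rgb_frames=rgb,
        rgb_timestamps=rgb_ts,
        rig=rig,
        ground_truth=gt,
        meta={"hen_id": hen_id, "seed": int(config.seed), "date": "synthetic"},
    )


def render_floor_frames(
    rig: CameraRig,
    n_frames: int,
    noise_sigma: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Empty-scene frames (flat board only) for floor calibration."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    base = np.full(tuple(rig.depth_resolution), rig.camera_height, dtype=np.float64)
    return np.stack([
        quantize_depth(apply_sensor_noise(base, noise_sigma, dropout_rate, rng))
        for _ in range(n_frames)
    ])


def render_block_frame(rig: CameraRig, height_cm: float, side_cm: float = 30.0) -> np.ndarray:
    """Scene with a centred rectangular block of known height (rig check)."""
    if not (0 <= height_cm < rig.camera_height):
        raise ValueError("block height must lie below the camera")
    rows, cols = rig.depth_resolution
    yc, xc = _grid_coords(rig)
    inside = (np.abs(yc[:, None]) <= side_cm / 2.0) & (np.abs(xc[None, :]) <= side_cm / 2.0)
    d = np.full((rows, cols), rig.camera_height, dtype=np.float64)
    d[inside] = rig.camera_height - height_cm
    return d
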