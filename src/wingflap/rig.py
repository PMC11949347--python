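"""Camera rig and flap-kinematics configuration.

The measurement geometry is a ceiling-mounted depth camera looking straight
down at a flat board.  Heights are always expressed in centimetres above the
board surface; the camera reports per-pixel distance along its optical axis,
so ``height = camera_height - depth``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass(frozen=True)
class CameraRig:
    """Geometry and timing of the top-down depth/RGB rig.

    Parameters
    ----------
    camera_height:
        Distance (cm) from the camera face to the board surface.
    depth_fps, rgb_fps:
        Frame rates of the depth and colour streams.  The depth stream is
        the faster one; the colour stream is paired to it afterwards.
    depth_resolution, rgb_resolution:
        ``(rows, cols)`` of each stream.
    board_side:
        Side length (cm) of the square board the bird stands on.
    pixel_pitch:
        Footprint (cm) of one depth pixel on the floor plane.  The default
        0.6 cm/px is representative of a consumer stereo-depth sensor's
        floor footprint at a 2.5 m working distance.
    """

    camera_height: float = 250.0
    depth_fps: float = 90.0
    rgb_fps: float = 30.0
    depth_resolution: Tuple[int, int] = (480, 640)
    rgb_resolution: Tuple[int, int] = (720, 1280)
    board_side: float = 121.0
    pixel_pitch: float = 0.6

    def __post_init__(self) -> None:
        if not (self.camera_height > 0 and math.isfinite(self.camera_height)):
            raise ValueError("camera_height must be positive and finite")
        if self.depth_fps < self.rgb_fps:
            raise ValueError("depth_fps must be >= rgb_fps")
        if self.depth_fps <= 0 or self.rgb_fps <= 0:
            raise ValueError("frame rates must be positive")
        for res in (self.depth_resolution, self.rgb_resolution):
            if len(res) != 2 or res[0] <= 0 or res[1] <= 0:
                raise ValueError(f"resolution must be positive (rows, cols), got {res}")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.board_side <= 0:
            raise ValueError("board_side must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depth_resolution"] = list(self.depth_resolution)
        d["rgb_resolution"] = list(self.rgb_resolution)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CameraRig":
        d = dict(d)
        d["depth_resolution"] = tuple(d["depth_resolution"])
        d["rgb_resolution"] = tuple(d["rgb_resolution"])
        return cls(**d)


@dataclass(frozen=True)
class FlapConfig:
    """Kinematic stand-in for a standing, wing-flapping hen.

    The body is a half-ellipsoid resting on the floor; each wing is a planar
    panel hinged at the shoulder that sweeps up and down.  Wing elevation
    ``theta(t)`` follows a rectified sinusoid between ``rest_angle`` and
    ``peak_angle`` (wings never drop below rest), so the analytic peak of
    the wing tip is ``shoulder_height + wing_length * sin(peak_angle)``.

    None of the body dimensions are published measurements; they are
    plausible placeholders for a mature white egg-laying hen.
    """

    body_length: float = 35.0       # cm, along the bird's axis
    body_width: float = 16.0        # cm
    standing_height: float = 34.0   # cm, apex of the body ellipsoid
    shoulder_height: float = 30.0   # cm, wing hinge above the floor
    wing_length: float = 21.0       # cm, shoulder to tip
    rest_angle: float = 10.0        # deg above horizontal
    peak_angle: float = 72.0        # deg above horizontal
    flap_frequency: float = 4.0     # Hz
    duration: float = 2.0           # s
    noise_sigma: float = 0.3        # cm, per-pixel depth noise SD
    dropout_rate: float = 0.02      # fraction of pixels with no return
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.body_length, self.body_width, self.standing_height,
                self.shoulder_height, self.wing_length, self.rest_angle,
                self.peak_angle, self.flap_frequency, self.duration,
                self.noise_sigma, self.dropout_rate]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all FlapConfig values must be finite")
        if not (0.0 <= self.rest_angle <= self.peak_angle <= 90.0):
            raise ValueError("need 0 <= rest_angle <= peak_angle <= 90 degrees")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.wing_length <= 0:
            raise ValueError("wing_length must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if min(self.body_length, self.body_width, self.standing_height,
               self.shoulder_height) <= 0:
            raise ValueError("body dimensions must be positive")
        if self.flap_frequency < 0:
            raise ValueError("flap_frequency must be non-negative")

    @property
    def peak_tip_height(self) -> float:
        """Analytic maximum height (cm) of any body point during the bout."""
        tip = self.shoulder_height + self.wing_length * math.sin(
            math.radians(self.peak_angle))
        return max(tip, self.standing_height)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FlapConfig":
        return cls(**d)
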