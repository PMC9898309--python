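"""Neck-angle kinematics from three digitized landmarks.

The neck angle in a frame is formed by the tail base, the withers and the
occiput.  With ``u`` the back vector (tail base -> withers) and ``v`` the
neck vector (withers -> occiput), the reported angle is ``180 - theta``
degrees, where ``theta`` is the signed turn from ``u`` to ``v`` with
dorsal (upward) deviation positive.  Collinear landmarks give 180; dorsal
extension (neck more vertical) lowers the angle below 180 and ventral
flexion (neck more horizontal) raises it above 180, matching the walking
range of roughly 177-196 degrees in adult giraffe.

The sign of the turn is normalized by the travel direction and by the
image y-axis convention (digitizing software usually emits y-down pixel
coordinates), so the same angle is reported whichever way the animal
crosses the frame.

During a walking stride the neck oscillates twice (once per forelimb);
per stride we extract the minimum of the angle series (peak dorsal
extension), the maximum (peak ventral flexion) and their difference, the
range of motion (ROM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import NeckLandmarks, TravelDirection


@dataclass(frozen=True)
class NeckKinematics:
    """Per-stride neck-angle summary, degrees."""

    peak_dorsal_extension_deg: float
    peak_ventral_flexion_deg: float
    rom_deg: float


def neck_angle(
    landmarks: NeckLandmarks,
    travel_direction: TravelDirection = TravelDirection.LEFT_TO_RIGHT,
    y_up: bool = False,
) -> float:
    """Neck angle in degrees for one frame.

    ``y_up=False`` (default) treats coordinates as image pixels with the
    y axis pointing down; set ``y_up=True`` for mathematical coordinates.
    """
    u = np.subtract(landmarks.withers, landmarks.tail_base)
    v = np.subtract(landmarks.occiput, landmarks.withers)
    if np.allclose(u, 0) or np.allclose(v, 0):
        raise ValueError("neck landmarks must not coincide")
    sign = 1.0
    if travel_direction is TravelDirection.RIGHT_TO_LEFT:
        sign = -sign
    if not y_up:
        sign = -sign
    theta = sign * math.atan2(u[0] * v[1] - u[1] * v[0], u[0] * v[0] + u[1] * v[1])
    return 180.0 - math.degrees(theta)


def angle_series(
    frames: list[NeckLandmarks],
    travel_direction: TravelDirection = TravelDirection.LEFT_TO_RIGHT,
    y_up: bool = False,
) -> np.ndarray:
    """Neck angle for each frame of a landmark sequence."""
    return np.array([neck_angle(lm, travel_direction, y_up) for lm in frames])


def extract_neck_peaks(angles_deg: np.ndarray) -> NeckKinematics:
    """Per-stride peaks from a per-frame angle series.

    Peak dorsal extension is the series minimum, peak ventral flexion the
    maximum, ROM their difference.  Requires at least 3 frames so that an
    oscillation is resolvable at all.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.ndim != 1 or angles.size < 3:
        raise ValueError(f"need an angle series of >= 3 frames, got {angles.size}")
    ext = float(np.min(angles))
    flex = float(np.max(angles))
    return NeckKinematics(
        peak_dorsal_extension_deg=ext,
        peak_ventral_flexion_deg=flex,
        rom_deg=flex - ext,
    )
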