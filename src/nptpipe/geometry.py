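"""Screen geometry and pixel/visual-angle conversion.

Gaze positions are recorded in screen pixels (origin top-left, y down);
saccade amplitudes and velocity thresholds are specified in degrees of
visual angle, so every threshold comparison goes through the conversion
here. The default geometry is a 24-inch 16:9 panel at 1920 px width
(pixel pitch 0.2766 mm/px) viewed from 800 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScreenGeometry", "pixels_to_degrees", "degrees_to_pixels"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Viewing geometry used to convert pixel displacements to visual angle.

    Parameters
    ----------
    distance_mm : float
        Eye-to-screen distance in millimetres.
    pixel_pitch_mm : float
        Physical size of one pixel in millimetres.
    resolution : tuple of int
        Screen resolution (width, height) in pixels; metadata only.
    """

    distance_mm: float = 800.0
    pixel_pitch_mm: float = 0.2766
    resolution: tuple[int, int] = (1980, 1080)

    def __post_init__(self) -> None:
        if self.distance_mm <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("distance and pixel pitch must be positive")
        if min(self.resolution) <= 0:
            raise ValueError("resolution must be positive")


def pixels_to_degrees(displacement_px: float, geometry: ScreenGeometry) -> float:
    """Convert an on-screen displacement in pixels to degrees of visual angle.

    Uses the full (non-small-angle) formula
    ``deg = 2 * atan(px * pitch / (2 * d)) * 180 / pi``.
    """
    mm = displacement_px * geometry.pixel_pitch_mm
    return math.degrees(2.0 * math.atan2(mm, 2.0 * geometry.distance_mm))


def degrees_to_pixels(angle_deg: float, geometry: ScreenGeometry) -> float:
    """Inverse of :func:`pixels_to_degrees`."""
    mm = 2.0 * geometry.distance_mm * math.tan(math.radians(angle_deg) / 2.0)
    return mm / geometry.pixel_pitch_mm
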