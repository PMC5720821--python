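"""Coordinate and angle conventions used throughout the package.

Single authoritative convention:

* Physical coordinates are in micrometres, right-handed: ``x`` grows along
  image columns, ``y`` grows *upward*. The image row axis (which grows
  downward) is flipped exactly once, at the pixel<->physical boundary, and
  nowhere else.
* Movement directions are degrees in ``[0, 360)`` measured from the anterior
  direction of the egg chamber (``ap_angle``, the direction of the anterior
  in the physical frame), increasing toward "Up". With the default
  ``ap_angle = 0`` this is the ordinary counter-clockwise angle from +x.
* Axial quantities (cell elongation, Myo-II pattern axis) live in
  ``[0, 180)``.
"""

from __future__ import annotations

import numpy as np


def wrap360(angles):
    """Wrap angles (degrees) into ``[0, 360)``."""
    return np.mod(angles, 360.0)


def wrap180(angles):
    """Wrap axial angles (degrees) into ``[0, 180)``."""
    return np.mod(angles, 180.0)


def signed_delta(from_angle, to_angle):
    """Smallest signed rotation (degrees) taking ``from_angle`` to
    ``to_angle``, in ``(-180, 180]``."""
    d = np.mod(np.asarray(to_angle, dtype=float) - from_angle, 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def axial_difference(a, b):
    """Minimal axial difference between two 0-180 orientations, in [0, 90]."""
    d = np.abs(wrap180(a) - wrap180(b))
    return np.minimum(d, 180.0 - d)


def movement_angle(dx, dy, ap_angle: float = 0.0):
    """Direction of a displacement (µm, physical frame) in the AP convention.

    0 degrees = toward the anterior, 90 = "Up"; returned in [0, 360).
    """
    theta = np.degrees(np.arctan2(dy, dx))
    return wrap360(theta - ap_angle)


def circular_mean(angles_deg):
    """Directed circular mean (degrees in [0, 360)) and mean resultant length.

    Returns ``(mu, R)``; ``mu`` is ``nan`` when ``R`` is numerically zero.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        return float("nan"), 0.0
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return float("nan"), r
    return float(wrap360(np.degrees(np.arctan2(s, c)))), r


def circular_variance(angles_deg) -> float:
    """1 - mean resultant length; rotation-invariant dispersion in [0, 1]."""
    _, r = circular_mean(angles_deg)
    return 1.0 - r


def axial_mean(angles_deg):
    """Axial circular mean of 0-180 orientations via angle doubling.

    Returns the mean axis in [0, 180), or ``nan`` for a degenerate
    (uniform) set.
    """
    doubled_mu, r = circular_mean(2.0 * np.asarray(angles_deg, dtype=float))
    if not np.isfinite(doubled_mu):
        return float("nan")
    return float(wrap180(doubled_mu / 2.0))


def pixels_to_um(rows, cols, n_rows: int, pixel_size: float):
    """Continuous (row, col) pixel coordinates -> physical (x, y) in µm."""
    x = np.asarray(cols, dtype=float) * pixel_size
    y = (n_rows - 1 - np.asarray(rows, dtype=float)) * pixel_size
    return x, y


def um_to_pixels(x, y, n_rows: int, pixel_size: float):
    """Physical (x, y) µm -> continuous (row, col) pixel coordinates."""
    col = np.asarray(x, dtype=float) / pixel_size
    row = (n_rows - 1) - np.asarray(y, dtype=float) / pixel_size
    return row, col
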