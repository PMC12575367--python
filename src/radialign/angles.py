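"""Angle conventions shared by every module.

All interfaces use degrees, counter-clockwise positive, measured from the +x
axis in the mathematical convention.  In-memory coordinates are image
coordinates in micrometres: x runs along columns, y along rows with y
increasing *downward*.  The single documented conversion between the two is
the y-flip inside :func:`polar_angle_deg`; no other function touches signs.

Directional data (step headings, turning angles) live on the full circle and
wrap to (-180, 180].  Axial data (orientations of nuclei, actin, pattern
stripes) are defined modulo 180 and wrap to [0, 180); axial *differences*
wrap to [-90, 90).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "polar_angle_deg",
    "wrap_directional",
    "wrap_axial_difference",
    "mod_axial",
    "rotation_matrix",
    "unit_vector",
    "axial_circular_mean",
    "axial_circular_std",
    "circular_resultant_length",
]


def polar_angle_deg(dx, dy):
    """Mathematical-convention angle of image-coordinate vector (dx, dy).

    ``dy`` is measured downward (row direction); the y-flip happens here and
    only here.  Returns degrees in (-180, 180].
    """
    return wrap_directional(np.degrees(np.arctan2(-np.asarray(dy, float), np.asarray(dx, float))))


def wrap_directional(angle_deg):
    """Wrap directional angles to (-180, 180]."""
    a = np.asarray(angle_deg, float)
    w = (a + 180.0) % 360.0 - 180.0  # [-180, 180)
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return w if w.ndim else float(w)


def wrap_axial_difference(angle_deg):
    """Wrap an axial (mod-180) difference to [-90, 90)."""
    a = np.asarray(angle_deg, float)
    w = (a + 90.0) % 180.0 - 90.0
    return w if w.ndim else float(w)


def mod_axial(angle_deg):
    """Reduce an orientation to [0, 180)."""
    a = np.asarray(angle_deg, float) % 180.0
    a = np.where(np.isclose(a, 180.0), 0.0, a)
    return a if a.ndim else float(a)


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """2x2 matrix acting on image coordinates that rotates vectors by
    ``angle_deg`` counter-clockwise in the reported (mathematical) convention.

    Because image y points down, a CCW mathematical rotation appears as
    ``[[c, s], [-s, c]]`` on raw (x, y_image) coordinates.
    """
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    return np.array([[c, s], [-s, c]])


def unit_vector(angle_deg):
    """Image-coordinate unit vector pointing along a mathematical-convention
    heading (inverse of :func:`polar_angle_deg`)."""
    a = np.radians(np.asarray(angle_deg, float))
    return np.stack([np.cos(a), -np.sin(a)], axis=-1)


def axial_circular_mean(orientations_deg):
    """Circular mean of axial data via angle doubling, in [0, 180)."""
    t = np.radians(2.0 * np.asarray(orientations_deg, float))
    mean = 0.5 * np.degrees(np.arctan2(np.mean(np.sin(t)), np.mean(np.cos(t))))
    return float(mod_axial(mean))


def axial_circular_std(orientations_deg):
    """Circular standard deviation (deg) of axial data via angle doubling.

    For a wrapped normal with small sd this estimates the underlying sd.
    """
    t = np.radians(2.0 * np.asarray(orientations_deg, float))
    r = np.hypot(np.mean(np.sin(t)), np.mean(np.cos(t)))
    r = min(max(r, 1e-12), 1.0)
    return float(0.5 * np.degrees(np.sqrt(-2.0 * np.log(r))))


def circular_resultant_length(angles_deg):
    """Mean resultant length of directional angles; 1 = perfectly aligned."""
    t = np.radians(np.asarray(angles_deg, float))
    if t.size == 0:
        return float("nan")
    return float(np.hypot(np.mean(np.sin(t)), np.mean(np.cos(t))))
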