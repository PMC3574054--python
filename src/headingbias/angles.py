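"""Circular (heading-angle) utilities.

Headings are measured in degrees in the earth-horizontal plane, canonical
range (-180, 180], 0 = straight forward, positive = rightward (clockwise
viewed from above).  All wrapping in the package goes through
:func:`wrap_deg` so the convention lives in exactly one place.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "wrap_deg",
    "heading_unit_vector",
    "circular_mean_deg",
    "circular_sd_deg",
    "resultant_length",
]

#: below this mean-resultant length the circular mean is treated as undefined
_RESULTANT_EPS = 1e-9


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the canonical range (-180, 180].

    Accepts scalars or arrays; returns the same shape.  Note the closed
    upper end: ``wrap_deg(-180) == 180``.
    """
    a = np.asarray(angle, dtype=float)
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(w)
    return w


def heading_unit_vector(heading_deg):
    """3-D unit vector for a horizontal heading in head-fixed coordinates.

    Frame: x forward, y leftward, z up.  A positive (rightward) heading
    therefore has a negative y component.
    """
    rad = np.deg2rad(heading_deg)
    return np.array([np.cos(rad), -np.sin(rad), 0.0])


def resultant_length(angles_deg) -> float:
    """Mean resultant length R-bar of a sample of angles (0 = dispersed, 1 = aligned)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    return float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))


def circular_mean_deg(angles_deg) -> float:
    """Circular mean direction, in degrees, wrapped to (-180, 180].

    Raises
    ------
    ValueError
        If the list is empty.
    DegenerateInputError
        If the mean resultant vector is (numerically) zero, in which case
        the mean direction is undefined.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circular mean of an empty sample is undefined")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    if np.hypot(s, c) <= _RESULTANT_EPS:
        raise DegenerateInputError(
            "mean resultant length is zero; circular mean undefined"
        )
    return wrap_deg(np.rad2deg(np.arctan2(s, c)))


def circular_sd_deg(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R-bar), converted to degrees.

    For small dispersion this is the wrapped-normal-equivalent SD, i.e. it
    agrees with the ordinary SD of the unwrapped sample.
    """
    r = resultant_length(angles_deg)
    if r <= _RESULTANT_EPS:
        raise DegenerateInputError("zero resultant; circular SD undefined")
    if r < 1.0 - 1e-9:
        return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))
    # near-degenerate dispersion: 1 - R underflows, so use the stable
    # small-angle equivalent -2 ln R ~ mean((2 sin(dev/2))^2)
    m = circular_mean_deg(angles_deg)
    dev = np.deg2rad(wrap_deg(np.asarray(angles_deg, dtype=float) - m))
    return float(np.rad2deg(np.sqrt(np.mean((2.0 * np.sin(dev / 2.0)) ** 2))))
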