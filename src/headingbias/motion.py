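"""Translation stimulus kinematics.

The motion platform delivers brief linear translations with a Gaussian
speed profile.  The profile is parameterised by its duration and total
displacement; the Gaussian SD is duration/6 so that the profile is
truncated at +/-3 SD (speed is identically zero outside the motion
interval).  With a 1 s, 13 cm translation this yields a peak velocity of
about 0.31 m/s and peak acceleration/deceleration of about 1.13 m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = ["MotionProfile", "make_motion_profile"]

# fraction of the Gaussian mass inside +/-3 SD
_MASS_3SIGMA = float(special.erf(3.0 / np.sqrt(2.0)))


@dataclass(frozen=True)
class MotionProfile:
    """Gaussian-speed translation profile, truncated at +/-3 SD.

    Attributes
    ----------
    duration_s : float
        Total movement duration (the speed profile is supported on
        [0, duration_s]).
    displacement_m : float
        Integral of speed over the movement.
    sigma_s : float
        SD of the Gaussian speed profile; fixed at duration/6.
    peak_velocity_m_s : float
        Maximum speed, attained at duration/2.
    peak_accel_m_s2 : float
        Maximum |d(speed)/dt|, attained at duration/2 -/+ sigma.
    """

    duration_s: float
    displacement_m: float
    sigma_s: float
    peak_velocity_m_s: float
    peak_accel_m_s2: float

    def speed(self, t):
        """Speed in m/s at time(s) t; zero outside [0, duration]."""
        t = np.asarray(t, dtype=float)
        mu = self.duration_s / 2.0
        v = self.peak_velocity_m_s * np.exp(
            -((t - mu) ** 2) / (2.0 * self.sigma_s**2)
        )
        inside = (t >= 0.0) & (t <= self.duration_s)
        return np.where(inside, v, 0.0)

    def accel(self, t):
        """Signed acceleration dv/dt in m/s^2 (analytic inside the window)."""
        t = np.asarray(t, dtype=float)
        mu = self.duration_s / 2.0
        a = (
            -self.peak_velocity_m_s
            * (t - mu)
            / self.sigma_s**2
            * np.exp(-((t - mu) ** 2) / (2.0 * self.sigma_s**2))
        )
        inside = (t >= 0.0) & (t <= self.duration_s)
        return np.where(inside, a, 0.0)

    def extremal_accel_times(self) -> tuple[float, float]:
        """Times of maximum acceleration and maximum deceleration.

        Located numerically on the sampled profile (they sit at
        duration/2 -/+ sigma for the Gaussian shape).
        """
        res_max = optimize.minimize_scalar(
            lambda t: -self.accel(t),
            bounds=(0.0, self.duration_s),
            method="bounded",
            options={"xatol": 1e-12},
        )
        res_min = optimize.minimize_scalar(
            self.accel,
            bounds=(0.0, self.duration_s),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return float(res_max.x), float(res_min.x)


def make_motion_profile(duration_s: float, displacement_m: float) -> MotionProfile:
    """Build the Gaussian-speed profile for a translation stimulus.

    The peak speed is chosen so that the integral of the truncated
    profile equals ``displacement_m`` exactly.

    Raises
    ------
    ValueError
        If duration is not positive or displacement is negative.
    """
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    if displacement_m < 0:
        raise ValueError(f"displacement must be non-negative, got {displacement_m}")
    sigma = duration_s / 6.0
    # integral of A*exp(-(t-mu)^2 / 2 sigma^2) over +/-3 sigma
    peak_v = displacement_m / (sigma * np.sqrt(2.0 * np.pi) * _MASS_3SIGMA)
    peak_a = peak_v / sigma * np.exp(-0.5)
    return MotionProfile(
        duration_s=float(duration_s),
        displacement_m=float(displacement_m),
        sigma_s=float(sigma),
        peak_velocity_m_s=float(peak_v),
        peak_accel_m_s2=float(peak_a),
    )
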