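"""Refraction corrections to looming-stimulus sizes and cross-study statistics.

Two published escape-behavior geometries are covered: a flat below-dish
projection with the stimulus offset along the screen, and a curved-dish side
projection with the stimulus centered on the eye's axis.  In both cases a
"naive" angular size (the value an experimenter reports ignoring refraction)
is converted to the physical stimulus disc, the disc border is traced
through the interface, and the corrected stimulus is quantified by its
solid angle.

Naive angular size convention: a disc of radius R whose center sits a
straight-line distance D from the eye subtends ``2·arctan(R / D)``.

Corrected flat shapes are registered by the footprint of the received rays
on the refracting interface expressed in the experimenter's screen frame
(see docs/methods.md for the registration convention and its alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .media import CurvedDishGeometry, MediaStack
from .optics import curved_trace, flat_apparent_from_true
from .spherical import polygon_solid_angle, spherical_cap_solid_angle

__all__ = [
    "CriticalSize",
    "disc_border_mm",
    "naive_disc_solid_angle",
    "corrected_flat_solid_angle",
    "corrected_curved_solid_angle",
    "discrepancy",
    "timecourse_correct",
]

#: 95% two-sided normal quantile used to move between CIs and SDs.
_Z95 = 1.959963984540054

#: Border sampling density for discs; cap-formula agreement is then < 0.1%.
N_BORDER = 720


@dataclass(frozen=True)
class CriticalSize:
    """A size estimate (steradians or degrees) with its 95% CI."""

    mean: float
    ci95_lo: float
    ci95_hi: float

    def __post_init__(self) -> None:
        if not (self.ci95_lo <= self.mean <= self.ci95_hi):
            raise ValueError("CI must bracket the mean")

    @property
    def sd(self) -> float:
        """SD implied by a symmetric-normal reading of the CI."""
        return (self.ci95_hi - self.ci95_lo) / (2.0 * _Z95)

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float) -> "CriticalSize":
        return cls(mean, mean - _Z95 * sd, mean + _Z95 * sd)


def disc_border_mm(naive_angle_deg: float, offset_mm: float,
                   eye_height_mm: float, n_border: int = N_BORDER):
    """Border (x, y in mm from the eye's foot point) of the naive-size disc.

    The disc radius follows the naive convention
    ``R = hypot(offset, eye_height) · tan(angle / 2)``.
    """
    if not 0 <= naive_angle_deg < 180:
        raise ValueError("naive angular size must lie in [0, 180) degrees")
    dist = np.hypot(offset_mm, eye_height_mm)
    radius = dist * np.tan(np.deg2rad(naive_angle_deg) / 2.0)
    t = np.linspace(0.0, 2.0 * np.pi, n_border, endpoint=False)
    return offset_mm + radius * np.cos(t), radius * np.sin(t)


def naive_disc_solid_angle(naive_angle_deg: float, offset_mm: float = 10.0,
                           eye_height_mm: float = 4.5,
                           n_border: int = N_BORDER) -> float:
    """Solid angle of the naive disc under straight-line (no-refraction) optics."""
    if naive_angle_deg == 0:
        return 0.0
    bx, by = disc_border_mm(naive_angle_deg, offset_mm, eye_height_mm, n_border)
    rho = np.hypot(bx, by)
    polar = np.rad2deg(np.arctan2(rho, eye_height_mm))
    lon = np.rad2deg(np.arctan2(by, bx))
    return polygon_solid_angle(90.0 - polar, lon)


def corrected_flat_solid_angle(naive_angle_deg: float, stack: MediaStack,
                               offset_mm: float = 10.0,
                               n_border: int = N_BORDER) -> float:
    """Refraction-corrected solid angle of an offset disc behind a flat stack.

    Each border point's true angle is mapped to the apparent angle of the
    received ray; the apparent border is registered at the ray's crossing of
    the refracting interface (radial position ``d_w·tanθ`` on the screen
    raster) and converted back to sphere angles in the experimenter's
    straight-line frame (eye height = total stack thickness).
    """
    if naive_angle_deg == 0:
        return 0.0
    H = stack.total_thickness_mm
    bx, by = disc_border_mm(naive_angle_deg, offset_mm, H, n_border)
    rho = np.hypot(bx, by)
    true_deg = np.rad2deg(np.arctan2(rho, H))
    theta = np.asarray(flat_apparent_from_true(true_deg, stack))
    r_app = stack.eye_side_thickness_mm * np.tan(np.deg2rad(theta))
    polar = np.rad2deg(np.arctan2(r_app, H))
    lon = np.rad2deg(np.arctan2(by, bx))
    return polygon_solid_angle(90.0 - polar, lon)


def corrected_curved_solid_angle(naive_angle_deg: float,
                                 geometry: CurvedDishGeometry) -> float:
    """Refraction-corrected solid angle of a centered cap behind a curved dish.

    The naive apex half-angle fixes the disc radius on the screen plane; the
    disc edge is ray-traced through the two dish-wall arcs and the corrected
    stimulus is the spherical cap at the resulting apparent half-angle.
    """
    if naive_angle_deg == 0:
        return 0.0
    if not 0 < naive_angle_deg < 180:
        raise ValueError("naive angular size must lie in (0, 180) degrees")
    y_s = geometry.screen_distance_mm * np.tan(np.deg2rad(naive_angle_deg) / 2.0)
    x_s = geometry.radius_mm - geometry.d_w + geometry.screen_distance_mm
    apparent_half, _ = curved_trace((x_s, y_s), geometry)
    return spherical_cap_solid_angle(2.0 * abs(apparent_half))


def discrepancy(size_a: CriticalSize, size_b: CriticalSize,
                mode: str = "difference") -> CriticalSize:
    """Difference or ratio of two independent size estimates, with error
    propagation.

    Difference: mean A−B, variances add.  Ratio: mean A/B with first-order
    relative-variance propagation.  Both assume independent, symmetric
    (Gaussian) uncertainties.
    """
    sa, sb = size_a.sd, size_b.sd
    if mode == "difference":
        mean = size_a.mean - size_b.mean
        sd = float(np.hypot(sa, sb))
    elif mode == "ratio":
        if abs(size_b.mean) < 1e-12:
            raise ZeroDivisionError("ratio undefined: denominator mean is ~0")
        mean = size_a.mean / size_b.mean
        sd = abs(mean) * float(np.hypot(sa / size_a.mean if size_a.mean else 0.0,
                                        sb / size_b.mean))
    else:
        raise ValueError("mode must be 'difference' or 'ratio'")
    return CriticalSize.from_mean_sd(mean, sd)


def timecourse_correct(time_s, naive_angles_deg,
                       geometry: MediaStack | CurvedDishGeometry,
                       offset_mm: float = 10.0):
    """Correct a naive angular-size time course to solid angles (sr).

    Returns ``(time_s, solid_angle_sr)`` arrays.  Flat geometries use the
    offset-disc pipeline; curved geometries the centered-cap pipeline.  A
    monotone naive series yields a monotone corrected series because the
    angle transformation is monotone.
    """
    time_s = np.asarray(time_s, dtype=float)
    angles = np.asarray(naive_angles_deg, dtype=float)
    if time_s.shape != angles.shape:
        raise ValueError("time and angle series must have matching shapes")
    if isinstance(geometry, CurvedDishGeometry):
        out = np.array([corrected_curved_solid_angle(a, geometry) for a in angles])
    else:
        out = np.array([
            corrected_flat_solid_angle(a, geometry, offset_mm=offset_mm)
            for a in angles
        ])
    return time_s, out
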