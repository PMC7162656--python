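"""Simulated receptive-field mapping through a refracting interface.

A neuron's receptive field (RF) is a Gaussian of great-circle distance on
the viewing sphere: ``P(ρ) = exp(−ρ² / 2σ²)``.  Pixel-wise stimulation on
the screen probes the RF along each pixel's retinal direction; without the
interface that direction is the straight line to the pixel ("true RF"),
with it, the Snell-refracted direction scaled by the Fresnel transmittance
("apparent RF"):

    F(x) = T(ψ_a(x)) · P(ρ(x; μ_RF), σ_RF).

The measured map lives on screen pixels, so peak positions and half-max
sizes are quantified in the experimenter's straight-line frame — exactly the
naive quantities a mapping experiment would report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .media import MediaStack
from .optics import AngleMap
from .screen import ScreenSpec
from .spherical import extract_border, polygon_solid_angle

__all__ = ["GaussianRF", "RFMeasurement", "great_circle_distance",
           "apparent_rf", "rf_summary", "rf_error_sweep"]


@dataclass(frozen=True)
class GaussianRF:
    """Gaussian RF on the unit sphere: center (lat, lon) and width, degrees.

    Latitude 90° is the eye's vertical axis (straight down at the screen);
    a center at latitude ``90 − p`` and longitude 0 sits at the along-screen
    angle ``p`` from vertical.
    """

    lat_deg: float
    lon_deg: float
    sigma_deg: float

    def __post_init__(self) -> None:
        if self.sigma_deg <= 0:
            raise ValueError("sigma must be > 0")

    @classmethod
    def at_screen_angle(cls, position_deg: float, sigma_deg: float) -> "GaussianRF":
        return cls(90.0 - position_deg, 0.0, sigma_deg)


@dataclass
class RFMeasurement:
    """Normalized pixel-response map with its summary quantities."""

    response: np.ndarray          # F(x) over screen pixels, max-normalized
    screen: ScreenSpec
    eye_height_mm: float
    peak_angle_deg: float         # along-screen angle of the argmax pixel
    size_sr: float                # solid angle of the half-max region


def great_circle_distance(lat1_deg, lon1_deg, lat2_deg, lon2_deg):
    """Great-circle distance in degrees:
    ``cos ρ = sin α₁ sin α₂ + cos α₁ cos α₂ cos(β₂ − β₁)``."""
    a1 = np.deg2rad(np.asarray(lat1_deg, dtype=float))
    b1 = np.deg2rad(np.asarray(lon1_deg, dtype=float))
    a2 = np.deg2rad(np.asarray(lat2_deg, dtype=float))
    b2 = np.deg2rad(np.asarray(lon2_deg, dtype=float))
    c = np.sin(a1) * np.sin(a2) + np.cos(a1) * np.cos(a2) * np.cos(b2 - b1)
    out = np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))
    return out if np.ndim(out) else float(out)


def _pixel_directions(screen: ScreenSpec, H: float, amap: AngleMap | None):
    """(lat, lon) of every pixel's retinal direction; refracted if amap given."""
    n_rows, n_cols = screen.shape
    cgrid, rgrid = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x, y = screen.pixel_to_mm(rgrid, cgrid)
    rho = np.hypot(x, y)
    polar = np.rad2deg(np.arctan2(rho, H))
    if amap is not None:
        polar = amap.apparent_of(polar)
    return 90.0 - polar, np.rad2deg(np.arctan2(y, x)), polar


def apparent_rf(rf: GaussianRF, screen: ScreenSpec, stack: MediaStack,
                angle_map: AngleMap | None = None,
                ) -> tuple[RFMeasurement, RFMeasurement]:
    """Measure a ground-truth RF by pixel-wise stimulation.

    Returns ``(apparent, true)`` measurements: the apparent map uses
    Snell-refracted pixel directions and Fresnel-scaled responses, the true
    map uses straight-line directions with no interface.  An RF centered
    outside the Snell window is unreachable by any screen pixel.
    """
    amap = angle_map or AngleMap.from_stack(stack)
    if 90.0 - rf.lat_deg >= amap.window_half_angle_deg:
        raise ValueError(
            "RF center lies outside the Snell window and cannot be probed"
        )
    H = stack.total_thickness_mm

    lat_a, lon, _ = _pixel_directions(screen, H, amap)
    rho_a = great_circle_distance(lat_a, lon, rf.lat_deg, rf.lon_deg)
    n_rows, n_cols = screen.shape
    cgrid, rgrid = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x, y = screen.pixel_to_mm(rgrid, cgrid)
    tp = np.rad2deg(np.arctan2(np.hypot(x, y), H))
    trans = amap.transmittance_of(tp)
    f_app = trans * np.exp(-np.deg2rad(rho_a) ** 2 /
                           (2.0 * np.deg2rad(rf.sigma_deg) ** 2))

    lat_t, lon_t, _ = _pixel_directions(screen, H, None)
    rho_t = great_circle_distance(lat_t, lon_t, rf.lat_deg, rf.lon_deg)
    f_true = np.exp(-np.deg2rad(rho_t) ** 2 /
                    (2.0 * np.deg2rad(rf.sigma_deg) ** 2))

    return (_summarize(f_app, screen, H), _summarize(f_true, screen, H))


def _summarize(f: np.ndarray, screen: ScreenSpec, H: float) -> RFMeasurement:
    peak, size = rf_summary(f, screen, H)
    fmax = f.max()
    return RFMeasurement(f / fmax if fmax > 0 else f, screen, H, peak, size)


def rf_summary(response: np.ndarray, screen: ScreenSpec,
               eye_height_mm: float) -> tuple[float, float]:
    """Peak position (along-screen angle, deg) and half-max size (sr).

    The peak is the argmax pixel converted to the straight-line angle from
    vertical; the size is the solid angle of the region where the response
    is at least half its maximum (ties included), measured by tracing the
    half-max contour.  Both are invariant to scaling the map.
    """
    f = np.asarray(response, dtype=float)
    fmax = f.max()
    if fmax <= 0:
        raise ValueError("response map is all zero")
    r_pk, c_pk = np.unravel_index(int(np.argmax(f)), f.shape)
    x_pk, y_pk = screen.pixel_to_mm(r_pk, c_pk)
    peak_angle = float(np.rad2deg(np.arctan2(np.hypot(x_pk, y_pk), eye_height_mm)))
    mask = f >= 0.5 * fmax
    lat, lon = extract_border(mask, screen, eye_height_mm)
    size = polygon_solid_angle(lat, lon) if len(np.atleast_1d(lat)) >= 3 else 0.0
    return peak_angle, size


def rf_error_sweep(true_positions_deg, true_sigmas_deg, stacks,
                   screen: ScreenSpec | None = None,
                   labels=None) -> pd.DataFrame:
    """Apparent-vs-true RF errors over a grid of RFs and geometries.

    For every (position, sigma, stack) combination, reports the apparent
    minus true peak position (degrees) and the apparent/true size ratio.
    Errors grow as the true position approaches the Snell window edge, and
    both over- and under-estimation regimes occur depending on the
    air/water distance ratio.
    """
    positions = list(true_positions_deg)
    sigmas = list(true_sigmas_deg)
    stacks = list(stacks)
    if not positions or not sigmas or not stacks:
        raise ValueError("sweep grids must be non-empty")
    screen = screen or ScreenSpec()
    if labels is None:
        labels = [
            f"da_dw={_da_dw(s):g}" if _da_dw(s) is not None else f"stack{i}"
            for i, s in enumerate(stacks)
        ]
    rows = []
    for stack, label in zip(stacks, labels):
        amap = AngleMap.from_stack(stack)
        for sigma in sigmas:
            for pos in positions:
                rf = GaussianRF.at_screen_angle(pos, sigma)
                try:
                    app, true = apparent_rf(rf, screen, stack, angle_map=amap)
                except ValueError:
                    continue  # unreachable RF at this geometry
                rows.append({
                    "true_pos_deg": pos,
                    "true_sigma_deg": sigma,
                    "geometry": label,
                    "peak_shift_deg": app.peak_angle_deg - true.peak_angle_deg,
                    "size_ratio": (app.size_sr / true.size_sr
                                   if true.size_sr > 0 else np.nan),
                })
    return pd.DataFrame(rows)


def _da_dw(stack: MediaStack):
    air = sum(l.thickness_mm for l in stack.layers if l.n == 1.0)
    water = sum(l.thickness_mm for l in stack.layers if l.n != 1.0)
    return air / water if water > 0 else None
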