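"""Screen geometry and calibrated stimulus rasters.

Intensities are handled in physical illuminance (lux).  A projector applies
gamma encoding: the stored pixel value is ``x**(1/γ)`` of the (normalized)
illuminance x, with γ = 2.2 by default.  All optical simulation happens on
gamma-decoded (linear) rasters; :meth:`ScreenImage.decode` and
:meth:`ScreenImage.encode` move explicitly between the two states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = ["ScreenSpec", "ScreenImage", "ApparentImage", "make_grating",
           "load_image", "save_image"]


@dataclass(frozen=True)
class ScreenSpec:
    """Physical screen: size, resolution, and the eye's foot point.

    The raster origin is the top-left pixel center.  ``eye_position`` is the
    (x, y) offset, in cm from the screen center, of the point on the screen
    plane directly under the eye; it may lie outside the screen bounds.
    ``emission_profile`` maps the emission angle in the screen-side medium
    (degrees from the screen normal) to a relative intensity; None means
    uniform (Lambertian screens or diffusers can be passed explicitly).
    """

    width_cm: float = 4.0
    height_cm: float = 4.0
    resolution: float = 250.0  # pixels / cm
    eye_position: tuple[float, float] = (0.0, 0.0)
    emission_profile: Callable | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0 pixels/cm")
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("screen dimensions must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.height_cm * self.resolution)),
                int(round(self.width_cm * self.resolution)))

    @property
    def pixel_cm(self) -> float:
        return 1.0 / self.resolution

    def pixel_centers_cm(self):
        """(x, y) coordinates of pixel centers relative to the screen center."""
        n_rows, n_cols = self.shape
        x = (np.arange(n_cols) + 0.5) * self.pixel_cm - self.width_cm / 2
        y = (np.arange(n_rows) + 0.5) * self.pixel_cm - self.height_cm / 2
        return x, y

    def pixel_to_mm(self, rows, cols):
        """Pixel indices -> mm offsets from the eye's foot point."""
        ex, ey = self.eye_position
        x = ((np.asarray(cols) + 0.5) * self.pixel_cm - self.width_cm / 2 - ex) * 10.0
        y = ((np.asarray(rows) + 0.5) * self.pixel_cm - self.height_cm / 2 - ey) * 10.0
        return x, y

    def mm_to_pixel(self, x_mm, y_mm):
        """Inverse of :meth:`pixel_to_mm` (fractional pixel indices)."""
        ex, ey = self.eye_position
        cols = (np.asarray(x_mm) / 10.0 + ex + self.width_cm / 2) / self.pixel_cm - 0.5
        rows = (np.asarray(y_mm) / 10.0 + ey + self.height_cm / 2) / self.pixel_cm - 0.5
        return rows, cols


@dataclass
class ScreenImage:
    """A stimulus raster with explicit gamma state and illuminance calibration.

    ``data`` holds either encoded values in [0, 1] (``gamma_state ==
    'encoded'``) or physical illuminance in lux (``'linear'``), spanning
    ``lux_range`` after decoding.
    """

    data: np.ndarray
    gamma_state: str = "encoded"
    gamma: float = 2.2
    lux_range: tuple[float, float] = (1.0, 500.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.gamma_state not in ("encoded", "linear"):
            raise ValueError("gamma_state must be 'encoded' or 'linear'")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    def decode(self) -> "ScreenImage":
        """Gamma-decode to linear illuminance over ``lux_range``."""
        if self.gamma_state == "linear":
            return self
        lo, hi = self.lux_range
        lin = lo + (hi - lo) * np.clip(self.data, 0.0, 1.0) ** self.gamma
        return ScreenImage(lin, "linear", self.gamma, self.lux_range)

    def encode(self) -> "ScreenImage":
        """Gamma-compress back to the normalized encoded representation."""
        if self.gamma_state == "encoded":
            return self
        lo, hi = self.lux_range
        enc = (np.clip(self.data, lo, hi) - lo) / (hi - lo)
        return ScreenImage(enc ** (1.0 / self.gamma), "encoded", self.gamma,
                           self.lux_range)


@dataclass
class ApparentImage:
    """Distorted view binned on the source pixel grid, plus bookkeeping.

    ``data`` is linear illuminance per bin.  ``clipped_fraction`` is the
    traced energy that fell outside the raster.  Display saturation is a
    render-time policy only (:meth:`display`); the stored raster is never
    altered.
    """

    data: np.ndarray
    window_radius_px: float
    seed: int | None = None
    clipped_fraction: float = 0.0
    saturation_percentile: float = 99.0

    def display(self, gamma: float = 2.2) -> np.ndarray:
        """Render to [0, 1] with percentile clipping and gamma compression."""
        cap = np.percentile(self.data, self.saturation_percentile)
        cap = cap if cap > 0 else self.data.max() or 1.0
        out = np.clip(self.data / cap, 0.0, 1.0)
        return out ** (1.0 / gamma)


def make_grating(spatial_frequency: float, screen: ScreenSpec,
                 lux_range: tuple[float, float] = (1.0, 500.0),
                 gamma: float = 2.2) -> ScreenImage:
    """Gamma-encoded horizontal sinusoidal grating.

    The encoded value follows ``x**(1/γ) = sin`` of the phase, rescaled to
    [0, 1], so the decoded illuminance sweeps exactly ``lux_range``.
    """
    if spatial_frequency <= 0:
        raise ValueError("spatial frequency must be > 0 cycles/cm")
    x, _ = screen.pixel_centers_cm()
    phase = 2.0 * np.pi * spatial_frequency * x
    encoded = (np.sin(phase) + 1.0) / 2.0
    n_rows, _ = screen.shape
    data = np.broadcast_to(encoded, (n_rows, len(encoded))).copy()
    return ScreenImage(data, "encoded", gamma, lux_range)


# ---------------------------------------------------------------------------
# 8/16-bit grayscale PNG & TIFF I/O
# ---------------------------------------------------------------------------

def load_image(path, gamma_state: str = "encoded", gamma: float = 2.2,
               lux_range: tuple[float, float] = (1.0, 500.0)) -> ScreenImage:
    """Load an 8- or 16-bit grayscale PNG/TIFF as an encoded ScreenImage."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB(A) to gray
        arr = arr[..., :3].mean(axis=-1)
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    data = arr.astype(float) / scale
    return ScreenImage(data, gamma_state, gamma, lux_range)


def save_image(image, path, bitdepth: int = 16) -> None:
    """Save a raster (ScreenImage, ApparentImage or array) as PNG/TIFF."""
    import imageio.v3 as iio

    if isinstance(image, ApparentImage):
        data = image.display()
    elif isinstance(image, ScreenImage):
        data = image.encode().data
    else:
        data = np.asarray(image, dtype=float)
        if data.max() > 1:
            data = data / data.max()
    data = np.clip(data, 0.0, 1.0)
    if bitdepth == 16:
        out = (data * 65535.0 + 0.5).astype(np.uint16)
    else:
        out = (data * 255.0 + 0.5).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
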