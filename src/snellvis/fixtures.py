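"""Deterministic synthetic stimulus fixtures.

Every stimulus family needed to exercise the toolkit is generated
programmatically: uniform fields, gamma-encoded gratings, naive-size discs,
and a checkered ball (a disc carrying a polar checkerboard, the standard
demonstration target for inverse correction).
"""

from __future__ import annotations

import numpy as np

from .screen import ScreenImage, ScreenSpec, make_grating

__all__ = ["generate_fixture", "disc_mask"]


def disc_mask(screen: ScreenSpec, naive_angle_deg: float, offset_mm: float,
              eye_height_mm: float) -> np.ndarray:
    """Binary mask of a disc sized to subtend ``naive_angle_deg``.

    The disc center sits ``offset_mm`` from the eye's foot point along +x;
    its radius follows the naive convention
    ``R = hypot(offset, eye_height)·tan(angle/2)``.
    """
    radius = np.hypot(offset_mm, eye_height_mm) * np.tan(
        np.deg2rad(naive_angle_deg) / 2.0)
    n_rows, n_cols = screen.shape
    cgrid, rgrid = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x, y = screen.pixel_to_mm(rgrid, cgrid)
    return (x - offset_mm) ** 2 + y**2 <= radius**2


def generate_fixture(kind: str, screen: ScreenSpec | None = None,
                     **params) -> ScreenImage:
    """Generate a deterministic stimulus raster of the requested family.

    Kinds
    -----
    uniform
        Constant encoded level (``level``, default 1.0).
    grating
        Gamma-encoded sinusoidal grating (``spatial_frequency`` cycles/cm).
    disc
        Dark disc of naive angular size ``naive_angle_deg`` at
        ``offset_mm`` from the eye foot (``eye_height_mm`` sets the size
        convention; defaults to 4.5), dark/bright encoded levels
        ``fg``/``bg``.
    checkerball
        Checkered ball: a disc carrying a polar checkerboard with
        ``n_rings`` radial and ``n_wedges`` angular checks.
    """
    screen = screen or ScreenSpec()
    if kind == "uniform":
        level = params.get("level", 1.0)
        return ScreenImage(np.full(screen.shape, float(level)), "encoded")
    if kind == "grating":
        return make_grating(params.get("spatial_frequency", 1.0), screen,
                            lux_range=params.get("lux_range", (1.0, 500.0)))
    if kind == "disc":
        mask = disc_mask(screen, params.get("naive_angle_deg", 72.0),
                         params.get("offset_mm", 10.0),
                         params.get("eye_height_mm", 4.5))
        fg = params.get("fg", 0.0)
        bg = params.get("bg", 1.0)
        return ScreenImage(np.where(mask, fg, bg).astype(float), "encoded")
    if kind == "checkerball":
        return _checkerball(screen, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _checkerball(screen: ScreenSpec, radius_mm: float = 8.0,
                 center_mm: tuple[float, float] = (0.0, 0.0),
                 n_rings: int = 4, n_wedges: int = 8, bg: float = 0.5,
                 **_ignored) -> ScreenImage:
    n_rows, n_cols = screen.shape
    cgrid, rgrid = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x, y = screen.pixel_to_mm(rgrid, cgrid)
    dx = x - center_mm[0]
    dy = y - center_mm[1]
    r = np.hypot(dx, dy)
    inside = r <= radius_mm
    ring = np.floor(r / radius_mm * n_rings).astype(int)
    wedge = np.floor((np.arctan2(dy, dx) + np.pi) / (2 * np.pi) * n_wedges
                     ).astype(int) % n_wedges
    checks = ((ring + wedge) % 2).astype(float)
    data = np.where(inside, checks, bg)
    return ScreenImage(data, "encoded")
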