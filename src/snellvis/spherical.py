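"""Solid-angle quantification of stimulus shapes on the viewing sphere.

A stimulus shape is reduced to its ordered border, each border point
described by a latitude α and longitude β with the eye at the origin and the
pole on the eye's vertical axis.  The equal-area sinusoidal projection
``(x, y) = (β cos α, α)`` maps the sphere to the plane while preserving area
as a fraction of the sphere's surface, so the solid angle of a shape is just
the planar shoelace area of its projected border polygon.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "UnsupportedTopologyError",
    "spherical_cap_solid_angle",
    "sinusoidal_project",
    "polygon_solid_angle",
    "extract_border",
    "latlon_from_screen",
    "screen_border_solid_angle",
]


class UnsupportedTopologyError(ValueError):
    """Border is self-intersecting, or spans more than a hemisphere."""


def spherical_cap_solid_angle(apex_angle_deg: float) -> float:
    """Solid angle of a spherical cap, ``A = 2π (1 − cos θ)``.

    ``apex_angle_deg`` is the full apex angle 2θ of the cap, in [0, 360].
    A 180° apex is a hemisphere (2π sr); 360° is the full sphere (4π sr).
    """
    apex = np.asarray(apex_angle_deg, dtype=float)
    if np.any(apex < 0) or np.any(apex > 360):
        raise ValueError("apex angle must lie in [0, 360] degrees")
    out = 2.0 * np.pi * (1.0 - np.cos(np.deg2rad(apex) / 2.0))
    return out if out.shape else float(out)


def sinusoidal_project(lat_deg, lon_deg):
    """Equal-area sinusoidal projection ``(x, y) = (β cos α, α)`` in radians."""
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
    return lon * np.cos(lat), lat


def _unit_vectors(lat_rad: np.ndarray, lon_rad: np.ndarray) -> np.ndarray:
    return np.stack(
        [np.cos(lat_rad) * np.cos(lon_rad),
         np.cos(lat_rad) * np.sin(lon_rad),
         np.sin(lat_rad)], axis=-1
    )


def _rotation_to_origin(c: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``c`` to (1, 0, 0) (lat 0, lon 0)."""
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(c, target)
    s = np.linalg.norm(v)
    cth = float(c @ target)
    if s < 1e-15:
        if cth > 0:
            return np.eye(3)
        # antipodal: rotate 180 deg about z
        return np.diag([-1.0, -1.0, 1.0])
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k * ((1.0 - cth) / s**2)


def polygon_solid_angle(lat_deg, lon_deg, *, rotate: bool = True,
                        check_simple: bool = True) -> float:
    """Solid angle (sr) enclosed by an ordered closed border on the sphere.

    The border is rotated so its mean direction sits at latitude 0,
    longitude 0 before projecting — a rotation changes nothing about the
    area but keeps connected shapes smaller than a hemisphere away from the
    projection's antimeridian and pole.  Degenerate borders return 0.
    """
    lat = np.deg2rad(np.atleast_1d(np.asarray(lat_deg, dtype=float)))
    lon = np.deg2rad(np.atleast_1d(np.asarray(lon_deg, dtype=float)))
    if lat.shape != lon.shape or lat.ndim != 1:
        raise ValueError("latitude and longitude must be 1-D arrays of equal length")
    if len(lat) < 3:
        return 0.0
    v = _unit_vectors(lat, lon)
    c = v.mean(axis=0)
    norm = np.linalg.norm(c)
    if norm < 1e-12:
        raise UnsupportedTopologyError(
            "border has no well-defined mean direction (larger than a hemisphere?)"
        )
    if rotate:
        v = v @ _rotation_to_origin(c / norm).T
    lat_r = np.arcsin(np.clip(v[:, 2], -1.0, 1.0))
    lon_r = np.arctan2(v[:, 1], v[:, 0])
    if np.max(lon_r) - np.min(lon_r) > np.pi:
        raise UnsupportedTopologyError(
            "border spans more than a hemisphere in longitude after centering"
        )
    x = lon_r * np.cos(lat_r)
    y = lat_r
    if check_simple:
        poly = Polygon(np.column_stack([x, y]))
        if poly.area > 0 and not poly.is_valid:
            raise UnsupportedTopologyError("border polygon is self-intersecting")
    # shoelace; orientation normalized by the absolute value
    area = 0.5 * np.abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area)


# ---------------------------------------------------------------------------
# Border extraction from binary masks (Moore-neighbor contour following)
# ---------------------------------------------------------------------------

_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-border pixel coordinates (row, col) of a binary mask."""
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("mask is empty")
    start = (int(rows[0]), int(cols[0]))  # first foreground pixel in raster order
    if len(rows) == 1:
        return np.array([start])

    def fg(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    border = [start]
    # backtrack starts from the pixel west of the start (raster scan came from there)
    prev = (start[0], start[1] - 1)
    current = start
    first_next = None
    while True:
        offset = (prev[0] - current[0], prev[1] - current[1])
        k = _MOORE.index(offset)
        nxt = None
        for i in range(1, 9):
            cand_off = _MOORE[(k + i) % 8]
            cand = (current[0] + cand_off[0], current[1] + cand_off[1])
            if fg(cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel
            break
        # Jacob's stopping criterion: re-enter the start from the same neighbour
        if current == start and first_next is not None and nxt == first_next:
            break
        if first_next is None:
            first_next = nxt
        border.append(nxt)
        prev, current = current, nxt
        if len(border) > 4 * mask.size:  # safety net; cannot trigger on valid masks
            raise RuntimeError("border tracing failed to terminate")
    # drop the duplicated closing vertex if present
    if len(border) > 1 and border[-1] == border[0]:
        border.pop()
    return np.array(border)


def extract_border(mask, screen, eye_height_mm: float, stack=None):
    """Ordered (latitude, longitude) border of a one-component binary mask.

    Border pixels are found by Moore-neighbor contour following; pixel
    centers define the vertices.  Each center is converted to spherical
    coordinates about the eye using straight-line rays, or refracted rays
    when ``stack`` is given (the apparent direction of each border pixel).

    Returns ``(lat_deg, lon_deg)`` arrays.
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    n_comp = ndimage.label(mask)[1]
    if n_comp == 0:
        raise ValueError("mask has no foreground pixels")
    if n_comp > 1:
        raise ValueError(f"mask has {n_comp} connected components; expected 1")
    rc = _moore_trace(mask)
    x_mm, y_mm = screen.pixel_to_mm(rc[:, 0], rc[:, 1])
    return latlon_from_screen(x_mm, y_mm, eye_height_mm, stack=stack)


def latlon_from_screen(x_mm, y_mm, eye_height_mm: float, stack=None):
    """Spherical coordinates of screen points as seen from the eye.

    ``(x_mm, y_mm)`` are positions on the screen plane relative to the point
    directly under the eye; the pole of the coordinate system is the eye's
    vertical axis (latitude 90°).  With ``stack`` given, the direction is
    the refracted (apparent) one: the straight-line polar angle is mapped
    through the flat-interface transformation.
    """
    from .optics import flat_apparent_from_true

    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    rho = np.hypot(x, y)
    polar = np.rad2deg(np.arctan2(rho, eye_height_mm))
    if stack is not None:
        polar = np.asarray(flat_apparent_from_true(polar, stack))
    lat = 90.0 - polar
    lon = np.rad2deg(np.arctan2(y, x))
    return lat, lon


def screen_border_solid_angle(x_mm, y_mm, eye_height_mm: float, stack=None) -> float:
    """Solid angle of a closed border given by screen-plane coordinates."""
    lat, lon = latlon_from_screen(x_mm, y_mm, eye_height_mm, stack=stack)
    return polygon_solid_angle(lat, lon)
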