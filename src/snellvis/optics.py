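"""Snell/Fresnel optics for flat layered stacks and curved dish interfaces.

All public angles are in degrees, measured from the axis through the eye
perpendicular to the interface (the "vertical" for the below-dish geometry).
Internally everything is computed in radians.

The central objects are the forward transformation from an apparent viewing
angle θ (the direction a ray arrives at the eye) to the true screen position
angle θ′, its numerical inverse, and per-ray Fresnel transmittances.  For a
flat stack of layers with thicknesses ``d_i`` and indices ``n_i`` the ray
that reaches the eye at angle θ crossed layer ``i`` at the Snell angle ψ_i
(``n_i sin ψ_i = n_eye sin θ``), so the true position satisfies

    tan θ′ = Σ_i d_i tan ψ_i / Σ_i d_i .

Because every layer on the screen side is optically rarer than the water the
eye sits in, θ is confined to the Snell window of half-angle
``arcsin(n_air / n_water) ≈ 48.6°`` no matter how thick the layers are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .media import CurvedDishGeometry, MediaStack

__all__ = [
    "TotalInternalReflectionError",
    "OutOfWindowError",
    "UnreachableSourceError",
    "snell_refract",
    "fresnel_transmittance",
    "stack_transmittance",
    "transmittance_from_apparent",
    "snell_window_half_angle",
    "flat_true_from_apparent",
    "flat_apparent_from_true",
    "dtrue_dapparent",
    "AngleMap",
    "curved_trace",
]


class TotalInternalReflectionError(ValueError):
    """The ray cannot be transmitted across the boundary (n_in sinψ / n_out > 1)."""


class OutOfWindowError(ValueError):
    """The requested apparent angle lies at or beyond the Snell window edge."""


class UnreachableSourceError(ValueError):
    """No refracted ray connects the source point to the eye."""


def snell_refract(incidence_deg: float, n_in: float, n_out: float) -> float:
    """Refraction angle across a boundary, ``n_in sin ψ_in = n_out sin ψ_out``.

    Raises :class:`TotalInternalReflectionError` when the transmitted ray
    does not exist.
    """
    if not 0 <= incidence_deg < 90:
        raise ValueError("incidence angle must be in [0, 90) degrees")
    s = n_in * np.sin(np.deg2rad(incidence_deg)) / n_out
    if s > 1:
        raise TotalInternalReflectionError(
            f"total internal reflection at {incidence_deg:g} deg "
            f"({n_in:g} -> {n_out:g})"
        )
    return float(np.rad2deg(np.arcsin(s)))


def fresnel_transmittance(incidence_deg: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel transmittance ``T = 1 - (Rs + Rp) / 2``.

    ``Rs`` and ``Rp`` are the reflectances for s- (perpendicular) and
    p-polarized (parallel) light.
    """
    refr_deg = snell_refract(incidence_deg, n_in, n_out)  # raises on TIR
    ci = np.cos(np.deg2rad(incidence_deg))
    ct = np.cos(np.deg2rad(refr_deg))
    rs = ((n_in * ci - n_out * ct) / (n_in * ci + n_out * ct)) ** 2
    rp = ((n_in * ct - n_out * ci) / (n_in * ct + n_out * ci)) ** 2
    return float(1.0 - (rs + rp) / 2.0)


def stack_transmittance(psi_first_deg: float, stack: MediaStack) -> float:
    """Product of per-boundary Fresnel transmittances along the refracted ray.

    ``psi_first_deg`` is the ray angle in the first (screen-side) layer.
    Multiple internal reflections are ignored; the transmitted fractions at
    successive boundaries simply multiply.
    """
    t = 1.0
    psi = psi_first_deg
    for a, b in zip(stack.layers[:-1], stack.layers[1:]):
        if a.n != b.n:
            t *= fresnel_transmittance(psi, a.n, b.n)
        psi = snell_refract(psi, a.n, b.n)
    return t


def transmittance_from_apparent(theta_deg, stack: MediaStack):
    """Vectorized stack transmittance as a function of the eye-side angle θ."""
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    n_eye = stack.n_last
    t = np.ones_like(theta)
    for a, b in zip(stack.layers[:-1], stack.layers[1:]):
        if a.n == b.n:
            continue
        # ray angle in each medium follows from the invariant n sin psi
        si = np.clip(n_eye * np.sin(theta) / a.n, 0.0, 1.0)
        st = np.clip(n_eye * np.sin(theta) / b.n, 0.0, 1.0)
        ci = np.sqrt(1.0 - si**2)
        ct = np.sqrt(1.0 - st**2)
        rs = ((a.n * ci - b.n * ct) / (a.n * ci + b.n * ct)) ** 2
        rp = ((a.n * ct - b.n * ci) / (a.n * ct + b.n * ci)) ** 2
        t = t * (1.0 - (rs + rp) / 2.0)
    return t if t.shape else float(t)


def snell_window_half_angle(n_out: float, n_in: float) -> float:
    """Half-angle of the Snell window, ``arcsin(n_out / n_in)`` in degrees.

    ``n_in`` is the (denser) medium the eye sits in, ``n_out`` the rarest
    medium on the far side.  The full window is twice this.  Equal indices
    give the degenerate 90° (full hemisphere, no compression).
    """
    if n_in < n_out:
        raise ValueError("no Snell window: the eye-side medium must be denser")
    return float(np.rad2deg(np.arcsin(n_out / n_in)))


def window_half_angle_for(stack: MediaStack) -> float:
    """Snell window half-angle of a stack (set by its rarest layer)."""
    n_min = min(l.n for l in stack.layers)
    return snell_window_half_angle(n_min, stack.n_last)


def _true_from_apparent_rad(theta: np.ndarray, stack: MediaStack) -> np.ndarray:
    n_eye = stack.n_last
    num = np.zeros_like(theta)
    den = 0.0
    for layer in stack.layers:
        s = n_eye * np.sin(theta) / layer.n
        psi = np.arcsin(s)
        num = num + layer.thickness_mm * np.tan(psi)
        den += layer.thickness_mm
    return np.arctan2(num, den)


def flat_true_from_apparent(theta_deg, stack: MediaStack):
    """True position angle θ′ of the screen point seen at apparent angle θ.

    Closed form: ``θ′ = arctan(Σ d_i tan ψ_i / Σ d_i)`` with
    ``n_i sin ψ_i = n_eye sin θ``.  θ must lie strictly inside the Snell
    window; the edge itself maps to the horizon and is treated as
    out-of-window.
    """
    theta_arr = np.asarray(theta_deg, dtype=float)
    win = window_half_angle_for(stack)
    if np.any(theta_arr < 0) or np.any(theta_arr >= win):
        raise OutOfWindowError(
            f"apparent angle must lie in [0, {win:.4f}) degrees for this stack"
        )
    out = np.rad2deg(_true_from_apparent_rad(np.deg2rad(theta_arr), stack))
    return out if out.shape else float(out)


def dtrue_dapparent(theta_deg, stack: MediaStack):
    """Analytic derivative dθ′/dθ of the layered-tangent transformation."""
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    n_eye = stack.n_last
    num = np.zeros_like(theta)
    dnum = np.zeros_like(theta)
    den = 0.0
    for layer in stack.layers:
        k = n_eye / layer.n
        s = k * np.sin(theta)
        c = np.sqrt(1.0 - s**2)
        num = num + layer.thickness_mm * s / c
        dnum = dnum + layer.thickness_mm * k * np.cos(theta) / c**3
        den += layer.thickness_mm
    deriv = (den * dnum) / (den**2 + num**2)
    return deriv if deriv.shape else float(deriv)


def flat_apparent_from_true(theta_prime_deg, stack: MediaStack,
                            tolerance: float = 1e-9):
    """Numerically invert θ′(θ): the apparent angle of a true position θ′.

    The transformation is strictly monotone on [0, window), so a bracketed
    Brent search is guaranteed to converge.  Accepts scalars or arrays.
    ``tolerance`` is the absolute tolerance, in degrees, on the residual
    θ′(θ) − θ′.
    """
    tp = np.asarray(theta_prime_deg, dtype=float)
    if np.any(tp < 0) or np.any(tp >= 90):
        raise ValueError("true angle must lie in [0, 90) degrees")
    win = np.deg2rad(window_half_angle_for(stack))
    hi = win * (1 - 1e-13)

    def solve(tp_deg: float) -> float:
        if tp_deg == 0.0:
            return 0.0
        target = np.deg2rad(tp_deg)

        def objective(theta: float) -> float:
            return float(_true_from_apparent_rad(np.asarray(theta), stack) - target)

        try:
            root = brentq(objective, 0.0, hi, xtol=np.deg2rad(tolerance) * 1e-3,
                          maxiter=200)
        except ValueError as exc:  # pragma: no cover - monotone, bracketed
            raise RuntimeError(
                f"inversion failed for theta'={tp_deg:g} deg: {exc}"
            ) from exc
        return float(np.rad2deg(root))

    if tp.shape:
        return np.array([solve(float(x)) for x in tp.ravel()]).reshape(tp.shape)
    return solve(float(tp))


@dataclass(frozen=True)
class AngleMap:
    """Tabulated θ′ ↔ θ transformation with per-angle transmittance.

    ``true_deg`` is a strictly increasing grid of true angles, ``apparent_deg``
    the corresponding apparent angles (strictly increasing, bounded by the
    Snell window), ``transmittance`` the stacked Fresnel factor for each ray.
    The interpolators below give fast vectorized access for image work.
    """

    true_deg: np.ndarray
    apparent_deg: np.ndarray
    transmittance: np.ndarray
    window_half_angle_deg: float

    @classmethod
    def from_stack(cls, stack: MediaStack, n_points: int = 2048,
                   max_true_deg: float = 89.95) -> "AngleMap":
        true = np.linspace(0.0, max_true_deg, n_points)
        apparent = flat_apparent_from_true(true, stack)
        trans = transmittance_from_apparent(apparent, stack)
        return cls(true, np.asarray(apparent), np.asarray(trans),
                   window_half_angle_for(stack))

    def apparent_of(self, true_deg):
        return np.interp(true_deg, self.true_deg, self.apparent_deg)

    def transmittance_of(self, true_deg):
        return np.interp(true_deg, self.true_deg, self.transmittance)

    def true_of(self, apparent_deg):
        return np.interp(apparent_deg, self.apparent_deg, self.true_deg)


# ---------------------------------------------------------------------------
# Curved dish: 2-D ray trace in the plane of eye, dish center and source
# ---------------------------------------------------------------------------

def _refract_dir(d: np.ndarray, normal: np.ndarray, n1: float, n2: float):
    """Vector Snell refraction; ``normal`` must oppose the ray direction."""
    ci = -float(d @ normal)
    eta = n1 / n2
    s2 = eta**2 * (1.0 - ci**2)
    if s2 > 1.0:
        return None
    return eta * d + (eta * ci - np.sqrt(1.0 - s2)) * normal


def curved_trace(source_point, geometry: CurvedDishGeometry,
                 tolerance: float = 1e-9) -> tuple[float, float]:
    """Trace a ray from a source outside the dish to the eye inside it.

    The dish wall is two concentric arcs with radial normals.  Coordinates:
    dish center at the origin, the stimulus axis along +x, the eye at
    ``(radius - d_w, 0)``.  ``source_point`` is ``(x, y)`` in mm with
    ``x >= radius + d_p`` (outside the plastic).

    Returns ``(apparent_angle_deg, transmittance)`` where the apparent angle
    is that of the ray arriving at the eye, measured from the stimulus axis.
    Raises :class:`UnreachableSourceError` when no refracted path exists.
    """
    g = geometry
    sx, sy = float(source_point[0]), float(source_point[1])
    if sx < g.radius_mm + g.d_p:
        raise UnreachableSourceError("source point must lie outside the dish wall")
    eye = np.array([g.radius_mm - g.d_w, 0.0])
    if sy == 0.0:
        return 0.0, _curved_transmittance(0.0, g)

    sign = 1.0 if sy > 0 else -1.0
    sy_abs = abs(sy)

    def miss_distance(phi: float) -> float:
        """Signed perpendicular miss of the exit ray relative to the source."""
        out = _trace_exit_ray(phi, g)
        if out is None:
            return np.nan
        origin, direction = out
        rel = np.array([sx, sy_abs]) - origin
        # positive when the source lies to the left of the exit ray
        return float(direction[0] * rel[1] - direction[1] * rel[0])

    # The traceable band of phi (inner-arc polar angle) ends where total
    # internal reflection at the outer arc sets in; bisect for that edge.
    phi_lo = 1e-9
    if not np.isfinite(miss_distance(phi_lo)):
        raise UnreachableSourceError(
            f"no refracted ray reaches the eye from ({sx:g}, {sy:g})"
        )
    phi_hi = np.pi / 2 * (1 - 1e-12)
    if not np.isfinite(miss_distance(phi_hi)):
        lo_f, hi_n = phi_lo, phi_hi
        for _ in range(100):
            mid = 0.5 * (lo_f + hi_n)
            if np.isfinite(miss_distance(mid)):
                lo_f = mid
            else:
                hi_n = mid
        phi_hi = lo_f
    lo_val = miss_distance(phi_lo)
    hi_val = miss_distance(phi_hi)
    if np.sign(lo_val) == np.sign(hi_val):
        # no crossing on the coarse bracket; scan for an interior one
        phis = np.linspace(phi_lo, phi_hi, 512)
        vals = np.array([miss_distance(p) for p in phis])
        idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if len(idx) == 0:
            raise UnreachableSourceError(
                f"no refracted ray reaches the eye from ({sx:g}, {sy:g})"
            )
        phi_lo, phi_hi = phis[idx[0]], phis[idx[0] + 1]
    phi = brentq(miss_distance, phi_lo, phi_hi, xtol=tolerance)
    inner = g.radius_mm * np.array([np.cos(phi), np.sin(phi)])
    d = inner - eye
    apparent = float(np.arctan2(d[1], d[0]))
    return sign * np.rad2deg(apparent), _curved_transmittance(phi, g)


def _trace_exit_ray(phi: float, g: CurvedDishGeometry):
    """Refract the eye->interface ray out through both arcs.

    Returns the exit ray (origin on the outer arc, unit direction in air), or
    None when total internal reflection or backward geometry blocks it.
    """
    eye = np.array([g.radius_mm - g.d_w, 0.0])
    inner = g.radius_mm * np.array([np.cos(phi), np.sin(phi)])
    d = inner - eye
    norm = np.linalg.norm(d)
    if norm == 0:
        return None
    d = d / norm
    inward = -inner / np.linalg.norm(inner)
    d_p = _refract_dir(d, inward, g.n_w, g.n_p)
    if d_p is None:
        return None
    # propagate across the plastic to the outer arc
    b = float(inner @ d_p)
    c = float(inner @ inner) - (g.radius_mm + g.d_p) ** 2
    disc = b * b - c
    if disc < 0:
        return None
    t = -b + np.sqrt(disc)
    outer = inner + t * d_p
    inward2 = -outer / np.linalg.norm(outer)
    d_a = _refract_dir(d_p, inward2, g.n_p, g.n_a)
    if d_a is None or d_a[0] <= 0:
        return None
    return outer, d_a


def _curved_transmittance(phi: float, g: CurvedDishGeometry) -> float:
    """Fresnel product for the two dish-wall boundaries at arc angle phi.

    Transmittance is direction-symmetric, so tracing eye->screen gives the
    same factor as the physical screen->eye ray.
    """
    eye = np.array([g.radius_mm - g.d_w, 0.0])
    inner = g.radius_mm * np.array([np.cos(phi), np.sin(phi)])
    d = inner - eye
    norm = np.linalg.norm(d)
    if norm == 0.0:  # on-axis: normal incidence at both arcs
        t1 = fresnel_transmittance(0.0, g.n_w, g.n_p)
        t2 = fresnel_transmittance(0.0, g.n_p, g.n_a)
        return t1 * t2
    d = d / norm
    inward = -inner / np.linalg.norm(inner)
    inc1 = np.rad2deg(np.arccos(np.clip(-d @ inward, -1, 1)))
    t1 = fresnel_transmittance(inc1, g.n_w, g.n_p)
    d_p = _refract_dir(d, inward, g.n_w, g.n_p)
    b = float(inner @ d_p)
    c = float(inner @ inner) - (g.radius_mm + g.d_p) ** 2
    outer = inner + (-b + np.sqrt(b * b - c)) * d_p
    inward2 = -outer / np.linalg.norm(outer)
    inc2 = np.rad2deg(np.arccos(np.clip(-d_p @ inward2, -1, 1)))
    t2 = fresnel_transmittance(inc2, g.n_p, g.n_a)
    return t1 * t2
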