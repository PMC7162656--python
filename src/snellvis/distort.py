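"""Forward distortion of screen images and its inverse (pre-correction).

The forward model follows the pinhole-eye ray trace: every (sub)pixel emits
a ray towards the eye; the ray's true position angle θ′ is mapped to its
apparent angle θ through the flat-interface transformation, its intensity is
scaled by the stacked Fresnel transmittance (and the screen's emission
profile), and the result is accumulated into the bin at the apparent
position on the screen plane (the point where the received ray, extended
straight back from the eye, crosses the screen plane: ρ_app = H·tanθ).

Moiré artifacts from the nonuniform compression are suppressed with 16×
ray supersampling plus stochastic jitter of each ray within ±1 sub-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .media import MediaStack
from .optics import AngleMap, dtrue_dapparent
from .screen import ApparentImage, ScreenImage, ScreenSpec

__all__ = ["distort_image", "correct_image", "CorrectionResult",
           "UncorrectableContentError"]


class UncorrectableContentError(ValueError):
    """Too much target energy lies outside the Snell window to be delivered."""

    def __init__(self, clipped_fraction: float, limit: float):
        self.clipped_fraction = clipped_fraction
        super().__init__(
            f"{clipped_fraction:.1%} of target energy lies outside the Snell "
            f"window (limit {limit:.1%}); it cannot be produced by any screen image"
        )


def _emission_weights(screen: ScreenSpec, stack: MediaStack, theta_deg):
    """Relative emission intensity for rays leaving at the screen-side angle."""
    if screen.emission_profile is None:
        return 1.0
    s = np.clip(stack.n_last * np.sin(np.deg2rad(theta_deg)) / stack.n_first, 0, 1)
    psi_a = np.rad2deg(np.arcsin(s))
    return screen.emission_profile(psi_a)


def distort_image(image: ScreenImage, screen: ScreenSpec, stack: MediaStack,
                  supersample: int = 16, jitter: bool = True,
                  seed: int | None = None,
                  angle_map: AngleMap | None = None) -> ApparentImage:
    """Trace a screen image through the stack into the eye's apparent view.

    ``supersample`` must be a square number; each pixel averages that many
    sub-pixel rays.  With ``jitter`` each ray is displaced uniformly within
    ±1 sub-pixel (a seeded stochastic-sampling scheme); a seed is then
    required so runs are reproducible.
    """
    if stack.total_thickness_mm <= 0:
        raise ValueError("stack has zero total thickness")
    g = int(round(np.sqrt(supersample)))
    if g * g != supersample or supersample < 1:
        raise ValueError("supersample must be a positive square number")
    if jitter and seed is None:
        raise ValueError("jitter requires a seed for reproducibility")

    lin = image.decode()
    data = lin.data
    n_rows, n_cols = data.shape
    if (n_rows, n_cols) != screen.shape:
        raise ValueError(f"image shape {data.shape} != screen raster {screen.shape}")

    amap = angle_map or AngleMap.from_stack(stack)
    H = stack.total_thickness_mm
    px_mm = screen.pixel_cm * 10.0
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    cgrid, rgrid = np.meshgrid(cols, rows)
    x0, y0 = screen.pixel_to_mm(rgrid.ravel(), cgrid.ravel())
    weights0 = data.ravel() / supersample

    rng = np.random.default_rng(seed) if jitter else None
    out = np.zeros(n_rows * n_cols)
    total_traced = 0.0
    clipped = 0.0
    sub = (np.arange(g) + 0.5) / g - 0.5  # sub-pixel offsets in pixel units
    for iy in range(g):
        for ix in range(g):
            dx = sub[ix]
            dy = sub[iy]
            if rng is not None:
                jx = rng.uniform(-1.0, 1.0, size=x0.shape) / g
                jy = rng.uniform(-1.0, 1.0, size=x0.shape) / g
            else:
                jx = jy = 0.0
            x = x0 + (dx + jx) * px_mm
            y = y0 + (dy + jy) * px_mm
            rho = np.hypot(x, y)
            tp = np.rad2deg(np.arctan2(rho, H))
            theta = amap.apparent_of(tp)
            trans = amap.transmittance_of(tp)
            w = weights0 * trans * _emission_weights(screen, stack, theta)
            total_traced += float(w.sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(rho > 1e-12,
                                 H * np.tan(np.deg2rad(theta)) / np.maximum(rho, 1e-12),
                                 1.0)
            r_f, c_f = screen.mm_to_pixel(x * scale, y * scale)
            r_i = np.rint(r_f).astype(np.intp)
            c_i = np.rint(c_f).astype(np.intp)
            ok = (r_i >= 0) & (r_i < n_rows) & (c_i >= 0) & (c_i < n_cols)
            np.add.at(out, r_i[ok] * n_cols + c_i[ok], w[ok])
            clipped += float(w[~ok].sum())

    window_px = H * np.tan(np.deg2rad(amap.window_half_angle_deg)) / px_mm
    return ApparentImage(
        data=out.reshape(n_rows, n_cols),
        window_radius_px=float(window_px),
        seed=seed,
        clipped_fraction=clipped / total_traced if total_traced else 0.0,
    )


@dataclass
class CorrectionResult:
    """Pre-corrected screen image plus the undeliverable target fraction."""

    image: ScreenImage
    clipped_fraction: float


def correct_image(target, screen: ScreenSpec, stack: MediaStack,
                  max_clipped_fraction: float = 0.25,
                  angle_map: AngleMap | None = None) -> CorrectionResult:
    """Invert the distortion: a screen image that reproduces ``target``.

    ``target`` is the desired apparent view (an :class:`ApparentImage` or a
    linear-intensity array on the screen raster).  For each source pixel the
    forward map gives its apparent position; the target is sampled there and
    compensated by the stacked transmittance and the analytic Jacobian of
    the position mapping, so that ``distort_image`` of the result
    approximates the target inside the Snell window.  Target content outside
    the window is physically undeliverable: it is zeroed and reported, and
    more than ``max_clipped_fraction`` of target energy there is an error.
    """
    tdata = target.data if isinstance(target, ApparentImage) else np.asarray(
        target, dtype=float)
    n_rows, n_cols = screen.shape
    if tdata.shape != (n_rows, n_cols):
        raise ValueError("target raster does not match the screen")

    amap = angle_map or AngleMap.from_stack(stack)
    H = stack.total_thickness_mm

    # undeliverable energy: target bins beyond the window's screen footprint
    cgrid, rgrid = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    tx, ty = screen.pixel_to_mm(rgrid, cgrid)
    trho = np.hypot(tx, ty)
    window_mm = H * np.tan(np.deg2rad(amap.window_half_angle_deg))
    outside = trho >= window_mm * (1 - 1e-9)
    total = float(tdata.sum())
    clipped_fraction = float(tdata[outside].sum()) / total if total > 0 else 0.0
    if clipped_fraction > max_clipped_fraction:
        raise UncorrectableContentError(clipped_fraction, max_clipped_fraction)

    rho = trho  # source-pixel radii coincide with the raster grid
    tp = np.rad2deg(np.arctan2(rho, H))
    theta = amap.apparent_of(tp)
    trans = amap.transmittance_of(tp)
    r_app = H * np.tan(np.deg2rad(theta))

    sampled = _bilinear_sample(np.where(outside, 0.0, tdata), screen,
                               tx, ty, r_app, rho)

    # Jacobian dA_apparent / dA_source of the radial position mapping
    with np.errstate(divide="ignore", invalid="ignore"):
        dtheta_dtp = 1.0 / np.asarray(dtrue_dapparent(theta, stack))
        radial = (np.cos(np.deg2rad(tp)) ** 2 /
                  np.cos(np.deg2rad(theta)) ** 2) * dtheta_dtp
        ring = np.where(rho > 1e-9, r_app / np.maximum(rho, 1e-9), dtheta_dtp)
    jac = ring * radial

    emission = _emission_weights(screen, stack, theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        source = sampled * jac / (trans * np.where(emission > 0, emission, np.inf))
    source = np.where(np.isfinite(source), source, 0.0)
    img = ScreenImage(np.clip(source, 0.0, None), "linear")
    return CorrectionResult(image=img, clipped_fraction=clipped_fraction)


def _bilinear_sample(data, screen, tx, ty, r_app, rho):
    """Sample the target raster at the apparent positions of source pixels."""
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 1e-12, r_app / np.maximum(rho, 1e-12), 1.0)
    r_f, c_f = screen.mm_to_pixel(tx * scale, ty * scale)
    n_rows, n_cols = data.shape
    r0 = np.clip(np.floor(r_f).astype(np.intp), 0, n_rows - 2)
    c0 = np.clip(np.floor(c_f).astype(np.intp), 0, n_cols - 2)
    fr = np.clip(r_f - r0, 0.0, 1.0)
    fc = np.clip(c_f - c0, 0.0, 1.0)
    v = (data[r0, c0] * (1 - fr) * (1 - fc)
         + data[r0 + 1, c0] * fr * (1 - fc)
         + data[r0, c0 + 1] * (1 - fr) * fc
         + data[r0 + 1, c0 + 1] * fr * fc)
    return v
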