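# Methods

## The physical problem

In a typical aquatic-vision experiment (larval zebrafish are the motivating
case) a stimulus is projected onto a screen beneath a water-filled plastic
dish. Between the screen and the animal's eye the light crosses an air gap
(`d_a`), the plastic dish bottom (`d_p`, polystyrene, n = 1.55), and the
water column (`d_w`, n = 1.333). Refraction at each boundary bends every
ray toward the vertical, so the image the animal receives is a compressed,
translated version of the image on the screen, and the fraction of light
transmitted falls with incidence angle. `snellvis` models these effects,
quantifies their consequences for two classes of experiments (looming
stimuli and receptive-field mapping), and inverts them so stimuli can be
pre-corrected.

## Flat layered interface

For a ray arriving at the eye at angle θ from the vertical, Snell's law
fixes the ray angle in every layer: `n_i sin ψ_i = n_w sin θ`. Summing the
horizontal runs of the ray across the layers gives the true position angle
of its source on the screen,

    tan θ′ = ( Σ_i d_i tan ψ_i ) / ( Σ_i d_i ),

a closed form implemented in `optics.flat_true_from_apparent`. The inverse
θ(θ′) has no closed form; because θ′(θ) is strictly monotone on the Snell
window `[0, arcsin(n_air/n_water))`, we invert with bracketed Brent root
finding (`scipy.optimize.brentq`, objective tolerance 1e-12 degrees;
bracketing makes convergence guaranteed, so no fallback path is needed).
All public angles are degrees; radians are used internally.

The Snell window half-angle `arcsin(1/1.333) = 48.607°` depends only on the
refractive indices — the layer thicknesses control only how abruptly θ(θ′)
saturates (the ratio `d_a/d_w` is the governing parameter). The window edge
itself maps to the horizon and is treated as out-of-window (half-open
interval).

Transmittance uses the unpolarized Fresnel average `T = 1 − (Rs + Rp)/2`
per boundary, with the full stack transmittance the product of the
boundary factors. Multiple internal reflections inside the plastic are
ignored; they contribute at the `(R_ap·R_pw) ≈ 10⁻³` level. Total internal
reflection cannot occur for screen→eye rays (every boundary goes rarer →
denser), but the error path exists for API symmetry.

For image work the transformation and transmittance are tabulated on a
2048-point grid of true angles up to 89.95° (`AngleMap`) and interpolated
linearly; interpolation error is < 1e-4 degrees, negligible against pixel
quantization.

## Curved dish interface

When the stimulus is shown from the side through the dish wall, the wall is
modeled as two concentric circular arcs (water–plastic at the dish radius
r, plastic–air at r + d_p) with radial normals, a plane screen at `d_a`
beyond the outer arc, and the eye on the stimulus axis `d_w` inside the
inner arc. Centered stimuli make the 3-D problem axially symmetric, so the
trace is 2-D in the plane containing eye, dish center and source
(`optics.curved_trace`). For a given crossing point on the inner arc we
refract the eye-side ray outward through both arcs analytically; the
crossing angle is then solved so the exit ray passes through the source
(Brent, tolerance 1e-9). The traceable band of crossing angles is bounded
by total internal reflection at the plastic–air arc; the implementation
first bisects for that boundary, then root-finds inside it (the solution
can sit very close to the boundary for near-edge sources). At
`r ≥ 10⁴·d_w` the trace agrees with the flat solution to better than
0.01°, which is the validation oracle for the geometry.

## Solid angles on the viewing sphere

Stimulus size is quantified by solid angle: the area of the shape projected
on the unit sphere, independent of distance. Circular caps use the closed
form `A = 2π(1 − cos θ)` (θ the half-apex angle). Irregular shapes are
reduced to an ordered border in latitude/longitude (pole on the eye's
vertical axis) and measured by the shoelace area of the border polygon in
the equal-area sinusoidal projection `(x, y) = (β cos α, α)`. Because the
projection preserves area exactly, the only approximation is the polygonal
sampling of the border: 720 points keep cap-formula agreement below 0.1%.
Before projecting, the border is rotated so its mean direction sits at the
projection origin; a rotation changes no area and keeps every connected
shape smaller than a hemisphere away from the projection's pole and
antimeridian (shapes that still span more than a hemisphere raise an
unsupported-topology error — they are out of scope). Borders of raster
masks are traced with Moore-neighbor contour following, with pixel centers
as vertices; this matches how an experimenter would outline a thresholded
shape, and its cost is a half-pixel inward bias quantified below.

## Image distortion and correction

`distort_image` implements the pinhole-eye forward model: each pixel is
split into 16 sub-pixel rays (4×4), each ray optionally jittered uniformly
within ±1 sub-pixel (one seeded uniform draw per ray; the jitter suppresses
moiré from the strongly nonuniform compression), its intensity is the
gamma-decoded illuminance scaled by the stack transmittance and the
screen's angular emission profile (uniform by default), and the result is
accumulated in the bin at the ray's apparent position — the point where the
received ray, extended straight back from the eye, crosses the screen
plane (`ρ_app = H·tan θ`, H the total stack thickness). Nearest-pixel
accumulation is the default (bilinear splatting would trade energy
locality for smoothness); binning therefore conserves the traced,
transmittance-weighted energy exactly. With matched refractive indices the
transform is the identity at the raster level. The bright ring where the
compressed horizon piles up at the window edge is physical in this model; a
real eye's photoreceptor blur would attenuate it, so display saturation
(99th-percentile clipping) is applied only at render time and never to
stored rasters. An optional Gaussian blur post-filter is deliberately not
applied by default: the pinhole model keeps the geometry interpretable.

`correct_image` inverts the process: for each source pixel the forward map
gives its apparent position; the target is sampled there bilinearly and
compensated by the transmittance and the analytic Jacobian of the position
mapping (built from the closed-form derivative dθ′/dθ — no numerical
differentiation). Target content outside the window's screen footprint is
physically undeliverable; it is zeroed, reported as a clipped fraction, and
rejected above a configurable threshold (default 25% of target energy).
The round trip distort∘correct restores smooth in-window targets with
normalized RMS error below 5% at the default 250 px/cm.

Gamma handling follows standard projector practice: stored pixel values are
`x^(1/γ)` with γ = 2.2; decoding normalizes the encoded range to [0, 1],
applies the power γ, and rescales to the calibrated illuminance range
(default 1.0–500.0 lux, a typical lab projector span). Gratings are
generated in encoded space so their decoded illuminance sweeps that range
exactly.

## Looming-stimulus corrections

Two published escape-behavior geometries ship as presets:

* `dunn2016` — flat stack, d_a = 0.5 mm, d_p = 1 mm, d_w = 3 mm, stimulus
  center offset 10 mm along the screen. The water depth is treated as
  constant, a stated approximation for freely swimming animals.
* `temizer2015` — curved dish, r = 17.5 mm, d_a = 8 mm, d_p = 1 mm,
  d_w = 2 mm, stimulus centered.

The naive angular size of an offset disc is defined as
`2·arctan(R / hypot(offset, eye height))` — the disc radius over the
straight-line distance to the disc center, the standard convention in the
looming literature. Under it, the flat-geometry critical stimulus (72.0°)
becomes a 7.97 mm disc whose straight-line solid angle is 1.02 sr, and the
curved-geometry critical cap (21.7°) measures 0.11 sr.

The corrected flat-geometry size maps each border ray through the layered
transformation and registers the apparent border at the ray's crossing of
the refracting interface, expressed on the screen raster
(`ρ_app = d_w·tan θ`), then converts border pixels to sphere angles in the
experimenter's straight-line frame (eye height `d_a + d_p + d_w`). This
interface-footprint registration is the convention under which the
corrected critical sizes and the cross-study discrepancy statistics of the
toolkit are defined; note it intentionally differs from the screen-plane
back-projection used by the image engine (`ρ_app = H·tan θ`), which an
identity stack must leave raster-invariant. Users who want the pure
apparent-direction solid angle can compute it directly from
`flat_apparent_from_true` plus `polygon_solid_angle`; for the flat preset
it is larger (≈ 0.38 sr for the critical disc) because the apparent
directions themselves are what the eye receives, while the registered
footprint describes the corrected image analysis. The curved-geometry
correction is registration-free: the traced apparent half-angle feeds the
cap formula directly (0.08 sr for the critical cap).

Discrepancy statistics propagate independent Gaussian errors: variances add
for differences; relative variances add for ratios. Printed asymmetric CIs
are converted to an SD via their half-width; the propagated CI is reported
as such and never blended with asymmetric bounds.

## Receptive-field mapping simulation

A neuron's RF is a Gaussian of great-circle distance ρ on the sphere,
`P(ρ) = exp(−ρ²/2σ²)`, with ρ from the spherical law of cosines. The
simulated pixel-wise response is `F(x) = T(ψ_a(x))·P(ρ(x))` where the
pixel's retinal direction is the refracted one; the "true RF" uses
straight-line directions and T = 1. Peak position is the argmax pixel
converted to the straight-line along-screen angle (the naive coordinate an
experimenter reports); RF size is the solid angle of the half-maximum
region (threshold exactly 0.5·max, ties in the foreground), measured by
border tracing. The screen defaults to the same 4×4 cm, 250 px/cm raster
used for the grating illustrations; that inheritance is a package choice,
since RF-mapping rigs vary widely in screen geometry.

## Numerical choices and degenerate inputs

* Brent tolerances: 1e-12° (flat inversion), 1e-9 (curved trace objective).
* Border sampling: 720 points for analytic discs; Moore-traced pixel
  centers for rasters. Pixel-center tracing biases areas low by roughly one
  half-pixel ring (≈ 3% at 250 px/cm for a σ = 10° RF); tests budget for
  exactly this, and estimates converge at ~1/resolution.
* Degenerate inputs: zero-size stimuli return 0 sr; all-zero RF maps,
  empty or multi-component masks, self-intersecting borders and
  out-of-window angles raise typed errors rather than returning numbers.
* Randomness: the ray jitter is the only stochastic element; it draws from
  one `numpy` generator seeded by a single user-visible integer, so any
  result is bit-reproducible from (inputs, seed).

## What the synthetic fixtures do and do not capture

The fixture generator produces gratings, uniform fields, naive-size discs
and checkered balls — idealized, noise-free rasters with exact geometry.
They exercise every code path (distortion, correction, border extraction,
solid angles) but contain none of the complications of real rigs:
non-uniform projector emission (modelable via `emission_profile`, but not
measured here), display nonlinearity beyond a scalar gamma, eye optics
beyond the pinhole (photoreceptor blur, lens aberrations), meniscus
curvature at dish edges, or depth changes of a swimming animal. Passing
tests therefore demonstrate the geometric-optics computations, not a
calibrated end-to-end model of any particular rig.

## Problem sizes

Default simulations use the 4×4 cm, 250 px/cm screen (10⁶ pixels; 1.6×10⁷
rays at 16× supersampling). Test and illustration runs use 50–250 px/cm as
appropriate to the quantity under test; the looming and window quantities
are resolution-free (analytic borders), so their values do not depend on
any raster.

## Known limitations

* The curved-dish trace covers centered (axially symmetric) stimuli only;
  off-axis sources through curved walls would need a full 3-D trace.
* Shapes larger than a hemisphere and multi-component stimuli are not
  quantified (per-component quantification and summation is the intended
  route).
* Polarization is averaged; refractive indices are achromatic.
* The interface-footprint registration for corrected flat looming sizes is
  a defined analysis convention (see above), not a physical image position;
  both conventions are exposed through the API.
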