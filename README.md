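# snellvis

A geometric-optics toolkit for visual neuroscience in aquatic animals.
When a stimulus is projected onto a screen outside a water-filled arena —
the standard arrangement in larval-zebrafish experiments — every light ray
refracts at the air–plastic–water boundaries on its way to the eye. The
image the animal actually receives is compressed into the **Snell window**
(a cone of half-angle `arcsin(n_air/n_water) ≈ 48.6°`), translated, and
dimmed by Fresnel reflection. Ignoring this changes what "stimulus size"
and "stimulus position" mean, which matters for anyone designing stimuli,
measuring receptive fields, or comparing thresholds across rigs.

`snellvis` provides:

* **Flat-stack optics** — the closed-form transformation
  `tan θ′ = Σ dᵢ tan ψᵢ / Σ dᵢ` between a point's true screen angle θ′ and
  its apparent angle θ (with `nᵢ sin ψᵢ = n_w sin θ`), its guaranteed
  monotone numerical inverse, and unpolarized Fresnel transmittance
  `T = 1 − (Rs+Rp)/2` stacked across boundaries.
* **Curved-dish optics** — a 2-D ray trace through the two concentric arcs
  of a plastic dish wall for side-projected, centered stimuli.
* **An image engine** — forward-distort any grayscale stimulus into the
  animal's apparent view (gamma decoding, 16× supersampling, seeded
  anti-moiré jitter, emission profiles), and invert the distortion to
  pre-correct a target view into a displayable image.
* **Solid-angle measurement** — spherical-cap closed form, and arbitrary
  shapes via Moore-traced borders projected through the equal-area
  sinusoidal map `(x, y) = (β cos α, α)` with shoelace integration.
* **Looming corrections** — critical-size and time-course corrections for
  the two published escape-behavior geometries (`dunn2016` flat,
  `temizer2015` curved presets), with difference/ratio error propagation.
* **RF-mapping simulation** — how interface distortion shifts measured
  receptive-field peaks and sizes for Gaussian RFs on the viewing sphere.

## Worked example

Two escape-behavior studies reported critical looming sizes of 72.0°
(flat below-dish projection, stimulus 10 mm off-axis) and 21.7° (curved
side projection, centered) — naively a nine-fold disagreement in solid
angle. Correcting both for refraction:

```python
import snellvis as sv

dunn = sv.get_preset("dunn2016")        # air 0.5 | plastic 1 | water 3 mm
temizer = sv.get_preset("temizer2015")  # dish r 17.5, air 8, plastic 1, water 2 mm

sv.snell_window_half_angle(1.0, 1.333)       # 48.60662639169028
sv.naive_disc_solid_angle(72.0)              # 1.0225688135833326
sv.corrected_flat_solid_angle(72.0, dunn)    # 0.24749975366568655
sv.spherical_cap_solid_angle(21.7)           # 0.11232226894946323
sv.corrected_curved_solid_angle(21.7, temizer)  # 0.07951844015365235
```

Uncorrected, the two critical stimuli differ by 1.02 − 0.11 ≈ 0.91 sr
(a ~9× ratio). After tracing each stimulus border through its interface,
the corrected sizes are 0.247 and 0.080 sr: the gap shrinks to ≈ 0.17 sr
and the ratio to ~3×. Most of the apparent disagreement between the two
studies is interface optics, not biology.

The same numbers from the command line:

```sh
$ snellvis loom --preset dunn2016 --naive-angle 72.0
{"mode": "loom", "naive_angle_deg": 72.0, "corrected_solid_angle_sr": 0.24749975366568655, "naive_solid_angle_sr": 1.0225688135833326}
```

Distorting and pre-correcting images:

```sh
snellvis distort --config geom.yaml --in stim.png --out stim_distorted.tiff \
    --supersample 16 --jitter --seed 0
snellvis correct --config geom.yaml --in target.png --out precorrected.png
```

where `geom.yaml` lists the layers (`thickness_mm`, `n`) and the screen
(`width_cm`, `height_cm`, `resolution`). Content outside the Snell window
is physically undeliverable; `correct` zeroes it and reports the clipped
energy fraction.

See `docs/methods.md` for the model, conventions (including the
apparent-border registration used for corrected looming sizes), numerical
choices, and limitations.

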