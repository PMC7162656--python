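"""Optical media geometry: layered flat stacks, curved dishes, and presets.

A typical zebrafish rig projects the stimulus onto a screen below a plastic
dish of water.  Between the screen and the eye the light crosses an air gap,
the plastic dish bottom, and the water column.  :class:`MediaStack` describes
this layered flat geometry ordered from the screen towards the eye;
:class:`CurvedDishGeometry` describes the alternative arrangement where the
stimulus is shown from the side through the curved dish wall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "Layer",
    "MediaStack",
    "CurvedDishGeometry",
    "PRESETS",
    "get_preset",
    "load_config",
    "save_config",
]

#: Refractive indices used throughout: air, polystyrene plastic, water.
N_AIR = 1.0
N_PLASTIC = 1.55
N_WATER = 1.333


@dataclass(frozen=True)
class Layer:
    """One optical layer: a name, a thickness in mm and a refractive index."""

    name: str
    thickness_mm: float
    n: float

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise ValueError(f"layer {self.name!r}: thickness must be >= 0")
        if self.n < 1:
            raise ValueError(f"layer {self.name!r}: refractive index must be >= 1")


@dataclass(frozen=True)
class MediaStack:
    """Ordered flat layers between the screen (first) and the eye (last).

    Parameters
    ----------
    layers
        Sequence of :class:`Layer`, ordered from the screen towards the eye,
        e.g. ``air | plastic | water`` for the standard below-dish projection.
    """

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("a MediaStack needs at least one layer")
        if self.total_thickness_mm <= 0:
            raise ValueError("total stack thickness must be > 0")

    @classmethod
    def from_tuples(cls, layers: Sequence[tuple[str, float, float]]) -> "MediaStack":
        return cls(tuple(Layer(*t) for t in layers))

    @classmethod
    def air_water(cls, d_a: float, d_w: float) -> "MediaStack":
        """Plain air|water stack (the plastic is often negligible)."""
        return cls.from_tuples([("air", d_a, N_AIR), ("water", d_w, N_WATER)])

    @classmethod
    def air_plastic_water(cls, d_a: float, d_p: float, d_w: float) -> "MediaStack":
        return cls.from_tuples(
            [("air", d_a, N_AIR), ("plastic", d_p, N_PLASTIC), ("water", d_w, N_WATER)]
        )

    @classmethod
    def identity(cls, total_mm: float = 10.0, n: float = 1.0) -> "MediaStack":
        """A single uniform medium; refraction-free reference geometry."""
        return cls.from_tuples([("medium", total_mm, n)])

    @property
    def total_thickness_mm(self) -> float:
        return sum(l.thickness_mm for l in self.layers)

    @property
    def n_first(self) -> float:
        return self.layers[0].n

    @property
    def n_last(self) -> float:
        return self.layers[-1].n

    @property
    def eye_side_thickness_mm(self) -> float:
        """Thickness of the medium the eye sits in (the last layer)."""
        return self.layers[-1].thickness_mm

    @property
    def is_identity(self) -> bool:
        return all(l.n == self.layers[0].n for l in self.layers)


@dataclass(frozen=True)
class CurvedDishGeometry:
    """Stimulus shown through the curved wall of a circular dish.

    The dish wall is modelled as two concentric circular arcs: the
    water-plastic interface at ``radius_mm`` and the plastic-air interface at
    ``radius_mm + d_p``.  The screen is a plane at distance ``d_a`` beyond the
    outer arc, perpendicular to the stimulus axis; the eye sits inside the
    dish on that axis, ``d_w`` from the inner arc.
    """

    radius_mm: float
    d_a: float
    d_p: float
    d_w: float
    n_a: float = N_AIR
    n_p: float = N_PLASTIC
    n_w: float = N_WATER

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("dish radius must be > 0")
        if self.d_w >= self.radius_mm:
            raise ValueError("the eye must sit inside the dish (d_w < radius)")
        for name in ("d_a", "d_p", "d_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def screen_distance_mm(self) -> float:
        """Axial distance from the eye to the screen plane."""
        return self.d_w + self.d_p + self.d_a


# ---------------------------------------------------------------------------
# Published experiment presets
# ---------------------------------------------------------------------------

#: Flat below-dish geometry used in the free-swimming escape study:
#: 0.5 mm air, 1 mm plastic, 3 mm water, stimulus offset 10 mm along the screen.
DUNN2016 = {
    "geometry": "flat",
    "layers": [
        {"name": "air", "thickness_mm": 0.5, "n": N_AIR},
        {"name": "plastic", "thickness_mm": 1.0, "n": N_PLASTIC},
        {"name": "water", "thickness_mm": 3.0, "n": N_WATER},
    ],
    "stimulus_offset_mm": 10.0,
}

#: Curved side-projection geometry used in the embedded escape study:
#: dish radius 17.5 mm, 8 mm air, 1 mm plastic, 2 mm water, stimulus centered.
TEMIZER2015 = {
    "geometry": "curved",
    "radius_mm": 17.5,
    "d_a": 8.0,
    "d_p": 1.0,
    "d_w": 2.0,
    "n_a": N_AIR,
    "n_p": N_PLASTIC,
    "n_w": N_WATER,
    "stimulus_offset_mm": 0.0,
}

PRESETS: dict[str, dict] = {"dunn2016": DUNN2016, "temizer2015": TEMIZER2015}


def get_preset(name: str) -> MediaStack | CurvedDishGeometry:
    """Return the geometry object for a named preset."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return _geometry_from_dict(cfg)


def _geometry_from_dict(cfg: dict) -> MediaStack | CurvedDishGeometry:
    kind = cfg.get("geometry", "flat")
    if kind == "flat":
        return MediaStack.from_tuples(
            [(l["name"], l["thickness_mm"], l["n"]) for l in cfg["layers"]]
        )
    if kind == "curved":
        return CurvedDishGeometry(
            radius_mm=cfg["radius_mm"],
            d_a=cfg["d_a"],
            d_p=cfg["d_p"],
            d_w=cfg["d_w"],
            n_a=cfg.get("n_a", N_AIR),
            n_p=cfg.get("n_p", N_PLASTIC),
            n_w=cfg.get("n_w", N_WATER),
        )
    raise ValueError(f"unknown geometry kind {kind!r}")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON geometry/run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def geometry_from_config(cfg: dict) -> MediaStack | CurvedDishGeometry:
    """Build a geometry object from a config dict, honouring ``preset`` keys."""
    if "preset" in cfg:
        return get_preset(cfg["preset"])
    return _geometry_from_dict(cfg)
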