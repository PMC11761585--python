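"""Four-layer head phantom with an embedded blood vessel.

The phantom stacks scalp (3 mm), skull (5 mm), cerebrospinal fluid
(2 mm) and gray matter (4 mm) along +Z inside a 14 mm cube, and embeds
a 2 mm-diameter cylindrical vessel centred in the gray-matter layer
(axis along Y by default, so the circular cross-section appears in the
x-z analysis plane).  Optical coefficients are the 800 nm literature
values used throughout the pipeline; acoustically all soft tissue is
treated as water, with the skull optionally given its own sound speed
and density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DEFAULT_GEOMETRY, GridGeometry

__all__ = [
    "TISSUES",
    "TissueProperties",
    "LabelVolume",
    "build_phantom",
    "property_lookup",
    "OPTICAL_TABLE",
    "WATER_SOUND_SPEED",
    "WATER_DENSITY",
    "SKULL_SOUND_SPEED",
    "SKULL_DENSITY",
    "DEFAULT_LAYERS",
]

#: Tissue names in label order (label value = position in this tuple).
TISSUES = ("scalp", "skull", "csf", "gray", "vessel")

#: Layer thicknesses in mm, top (illuminated) to bottom.
DEFAULT_LAYERS = (3.0, 5.0, 2.0, 4.0)

WATER_SOUND_SPEED = 1500.0  # m/s
WATER_DENSITY = 1000.0  # kg/m^3
SKULL_SOUND_SPEED = 2190.0  # m/s
SKULL_DENSITY = 1800.0  # kg/m^3


@dataclass(frozen=True)
class TissueProperties:
    """Optical and acoustic constants of one tissue class.

    mu_a and mu_s are in 1/mm, g and n dimensionless, sound_speed in
    m/s and density in kg/m^3.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float
    sound_speed: float = WATER_SOUND_SPEED
    density: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be nonnegative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound speed and density must be positive")


# 800 nm optical constants (mu_a, mu_s in 1/mm; g; n).
OPTICAL_TABLE: dict[str, TissueProperties] = {
    "scalp": TissueProperties(0.018, 19.0, 0.9, 1.37),
    "skull": TissueProperties(0.016, 16.0, 0.9, 1.43),
    "csf": TissueProperties(0.004, 2.4, 0.9, 1.33),
    "gray": TissueProperties(0.036, 22.0, 0.9, 1.37),
    "vessel": TissueProperties(0.223, 50.0, 0.99, 1.4),
}


def property_lookup(
    label: str,
    modality: str = "optical",
    skull_mode: str = "homogeneous",
) -> TissueProperties:
    """Return the property set for one tissue.

    Optical coefficients are always the built-in 800 nm values.  The
    acoustic fields depend on the skull mode: in ``homogeneous`` mode
    every tissue is acoustically water; in ``heterogeneous`` mode the
    skull carries its own sound speed (2190 m/s) and density
    (1800 kg/m^3).
    """
    if label not in OPTICAL_TABLE:
        raise KeyError(f"unknown tissue label {label!r}")
    if modality not in ("optical", "acoustic"):
        raise ValueError(f"unknown modality {modality!r}")
    if skull_mode not in ("homogeneous", "heterogeneous"):
        raise ValueError(f"unknown skull mode {skull_mode!r}")
    base = OPTICAL_TABLE[label]
    if skull_mode == "heterogeneous" and label == "skull":
        return TissueProperties(
            base.mu_a, base.mu_s, base.g, base.n, SKULL_SOUND_SPEED, SKULL_DENSITY
        )
    return base


@dataclass(frozen=True)
class LabelVolume:
    """Voxelized tissue-label map plus the property table it refers to."""

    geometry: GridGeometry
    labels: np.ndarray  # uint8, shape = geometry.shape, values index `tissues`
    tissues: tuple[str, ...] = TISSUES
    table: dict[str, TissueProperties] = field(default_factory=lambda: dict(OPTICAL_TABLE))

    def __post_init__(self) -> None:
        if tuple(self.labels.shape) != self.geometry.shape:
            raise ValueError("label array shape does not match geometry")
        if self.labels.dtype != np.uint8:
            object.__setattr__(self, "labels", self.labels.astype(np.uint8))
        if int(self.labels.max(initial=0)) >= len(self.tissues):
            raise ValueError("label value outside tissue list")
        missing = [t for t in self.tissues if t not in self.table]
        if missing:
            raise KeyError(f"tissues missing from property table: {missing}")

    def label_of(self, name: str) -> int:
        return self.tissues.index(name)

    def optical_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-label (mu_a, mu_s, g, n) arrays for the transport kernel."""
        props = [self.table[t] for t in self.tissues]
        mua = np.array([p.mu_a for p in props])
        mus = np.array([p.mu_s for p in props])
        g = np.array([p.g for p in props])
        n = np.array([p.n for p in props])
        return mua, mus, g, n

    def mu_a_volume(self) -> np.ndarray:
        """Per-voxel absorption coefficient (1/mm)."""
        mua, _, _, _ = self.optical_arrays()
        return mua[self.labels]

    def counts(self) -> dict[str, int]:
        c = np.bincount(self.labels.ravel(), minlength=len(self.tissues))
        return {t: int(c[i]) for i, t in enumerate(self.tissues)}


def build_phantom(
    geometry: GridGeometry = DEFAULT_GEOMETRY,
    layer_thicknesses: tuple[float, ...] = DEFAULT_LAYERS,
    vessel_center: tuple[float, float] = (7.0, 12.0),
    vessel_radius: float = 1.0,
    vessel_axis: str = "y",
) -> LabelVolume:
    """Build the layered phantom with the embedded vessel.

    Layers are assigned by voxel-center z over half-open bands; the
    vessel is a full-span cylinder overriding the gray-matter label
    where ``(u - u0)^2 + (z - z0)^2 <= r^2`` holds at the voxel center
    (``u`` = x for a Y-axis vessel, y for an X-axis vessel).

    Raises
    ------
    ValueError
        If the thicknesses do not tile the domain depth, or the vessel
        protrudes outside the gray-matter band.
    """
    if len(layer_thicknesses) != 4:
        raise ValueError("expected four layer thicknesses")
    if any(t <= 0 for t in layer_thicknesses):
        raise ValueError("layer thicknesses must be positive")
    depth = geometry.extent[2]
    if abs(sum(layer_thicknesses) - depth) > 1e-9:
        raise ValueError(
            f"layer thicknesses sum to {sum(layer_thicknesses)} mm, domain depth is {depth} mm"
        )
    if vessel_axis not in ("x", "y"):
        raise ValueError("vessel axis must be 'x' or 'y'")
    u0, z0 = vessel_center
    gray_lo = sum(layer_thicknesses[:3])
    gray_hi = depth
    if z0 - vessel_radius < gray_lo - 1e-9 or z0 + vessel_radius > gray_hi + 1e-9:
        raise ValueError("vessel cylinder protrudes outside the gray-matter band")

    zc = geometry.axis_centers(2)
    bounds = np.cumsum(layer_thicknesses)
    # half-open bands [0,b0), [b0,b1), ... ; centers at half-spacing offsets never tie
    zone = np.searchsorted(bounds, zc, side="right")
    zone = np.clip(zone, 0, 3).astype(np.uint8)
    labels = np.broadcast_to(zone[None, None, :], geometry.shape).copy()

    xc = geometry.axis_centers(0)
    yc = geometry.axis_centers(1)
    uc = xc if vessel_axis == "y" else yc
    in_circle = (uc[:, None] - u0) ** 2 + (zc[None, :] - z0) ** 2 <= vessel_radius**2
    gray_label = TISSUES.index("gray")
    vessel_label = TISSUES.index("vessel")
    if vessel_axis == "y":
        mask = in_circle[:, None, :] & (labels == gray_label)
    else:
        mask = in_circle[None, :, :] & (labels == gray_label)
    labels = np.where(mask, np.uint8(vessel_label), labels)
    return LabelVolume(geometry=geometry, labels=labels)
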