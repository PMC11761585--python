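"""The sixteen optical source types as samplable launch distributions.

Every source launches photons from the illuminated (z = 0) face of the
phantom into the +Z half-space.  Kinds split into three families:

* point kinds (pencil, isotropic, arcsine, cone, angular Gaussian)
  differ only in their angular distribution;
* line kinds (slit, line) spread positions over a 1 mm X-aligned
  segment;
* surface kinds (planar, disk, ring, pencil array, collimated /
  hyperboloid Gaussian, Fourier patterns) spread positions over a
  1 mm-scale aperture, collimated along +Z.

The characteristic length / diameter / pitch of every kind is 1 mm and
the characteristic angle is pi/6.  Patterned (Fourier) kinds modulate
the launch *weight* rather than rejecting positions, so the launched
photon count is deterministic.  The per-kind defaults are this
package's own declared definitions and are configurable through
:class:`SourceSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SOURCE_KINDS",
    "SourceSpec",
    "PhotonLaunch",
    "source_spec",
    "sample_launch",
    "sample_launches",
    "aperture_intensity",
]

#: The sixteen kinds in canonical listing order (used for tie-breaks).
SOURCE_KINDS = (
    "pencil",
    "isotropic",
    "arcsine",
    "cone",
    "slit",
    "line",
    "collimated_gaussian",
    "angular_gaussian",
    "hyperboloid_gaussian",
    "planar",
    "disk",
    "ring",
    "pencil_array",
    "fourier_sf",
    "fourier_1d",
    "fourier_2d",
)

_COLLIMATED = frozenset(
    {
        "pencil",
        "slit",
        "collimated_gaussian",
        "planar",
        "disk",
        "ring",
        "pencil_array",
        "fourier_sf",
        "fourier_1d",
        "fourier_2d",
    }
)

_SURFACE = frozenset(
    {
        "planar",
        "disk",
        "ring",
        "collimated_gaussian",
        "fourier_sf",
        "fourier_1d",
        "fourier_2d",
    }
)

#: Spatial-frequency pattern (k_x cycles, k_y cycles, phase) per Fourier kind.
_FOURIER_PATTERNS = {
    "fourier_sf": (1.0, 1.0, 0.0),
    "fourier_1d": (1.0, 0.0, 0.0),
    "fourier_2d": (1.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class SourceSpec:
    """Parameters of one optical source.

    extent is the characteristic length / diameter / thickness / pitch
    in mm; angle the half-angle or angular spread in rad.  pattern holds
    (k_x, k_y, phase) for the Fourier kinds, array_shape the beam grid
    of the pencil array, and focus_depth the focal depth (mm) of the
    hyperboloid Gaussian.
    """

    kind: str
    position: tuple[float, float, float] = (7.0, 7.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    extent: float = 1.0
    angle: float = math.pi / 6
    pattern: tuple[float, float, float] = (1.0, 0.0, 0.0)
    array_shape: tuple[int, int] = (3, 3)
    focus_depth: float = 7.0

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        d = np.asarray(self.direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, rel_tol=1e-9):
            raise ValueError("direction must be unit-norm")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if not 0 < self.angle < math.pi / 2:
            raise ValueError("angle must lie in (0, pi/2)")

    @property
    def is_collimated(self) -> bool:
        return self.kind in _COLLIMATED

    @property
    def is_surface(self) -> bool:
        return self.kind in _SURFACE


@dataclass(frozen=True)
class PhotonLaunch:
    """Initial state of one photon packet (position mm, unit direction, weight)."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    weight: float = 1.0


def source_spec(kind: str, **overrides) -> SourceSpec:
    """Build the default spec of a kind (Fourier patterns filled in)."""
    spec = SourceSpec(kind=kind, **overrides)
    if kind in _FOURIER_PATTERNS and "pattern" not in overrides:
        spec = replace(spec, pattern=_FOURIER_PATTERNS[kind])
    return spec


def _hemisphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """Directions uniform in solid angle over the downward (+Z) hemisphere.

    Equivalent to sampling the full sphere and re-drawing upward-going
    launches.
    """
    cos_t = rng.uniform(0.0, 1.0, n)
    return _dirs_from_cos(cos_t, rng.uniform(0.0, 2 * math.pi, n))


def _dirs_from_cos(cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    return np.column_stack((sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t))


def sample_launches(
    spec: SourceSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` photon launches.

    Returns (positions (n, 3) mm, unit directions (n, 3), weights (n,)).
    Repeated calls with an identically seeded generator reproduce the
    same sequence.
    """
    x0, y0, z0 = spec.position
    a = spec.extent  # characteristic length, mm
    pos = np.tile(np.asarray(spec.position, dtype=float), (n, 1))
    wts = np.ones(n)
    kind = spec.kind

    if kind == "pencil":
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif kind == "isotropic":
        dirs = _hemisphere(rng, n)
    elif kind == "arcsine":
        # polar angle uniform on [0, pi/2]  (cos(theta) arcsine-distributed)
        theta = rng.uniform(0.0, math.pi / 2, n)
        dirs = _dirs_from_cos(np.cos(theta), rng.uniform(0.0, 2 * math.pi, n))
    elif kind == "cone":
        cos_t = rng.uniform(math.cos(spec.angle), 1.0, n)
        dirs = _dirs_from_cos(cos_t, rng.uniform(0.0, 2 * math.pi, n))
    elif kind == "angular_gaussian":
        # half-normal polar angle, sigma = spec.angle, truncated at pi/2
        theta = np.abs(rng.normal(0.0, spec.angle, n))
        while np.any(theta >= math.pi / 2):
            bad = theta >= math.pi / 2
            theta[bad] = np.abs(rng.normal(0.0, spec.angle, int(bad.sum())))
        dirs = _dirs_from_cos(np.cos(theta), rng.uniform(0.0, 2 * math.pi, n))
    elif kind in ("slit", "line"):
        pos[:, 0] = x0 + rng.uniform(-a / 2, a / 2, n)
        if kind == "slit":
            dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        else:
            dirs = _hemisphere(rng, n)
    elif kind == "collimated_gaussian":
        # transverse Gaussian, 1/e^2 beam diameter = extent  (sigma = extent/4)
        sigma = a / 4.0
        pos[:, 0] = x0 + rng.normal(0.0, sigma, n)
        pos[:, 1] = y0 + rng.normal(0.0, sigma, n)
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif kind == "hyperboloid_gaussian":
        # Gaussian-beam ray bundle: waist 1/e^2 diameter = extent at depth
        # focus_depth, Rayleigh-range parameter set equal to the focal
        # depth so the beam converges from sqrt(2) x the waist size at
        # the surface down to the waist at the focus.
        sigma_w = a / 4.0
        sigma_t = sigma_w / spec.focus_depth
        gw = rng.normal(0.0, sigma_w, (n, 2))  # waist-plane offsets
        ga = rng.normal(0.0, sigma_t, (n, 2))  # ray angles (small)
        pos[:, 0] = x0 + gw[:, 0] - spec.focus_depth * ga[:, 0]
        pos[:, 1] = y0 + gw[:, 1] - spec.focus_depth * ga[:, 1]
        dirs = np.column_stack((ga[:, 0], ga[:, 1], np.ones(n)))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    elif kind in ("planar", "fourier_sf", "fourier_1d", "fourier_2d"):
        u = rng.uniform(0.0, 1.0, n)
        v = rng.uniform(0.0, 1.0, n)
        pos[:, 0] = x0 + (u - 0.5) * a
        pos[:, 1] = y0 + (v - 0.5) * a
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        if kind != "planar":
            kx, ky, phase = spec.pattern
            wts = 0.5 * (1.0 + np.cos(2 * math.pi * (kx * u + ky * v + phase)))
    elif kind in ("disk", "ring"):
        r_out = a / 2.0
        r_in = 0.0 if kind == "disk" else a / 4.0
        r = np.sqrt(rng.uniform(r_in**2, r_out**2, n))
        phi = rng.uniform(0.0, 2 * math.pi, n)
        pos[:, 0] = x0 + r * np.cos(phi)
        pos[:, 1] = y0 + r * np.sin(phi)
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif kind == "pencil_array":
        nx, ny = spec.array_shape
        ox = (np.arange(nx) - (nx - 1) / 2.0) * a
        oy = (np.arange(ny) - (ny - 1) / 2.0) * a
        beam = rng.integers(0, nx * ny, n)
        pos[:, 0] = x0 + ox[beam % nx]
        pos[:, 1] = y0 + oy[beam // nx]
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    else:  # pragma: no cover - guarded by SourceSpec validation
        raise ValueError(f"unknown source kind {kind!r}")

    return pos, dirs, wts


def sample_launch(spec: SourceSpec, rng: np.random.Generator) -> PhotonLaunch:
    """Draw a single launch (convenience wrapper over sample_launches)."""
    pos, dirs, wts = sample_launches(spec, 1, rng)
    return PhotonLaunch(tuple(pos[0]), tuple(dirs[0]), float(wts[0]))


def aperture_intensity(spec: SourceSpec, x: float, y: float) -> float:
    """Relative launch density of a surface kind at a point on z = 0.

    Proportional to the probability density (times weight for patterned
    kinds) of launching at ``(x, y)``; integrates to 1 over the
    aperture and is 0 outside it.  Units: 1/mm^2.
    """
    if not spec.is_surface:
        raise ValueError(f"{spec.kind!r} is not a surface source kind")
    x0, y0, _ = spec.position
    a = spec.extent
    dx, dy = x - x0, y - y0
    if spec.kind == "planar":
        inside = abs(dx) <= a / 2 and abs(dy) <= a / 2
        return 1.0 / a**2 if inside else 0.0
    if spec.kind == "disk":
        return 1.0 / (math.pi * (a / 2) ** 2) if dx**2 + dy**2 <= (a / 2) ** 2 else 0.0
    if spec.kind == "ring":
        r_out, r_in = a / 2, a / 4
        r2 = dx**2 + dy**2
        if r_in**2 < r2 <= r_out**2:
            return 1.0 / (math.pi * (r_out**2 - r_in**2))
        return 0.0
    if spec.kind == "collimated_gaussian":
        sigma = a / 4.0
        return float(
            math.exp(-(dx**2 + dy**2) / (2 * sigma**2)) / (2 * math.pi * sigma**2)
        )
    # Fourier kinds: uniform positions, cosine weight; density = weight / integral
    u, v = dx / a + 0.5, dy / a + 0.5
    if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
        return 0.0
    kx, ky, phase = spec.pattern
    w = 0.5 * (1.0 + math.cos(2 * math.pi * (kx * u + ky * v + phase)))
    # integral of the weight over the aperture: 0.5 * a^2 when (kx, ky)
    # has an integer nonzero component, else full closed form
    total = _pattern_integral(kx, ky, phase) * a**2
    return w / total


def _pattern_integral(kx: float, ky: float, phase: float) -> float:
    """Mean of (1 + cos(2 pi (kx u + ky v + phase)))/2 over the unit square."""

    def sinc(t: float) -> float:
        return 1.0 if t == 0 else math.sin(math.pi * t) / (math.pi * t)

    return 0.5 * (1.0 + sinc(kx) * sinc(ky) * math.cos(math.pi * (kx + ky + 2 * phase)))
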