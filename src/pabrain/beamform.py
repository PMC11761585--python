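"""Delay-and-sum beamforming with homogeneous or skull-corrected delays.

Each image pixel accumulates the bare (unapodised, unnormalised) sum
over the 140 element traces evaluated at the one-way time of flight,
with linear interpolation between samples.  The homogeneous delay
model uses water speed along the whole straight path; the layered
model splits the same straight ray at the skull-band planes
(z in [3, 8) mm) and charges the in-band segment at the bone sound
speed — no refraction, matching a distance-over-speed correction.

The reported image is the absolute value of the signed sum; the signed
map is retained for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acoustics import SensorArraySpec, SensorData
from .phantom import SKULL_SOUND_SPEED, WATER_SOUND_SPEED

__all__ = ["DelayModel", "ReconImage", "compute_delay", "das_reconstruct"]


@dataclass(frozen=True)
class DelayModel:
    """Time-of-flight model for the beamformer (speeds m/s, band mm)."""

    mode: str = "homogeneous"
    water_speed: float = WATER_SOUND_SPEED
    skull_speed: float = SKULL_SOUND_SPEED
    skull_band: tuple[float, float] = (3.0, 8.0)

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "layered"):
            raise ValueError(f"unknown delay mode {self.mode!r}")


@dataclass(frozen=True)
class ReconImage:
    """Reconstructed PA map: signed DAS sum and its amplitude, [ix, iz]."""

    signed: np.ndarray
    spacing: float = 0.1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.signed)):
            raise FloatingPointError("non-finite reconstruction")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.signed)


def _delay_grid(
    px: np.ndarray, pz: np.ndarray, ex: np.ndarray, model: DelayModel
) -> np.ndarray:
    """Delays (s) for pixel coords (mm) against element x coords (mm).

    Broadcasts to shape px.shape x ex.shape; elements sit at z = 0.
    """
    dxs = px[..., None] - ex
    dist = np.sqrt(dxs**2 + pz[..., None] ** 2) * 1e-3  # m
    if model.mode == "homogeneous":
        return dist / model.water_speed
    z0, z1 = model.skull_band
    with np.errstate(divide="ignore", invalid="ignore"):
        overlap = np.clip(np.minimum(pz, z1) - z0, 0.0, None)
        frac = np.where(pz > 0, overlap / np.where(pz > 0, pz, 1.0), 0.0)
    skull_len = dist * frac[..., None]
    return (dist - skull_len) / model.water_speed + skull_len / model.skull_speed


def compute_delay(
    pixel: tuple[float, float], element_x: float, model: DelayModel
) -> float:
    """One-way propagation time (s) from a pixel (x, z) mm to an element."""
    px = np.asarray([pixel[0]])
    pz = np.asarray([pixel[1]])
    return float(_delay_grid(px, pz, np.asarray([element_x]), model)[0, 0])


def das_reconstruct(
    data: SensorData,
    model: DelayModel,
    spacing: float = 0.1,
    sensor: SensorArraySpec | None = None,
) -> ReconImage:
    """Beamform the sensor traces onto the 2D grid.

    I(x, z) = sum_i p_i(dt_i(x, z)); traces are linearly interpolated,
    delays beyond the record contribute zero.
    """
    sensor = sensor or data.sensor
    if data.values.shape != (sensor.n_elements, sensor.n_samples):
        raise ValueError("sensor data does not match the sensor spec")
    n = sensor.n_elements
    coords = (np.arange(n) + 0.5) * spacing  # pixel/element centres, mm
    px = np.broadcast_to(coords[:, None], (n, n))
    pz = np.broadcast_to(coords[None, :], (n, n))
    delays = _delay_grid(px, pz, coords, model)  # (nx, nz, n_elem)

    s = delays / sensor.dt
    i0 = np.floor(s).astype(np.int64)
    frac = s - i0
    valid = (i0 >= 0) & (i0 < sensor.n_samples - 1)
    i0c = np.clip(i0, 0, sensor.n_samples - 2)
    elem = np.broadcast_to(np.arange(n), delays.shape)
    lo = data.values[elem, i0c]
    hi = data.values[elem, i0c + 1]
    contrib = np.where(valid, lo * (1 - frac) + hi * frac, 0.0)
    return ReconImage(signed=contrib.sum(axis=-1), spacing=spacing)
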