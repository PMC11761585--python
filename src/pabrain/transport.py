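"""Steady-state Monte Carlo photon transport on the voxel phantom.

Fluence is estimated with the track-length estimator and normalised
per launched photon and per mm^2 (sum of weight x path / voxel volume
/ photon count), so the absorbed energy density A = mu_a * F inherits
the same per-photon arbitrary-unit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mc_kernel import transport_kernel
from .geometry import GridGeometry
from .phantom import LabelVolume
from .sources import SourceSpec, sample_launches

__all__ = [
    "McConfig",
    "FluenceVolume",
    "AbsorptionVolume",
    "run_mc",
    "run_mc_launches",
    "absorption_from_fluence",
    "mc_std_error",
]


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo run settings.

    weight_threshold triggers Russian roulette; surviving packets are
    boosted by 1/roulette_survival so the estimator stays unbiased.
    mismatch toggles Snell/Fresnel physics at refractive-index steps
    (including the external boundary, ambient n = 1).
    """

    photon_count: int = 1_000_000
    seed: int = 0
    weight_threshold: float = 1e-4
    roulette_survival: float = 0.1
    mismatch: bool = True

    def __post_init__(self) -> None:
        if self.photon_count < 1:
            raise ValueError("photon_count must be >= 1")
        if not 0.0 < self.weight_threshold < 1.0:
            raise ValueError("weight_threshold must lie in (0, 1)")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must lie in (0, 1)")


@dataclass(frozen=True)
class FluenceVolume:
    """Per-voxel fluence, units mm^-2 per launched photon."""

    geometry: GridGeometry
    values: np.ndarray  # float64, shape = geometry.shape
    launched_weight: float = 1.0
    absorbed_weight: float = 0.0
    escaped_weight: float = 0.0

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.geometry.shape:
            raise ValueError("fluence shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError("non-finite fluence accumulation")


@dataclass(frozen=True)
class AbsorptionVolume:
    """Per-voxel absorbed energy density A = mu_a * F (same a.u. as F)."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.geometry.shape:
            raise ValueError("absorption shape does not match geometry")


def run_mc_launches(
    phantom: LabelVolume,
    positions: np.ndarray,
    directions: np.ndarray,
    weights: np.ndarray,
    config: McConfig,
) -> FluenceVolume:
    """Transport an explicit batch of photon launches through the phantom.

    Lower-level entry point used by :func:`run_mc` and by validation
    studies that need interior or full-sphere sources.
    """
    mua, mus, g, n = phantom.optical_arrays()
    raw, absorbed, escaped = transport_kernel(
        phantom.labels,
        mua,
        mus,
        g,
        n,
        np.ascontiguousarray(positions, dtype=np.float64),
        np.ascontiguousarray(directions, dtype=np.float64),
        np.ascontiguousarray(weights, dtype=np.float64),
        config.seed,
        config.weight_threshold,
        config.roulette_survival,
        config.mismatch,
        phantom.geometry.spacing,
    )
    n_photons = positions.shape[0]
    fluence = raw / (phantom.geometry.voxel_volume * n_photons)
    return FluenceVolume(
        geometry=phantom.geometry,
        values=fluence,
        launched_weight=float(np.sum(weights)),
        absorbed_weight=float(absorbed),
        escaped_weight=float(escaped),
    )


def run_mc(phantom: LabelVolume, spec: SourceSpec, config: McConfig) -> FluenceVolume:
    """Run the Monte Carlo simulation for one source type.

    Launch states are drawn from the source's distribution with a
    generator seeded from ``config.seed``; the same seed and
    configuration reproduce a bit-identical fluence volume.
    """
    rng = np.random.default_rng(config.seed)
    pos, dirs, wts = sample_launches(spec, config.photon_count, rng)
    return run_mc_launches(phantom, pos, dirs, wts, config)


def absorption_from_fluence(fluence: FluenceVolume, phantom: LabelVolume) -> AbsorptionVolume:
    """A[v] = mu_a(label[v]) * F[v] for every voxel."""
    if fluence.geometry != phantom.geometry:
        raise ValueError("fluence and phantom geometries differ")
    return AbsorptionVolume(
        geometry=fluence.geometry,
        values=phantom.mu_a_volume() * fluence.values,
    )


def mc_std_error(runs: list[FluenceVolume]) -> np.ndarray:
    """Unbiased per-voxel standard error of the mean over repeated runs."""
    if len(runs) < 2:
        raise ValueError("need at least two runs to estimate a standard error")
    geom = runs[0].geometry
    if any(r.geometry != geom for r in runs[1:]):
        raise ValueError("runs have mismatching geometries")
    stack = np.stack([r.values for r in runs])
    return stack.std(axis=0, ddof=1) / np.sqrt(len(runs))
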