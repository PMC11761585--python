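"""Orchestration of the 16-source x {skull on, off} sweep.

For every source and skull mode the full chain runs: phantom -> Monte
Carlo -> absorption -> x-z slice -> k-space propagation -> bandwidth
filter -> delay-and-sum with the matching delay model.  Profiles along
the Z direction (x = 7 mm) and the X direction (z = 11 / 12 / 13 mm)
are extracted for three stages — the initial PA signal (the absorption
slice), the reconstruction without the skull and the reconstruction
with the skull — and the sources are ranked by amplitude at each
analysis position.

Physical positions 7 / 11 / 12 / 13 mm map to grid indices
70 / 110 / 120 / 130 under the floor(p / spacing) convention.
Per-source random substreams are derived by hashing the master seed
with the source name, so sweep order never changes results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .acoustics import (
    Medium2D,
    SensorArraySpec,
    apply_bandwidth,
    simulate_propagation,
    slice_initial_pressure,
)
from .beamform import DelayModel, ReconImage, das_reconstruct
from .phantom import LabelVolume, build_phantom
from .sources import SOURCE_KINDS, source_spec
from .transport import McConfig, absorption_from_fluence, run_mc

__all__ = [
    "STAGES",
    "RunConfig",
    "ProfileSet",
    "SourceRanking",
    "ExperimentBundle",
    "source_seed",
    "run_experiment",
    "rank_sources",
    "render_report",
]

log = logging.getLogger("pabrain")

#: Analysis stages in reporting order.
STAGES = ("initial", "recon_homo", "recon_hetero")

_STAGE_SKULL = {"recon_homo": "homogeneous", "recon_hetero": "heterogeneous"}
_STAGE_DELAY = {"recon_homo": "homogeneous", "recon_hetero": "layered"}


@dataclass(frozen=True)
class RunConfig:
    """Full sweep configuration."""

    sources: tuple[str, ...] = SOURCE_KINDS
    skull_modes: tuple[str, ...] = ("homogeneous", "heterogeneous")
    photon_count: int = 1_000_000
    master_seed: int = 1
    profile_x_mm: float = 7.0
    profile_z_mm: tuple[float, ...] = (11.0, 12.0, 13.0)
    mismatch: bool = True
    pml_size: int = 10

    def __post_init__(self) -> None:
        unknown = [s for s in self.sources if s not in SOURCE_KINDS]
        if unknown:
            raise ValueError(f"unknown source kinds: {unknown}")
        bad = [m for m in self.skull_modes if m not in ("homogeneous", "heterogeneous")]
        if bad:
            raise ValueError(f"unknown skull modes: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("sources", "skull_modes", "profile_z_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "sources": list(self.sources),
            "skull_modes": list(self.skull_modes),
            "photon_count": self.photon_count,
            "master_seed": self.master_seed,
            "profile_x_mm": self.profile_x_mm,
            "profile_z_mm": list(self.profile_z_mm),
            "mismatch": self.mismatch,
            "pml_size": self.pml_size,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class ProfileSet:
    """Per (source, stage) profiles: 'z' -> 140 values along Z at x = 7 mm,
    'x' -> {z_mm: 140 values along X}."""

    profiles: dict[tuple[str, str], dict] = field(default_factory=dict)
    sources: tuple[str, ...] = ()

    def z_profile(self, source: str, stage: str) -> np.ndarray:
        return self.profiles[(source, stage)]["z"]

    def x_profile(self, source: str, stage: str, z_mm: float) -> np.ndarray:
        return self.profiles[(source, stage)]["x"][z_mm]


@dataclass(frozen=True)
class SourceRanking:
    """Sources ordered by PA amplitude at one position and stage."""

    position: tuple[float, float]  # (x, z) mm
    stage: str
    ordered: tuple[tuple[str, float], ...]  # descending by value

    @property
    def top_maxima(self) -> tuple[tuple[str, float], ...]:
        return self.ordered[:3]

    @property
    def top_minima(self) -> tuple[tuple[str, float], ...]:
        """The three smallest, listed smallest first."""
        return tuple(reversed(self.ordered[-3:]))


@dataclass
class ExperimentBundle:
    """Everything the sweep produced."""

    config: RunConfig
    phantom: LabelVolume
    profiles: ProfileSet
    images: dict[tuple[str, str], ReconImage]
    initial_slices: dict[str, np.ndarray]
    rankings: dict[tuple[float, str], SourceRanking]
    seeds: dict[str, int]
    failures: dict[tuple[str, str], str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def source_seed(master_seed: int, source: str, tag: str = "") -> int:
    """Deterministic per-source substream seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{source}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _extract_profiles(field2d: np.ndarray, config: RunConfig) -> dict:
    ix = int(np.floor(config.profile_x_mm / 0.1))
    out = {"z": field2d[ix, :].copy(), "x": {}}
    for z_mm in config.profile_z_mm:
        iz = int(np.floor(z_mm / 0.1))
        out["x"][z_mm] = field2d[:, iz].copy()
    return out


def run_experiment(config: RunConfig, phantom: LabelVolume | None = None) -> ExperimentBundle:
    """Run the sweep and collect profiles, images and rankings.

    A failing (source, mode) cell is logged and skipped; the sweep
    continues.  The same master seed reproduces the bundle exactly.
    """
    phantom = phantom if phantom is not None else build_phantom()
    sensor = SensorArraySpec()
    media = {
        mode: Medium2D.for_phantom(skull_mode=mode) for mode in config.skull_modes
    }
    profiles = ProfileSet(sources=tuple(config.sources))
    images: dict[tuple[str, str], ReconImage] = {}
    slices: dict[str, np.ndarray] = {}
    seeds: dict[str, int] = {}
    failures: dict[tuple[str, str], str] = {}
    timings: dict[str, float] = {}

    for kind in config.sources:
        seed = source_seed(config.master_seed, kind)
        seeds[kind] = seed
        t0 = time.perf_counter()
        try:
            mc = McConfig(
                photon_count=config.photon_count, seed=seed, mismatch=config.mismatch
            )
            fluence = run_mc(phantom, source_spec(kind), mc)
            absorption = absorption_from_fluence(fluence, phantom)
            p0 = slice_initial_pressure(absorption)
        except Exception as exc:  # noqa: BLE001 - sweep must survive a bad cell
            log.error("optical stage failed for %s: %s", kind, exc)
            for mode in config.skull_modes:
                failures[(kind, mode)] = f"optical: {exc}"
            continue
        slices[kind] = p0.values
        profiles.profiles[(kind, "initial")] = _extract_profiles(p0.values, config)
        timings[f"{kind}:optical"] = time.perf_counter() - t0

        for mode in config.skull_modes:
            stage = "recon_homo" if mode == "homogeneous" else "recon_hetero"
            t1 = time.perf_counter()
            try:
                raw = simulate_propagation(
                    p0, media[mode], sensor, pml_size=config.pml_size
                )
                filtered = apply_bandwidth(raw)
                model = DelayModel(mode=_STAGE_DELAY[stage])
                image = das_reconstruct(filtered, model)
            except Exception as exc:  # noqa: BLE001
                log.error("acoustic stage failed for %s/%s: %s", kind, mode, exc)
                failures[(kind, mode)] = f"acoustic: {exc}"
                continue
            images[(kind, stage)] = image
            profiles.profiles[(kind, stage)] = _extract_profiles(image.amplitude, config)
            timings[f"{kind}:{stage}"] = time.perf_counter() - t1

    rankings: dict[tuple[float, str], SourceRanking] = {}
    for stage in STAGES:
        if stage != "initial" and _STAGE_SKULL[stage] not in config.skull_modes:
            continue
        for z_mm in config.profile_z_mm:
            have = [k for k in config.sources if (k, stage) in profiles.profiles]
            if len(have) == len(config.sources) and have:
                rankings[(z_mm, stage)] = rank_sources(
                    profiles, (config.profile_x_mm, z_mm), stage
                )
    return ExperimentBundle(
        config=config,
        phantom=phantom,
        profiles=profiles,
        images=images,
        initial_slices=slices,
        rankings=rankings,
        seeds=seeds,
        failures=failures,
        timings=timings,
    )


def rank_sources(
    profiles: ProfileSet, position: tuple[float, float], stage: str
) -> SourceRanking:
    """Order the sources by amplitude at (x, z) mm for one stage.

    Ties break by the canonical source listing order (stable sort on
    the negated value).
    """
    x_mm, z_mm = position
    ix = int(np.floor(x_mm / 0.1))
    entries = []
    for kind in profiles.sources:
        if (kind, stage) not in profiles.profiles:
            raise KeyError(f"missing source {kind!r} for stage {stage!r}")
        prof = profiles.profiles[(kind, stage)]
        if z_mm in prof["x"]:
            value = float(prof["x"][z_mm][ix])
        else:
            value = float(prof["z"][int(np.floor(z_mm / 0.1))])
        entries.append((kind, value))
    order = sorted(range(len(entries)), key=lambda i: (-entries[i][1], i))
    return SourceRanking(
        position=position, stage=stage, ordered=tuple(entries[i] for i in order)
    )


def render_report(bundle: ExperimentBundle, outdir, figures: bool = True) -> dict:
    """Write ranking tables (CSV), profile figures and a provenance block.

    Returns the written paths.  Raises if the bundle holds no rankings.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not bundle.rankings:
        raise ValueError("empty bundle: no rankings to report")
    paths: dict[str, str] = {}

    for stage in STAGES:
        rows = []
        for z_mm in bundle.config.profile_z_mm:
            key = (z_mm, stage)
            if key not in bundle.rankings:
                continue
            r = bundle.rankings[key]
            row: dict = {"z_mm": z_mm, "x_mm": bundle.config.profile_x_mm}
            for i, (src, val) in enumerate(r.top_maxima, start=1):
                row[f"max{i}_source"] = src
                row[f"max{i}_value"] = val
            for i, (src, val) in enumerate(r.top_minima, start=1):
                row[f"min{i}_source"] = src
                row[f"min{i}_value"] = val
            rows.append(row)
        if rows:
            path = out / f"ranking_{stage}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            paths[f"ranking_{stage}"] = str(path)

    full = []
    for (z_mm, stage), r in sorted(bundle.rankings.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        for rank, (src, val) in enumerate(r.ordered, start=1):
            full.append(
                {"stage": stage, "z_mm": z_mm, "rank": rank, "source": src, "value": val}
            )
    if full:
        path = out / "ranking_full.csv"
        pd.DataFrame(full).to_csv(path, index=False)
        paths["ranking_full"] = str(path)

    if figures:
        paths.update(_render_figures(bundle, out))

    prov = {
        "seeds": bundle.seeds,
        "photon_count": bundle.config.photon_count,
        "master_seed": bundle.config.master_seed,
        "sources": list(bundle.config.sources),
        "failures": {f"{k}/{m}": msg for (k, m), msg in bundle.failures.items()},
        "timings_s": {k: round(v, 3) for k, v in bundle.timings.items()},
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "sources": list(bundle.config.sources),
                    "photon_count": bundle.config.photon_count,
                    "master_seed": bundle.config.master_seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2))
    paths["provenance"] = str(prov_path)
    return paths


def _render_figures(bundle: ExperimentBundle, out) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    zc = (np.arange(140) + 0.5) * 0.1
    stages_present = [
        s
        for s in STAGES
        if any((k, s) in bundle.profiles.profiles for k in bundle.profiles.sources)
    ]
    fig, axes = plt.subplots(1, len(stages_present), figsize=(5 * len(stages_present), 4))
    axes = np.atleast_1d(axes)
    for ax, stage in zip(axes, stages_present):
        for kind in bundle.profiles.sources:
            if (kind, stage) in bundle.profiles.profiles:
                ax.plot(zc, bundle.profiles.z_profile(kind, stage), lw=0.8, label=kind)
        ax.set_xlabel("z (mm)")
        ax.set_ylabel("PA signal (a.u.)")
        ax.set_title(stage)
    axes[-1].legend(fontsize=5, ncol=2)
    fig.tight_layout()
    p = out / "profiles_z.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["profiles_z"] = str(p)
    return paths
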