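"""Serialization of the pipeline's data products.

HDF5 is the primary container (grids as datasets, geometry and
property tables as attributes); label and scalar volumes can also be
exported to NIfTI for viewing and reconstructed images to 32-bit TIFF.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .acoustics import SensorArraySpec, SensorData
from .beamform import ReconImage
from .geometry import GridGeometry
from .phantom import LabelVolume, TissueProperties
from .transport import AbsorptionVolume, FluenceVolume

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_volumes",
    "save_sensor_data",
    "load_sensor_data",
    "save_recon",
    "volume_to_nifti",
    "recon_to_tiff",
]


def _write_geometry(group, geometry: GridGeometry) -> None:
    group.attrs["shape"] = geometry.shape
    group.attrs["spacing_mm"] = geometry.spacing


def _read_geometry(group) -> GridGeometry:
    return GridGeometry(tuple(int(n) for n in group.attrs["shape"]), float(group.attrs["spacing_mm"]))


def save_phantom(path, phantom: LabelVolume) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("labels", data=phantom.labels, compression="gzip")
        _write_geometry(ds, phantom.geometry)
        ds.attrs["tissues"] = json.dumps(list(phantom.tissues))
        ds.attrs["properties"] = json.dumps(
            {t: vars(p) for t, p in phantom.table.items()}
        )


def load_phantom(path) -> LabelVolume:
    with h5py.File(path, "r") as fh:
        ds = fh["labels"]
        geometry = _read_geometry(ds)
        tissues = tuple(json.loads(ds.attrs["tissues"]))
        table = {
            t: TissueProperties(**p) for t, p in json.loads(ds.attrs["properties"]).items()
        }
        return LabelVolume(geometry, ds[...].astype(np.uint8), tissues, table)


def save_volumes(
    path, fluence: FluenceVolume | None = None, absorption: AbsorptionVolume | None = None
) -> None:
    with h5py.File(path, "w") as fh:
        if fluence is not None:
            ds = fh.create_dataset("fluence", data=fluence.values, compression="gzip")
            _write_geometry(ds, fluence.geometry)
            ds.attrs["absorbed_weight"] = fluence.absorbed_weight
            ds.attrs["escaped_weight"] = fluence.escaped_weight
        if absorption is not None:
            ds = fh.create_dataset("absorption", data=absorption.values, compression="gzip")
            _write_geometry(ds, absorption.geometry)


def save_sensor_data(path, raw: SensorData | None = None, filtered: SensorData | None = None) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("sensor")
        for name, sd in (("raw", raw), ("filtered", filtered)):
            if sd is None:
                continue
            ds = grp.create_dataset(name, data=sd.values, compression="gzip")
            ds.attrs["dt_s"] = sd.sensor.dt
            ds.attrs["n_samples"] = sd.sensor.n_samples
            ds.attrs["center_frequency_hz"] = sd.sensor.center_frequency
            ds.attrs["fractional_bandwidth"] = sd.sensor.fractional_bandwidth


def load_sensor_data(path, name: str = "raw") -> SensorData:
    with h5py.File(path, "r") as fh:
        ds = fh["sensor"][name]
        values = ds[...]
        spec = SensorArraySpec(
            n_elements=values.shape[0],
            center_frequency=float(ds.attrs["center_frequency_hz"]),
            fractional_bandwidth=float(ds.attrs["fractional_bandwidth"]),
            dt=float(ds.attrs["dt_s"]),
            n_samples=int(ds.attrs["n_samples"]),
        )
        return SensorData(values=values, sensor=spec)


def save_recon(path, image: ReconImage) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("signed", data=image.signed, compression="gzip")
        ds.attrs["spacing_mm"] = image.spacing
        fh.create_dataset("amplitude", data=image.amplitude, compression="gzip")


def volume_to_nifti(path, values: np.ndarray, spacing_mm: float = 0.1) -> None:
    """Export a volume (or 2D map) to NIfTI with the voxel size in mm."""
    import nibabel as nib

    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))


def recon_to_tiff(path, image: ReconImage) -> None:
    import tifffile

    tifffile.imwrite(str(path), image.amplitude.astype(np.float32))
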