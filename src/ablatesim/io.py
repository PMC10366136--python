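"""Result export: NIfTI volumes, HDF5 result bundles, CSV metrics."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .metrics import LesionMetrics
from .scheduler import SimulationResult


def save_nifti(path, volume: np.ndarray, voxel_size: float) -> None:
    """Write a 3D array as NIfTI with isotropic voxel-size metadata in mm."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])


def save_result(path, result: SimulationResult) -> None:
    """Bundle the final fields, masks and metadata of a run into HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["voxel_size"] = result.grid.voxel_size
        f.attrs["surface_z"] = result.grid.surface_z
        f.attrs["time"] = result.state.time
        f.attrs["metadata"] = json.dumps(result.metadata)
        g = f.create_group("fields")
        g.create_dataset("H", data=result.state.H, compression="gzip")
        g.create_dataset("T", data=result.state.T, compression="gzip")
        g.create_dataset("S", data=result.last_absorption, compression="gzip")
        g.create_dataset("Omega", data=result.state.Omega, compression="gzip")
        m = f.create_group("masks")
        m.create_dataset("removed", data=result.removed, compression="gzip")
        m.create_dataset("coagulated", data=result.coagulated,
                         compression="gzip")
        m.create_dataset("material_id", data=result.grid.material_id,
                         compression="gzip")
        series = result.series.drop(columns=["phase"], errors="ignore")
        f.create_dataset("series", data=series.to_numpy(dtype=np.float64))
        f["series"].attrs["columns"] = list(series.columns)


def metrics_to_frame(name: str, power: float, speed: float,
                     lm: LesionMetrics) -> pd.DataFrame:
    """One CSV row per run: condition plus the six lesion metrics."""
    return pd.DataFrame([{"condition": name, "power_w": power,
                          "speed_mm_s": speed,
                          **dataclasses.asdict(lm)}])


def write_metrics_csv(path, frame: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
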