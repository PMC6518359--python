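"""Volume, sinogram and config I/O.

Volumes travel as NIfTI with voxel sizes (mm) in the header;
sinograms as raw little-endian binary plus a YAML sidecar recording
shape, dtype and scan geometry; configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import ActivityMap, GridSpec, MuMap
from .projection import ScanGeometry, Sinogram


def save_volume(vol: ActivityMap | MuMap | np.ndarray, grid: GridSpec, path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz) with mm voxel sizes."""
    values = vol.values if hasattr(vol, "values") else np.asarray(vol)
    affine = np.diag([grid.dx, grid.dy, grid.dz, 1.0])
    nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, GridSpec]:
    """Read a NIfTI volume; grid voxel sizes come from the header."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    grid = GridSpec(*data.shape, dx, dy, dz)
    return data, grid


def save_sinogram(sino: Sinogram, path) -> None:
    """Raw float64 binary plus a ``<path>.yaml`` geometry sidecar."""
    path = Path(path)
    sino.data.astype("<f8").tofile(path)
    sidecar = {
        "shape": list(sino.data.shape),
        "dtype": "<f8",
        "n_angles": sino.geometry.n_angles,
        "n_bins": sino.geometry.n_bins,
        "bin_width_mm": sino.geometry.bin_width_mm,
        "slice_index": sino.slice_index,
        # numpy scalars are not YAML-serializable; store plain Python
        "meta": {
            k: (v.item() if hasattr(v, "item") else v) for k, v in sino.meta.items()
        },
    }
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".yaml")) as fh:
        side = yaml.safe_load(fh)
    data = np.fromfile(path, dtype=side["dtype"]).reshape(side["shape"])
    geom = ScanGeometry(side["n_angles"], side["n_bins"], side["bin_width_mm"])
    return Sinogram(data, geom, side.get("slice_index"), side.get("meta") or {})


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg
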