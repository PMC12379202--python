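"""Lifetime image container, NIfTI round-trip, MIPs and slice views.

Maps are stored raw — no smoothing, filtering or resampling is ever applied.
Masked voxels carry NaN, which no physical lifetime or branching fraction
can take.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .histo import VoxelGrid

__all__ = ["LifetimeImage", "write_image", "read_image", "mip", "slice_views"]

_MAP_NAMES = ("tau3", "tau3_relsd", "br3", "qc")
_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class LifetimeImage:
    """Voxel maps of the oPs lifetime fit.

    ``tau3_map`` is the per-voxel posterior mean (ns), ``tau3_relsd_map`` the
    posterior SD divided by the mean, ``br3_map`` the posterior-mean oPs
    branching fraction.  ``qc_mask`` marks voxels with a usable fit; all
    other voxels are NaN in the float maps.
    """

    grid: VoxelGrid
    tau3_map: np.ndarray
    tau3_relsd_map: np.ndarray
    br3_map: np.ndarray
    qc_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        dims = tuple(self.grid.dims)
        for name in ("tau3_map", "tau3_relsd_map", "br3_map", "qc_mask"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != dims:
                raise ValueError(f"{name} shape {arr.shape} != grid dims {dims}")
        if np.any(self.tau3_relsd_map[np.isfinite(self.tau3_relsd_map)] < 0):
            raise ValueError("relative SD map must be non-negative")


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size
    # translation places voxel (0,0,0) at the centre of the first voxel
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.voxel_size)
    return aff


def write_image(image: LifetimeImage, path) -> None:
    """Write the maps as a 4D NIfTI-1 volume plus a JSON provenance sidecar.

    The four volumes along the last axis are tau3, relative SD, BR3 and the
    QC mask (0/1).  ``path`` is a basename; ``.nii`` and ``.json`` are added.
    """
    base = Path(path)
    stack = np.stack(
        [np.asarray(image.tau3_map, float),
         np.asarray(image.tau3_relsd_map, float),
         np.asarray(image.br3_map, float),
         image.qc_mask.astype(float)], axis=-1)
    nii = nib.Nifti1Image(stack, _affine(image.grid))
    nib.save(nii, str(base.with_suffix(".nii")))
    meta = {
        "maps": list(_MAP_NAMES),
        "grid": {"origin": list(image.grid.origin),
                 "voxel_size": list(image.grid.voxel_size),
                 "dims": list(image.grid.dims)},
        "provenance": image.provenance,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_image(path) -> LifetimeImage:
    """Inverse of :func:`write_image`; validates affine against the sidecar."""
    base = Path(path)
    nii = nib.load(str(base.with_suffix(".nii")))
    meta = json.loads(base.with_suffix(".json").read_text())
    grid = VoxelGrid(tuple(meta["grid"]["origin"]),
                     tuple(meta["grid"]["voxel_size"]),
                     tuple(meta["grid"]["dims"]))
    if not np.allclose(nii.affine, _affine(grid)):
        raise ValueError("NIfTI affine does not match the sidecar grid")
    data = np.asarray(nii.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[:3] != tuple(grid.dims) or data.shape[3] != 4:
        raise ValueError("image dimensions do not match the sidecar grid")
    return LifetimeImage(
        grid=grid,
        tau3_map=data[..., 0],
        tau3_relsd_map=data[..., 1],
        br3_map=data[..., 2],
        qc_mask=data[..., 3] > 0.5,
        provenance=meta.get("provenance", {}),
    )


def mip(volume, axis="z"):
    """Maximum intensity projection over unmasked (non-NaN) voxels.

    Rays with no unmasked voxel project to NaN.
    """
    a = _AXES[axis] if isinstance(axis, str) else int(axis)
    v = np.asarray(volume, float)
    all_nan = np.all(np.isnan(v), axis=a)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmax(v, axis=a)
    out[all_nan] = np.nan
    return out


def slice_views(image: LifetimeImage, plane: str, index: int,
                which: str = "tau3"):
    """Extract a 2D slice from one of the maps.

    ``plane='z-y'`` fixes the x index and returns an array of shape
    ``(dims_z, dims_y)``; ``plane='x-y'`` fixes the z index and returns
    ``(dims_x, dims_y)``.
    """
    vol = {"tau3": image.tau3_map, "tau3_relsd": image.tau3_relsd_map,
           "br3": image.br3_map}[which]
    dims = image.grid.dims
    if plane == "z-y":
        if not 0 <= index < dims[0]:
            raise ValueError("x index out of range")
        return vol[index, :, :].T
    if plane == "x-y":
        if not 0 <= index < dims[2]:
            raise ValueError("z index out of range")
        return vol[:, :, index]
    raise ValueError("plane must be 'z-y' or 'x-y'")
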