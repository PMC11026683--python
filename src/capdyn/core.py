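"""Core data structures shared across the pipeline.

A scan is held as a dense ``voxels x frames`` matrix tied to the voxel
coordinates of a binary brain mask, so that every stage (conditioning,
thresholding, clustering, mapping back to volumes) operates on the same
2-D representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelTimeSeries",
    "load_mask",
    "load_scan",
    "save_scan",
    "map_to_volume",
    "read_manifest",
]


@dataclass
class VoxelTimeSeries:
    """One subject-scan as an ``m x T`` matrix of voxel time traces.

    Parameters
    ----------
    data
        Array of shape ``(m, T)``; BOLD signal in arbitrary units before
        conditioning, z-units afterwards.
    voxel_coords
        Integer array of shape ``(m, 3)`` giving the (x, y, z) grid
        coordinate of each row within the mask volume.
    mask_shape
        Shape of the 3-D mask volume the coordinates refer to.
    tr_seconds
        Repetition time in seconds.
    subject_id, genotype, age
        Cohort metadata carried along for provenance.
    """

    data: np.ndarray
    voxel_coords: np.ndarray
    mask_shape: tuple[int, int, int]
    tr_seconds: float = 0.6
    subject_id: str = ""
    genotype: str = ""
    age: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x frames)")
        if self.voxel_coords.shape != (self.data.shape[0], 3):
            raise ValueError(
                f"voxel_coords shape {self.voxel_coords.shape} does not match "
                f"{self.data.shape[0]} voxels"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "VoxelTimeSeries":
        """Return a copy carrying new trace data but identical geometry."""
        return replace(self, data=np.asarray(data, dtype=float))

    def subset_voxels(self, keep: np.ndarray) -> "VoxelTimeSeries":
        """Return a copy restricted to the rows selected by ``keep``."""
        keep = np.asarray(keep)
        return replace(
            self, data=self.data[keep], voxel_coords=self.voxel_coords[keep]
        )


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary 3-D mask; return (boolean volume, voxel coords m x 3)."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj) > 0
    coords = np.column_stack(np.nonzero(vol))
    return vol, coords


def load_scan(path, mask_coords: np.ndarray, mask_shape, **meta) -> VoxelTimeSeries:
    """Load a 4-D NIfTI scan and extract the masked voxel x frame matrix."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"{path}: expected 4-D image, got {vol.ndim}-D")
    x, y, z = mask_coords.T
    data = vol[x, y, z, :]
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.6
    return VoxelTimeSeries(
        data=data,
        voxel_coords=mask_coords,
        mask_shape=tuple(mask_shape),
        tr_seconds=tr or 0.6,
        **meta,
    )


def save_scan(series: VoxelTimeSeries, path) -> None:
    """Write a series back to a 4-D NIfTI volume (zeros outside the mask)."""
    vol = np.zeros(series.mask_shape + (series.n_frames,), dtype=np.float32)
    x, y, z = series.voxel_coords.T
    vol[x, y, z, :] = series.data
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr_seconds))
    nib.save(img, str(path))


def map_to_volume(values: np.ndarray, coords: np.ndarray, shape, fill=0.0) -> np.ndarray:
    """Scatter per-voxel values back into a 3-D volume."""
    vol = np.full(tuple(shape), fill, dtype=float)
    x, y, z = np.asarray(coords).T
    vol[x, y, z] = values
    return vol


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV (subject_id, genotype, age, path)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "genotype": str, "age": str})
    required = {"subject_id", "genotype", "age", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
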