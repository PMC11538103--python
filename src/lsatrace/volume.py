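"""3D scalar image grid with physical voxel spacing.

``Volume`` is the universal raster carrier for the whole pipeline: a 3D
array plus per-axis spacing in millimetres and an origin offset.  Physical
coordinates follow the axis-aligned convention

    world_mm = origin + index * spacing

with 0-based voxel indices; direction cosines beyond axis alignment are a
documented non-goal.  NIfTI round-trips go through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume", "write_mask"]


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities; stored as float64 unless a mask.
    spacing : tuple of 3 floats
        Voxel size in mm per axis; all strictly positive.
    origin : tuple of 3 floats
        Physical position (mm) of voxel (0, 0, 0).
    intensity_scale : {"raw", "standardized"}
        Whether intensities live on the standardized 0-255 scale on which
        the pre-screen thresholds (80, 120) are defined.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_scale: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")
        if self.intensity_scale not in ("raw", "standardized"):
            raise ValueError(f"unknown intensity_scale {self.intensity_scale!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **kw) -> "Volume":
        """A copy carrying new voxel data but the same geometry."""
        return replace(self, data=data, **kw)

    def index_to_mm(self, idx) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_index(self, pos) -> np.ndarray:
        """Fractional voxel indices of physical positions (..., 3)."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_mm(self, pos) -> np.ndarray:
        """Whether physical points fall inside the grid extent."""
        idx = self.mm_to_index(pos)
        shape = np.asarray(self.shape)
        return np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=-1)


def _affine(v: Volume) -> np.ndarray:
    aff = np.diag(list(v.spacing) + [1.0])
    aff[:3, 3] = v.origin
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI-1/2 volume; spacing comes from the header zooms."""
    img = nib.load(str(path))
    hdr = img.header
    zooms = hdr.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"NIfTI header of {path} has invalid pixdim (zooms={zooms})")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, header dim gives {data.ndim}D")
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return Volume(data=np.asarray(data, dtype=np.float64),
                  spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(v: Volume, path) -> None:
    """Write as NIfTI; round-trip preserves data bit-exactly and spacing to 1e-6 mm."""
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), _affine(v))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, like: Volume, path) -> None:
    """Write a binary mask as unsigned 8-bit NIfTI with values {0, 1} only."""
    m = (np.asarray(mask) != 0).astype(np.uint8)
    img = nib.Nifti1Image(m, _affine(like))
    img.header.set_zooms(like.spacing)
    nib.save(img, str(path))
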