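"""3D scalar volume container and image I/O.

Physical coordinates are LPS (the DICOM patient convention) in mm
throughout the package. NIfTI files, which are natively RAS, are converted
on read/write by SimpleITK, so a ``VolumeGrid`` is always LPS regardless of
the source format.

The voxel array is indexed ``(slice, row, column)`` = (k, j, i) as returned
by ``sitk.GetArrayFromImage``; the physical mapping is

    p = origin + D @ ((i * sx, j * sy, k * sz))

with ``D`` the 3x3 direction-cosine matrix and spacing ``(sx, sy, sz)``
ordered (column, row, slice) — i.e. the SimpleITK convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk


@dataclass
class VolumeGrid:
    """A 3D scalar image with its physical-space geometry.

    ``data`` is ``(n_slices, n_rows, n_cols)``; ``spacing``/``origin`` are
    in mm, ``direction`` is the row-major 3x3 direction-cosine matrix.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (sx, sy, sz)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive on all axes")
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.abs(np.abs(np.linalg.det(self.direction)) - 1.0) > 1e-6:
            raise ValueError("direction cosines must form an orthonormal matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (k, j, i)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map continuous ``(i, j, k)`` voxel indices to physical mm (LPS).

        ``indices`` is ``(..., 3)`` ordered (column, row, slice), matching
        the SimpleITK index convention (the reverse of numpy axis order).
        """
        idx = np.asarray(indices, dtype=float)
        scaled = idx * np.asarray(self.spacing)
        return scaled @ self.direction.T + np.asarray(self.origin)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_physical` (continuous indices)."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.origin)
        return (pts @ np.linalg.inv(self.direction).T) / np.asarray(self.spacing)

    # --- SimpleITK bridge -------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data)
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        img.SetDirection(tuple(self.direction.reshape(-1)))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeGrid":
        return cls(
            data=sitk.GetArrayFromImage(img),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )

    def write(self, path: str | Path) -> None:
        """Write to any format SimpleITK infers from the suffix (.nii.gz, .nrrd, ...)."""
        sitk.WriteImage(self.to_sitk(), str(path))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a DICOM series directory or a single image file (NIfTI etc.).

    A directory is treated as a DICOM series; anything else is handed to
    SimpleITK's format sniffing. Either way the result is in LPS mm.
    """
    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise FileNotFoundError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        img = sitk.ReadImage(str(path))
    return VolumeGrid.from_sitk(img)
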