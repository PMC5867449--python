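"""Label and scalar volumes on a common voxel lattice.

All anatomical inputs (lesion masks, ventricle/WM masks, cortical
parcellations) are carried as :class:`LabeledVolume`; derived continuous
fields (Laplace potential, streamline arc lengths, relative distance) as
:class:`ScalarField`. Everything for one subject must live on the same
grid — the analyses assume co-registered volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledVolume",
    "ScalarField",
    "FormatError",
    "GridMismatchError",
    "read_labeled_volume",
    "write_labeled_volume",
    "write_scalar_field",
]

#: tolerance for accepting "integer" data stored as floats
_INT_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an input volume violates the expected format."""


class GridMismatchError(ValueError):
    """Raised when volumes for one subject disagree on shape or voxel size."""


@dataclass
class LabeledVolume:
    """3D integer label grid with voxel geometry.

    Parameters
    ----------
    grid
        3D array of non-negative integer labels.
    voxel_size
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all strictly positive.
    affine
        4x4 voxel-to-world affine. Defaults to a diagonal affine built
        from ``voxel_size``.
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"expected a 3D grid, got {self.grid.ndim}D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            rounded = np.rint(self.grid)
            if not np.allclose(self.grid, rounded, atol=_INT_TOL, rtol=0):
                raise FormatError("volume contains non-integer label values")
            self.grid = rounded.astype(np.int32)
        if self.grid.min() < 0:
            raise FormatError("labels must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise FormatError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise FormatError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def labels(self) -> np.ndarray:
        """Sorted array of distinct labels present in the grid."""
        return np.unique(self.grid)

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label, or of all non-zero voxels."""
        if label is None:
            return self.grid != 0
        return self.grid == label

    def same_grid_as(self, other: "LabeledVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )


@dataclass
class ScalarField:
    """3D real-valued field defined on a domain mask; NaN elsewhere."""

    values: np.ndarray
    domain_mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
        if self.values.shape != self.domain_mask.shape:
            raise GridMismatchError("values and domain_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.domain_mask])):
            raise ValueError("non-finite values inside the domain mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def on_domain(self) -> np.ndarray:
        """Values at domain voxels, as a flat array."""
        return self.values[self.domain_mask]


def check_same_grid(*volumes: LabeledVolume) -> None:
    """Hard error if the volumes do not share shape and voxel size."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_grid_as(v):
            raise GridMismatchError(
                f"volumes not co-registered: {ref.shape}@{ref.voxel_size} vs "
                f"{v.shape}@{v.voxel_size}"
            )


def read_labeled_volume(path: str | Path) -> LabeledVolume:
    """Read a 3D NIfTI label volume.

    Rejects 4D inputs and float data that is not within 1e-6 of integers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return LabeledVolume(grid=data, voxel_size=tuple(float(z) for z in zooms),
                        affine=np.asarray(img.affine))


def write_labeled_volume(vol: LabeledVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI (int32, lossless round trip)."""
    img = nib.Nifti1Image(vol.grid.astype(np.int32), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def write_scalar_field(fld: ScalarField, path: str | Path,
                       affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag(list(fld.voxel_size) + [1.0])
    img = nib.Nifti1Image(fld.values.astype(np.float32), affine)
    img.header.set_zooms(fld.voxel_size)
    nib.save(img, str(path))
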