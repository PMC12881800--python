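"""Labeled 3-D volumes and NIfTI persistence.

A :class:`LabelVolume` is the package's in-memory form of a thoracic
segmentation: an integer voxel grid plus the voxel-to-world affine (mm)
and a table naming each label code. Volumes round-trip through NIfTI-1
via :func:`write_label_volume` / :func:`read_label_volume`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .labels import LABEL_NAMES


@dataclass
class LabelVolume:
    """Integer-labeled voxel grid in world (mm) coordinates.

    Parameters
    ----------
    voxels:
        3-D integer array of label codes; 0 is background.
    affine:
        4x4 voxel-index -> world-mm transform (0-based indices, NIfTI
        convention). Must be invertible.
    label_table:
        Mapping label code -> structure name for every nonzero code
        present in ``voxels``.
    """

    voxels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise TypeError(f"voxels must be integer-typed, got dtype {self.voxels.dtype}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        present = set(int(v) for v in np.unique(self.voxels)) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise ValueError(f"voxel codes {sorted(unknown)} missing from label_table")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def mask(self, label: int) -> np.ndarray:
        """Binary mask of one label code."""
        return self.voxels == int(label)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world-mm corners of the voxel grid."""
        shape = np.array(self.voxels.shape, dtype=float)
        corners = np.array(
            [[i, j, k] for i in (0.0, shape[0] - 1) for j in (0.0, shape[1] - 1) for k in (0.0, shape[2] - 1)]
        )
        world = apply_affine(self.affine, corners)
        return world.min(axis=0), world.max(axis=0)

    def labels_present(self) -> list[int]:
        return [int(v) for v in np.unique(self.voxels) if v != 0]


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map Nx3 points through a 4x4 homogeneous transform."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Inverse of :func:`apply_affine` (continuous voxel coordinates)."""
    inv = np.linalg.inv(affine)
    return apply_affine(inv, points)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Persist a label volume as NIfTI-1 (.nii or .nii.gz)."""
    data = np.asarray(volume.voxels, dtype=np.int16)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Load a NIfTI-1 label volume.

    The file must carry an integer datatype; float-valued segmentations
    are rejected rather than silently rounded. NIfTI stores no label
    names, so codes are named from the package's fixed table (unknown
    codes get ``label_<code>``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if not np.issubdtype(dtype, np.integer):
        raise TypeError(f"label volume must have integer dtype, file has {dtype}")
    voxels = np.asanyarray(img.dataobj).astype(np.int16)
    table = {
        code: LABEL_NAMES.get(code, f"label_{code}")
        for code in (int(v) for v in np.unique(voxels))
        if code != 0
    }
    return LabelVolume(voxels=voxels, affine=np.asarray(img.affine), label_table=table)
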