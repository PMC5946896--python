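"""Voxel grid geometry shared by all volumetric containers.

A :class:`VolumeGeometry` couples a 3-D voxel grid with the affine map
from voxel indices to world (MNI-style millimetre) coordinates, the way
a NIfTI header does.  The default constructor builds an axis-aligned
grid centred on the world origin, which is what the synthetic datasets
use; real data supply their own affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGeometry:
    """A 3-D voxel grid and its voxel -> world (mm) mapping.

    Parameters
    ----------
    shape : tuple of int
        Grid size ``(nx, ny, nz)`` in voxels; every dimension >= 1.
    affine : (4, 4) ndarray
        Invertible voxel-to-world affine in millimetres.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three dimensions >= 1, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(
        cls, shape: tuple[int, int, int] = (20, 20, 20), voxel_size_mm: float = 3.0
    ) -> "VolumeGeometry":
        """Axis-aligned grid with cubic voxels, world origin at the grid centre.

        The 3 mm default matches a typical functional acquisition resampled
        to an isotropic grid; the 20**3 default keeps whole-pipeline runs at
        desk scale.
        """
        if voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        shape = tuple(int(s) for s in shape)
        affine = np.eye(4)
        affine[:3, :3] *= voxel_size_mm
        affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
        return cls(shape=shape, affine=affine)

    @classmethod
    def mni152_3mm(cls) -> "VolumeGeometry":
        """The standard whole-brain 3 mm grid in MNI space: 61 x 73 x 61
        voxels spanning x in [-90, 90], y in [-126, 90], z in [-72, 108] mm.
        Use this full-size grid when working with standard-space
        coordinates (e.g. the built-in ROI centres)."""
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-90.0, -126.0, -72.0)
        return cls(shape=(61, 73, 61), affine=affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.c_[xyz, np.ones(len(xyz))]
        return (homog @ inv.T)[:, :3]

    def world_coordinates(self) -> np.ndarray:
        """World mm coordinates of every voxel centre, shape ``shape + (3,)``."""
        grid = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(grid).reshape(self.shape + (3,))

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        """Boolean mask of which integer voxel indices fall inside the grid."""
        ijk = np.atleast_2d(np.asarray(ijk))
        ok = np.ones(len(ijk), dtype=bool)
        for axis in range(3):
            ok &= (ijk[:, axis] >= 0) & (ijk[:, axis] < self.shape[axis])
        return ok
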