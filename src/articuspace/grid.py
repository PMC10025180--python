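"""Image-grid primitives shared by every pipeline stage.

All volumes in this package live on isotropic 3D grids. The third array
axis is the scan axis (the axis the slice stack is acquired along); the
distal bone of a joint sits at lower indices along that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Native voxel size of the second-generation-free clinical scan protocol, mm.
DEFAULT_VOXEL_SIZE_MM = 0.082

#: Number of slices in a standard acquisition stack.
DEFAULT_STACK_SLICES = 330


@dataclass(frozen=True)
class GridSpec:
    """Isotropic 3D sampling grid.

    Parameters
    ----------
    shape
        Voxels per axis ``(nx, ny, nz)``; ``nz`` is the scan axis.
    voxel_size
        Edge length of a voxel in mm (isotropic).
    """

    shape: tuple[int, int, int]
    voxel_size: float = DEFAULT_VOXEL_SIZE_MM

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("grid shape must have three axes")
        if any(int(n) < 4 for n in self.shape):
            raise ValueError("each grid dimension must be at least 4 voxels")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.voxel_size) ** 3

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical grid extent per axis in mm."""
        return tuple(n * self.voxel_size for n in self.shape)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) as an open meshgrid.

        Voxel ``(i, j, k)`` has its center at ``((i + 0.5) h, ...)`` so the
        solid modelled by a mask is the union of voxel cubes spanning
        ``[0, n*h]`` per axis.
        """
        axes = [
            (np.arange(n, dtype=np.float64) + 0.5) * self.voxel_size
            for n in self.shape
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


@dataclass
class VolumeImage:
    """A scalar 3D image on an isotropic grid."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")


@dataclass
class BonePairMask:
    """Labeled periosteal masks of an articulating bone pair.

    ``distal`` is the metacarpal-head side (lower indices along the scan
    axis by convention), ``proximal`` the phalangeal-base side. Masks are
    boolean, disjoint and each non-empty.
    """

    distal: np.ndarray
    proximal: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.distal = np.asarray(self.distal, dtype=bool)
        self.proximal = np.asarray(self.proximal, dtype=bool)
        for name, m in (("distal", self.distal), ("proximal", self.proximal)):
            if m.shape != self.grid.shape:
                raise ValueError(f"{name} mask shape does not match grid")
            if not m.any():
                raise ValueError(f"{name} mask is empty")
        if np.any(self.distal & self.proximal):
            raise ValueError("bone masks overlap")

    @property
    def union(self) -> np.ndarray:
        return self.distal | self.proximal

    def to_labels(self) -> np.ndarray:
        """Label volume: 0 background, 1 distal bone, 2 proximal bone."""
        out = np.zeros(self.grid.shape, dtype=np.uint8)
        out[self.distal] = 1
        out[self.proximal] = 2
        return out

    @classmethod
    def from_labels(cls, labels: np.ndarray, grid: GridSpec) -> "BonePairMask":
        labels = np.asarray(labels)
        return cls(distal=labels == 1, proximal=labels == 2, grid=grid)
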