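"""Volume I/O, configuration, and run provenance.

Supported volume formats: NIfTI (.nii / .nii.gz, via nibabel), MetaImage
(.mha / .mhd, via SimpleITK) and multi-page TIFF stacks (via tifffile,
with a JSON sidecar carrying the voxel size). The pipeline assumes
isotropic grids; anisotropic spacing is rejected on read. Axis order is
(x, y, z) with z the scan axis; NIfTI/MetaImage on-disk axis conventions
are mapped so that a write-read round trip is the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile
import yaml

from .grid import DEFAULT_STACK_SLICES, DEFAULT_VOXEL_SIZE_MM, GridSpec, VolumeImage

__all__ = ["read_volume", "write_volume", "read_labels", "write_labels", "PipelineConfig"]

_ISO_RTOL = 1e-6


def _check_isotropic(spacing) -> float:
    spacing = [float(s) for s in spacing]
    if max(spacing) - min(spacing) > _ISO_RTOL * max(spacing):
        raise ValueError(
            f"anisotropic voxels {spacing}: the pipeline assumes isotropic grids"
        )
    return spacing[0]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path: str | Path) -> VolumeImage:
    """Read a volume; voxel size is taken from the file header (NIfTI,
    MetaImage) or a JSON sidecar (TIFF stacks)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        # NIfTI-1 stores pixdim as float32; recover the intended voxel
        # size at float32's decimal precision so round trips are exact
        # for any size written by this package.
        zooms = [float(f"{z:.6g}") for z in img.header.get_zooms()[:3]]
        vox = _check_isotropic(zooms)
        values = np.asarray(img.dataobj)
    elif name.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        vox = _check_isotropic(img.GetSpacing())
        # SimpleITK arrays come back (z, y, x); restore (x, y, z).
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    elif name.endswith((".tif", ".tiff")):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"TIFF stack {path} lacks the voxel-size sidecar {sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
        if "voxel_size_mm" not in meta:
            raise ValueError(f"sidecar {sidecar.name} lacks 'voxel_size_mm'")
        vox = float(meta["voxel_size_mm"])
        # Pages are z slices: stored (z, y, x).
        values = tifffile.imread(str(path)).transpose(2, 1, 0)
    else:
        raise ValueError(f"unknown volume format: {path.name}")
    grid = GridSpec(shape=values.shape, voxel_size=vox)
    return VolumeImage(values=np.asarray(values, dtype=np.float64), grid=grid)


def write_volume(image: VolumeImage, path: str | Path) -> Path:
    """Write a volume, preserving the voxel size exactly in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    vox = image.grid.voxel_size
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag([vox, vox, vox, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(image.values), affine), str(path))
    elif name.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(np.asarray(image.values).transpose(2, 1, 0))
        img.SetSpacing((vox, vox, vox))
        sitk.WriteImage(img, str(path))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), np.asarray(image.values).transpose(2, 1, 0))
        _sidecar_path(path).write_text(json.dumps({"voxel_size_mm": vox}))
    else:
        raise ValueError(f"unknown volume format: {path.name}")
    return path


def read_labels(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an integer label volume (0 background, 1 distal, 2 proximal)."""
    vol = read_volume(path)
    return np.rint(vol.values).astype(np.uint8), vol.grid


def write_labels(labels: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    return write_volume(VolumeImage(values=labels.astype(np.float64), grid=grid), path)


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration of every stage."""

    voxel_size: float = DEFAULT_VOXEL_SIZE_MM
    stack_slices: int = DEFAULT_STACK_SLICES
    threshold: str = "otsu"  # "otsu" or "fixed:<t>"
    joint_axis: int = 2
    periosteal_radius_vox: float = 5.0
    bridging_radius_mm: float = 2.5
    robust_min: bool = False
    alpha: float = 0.05
    age_stratum_years: int = 5
    exact_test_n: int = 8
    seed: int = 0
    output_dir: str = "articuspace_out"

    def __post_init__(self) -> None:
        for name in ("voxel_size", "periosteal_radius_vox", "bridging_radius_mm", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.stack_slices < 4 or self.age_stratum_years < 1:
            raise ValueError("invalid config")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        """Short hash of the scientific parameters (the output location
        does not change what was computed)."""
        params = dataclasses.asdict(self)
        params.pop("output_dir")
        blob = yaml.safe_dump(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def threshold_value(self) -> str | float:
        if self.threshold.startswith("fixed:"):
            return float(self.threshold.split(":", 1)[1])
        return self.threshold
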