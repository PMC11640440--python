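"""NIfTI volume / mask I/O and voxel geometry.

CT volumes are held as float64 Hounsfield-unit grids together with their
4x4 voxel-index-to-world affine (millimetres).  Any intensity scaling
declared in the NIfTI header (scl_slope / scl_inter) is applied at read
time, so in-memory values are always HU.  Grids are never resampled: a
mask whose shape differs from its CT is a fatal error, because silent
interpolation would corrupt HU statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Mapping, Optional, Tuple

import nibabel as nib
import numpy as np

from .errors import GeometryError, GridMismatchError, InputError

NIFTI_EXTENSIONS = (".nii.gz", ".nii")

_DET_EPS = 1e-12


def strip_nifti_extension(name: str) -> str:
    """Return a file basename without its ``.nii`` / ``.nii.gz`` suffix."""
    for ext in NIFTI_EXTENSIONS:
        if name.endswith(ext):
            return name[: -len(ext)]
    return name


@dataclass
class CTVolume:
    """A 3-D CT grid in Hounsfield units with its world transform."""

    voxels: np.ndarray
    affine: np.ndarray
    patient_id: str = ""
    condition: str = "pre"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise InputError(
                f"CT volume must be a 3-D grid with positive dimensions, got shape {self.voxels.shape}"
            )
        if self.affine.shape != (4, 4):
            raise InputError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < _DET_EPS:
            raise GeometryError("CT affine has a singular linear part")
        if self.condition not in ("pre", "post"):
            raise InputError(f"condition must be 'pre' or 'post', got {self.condition!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self.affine)


@dataclass
class StructureMask:
    """Binary voxel mask for one named structure, on some CT grid."""

    voxels: np.ndarray
    structure_name: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != np.uint8:
            self.voxels = (self.voxels != 0).astype(np.uint8)
        if self.voxels.ndim != 3:
            raise InputError(
                f"mask {self.structure_name!r} must be 3-D, got shape {self.voxels.shape}"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class MaskSet:
    """Named binary masks sharing one grid shape."""

    masks: Dict[str, StructureMask] = field(default_factory=dict)
    source: str = "anatomical"

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GridMismatchError(f"masks in one set must share a grid, got shapes {shapes}")

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def __getitem__(self, name: str) -> StructureMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return sorted(self.masks)

    def items(self) -> Iterator[Tuple[str, StructureMask]]:
        return iter(sorted(self.masks.items()))

    def add(self, mask: StructureMask) -> None:
        if mask.structure_name in self.masks:
            raise InputError(f"duplicate structure name {mask.structure_name!r}")
        if self.masks:
            existing = next(iter(self.masks.values()))
            if mask.shape != existing.shape:
                raise GridMismatchError(
                    f"mask {mask.structure_name!r} shape {mask.shape} differs from set grid {existing.shape}"
                )
        self.masks[mask.structure_name] = mask


def read_ct(path: os.PathLike | str, patient_id: Optional[str] = None, condition: str = "pre") -> CTVolume:
    """Load a 3-D NIfTI CT series as Hounsfield units.

    Header intensity scaling is applied by the reader, and the affine follows
    the standard NIfTI precedence (sform when valid, else qform, else the
    fall-back pixdim transform) as implemented by nibabel.

    Raises
    ------
    InputError
        If the file is missing/corrupt, or if the image is not 3-D.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct error types
        raise InputError(f"cannot read NIfTI volume {path}: {exc}") from exc
    shape = img.shape
    if len(shape) != 3:
        raise InputError(
            f"{path} has {len(shape)} dimensions; supply a single 3-D series "
            "(split 4-D files into individual volumes first)"
        )
    try:
        data = np.asarray(img.get_fdata(dtype=np.float64))
    except Exception as exc:
        raise InputError(f"cannot decode voxel data from {path}: {exc}") from exc
    if patient_id is None:
        patient_id = strip_nifti_extension(path.name)
    return CTVolume(voxels=data, affine=np.asarray(img.affine), patient_id=patient_id, condition=condition)


def write_ct(volume: CTVolume, path: os.PathLike | str) -> None:
    """Write a CT volume as NIfTI.  Integer-valued grids round-trip exactly."""
    img = nib.Nifti1Image(volume.voxels, volume.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def write_mask(mask: StructureMask, affine: np.ndarray, path: os.PathLike | str) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), np.asarray(affine, dtype=np.float64))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def write_mask_set(mask_set: MaskSet, affine: np.ndarray, directory: os.PathLike | str) -> None:
    """Write every mask as ``<structure_name>.nii.gz`` under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in mask_set.items():
        write_mask(mask, affine, directory / f"{name}.nii.gz")


def read_label_table(path: os.PathLike | str) -> Dict[int, str]:
    """Parse a two-column plain-text table of ``<integer label> <structure name>``."""
    table: Dict[int, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected '<label> <name>', got {raw!r}")
        try:
            label = int(parts[0])
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: label {parts[0]!r} is not an integer") from exc
        name = parts[1].strip()
        if label in table:
            raise InputError(f"{path}:{lineno}: duplicate label {label}")
        if name in table.values():
            raise InputError(f"{path}:{lineno}: duplicate structure name {name!r}")
        table[label] = name
    if not table:
        raise InputError(f"label table {path} is empty")
    return table


def _load_mask_array(path: Path, grid_shape: Tuple[int, int, int]) -> np.ndarray:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise InputError(f"cannot read NIfTI mask {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise InputError(f"mask {path} must be 3-D, got shape {img.shape}")
    if tuple(img.shape) != tuple(grid_shape):
        raise GridMismatchError(
            f"mask {path} shape {tuple(img.shape)} does not match CT grid {tuple(grid_shape)}"
        )
    return np.asarray(img.get_fdata(dtype=np.float64))


def read_mask_set(
    path: os.PathLike | str,
    ct: CTVolume,
    labels: Optional[os.PathLike | str | Mapping[int, str]] = None,
    source: str = "anatomical",
) -> MaskSet:
    """Read structure masks for a CT volume.

    Two dialects are accepted:

    * a directory of per-structure binary NIfTI files named
      ``<structure_name>.nii.gz`` (or ``.nii``);
    * a single integer label image plus a two-column label table mapping
      integer labels to structure names (``labels`` argument: a path or an
      already-parsed mapping).  Label 0 is background and never a structure.

    Every mask is checked against the CT grid shape; mismatches are fatal.
    """
    path = Path(path)
    mask_set = MaskSet(source=source)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.name.endswith(NIFTI_EXTENSIONS)
        )
        if not files:
            raise InputError(f"mask directory {path} contains no NIfTI files")
        for f in files:
            name = strip_nifti_extension(f.name)
            if name in mask_set:
                raise InputError(f"duplicate structure name {name!r} in {path}")
            data = _load_mask_array(f, ct.shape)
            mask_set.add(StructureMask(voxels=data != 0, structure_name=name))
        return mask_set

    if labels is None:
        raise InputError(
            f"{path} is a label image; a label table (labels=) is required to name structures"
        )
    table = labels if isinstance(labels, Mapping) else read_label_table(labels)
    data = _load_mask_array(path, ct.shape)
    for label, name in sorted(table.items()):
        if label == 0:
            continue  # background is never a structure
        mask_set.add(StructureMask(voxels=data == label, structure_name=name))
    if not mask_set:
        raise InputError(f"label table for {path} names no non-background structures")
    return mask_set


def voxel_volume_ml(affine: np.ndarray) -> float:
    """Volume of one voxel in millilitres: |det(linear part)| / 1000 (mm^3 -> mL)."""
    affine = np.asarray(affine, dtype=np.float64)
    det = float(np.linalg.det(affine[:3, :3]))
    if abs(det) < _DET_EPS:
        raise GeometryError("affine linear part is singular; voxel volume undefined")
    return abs(det) / 1000.0
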