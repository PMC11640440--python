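"""Seeded synthetic CT phantoms with controlled longitudinal changes.

Phantoms place non-overlapping ellipsoidal structures (voxel-center
membership) on a uniform background and draw per-voxel HU values from a
normal distribution, so every extracted statistic has a closed-form
expectation.  Paired phantoms apply an isotropic semi-axis scaling of
``(1 + volume_change_pct / 100) ** (1/3)`` and a mean-HU shift for the post
condition, with independent noise draws per condition.

All randomness flows from one integer seed through a named, per-structure,
per-condition stream, so fixtures reproduce bit-identically across runs and
platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import PhantomError
from .imaging_io import CTVolume, MaskSet, StructureMask, write_ct, write_mask_set


@dataclass(frozen=True)
class EllipsoidSpec:
    """One ellipsoidal structure: geometry in voxel units, HU distribution."""

    name: str
    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    hu_mean: float
    hu_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.hu_sd < 0:
            raise PhantomError(f"structure {self.name!r}: hu_sd must be >= 0")
        if min(self.semi_axes) <= 0:
            raise PhantomError(f"structure {self.name!r}: semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    structures: Tuple[EllipsoidSpec, ...] = ()
    background_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise PhantomError(f"grid_shape must be three positive integers, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or min(self.spacing_mm) <= 0:
            raise PhantomError(f"spacing_mm must be three positive reals, got {self.spacing_mm}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
        return aff


@dataclass(frozen=True)
class StructureChange:
    """Longitudinal change injected into one structure for the post condition."""

    volume_change_pct: float = 0.0
    hu_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_change_pct <= -100:
            raise PhantomError("volume_change_pct must be > -100")


#: Per-structure change map; structures not listed are left unchanged.
ChangeSpec = Dict[str, StructureChange]


def _structure_rng(seed: int, name: str, condition: str) -> np.random.Generator:
    # Named stream: stable across platforms and independent per structure/condition.
    key = zlib.crc32(f"{name}/{condition}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _ellipsoid_mask(shape: Tuple[int, int, int], ellipsoid: EllipsoidSpec) -> np.ndarray:
    for dim, c, a in zip(shape, ellipsoid.center, ellipsoid.semi_axes):
        if c - a < 0 or c + a > dim - 1:
            raise PhantomError(
                f"structure {ellipsoid.name!r} (center {ellipsoid.center}, semi-axes "
                f"{ellipsoid.semi_axes}) does not fit inside grid {shape}"
            )
    ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cx, cy, cz = ellipsoid.center
    ax, ay, az = ellipsoid.semi_axes
    # Voxel-center inclusion test.
    return (
        ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2
    ) <= 1.0


def make_phantom(
    spec: PhantomSpec, patient_id: str = "phantom", condition: str = "pre"
) -> Tuple[CTVolume, MaskSet]:
    """Rasterize a phantom spec into a CT volume and its mask set.

    Structure ellipsoids must not overlap (overlap would break the analytic
    per-structure statistics and is a fatal error).
    """
    voxels = np.full(spec.grid_shape, float(spec.background_hu), dtype=np.float64)
    occupancy = np.zeros(spec.grid_shape, dtype=bool)
    mask_set = MaskSet(source="anatomical")
    for structure in spec.structures:
        mask = _ellipsoid_mask(spec.grid_shape, structure)
        if (mask & occupancy).any():
            raise PhantomError(f"structure {structure.name!r} overlaps a previous structure")
        occupancy |= mask
        n = int(mask.sum())
        if structure.hu_sd > 0:
            rng = _structure_rng(spec.seed, structure.name, condition)
            voxels[mask] = rng.normal(structure.hu_mean, structure.hu_sd, size=n)
        else:
            voxels[mask] = structure.hu_mean
        mask_set.add(StructureMask(voxels=mask, structure_name=structure.name))
    ct = CTVolume(voxels=voxels, affine=spec.affine, patient_id=patient_id, condition=condition)
    return ct, mask_set


def apply_change(spec: PhantomSpec, change: ChangeSpec) -> PhantomSpec:
    """Post-condition spec: scaled semi-axes and shifted HU means."""
    unknown = set(change) - {s.name for s in spec.structures}
    if unknown:
        raise PhantomError(f"change spec names unknown structures: {sorted(unknown)}")
    structures = []
    for s in spec.structures:
        ch = change.get(s.name)
        if ch is None:
            structures.append(s)
            continue
        scale = (1.0 + ch.volume_change_pct / 100.0) ** (1.0 / 3.0)
        structures.append(
            replace(
                s,
                semi_axes=tuple(a * scale for a in s.semi_axes),
                hu_mean=s.hu_mean + ch.hu_shift,
            )
        )
    return replace(spec, structures=tuple(structures))


def make_paired_phantoms(
    spec: PhantomSpec, change: ChangeSpec, patient_id: str = "phantom"
) -> Tuple[Tuple[CTVolume, MaskSet], Tuple[CTVolume, MaskSet]]:
    """Pre and post phantoms for one synthetic patient."""
    pre = make_phantom(spec, patient_id=patient_id, condition="pre")
    post = make_phantom(apply_change(spec, change), patient_id=patient_id, condition="post")
    return pre, post


def make_cohort_specs(
    base: PhantomSpec, n_patients: int, seed: int
) -> List[Tuple[str, PhantomSpec]]:
    """Per-patient specs differing only in their noise seed."""
    if n_patients < 1:
        raise PhantomError("n_patients must be >= 1")
    ss = np.random.SeedSequence(entropy=seed)
    seeds = ss.generate_state(n_patients)
    return [
        (f"patient{i + 1:03d}", replace(base, seed=int(s))) for i, s in enumerate(seeds)
    ]


def write_paired_cohort(
    out_dir: Path | str,
    base: PhantomSpec,
    change: ChangeSpec,
    n_patients: int,
    seed: int,
) -> Dict[str, Path]:
    """Write a paired phantom cohort in the directory layout the CLI consumes.

    Creates ``pre/``, ``post/`` with ``<patient>.nii.gz`` volumes and
    ``masks_pre/<patient>/``, ``masks_post/<patient>/`` with per-structure
    binary masks.  Returns the four directory paths.
    """
    out_dir = Path(out_dir)
    layout = {
        "pre": out_dir / "pre",
        "post": out_dir / "post",
        "masks_pre": out_dir / "masks_pre",
        "masks_post": out_dir / "masks_post",
    }
    for p in layout.values():
        p.mkdir(parents=True, exist_ok=True)
    for patient_id, spec in make_cohort_specs(base, n_patients, seed):
        (ct_pre, masks_pre), (ct_post, masks_post) = make_paired_phantoms(
            spec, change, patient_id=patient_id
        )
        write_ct(ct_pre, layout["pre"] / f"{patient_id}.nii.gz")
        write_ct(ct_post, layout["post"] / f"{patient_id}.nii.gz")
        write_mask_set(masks_pre, ct_pre.affine, layout["masks_pre"] / patient_id)
        write_mask_set(masks_post, ct_post.affine, layout["masks_post"] / patient_id)
    return layout


def load_phantom_spec(path: Path | str) -> PhantomSpec:
    """Read a phantom spec from a small YAML/JSON config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise PhantomError(f"phantom config {path} must be a mapping")
    try:
        structures = tuple(
            EllipsoidSpec(
                name=s["name"],
                center=tuple(s["center"]),
                semi_axes=tuple(s["semi_axes"]),
                hu_mean=float(s["hu_mean"]),
                hu_sd=float(s.get("hu_sd", 0.0)),
            )
            for s in raw.get("structures", [])
        )
        return PhantomSpec(
            grid_shape=tuple(raw.get("grid_shape", (64, 64, 64))),
            spacing_mm=tuple(raw.get("spacing_mm", (1.0, 1.0, 1.0))),
            structures=structures,
            background_hu=float(raw.get("background_hu", -1000.0)),
            seed=int(raw.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PhantomError(f"invalid phantom config {path}: {exc}") from exc
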