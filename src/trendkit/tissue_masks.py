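"""Body-composition tissue masks from HU thresholds.

A tissue mask is the intersection of an externally supplied body-region mask
with a Hounsfield-unit interval.  Seven tissue classes are crossed with 29
body regions (vertebral levels C1-C7, T1-T12, L1-L5 plus five whole-body
regions), giving the 203-mask schema.

HU intervals are closed on both ends.  The five adipose compartments
(SAT, VAT, IMAT, PAT, EAT) share the adipose interval [-190, +30] HU;
the compartment distinction comes entirely from which region mask is
supplied.  Muscle uses [-29, +150] HU — note the deliberate adipose/muscle
overlap on [-29, +30].  Bone has no published interval here; the default
[+151, +3000] continues contiguously above muscle and can be overridden.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import GridMismatchError, InputError
from .imaging_io import CTVolume, MaskSet, StructureMask

HuInterval = Tuple[float, float]

ADIPOSE_HU: HuInterval = (-190.0, 30.0)
MUSCLE_HU: HuInterval = (-29.0, 150.0)
BONE_HU: HuInterval = (151.0, 3000.0)  # package default; not a published threshold

#: Tissue classes in schema order; the first five are adipose compartments.
TISSUE_CLASSES: Dict[str, HuInterval] = {
    "SAT": ADIPOSE_HU,
    "VAT": ADIPOSE_HU,
    "IMAT": ADIPOSE_HU,
    "PAT": ADIPOSE_HU,
    "EAT": ADIPOSE_HU,
    "bone": BONE_HU,
    "muscle": MUSCLE_HU,
}

VERTEBRAL_LEVELS: Tuple[str, ...] = (
    tuple(f"C{i}" for i in range(1, 8))
    + tuple(f"T{i}" for i in range(1, 13))
    + tuple(f"L{i}" for i in range(1, 6))
)

WHOLE_BODY_REGIONS: Tuple[str, ...] = (
    "abdominal_cavity",
    "thoracic_cavity",
    "ventral_cavity",
    "mediastinum",
    "pericardium",
)

#: 29 body regions: anatomical vertebral order C1..L5, then whole-body regions.
BODY_REGIONS: Tuple[str, ...] = VERTEBRAL_LEVELS + WHOLE_BODY_REGIONS


def tissue_mask_name(tissue_class: str, region: str) -> str:
    return f"{tissue_class}_{region}"


def tissue_schema() -> List[Tuple[str, str]]:
    """All (tissue class, body region) identifiers, class-major order.

    7 classes x 29 regions = 203 identifiers.
    """
    return [(cls, region) for cls in TISSUE_CLASSES for region in BODY_REGIONS]


def classify_tissue(
    ct: CTVolume,
    region_mask: StructureMask,
    tissue_class: str,
    hu_interval: Optional[HuInterval] = None,
) -> StructureMask:
    """Intersect a region mask with a tissue class's HU interval.

    A voxel belongs to the output iff it belongs to the region mask and its
    HU value lies inside the closed interval [lo, hi].
    """
    if hu_interval is None:
        try:
            hu_interval = TISSUE_CLASSES[tissue_class]
        except KeyError:
            raise InputError(f"unknown tissue class {tissue_class!r}") from None
    if region_mask.shape != ct.shape:
        raise GridMismatchError(
            f"region mask {region_mask.structure_name!r} shape {region_mask.shape} "
            f"does not match CT grid {ct.shape}"
        )
    lo, hi = hu_interval
    inside = (ct.voxels >= lo) & (ct.voxels <= hi) & (region_mask.voxels != 0)
    return StructureMask(
        voxels=inside,
        structure_name=tissue_mask_name(tissue_class, region_mask.structure_name),
    )


def derive_tissue_masks(
    ct: CTVolume,
    region_masks: MaskSet,
    hu_intervals: Optional[Dict[str, HuInterval]] = None,
) -> MaskSet:
    """Derive one tissue mask per (class, region) pair with the region present.

    Regions absent from *region_masks* are simply omitted; region names that
    are not part of the 29-region schema are skipped with a warning.  Output
    order and content are independent of the iteration order of the input.
    """
    intervals = dict(TISSUE_CLASSES)
    if hu_intervals:
        intervals.update(hu_intervals)
    known = set(BODY_REGIONS)
    for name in region_masks.names():
        if name not in known:
            warnings.warn(f"unknown body region {name!r}: skipped", stacklevel=2)
    out = MaskSet(source="tissue")
    for cls, region in tissue_schema():
        if region not in region_masks:
            continue
        out.add(classify_tissue(ct, region_masks[region], cls, intervals[cls]))
    return out


def write_schema_manifest(path: os.PathLike | str) -> None:
    """Dump the tissue schema as a two-column text manifest (class, region)."""
    lines = [f"{cls}\t{region}" for cls, region in tissue_schema()]
    Path(path).write_text("\n".join(lines) + "\n")
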