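"""Per-structure radiomic features: volume in millilitres plus HU statistics.

The metric set has exactly eight members per structure:
``volume_ml``, ``hu_sum``, ``hu_q1``, ``hu_q3``, ``hu_mean``, ``hu_median``
(Q2), ``hu_min``, ``hu_max``.  Quartiles use linear interpolation of the
order statistics at position ``(n - 1) * q`` (the numpy default), fixed for
reproducibility.

Empty masks emit no feature records at all — "structure absent" — which is
what triggers the pairwise-existence exclusion during trend analysis.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyMaskError, GridMismatchError, InputError
from .imaging_io import CTVolume, MaskSet, StructureMask, voxel_volume_ml

#: Metric names in canonical (serialization) order.
METRICS: Tuple[str, ...] = (
    "volume_ml",
    "hu_sum",
    "hu_q1",
    "hu_q3",
    "hu_mean",
    "hu_median",
    "hu_min",
    "hu_max",
)

FEATURE_COLUMNS = ("patient_id", "condition", "structure", "metric", "value")


def hu_statistics(ct: CTVolume, mask: StructureMask) -> Dict[str, float]:
    """The seven HU statistics over the masked voxels.

    Raises
    ------
    EmptyMaskError
        If the mask selects no voxels (structure absent).
    """
    if mask.shape != ct.shape:
        raise GridMismatchError(
            f"mask {mask.structure_name!r} shape {mask.shape} does not match CT grid {ct.shape}"
        )
    values = ct.voxels[mask.voxels != 0]
    if values.size == 0:
        raise EmptyMaskError(f"structure {mask.structure_name!r} has no voxels")
    q1, median, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return {
        "hu_sum": float(values.sum()),
        "hu_q1": float(q1),
        "hu_q3": float(q3),
        "hu_mean": float(values.mean()),
        "hu_median": float(median),
        "hu_min": float(values.min()),
        "hu_max": float(values.max()),
    }


def structure_volume_ml(mask: StructureMask, affine: np.ndarray) -> float:
    """Structure volume in mL: voxel count times the single-voxel volume."""
    return mask.voxel_count * voxel_volume_ml(affine)


def extract_features(ct: CTVolume, masks: MaskSet) -> pd.DataFrame:
    """Extract the eight-metric feature set for every non-empty mask.

    Returns a tidy table with columns
    ``patient_id, condition, structure, metric, value``, ordered by structure
    name and then canonical metric order.  Empty masks contribute no rows.
    """
    records: List[Tuple[str, str, str, str, float]] = []
    for name, mask in masks.items():
        if mask.is_empty():
            continue
        stats = hu_statistics(ct, mask)
        stats["volume_ml"] = structure_volume_ml(mask, ct.affine)
        for metric in METRICS:
            records.append((ct.patient_id, ct.condition, name, metric, stats[metric]))
    return pd.DataFrame.from_records(records, columns=FEATURE_COLUMNS)


def feature_schema(structure_names: Sequence[str]) -> List[Tuple[str, str]]:
    """Cross product of structure names with the metric set, structure-major."""
    names = list(structure_names)
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise InputError(f"duplicate structure names: {dupes}")
    return [(name, metric) for name in names for metric in METRICS]


def write_feature_csv(table: pd.DataFrame, path: os.PathLike | str) -> None:
    """Serialize a feature table; values rounded to 6 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6g")


def read_feature_csv(path: os.PathLike | str) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"patient_id": str, "condition": str, "structure": str, "metric": str})
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"feature table {path} lacks columns {sorted(missing)}")
    return table
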