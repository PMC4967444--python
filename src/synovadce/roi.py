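"""ROI bookkeeping: masks, synovial volume, median aggregation, cohort assembly."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROIMask",
    "synovial_volume",
    "median_over_roi",
    "build_cohort_table",
    "COHORT_COLUMNS",
    "MRI_PARAMETERS",
]

#: Canonical long-format cohort schema (one row per subject-visit).
COHORT_COLUMNS = ["subject_id", "visit", "protocol", "volume_mm3",
                  "rer", "re_late", "re_max", "ktrans", "ve", "koos_pain"]

#: The six MRI measurements carried through the statistics, cohort-table names.
MRI_PARAMETERS = ["volume_mm3", "rer", "re_late", "re_max", "ve", "ktrans"]

VISITS = ("baseline", "followup")


@dataclass(frozen=True)
class ROIMask:
    """Binary synovium mask on a voxel grid with physical voxel size (mm)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=bool)
        object.__setattr__(self, "data", arr)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "voxel_size_mm", vs)
        if arr.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size_mm must be strictly positive")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def indices(self) -> np.ndarray:
        """In-mask voxel indices as an (n, 3) integer array."""
        return np.argwhere(self.data)


def synovial_volume(mask: ROIMask) -> float:
    """Synovial tissue volume in mm^3: voxel count times voxel volume."""
    return mask.n_voxels * mask.voxel_volume_mm3


def median_over_roi(values: np.ndarray, evaluable: np.ndarray | None = None) -> float:
    """Median of a voxelwise parameter over the evaluable ROI voxels.

    ``values`` holds one value per in-mask voxel; voxels with
    ``evaluable=False`` (or NaN value) are excluded.  With an even count the
    mean of the two central order statistics is returned.  Zero evaluable
    voxels raise so the caller can flag the record missing, mirroring the
    exclusion of knees without enhancing synovitis.
    """
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if evaluable is not None:
        keep &= np.asarray(evaluable, dtype=bool)
    if not keep.any():
        raise ValueError("no evaluable voxels in ROI")
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("median_over_roi: excluded %d non-evaluable voxels of %d", n_excluded, values.size)
    return float(np.median(values[keep]))


def build_cohort_table(mri_records: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Assemble the long-format analysis cohort from MRI records and the clinical table.

    ``mri_records`` holds one row per subject-visit with the imaging-derived
    measures (volume and ROI medians); ``clinical`` supplies
    ``koos_pain`` and ``protocol`` per subject-visit.  Parsing is
    schema-keyed: column order is irrelevant.  Subjects lacking either visit
    (after the merge) are dropped with a logged reason — complete-case
    analysis only.  Duplicate subject-visit rows are a hard error.
    """
    mri = mri_records.copy()
    clin = clinical.copy()
    for name, df, cols in (("mri_records", mri, {"subject_id", "visit"}),
                           ("clinical", clin, {"subject_id", "visit", "koos_pain"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} is missing columns {sorted(missing)}")
        bad = set(df["visit"].unique()) - set(VISITS)
        if bad:
            raise ValueError(f"{name} has unknown visit labels {sorted(bad)}")
        dup = df.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            raise ValueError(f"duplicate subject-visit rows in {name}: "
                             f"{df.loc[dup, ['subject_id', 'visit']].to_records(index=False).tolist()}")

    merged = mri.merge(clin, on=["subject_id", "visit"], how="inner", suffixes=("", "_clin"))

    counts = merged.groupby("subject_id")["visit"].nunique()
    complete = counts[counts == 2].index
    dropped = sorted(set(merged["subject_id"]) - set(complete))
    if dropped:
        logger.warning("build_cohort_table: dropped %d subjects without both visits: %s",
                       len(dropped), dropped)
    out = merged[merged["subject_id"].isin(complete)].copy()
    logger.info("build_cohort_table: %d complete subjects (%d rows)", len(complete), len(out))

    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out = out[cols].sort_values(["subject_id", "visit"]).reset_index(drop=True)
    return out
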