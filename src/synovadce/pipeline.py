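"""Pipeline orchestration: simulate -> extract -> stats with run manifests.

Each stage is a plain function over files plus a :class:`RunConfig`; the CLI
is a thin wrapper.  Every output directory receives a ``manifest.json``
recording the seed, the config hash and package versions, so two runs with
the same config are byte-identical and auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__, curve_metrics, roi, stats, synthetic
from .config import RunConfig, config_hash
from .kinetics import AIF
from .protocols import LTR, STANDARD

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_extract", "run_stats", "run_full"]

_PROTOCOL_BY_FRAMES = {STANDARD.n_frames: STANDARD, LTR.n_frames: LTR}


def _write_manifest(out_dir: Path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    manifest = {"stage": stage, "seed": config.seed, "config_hash": config_hash(config),
                "synovadce_version": __version__,
                "numpy_version": np.__version__, "pandas_version": pd.__version__}
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic cohort: 4-D dynamic series + masks (NIfTI), AIF
    tables, the clinical table and the ground-truth table."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    subjects, truth = synthetic.simulate_cohort(
        n_subjects=config.n_subjects, effect=config.effect.to_effect(),
        pain_model=config.pain.to_pain_model(), protocol_mix=config.protocol_mix,
        seed=config.seed, population=config.population.to_population(),
        gain=config.fitting.gain, voxel_size_mm=config.voxel_size_mm)

    shape = config.aif.to_shape()
    aifs = {p.name: synthetic.make_population_aif(shape, protocol=p) for p in (STANDARD, LTR)}
    for name, aif in aifs.items():
        aif.to_table(out_dir / f"aif_{name}.csv")

    skipped = []
    for sub in subjects:
        for visit in ("baseline", "followup"):
            try:
                vol, mask = synthetic.render_4d_volume(
                    sub, visit, grid_shape=config.grid_shape,
                    voxel_size_mm=config.voxel_size_mm,
                    aif=aifs[sub.protocol.name], gain=config.fitting.gain)
            except ValueError as err:
                logger.warning("simulate: skipping %s %s (%s)", sub.subject_id, visit, err)
                skipped.append({"subject_id": sub.subject_id, "visit": visit, "reason": str(err)})
                continue
            synthetic.write_nifti_pair(vol, mask, img_dir, sub.subject_id, visit)

    clinical = truth[["subject_id", "visit", "protocol", "koos_pain"]]
    clinical.to_csv(out_dir / "clinical.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False)
    _write_manifest(out_dir, config, "simulate", {"n_subjects": config.n_subjects,
                                                  "skipped": skipped})
    return out_dir


def _load_pair(dyn_path: Path, mask_path: Path, voxel_size_mm):
    dyn = np.asarray(nib.load(dyn_path).get_fdata())
    mask_arr = np.asarray(nib.load(mask_path).get_fdata()) > 0.5
    return dyn, roi.ROIMask(data=mask_arr, voxel_size_mm=voxel_size_mm)


def run_extract(image_dir: str | Path, clinical_csv: str | Path,
                config: RunConfig, out_dir: str | Path,
                aif_tables: dict[str, str | Path] | None = None) -> Path:
    """Extract the per-subject-visit cohort table from image files.

    Pairs ``{subject}_{visit}_dyn.nii.gz`` with its mask, computes the five
    voxelwise parameters, the ROI medians and the synovial volume, and
    merges with the clinical table.  Subject-visits with missing pairs or
    unreadable files are excluded and named in ``exclusions.json``; the run
    continues (attrition is reported, not fatal).
    """
    image_dir = Path(image_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if aif_tables is None:
        aif_tables = {p.name: image_dir.parent / f"aif_{p.name}.csv" for p in (STANDARD, LTR)}
    aifs = {name: AIF.from_table(path) for name, path in aif_tables.items() if Path(path).exists()}

    exclusions: list[dict] = []
    records = []
    for dyn_path in sorted(image_dir.glob("*_dyn.nii.gz")):
        stem = dyn_path.name[: -len("_dyn.nii.gz")]
        subject_id, _, visit = stem.rpartition("_")
        mask_path = image_dir / f"{stem}_mask.nii.gz"
        if not mask_path.exists():
            exclusions.append({"subject_id": subject_id, "visit": visit, "reason": "missing mask"})
            continue
        try:
            vol, mask = _load_pair(dyn_path, mask_path, config.voxel_size_mm)
            protocol = _PROTOCOL_BY_FRAMES[vol.shape[-1]]
            maps = curve_metrics.voxelwise_maps(
                vol, mask, protocol, aif=aifs[protocol.name],
                gain=config.fitting.gain, fit_vp=config.fitting.fit_vp)
            record = {"subject_id": subject_id, "visit": visit,
                      "volume_mm3": roi.synovial_volume(mask)}
            for key, col in (("rer", "rer"), ("re_late", "re_late"), ("re_max", "re_max"),
                             ("ktrans", "ktrans"), ("ve", "ve")):
                record[col] = roi.median_over_roi(maps[key], maps["evaluable"])
            record["n_voxels"] = mask.n_voxels
            record["n_evaluable"] = int(maps["evaluable"].sum())
            record["fit_converged_frac"] = float(np.mean(maps["converged"][maps["evaluable"]]))
            records.append(record)
            logger.info("extract: %s %s — %d voxels, %d evaluable", subject_id, visit,
                        record["n_voxels"], record["n_evaluable"])
        except Exception as err:  # corrupt file, empty mask, no evaluable voxels ...
            exclusions.append({"subject_id": subject_id, "visit": visit, "reason": str(err)})
            logger.warning("extract: excluding %s %s (%s)", subject_id, visit, err)

    mri = pd.DataFrame(records)
    clinical = pd.read_csv(clinical_csv)
    cohort = roi.build_cohort_table(mri, clinical)
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    with open(out_dir / "exclusions.json", "w") as fh:
        json.dump(exclusions, fh, indent=2)
    _write_manifest(out_dir, config, "extract",
                    {"n_records": len(records), "n_excluded": len(exclusions)})
    return out_dir / "cohort.csv"


def run_stats(cohort_csv: str | Path, config: RunConfig, out_dir: str | Path) -> Path:
    """Responsiveness and association tables from a cohort CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(cohort_csv)
    resp = stats.responsiveness_table(cohort, mode=config.stats.panel_mode)
    try:
        assoc = stats.association_table(cohort)
    except ValueError as err:  # e.g. fewer than 4 complete pairs
        logger.warning("stats: association table not computed (%s)", err)
        assoc = pd.DataFrame(columns=["parameter_type", "b", "b_ci_low", "b_ci_high",
                                      "p", "r", "r_ci_low", "r_ci_high", "n"])
    resp.to_csv(out_dir / "standardized_change.csv", index=False)
    assoc.to_csv(out_dir / "associations.csv", index=False)
    _write_manifest(out_dir, config, "stats", {"n_rows": len(cohort)})
    return out_dir


def run_full(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate + extract + stats; errors are propagated with the stage name."""
    out_dir = Path(out_dir)
    stages = [("simulate", lambda: run_simulate(config, out_dir / "sim")),
              ("extract", lambda: run_extract(out_dir / "sim" / "images",
                                              out_dir / "sim" / "clinical.csv",
                                              config, out_dir / "extract")),
              ("stats", lambda: run_stats(out_dir / "extract" / "cohort.csv",
                                          config, out_dir / "results"))]
    for name, step in stages:
        try:
            step()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    _write_manifest(out_dir, config, "full")
    return out_dir / "results"
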