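"""Pipeline orchestration: simulate -> compute -> compare -> report.

Every stage is a pure function of (inputs, config, seed); all tabular
outputs are CSV with a header row and are written atomically (temp file
+ rename), so a failed run leaves no partial tables.  A run manifest
records the config, package versions and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import ConditionModel, summarize_by_condition
from .core import LimbId, StrideRecord, TravelDirection
from .gaits import classify_gait, hildebrand_descriptor
from .io import (
    NECK_LANDMARK_COLUMNS,
    RunConfig,
    read_events_table,
    read_neck_table,
    write_events_table,
    write_neck_table,
)
from .kinematics import metrics_table
from .neck import NeckLandmarks, extract_neck_peaks, neck_angle
from .simulate import ConditionEffects, GaitParams, generate_cohort

logger = logging.getLogger("gaitkit")

#: Limb metrics compared across conditions (speed covariate rule applies
#: automatically to mean NSL; neck ROM is in NECK_METRICS).
LIMB_METRICS = [
    "relative_stride_length",
    "mean_stride_duration_s",
    "relative_speed",
    "limb_phase_pct",
    "mean_nsl",
    "ipsilateral_dfai_pct",
]
NECK_METRICS = ["peak_dorsal_extension_deg", "peak_ventral_flexion_deg", "rom_deg"]


def atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(text: str, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def neck_metrics_table(
    neck_table: pd.DataFrame,
    records: list[StrideRecord] | None = None,
    y_up: bool = False,
) -> pd.DataFrame:
    """Per-stride neck kinematics from the frame-level neck table.

    Accepts either pre-measured ``angle_deg`` rows or raw landmark
    coordinates (angles are then computed per frame, with the clip's
    travel direction taken from the stride records when available).
    """
    directions: dict[str, TravelDirection] = {}
    meta: dict[str, StrideRecord] = {}
    if records:
        for r in records:
            directions[r.clip.clip_id] = r.clip.travel_direction
            meta[r.clip.clip_id] = r

    rows = []
    for (clip_id, stride_index), grp in neck_table.groupby(
        ["clip_id", "stride_index"], sort=True
    ):
        grp = grp.sort_values("frame")
        if "angle_deg" in grp.columns and grp["angle_deg"].notna().all():
            angles = grp["angle_deg"].to_numpy(dtype=float)
        else:
            direction = directions.get(str(clip_id), TravelDirection.LEFT_TO_RIGHT)
            angles = np.array(
                [
                    neck_angle(
                        NeckLandmarks(
                            frame=int(r["frame"]),
                            tail_base=(r["tail_x"], r["tail_y"]),
                            withers=(r["withers_x"], r["withers_y"]),
                            occiput=(r["occiput_x"], r["occiput_y"]),
                        ),
                        direction,
                        y_up=y_up,
                    )
                    for _, r in grp.iterrows()
                ]
            )
        peaks = extract_neck_peaks(angles)
        row = {
            "clip_id": clip_id,
            "stride_index": stride_index,
            "peak_dorsal_extension_deg": peaks.peak_dorsal_extension_deg,
            "peak_ventral_flexion_deg": peaks.peak_ventral_flexion_deg,
            "rom_deg": peaks.rom_deg,
        }
        rec = meta.get(str(clip_id))
        if rec is not None:
            row["individual_id"] = rec.clip.individual_id
            row["condition"] = rec.clip.condition.value
            row["gsd_present"] = int(rec.clip.gsd_present)
            row["snare_present"] = int(rec.clip.snare_present)
        rows.append(row)
    return pd.DataFrame(rows)


def compute_stage(
    records: list[StrideRecord],
    neck_table: pd.DataFrame | None = None,
    classification_tolerance_pct: float = 2.0,
    y_up: bool = False,
    reference_limb: LimbId = LimbId.LH,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-stride metrics with gait-classification columns, plus per-stride
    neck kinematics when a neck table is given."""
    if reference_limb is not LimbId.LH:
        from dataclasses import replace

        records = [replace(r, reference_limb=reference_limb) for r in records]
    metrics = metrics_table(records)
    bands, named, descriptors = [], [], []
    for _, row in metrics.iterrows():
        gc = classify_gait(row["limb_phase_pct"], classification_tolerance_pct)
        bands.append(gc.band.value)
        named.append(gc.named_gait.value if gc.named_gait else "")
        descriptors.append(
            hildebrand_descriptor(row["mean_duty_factor"], row["limb_phase_pct"])
        )
    metrics["gait_band"] = bands
    metrics["named_gait"] = named
    metrics["hildebrand"] = descriptors

    neck_metrics = None
    if neck_table is not None:
        neck_metrics = neck_metrics_table(neck_table, records, y_up=y_up)
        # speed covariate for the neck ROM model
        neck_metrics = neck_metrics.merge(
            metrics[["clip_id", "stride_index", "relative_speed"]],
            on=["clip_id", "stride_index"],
            how="left",
        )
    return metrics, neck_metrics


def compare_stage(
    metrics: pd.DataFrame, neck_metrics: pd.DataFrame | None = None
) -> dict[str, object]:
    """Fit the condition model per metric; returns results keyed by metric."""
    results: dict[str, object] = {}
    for m in LIMB_METRICS:
        results[m] = ConditionModel.from_dataframe(metrics, m).fit()
    if neck_metrics is not None and {"gsd_present", "snare_present"} <= set(
        neck_metrics.columns
    ):
        for m in NECK_METRICS:
            results[m] = ConditionModel.from_dataframe(neck_metrics, m).fit()
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the enabled stages in order; returns the emitted files.

    Any stage error aborts with a stage-labeled exception; outputs are
    atomic, so no partial tables survive a failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    emitted: dict[str, Path] = {}
    stages = list(config.stages)

    events_path = Path(config.events_path) if config.events_path else out / "events.csv"
    neck_path = Path(config.neck_path) if config.neck_path else out / "neck.csv"

    try:
        if "simulate" in stages:
            records, neck_table = generate_cohort(
                n_individuals_per_condition=8, seed=config.seed
            )
            write_events_table(records, events_path)
            write_neck_table(neck_table, neck_path)
            emitted["events"] = events_path
            emitted["neck"] = neck_path
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    metrics = neck_metrics = None
    try:
        if "compute" in stages:
            records = read_events_table(events_path)
            neck_table = read_neck_table(neck_path) if neck_path.exists() else None
            metrics, neck_metrics = compute_stage(
                records,
                neck_table,
                classification_tolerance_pct=config.classification_tolerance_pct,
                y_up=config.y_up,
                reference_limb=LimbId(config.reference_limb),
            )
            atomic_write_csv(metrics, out / "metrics.csv")
            emitted["metrics"] = out / "metrics.csv"
            if neck_metrics is not None:
                atomic_write_csv(neck_metrics, out / "neck_metrics.csv")
                emitted["neck_metrics"] = out / "neck_metrics.csv"
    except Exception as exc:
        raise RuntimeError(f"[compute] {exc}") from exc

    try:
        if "compare" in stages and metrics is not None:
            summary = summarize_by_condition(metrics)
            atomic_write_csv(summary, out / "condition_summary.csv")
            emitted["condition_summary"] = out / "condition_summary.csv"
            results = compare_stage(metrics, neck_metrics)
            anova = pd.concat(
                [r.anova.assign(metric=m) for m, r in results.items()], ignore_index=True
            )
            emms = pd.concat(
                [r.emmeans.assign(metric=m) for m, r in results.items()], ignore_index=True
            )
            pairs = pd.concat(
                [r.pairwise.assign(metric=m) for m, r in results.items()], ignore_index=True
            )
            atomic_write_csv(anova, out / "fixed_effects.csv")
            atomic_write_csv(emms, out / "emmeans.csv")
            atomic_write_csv(pairs, out / "pairwise.csv")
            emitted["fixed_effects"] = out / "fixed_effects.csv"
            emitted["emmeans"] = out / "emmeans.csv"
            emitted["pairwise"] = out / "pairwise.csv"
            text = "\n\n".join(r.summary() for r in results.values())
            atomic_write_text(text, out / "comparison_summary.txt")
            emitted["comparison_summary"] = out / "comparison_summary.txt"
    except Exception as exc:
        raise RuntimeError(f"[compare] {exc}") from exc

    manifest = {
        "gaitkit_version": __version__,
        "config": {k: v for k, v in config.__dict__.items()},
        "inputs": {
            name: _sha256(p)
            for name, p in (("events", events_path), ("neck", neck_path))
            if p.exists()
        },
        "outputs": {name: str(p) for name, p in emitted.items()},
    }
    atomic_write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", out / "manifest.json")
    emitted["manifest"] = out / "manifest.json"
    return emitted
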