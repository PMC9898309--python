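"""Readers and writers for the tabular schemas, plus run configuration.

Two plain-CSV schemas carry all digitized data:

* **events CSV** — one row per footfall event with the stride-level pixel
  measures and clip metadata repeated on every row.  Columns: clip_id,
  individual_id, fps, stride_index, limb {LH,LF,RH,RF}, event {TD,LO},
  frame, stride_length_px, shoulder_height_px, gsd_present {0,1},
  snare_present {0,1}, injured_limb (blank or limb code),
  travel_direction {L2R,R2L}.
* **neck CSV** — one row per frame with clip_id, stride_index, frame and
  either the six landmark coordinates (tail_x..occiput_y) or a
  pre-measured angle_deg column (as exported from an on-screen angle
  tool).

Validation failures raise :class:`~gaitkit.core.SchemaError` (missing
column) or :class:`~gaitkit.core.ValidationError` (record-level invariant)
identifying the clip, stride and limb; per-clip summaries go to the
logger on stderr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import (
    LIMB_ORDER,
    ClipMeta,
    EventKind,
    FootfallEvent,
    LimbId,
    SchemaError,
    StrideRecord,
    TravelDirection,
    ValidationError,
)

logger = logging.getLogger("gaitkit")

EVENT_COLUMNS = [
    "clip_id",
    "individual_id",
    "fps",
    "stride_index",
    "limb",
    "event",
    "frame",
    "stride_length_px",
    "shoulder_height_px",
    "gsd_present",
    "snare_present",
    "injured_limb",
    "travel_direction",
]

NECK_KEY_COLUMNS = ["clip_id", "stride_index", "frame"]
NECK_LANDMARK_COLUMNS = ["tail_x", "tail_y", "withers_x", "withers_y", "occiput_x", "occiput_y"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_events_table(path: str | Path) -> list[StrideRecord]:
    """Read and validate an events CSV into StrideRecords, grouped by clip
    (records are ordered by clip_id then stride_index)."""
    df = pd.read_csv(path, dtype={"injured_limb": "string"})
    _require_columns(df, EVENT_COLUMNS, f"events table {path}")

    records: list[StrideRecord] = []
    for (clip_id, stride_index), grp in df.groupby(["clip_id", "stride_index"], sort=True):
        meta_row = grp.iloc[0]
        fps = float(meta_row["fps"])
        if fps <= 0:
            raise ValidationError(f"clip {clip_id}: fps must be > 0, got {fps}")
        injured = meta_row["injured_limb"]
        injured_limb = (
            LimbId(str(injured)) if pd.notna(injured) and str(injured).strip() else None
        )
        direction_raw = meta_row.get("travel_direction")
        if pd.isna(direction_raw) or not str(direction_raw).strip():
            logger.warning(
                "clip %s: travel_direction missing, defaulting to L2R", clip_id
            )
            direction = TravelDirection.LEFT_TO_RIGHT
        else:
            direction = TravelDirection(str(direction_raw))
        meta = ClipMeta(
            clip_id=str(clip_id),
            individual_id=str(meta_row["individual_id"]),
            fps=fps,
            gsd_present=bool(int(meta_row["gsd_present"])),
            snare_present=bool(int(meta_row["snare_present"])),
            injured_limb=injured_limb,
            travel_direction=direction,
        )
        events = tuple(
            FootfallEvent(
                frame=int(r["frame"]), limb=LimbId(r["limb"]), kind=EventKind(r["event"])
            )
            for _, r in grp.iterrows()
        )
        records.append(
            StrideRecord(
                clip=meta,
                stride_index=int(stride_index),
                events=events,
                stride_length_px=float(meta_row["stride_length_px"]),
                shoulder_height_px=float(meta_row["shoulder_height_px"]),
            )
        )
    for clip_id, n in pd.Series([r.clip.clip_id for r in records]).value_counts().items():
        logger.info("clip %s: %d valid stride(s)", clip_id, n)
    return records


def write_events_table(records: list[StrideRecord], path: str | Path) -> None:
    """Write StrideRecords to the events CSV schema (inverse of reading)."""
    rows = []
    for r in sorted(records, key=lambda s: (s.clip.clip_id, s.stride_index)):
        for e in r.events:
            rows.append(
                {
                    "clip_id": r.clip.clip_id,
                    "individual_id": r.clip.individual_id,
                    "fps": r.clip.fps,
                    "stride_index": r.stride_index,
                    "limb": e.limb.value,
                    "event": e.kind.value,
                    "frame": e.frame,
                    "stride_length_px": r.stride_length_px,
                    "shoulder_height_px": r.shoulder_height_px,
                    "gsd_present": int(r.clip.gsd_present),
                    "snare_present": int(r.clip.snare_present),
                    "injured_limb": r.clip.injured_limb.value if r.clip.injured_limb else "",
                    "travel_direction": r.clip.travel_direction.value,
                }
            )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_neck_table(path: str | Path) -> pd.DataFrame:
    """Read a neck CSV; returns the frame-level table with either landmark
    coordinates or a pre-measured angle_deg column (never both missing)."""
    df = pd.read_csv(path)
    _require_columns(df, NECK_KEY_COLUMNS, f"neck table {path}")
    has_landmarks = all(c in df.columns for c in NECK_LANDMARK_COLUMNS)
    if not has_landmarks and "angle_deg" not in df.columns:
        raise SchemaError(
            f"neck table {path} needs either the landmark columns "
            f"({', '.join(NECK_LANDMARK_COLUMNS)}) or an angle_deg column"
        )
    return df


def write_neck_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Pipeline run configuration (YAML key-value file).

    ``seed`` drives every stochastic stage; with a fixed seed the pipeline
    writes byte-identical outputs on identical inputs.
    """

    events_path: str | None = None
    neck_path: str | None = None
    out_dir: str = "gaitkit_out"
    reference_limb: str = "LH"
    classification_tolerance_pct: float = 2.0
    y_up: bool = False
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "compute", "compare"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"config {path}: unknown key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)
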