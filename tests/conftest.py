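"""Shared fixtures: hand-built strides and an independent NSL oracle."""

from __future__ import annotations

import numpy as np
import pytest

from gaitkit import ClipMeta, EventKind, FootfallEvent, LimbId, StrideRecord
from gaitkit.core import LIMB_ORDER


def build_stride(
    limb_frames: dict[LimbId, tuple[int, int, int]],
    fps: float = 30.0,
    stride_length_px: float = 630.0,
    shoulder_height_px: float = 500.0,
    clip: ClipMeta | None = None,
    stride_index: int = 0,
) -> StrideRecord:
    """StrideRecord from per-limb (TD1, LO, TD2) frame triples.

    A trailing liftoff is appended after each limb's second touchdown so
    records carry the full two-TD + two-LO digitization per limb.
    """
    clip = clip or ClipMeta("clip0", "ind0", fps)
    events = []
    for limb, (td1, lo, td2) in limb_frames.items():
        events += [
            FootfallEvent(frame=td1, limb=limb, kind=EventKind.TD),
            FootfallEvent(frame=lo, limb=limb, kind=EventKind.LO),
            FootfallEvent(frame=td2, limb=limb, kind=EventKind.TD),
            FootfallEvent(frame=td2 + (lo - td1), limb=limb, kind=EventKind.LO),
        ]
    return StrideRecord(
        clip=clip,
        stride_index=stride_index,
        events=tuple(events),
        stride_length_px=stride_length_px,
        shoulder_height_px=shoulder_height_px,
    )


def uniform_stride(
    period_frames: int = 60,
    duty: float = 0.66,
    phase_pct: float = 15.0,
    fps: float = 30.0,
    **kwargs,
) -> StrideRecord:
    """Symmetric walk with identical per-limb periods, exact frames."""
    p = phase_pct / 100.0
    offsets = {
        LimbId.LH: 0,
        LimbId.LF: int(round(p * period_frames)),
        LimbId.RH: period_frames // 2,
        LimbId.RF: int(round((0.5 + p) % 1.0 * period_frames)),
    }
    frames = {}
    for limb, off in offsets.items():
        td1 = 100 + off
        lo = td1 + int(round(duty * period_frames))
        frames[limb] = (td1, lo, td1 + period_frames)
    return build_stride(frames, fps=fps, **kwargs)


def nsl_by_sampling(stride: StrideRecord, n_points: int = 10_000) -> float:
    """Brute-force time-sampling oracle for mean NSL: evaluate each limb's
    periodically extended contact indicator at n midpoints of the window."""
    fps = stride.clip.fps
    w0, w1 = stride.window
    ts = w0 + (np.arange(n_points) + 0.5) * (w1 - w0) / n_points
    total = np.zeros(n_points)
    for limb in LIMB_ORDER:
        td = stride.touchdowns(limb)[0].time(fps)
        lo = stride.contact_liftoff(limb).time(fps)
        period = stride.touchdowns(limb)[1].time(fps) - td
        total += ((ts - td) % period) < (lo - td)
    return float(total.mean())


@pytest.fixture
def basic_clip() -> ClipMeta:
    return ClipMeta("clip0", "ind0", 30.0)
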