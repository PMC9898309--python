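"""Synthetic walking-gait generator with known ground truth.

Emulates digitized 30-fps video of a lateral-sequence lateral-couplet
quadruped walk: the default parameters are the healthy adult-giraffe
walk (stride duration 2.31 s, limb phase 13.1 %, duty factor 0.66,
relative stride length 1.26, neck angle oscillating twice per stride
around 188.5 degrees with ~7.5 degrees amplitude).

Event algebra for one stride with period ``T``, limb phase ``p`` and
duty factors ``d``: the reference hindlimb touches down at ``t0``, its
ipsilateral forelimb at ``t0 + p*T``; the contralateral hindlimb at
``t0 + T/2`` and its forelimb at ``t0 + (0.5 + p)*T (mod T)``.  Each limb
lifts off ``d*T`` after its touchdown and touches down again one period
later.  Independent Gaussian timing noise (default SD: one frame) is
added per event before quantizing to the nearest video frame —
emulating manual frame picking — and invalid draws are resampled with a
bounded retry count.

Cohorts draw per-individual random intercepts, apply condition effects
(snare wounds shorten strides, lower limb phase and reduce the injured
limb's duty factor; skin disease has no limb-kinematic effect by
default) and emit one to eight strides per individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    LIMB_ORDER,
    ClipMeta,
    EventKind,
    FootfallEvent,
    LimbId,
    StrideRecord,
    ValidationError,
)

_MAX_RETRIES = 100


class GenerationError(RuntimeError):
    """No valid event stream could be produced for the given parameters."""


@dataclass(frozen=True)
class GaitParams:
    """Ground-truth gait parameters for one simulated stride stream."""

    stride_duration_s: float = 2.31
    limb_phase_pct: float = 13.10
    duty_factor: dict[LimbId, float] = field(
        default_factory=lambda: {limb: 0.66 for limb in LIMB_ORDER}
    )
    stride_length_px: float = 630.0
    shoulder_height_px: float = 500.0
    fps: float = 30.0
    timing_noise_sd_s: float = 1.0 / 30.0
    neck_mean_deg: float = 188.45
    neck_amplitude_deg: float = 7.45
    neck_phase_rad: float | None = None  # default places dorsal peaks at fore TDs
    # per-frame angular jitter; kept sub-degree because min/max peak
    # extraction is extreme-value-biased upward by frame noise
    neck_noise_sd_deg: float = 0.25
    n_strides: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.limb_phase_pct < 100:
            raise ValueError(f"limb_phase_pct must be in [0, 100), got {self.limb_phase_pct}")
        if self.fps <= 0 or self.stride_duration_s <= 0:
            raise ValueError("fps and stride_duration_s must be > 0")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        for limb, d in self.duty_factor.items():
            if not 0 < d < 1:
                raise ValueError(f"duty factor for {limb.value} must be in (0, 1), got {d}")

    @property
    def neck_phase(self) -> float:
        """Phase that puts peak dorsal extension at early forelimb stance."""
        if self.neck_phase_rad is not None:
            return self.neck_phase_rad
        return math.pi * (1.0 - 4.0 * self.limb_phase_pct / 100.0)


@dataclass(frozen=True)
class ConditionEffects:
    """Injected condition effects and between-individual variability.

    Snare defaults reproduce the observed direction and size of
    unilateral limb-injury compensation: ~0.18 shoulder heights shorter
    relative strides, ~1.3 percentage points lower limb phase, and a
    duty-factor reduction on the injured limb sized to give roughly a
    -4.4 % ipsilateral asymmetry index.  Skin-disease deltas default to
    zero (no limb-kinematic effect).  ``individual_sd`` are the
    random-intercept SDs; ``stride_sd`` the residual stride-to-stride
    SDs beyond event-timing noise.
    """

    snare_delta_rel_stride_length: float = -0.18
    snare_delta_limb_phase_pct: float = -1.3
    injured_side_df_reduction: float = 0.058
    gsd_delta_rel_stride_length: float = 0.0
    gsd_delta_limb_phase_pct: float = 0.0
    individual_sd: dict[str, float] = field(
        default_factory=lambda: {
            "rel_stride_length": 0.07,
            "stride_duration_s": 0.09,
            "limb_phase_pct": 0.9,
            "neck_mean_deg": 5.0,
            "neck_amplitude_deg": 1.5,
        }
    )
    stride_sd: dict[str, float] = field(
        default_factory=lambda: {
            "rel_stride_length": 0.05,
            "stride_duration_s": 0.05,
        }
    )
    injured_limb_weights: dict[LimbId, float] = field(
        default_factory=lambda: {LimbId.LH: 8.0, LimbId.RH: 1.0, LimbId.RF: 4.0}
    )

    def __post_init__(self) -> None:
        if self.injured_side_df_reduction < 0:
            raise ValueError("injured_side_df_reduction must be >= 0")


def _quantize(t: float, fps: float) -> int:
    return int(round(t * fps))


def generate_stride_events(
    params: GaitParams,
    rng: np.random.Generator,
    clip: ClipMeta,
    stride_index: int = 0,
    t0_s: float = 1.0,
) -> StrideRecord:
    """One stride's footfall events from the gait model, frame-quantized.

    Resamples the timing noise (up to a bounded retry count) when a draw
    violates the stride invariants, e.g. a liftoff quantized onto a
    touchdown frame.
    """
    T = params.stride_duration_s
    p = params.limb_phase_pct / 100.0
    td_offsets = {
        LimbId.LH: 0.0,
        LimbId.LF: p * T,
        LimbId.RH: 0.5 * T,
        LimbId.RF: ((0.5 + p) % 1.0) * T,
    }
    last_err: Exception | None = None
    for _ in range(_MAX_RETRIES):
        events = []
        for limb in LIMB_ORDER:
            td1 = t0_s + td_offsets[limb]
            d = params.duty_factor[limb]
            for t, kind in (
                (td1, EventKind.TD),
                (td1 + d * T, EventKind.LO),
                (td1 + T, EventKind.TD),
                (td1 + T + d * T, EventKind.LO),
            ):
                t_noisy = t + rng.normal(0.0, params.timing_noise_sd_s)
                events.append(
                    FootfallEvent(
                        frame=max(0, _quantize(t_noisy, params.fps)), limb=limb, kind=kind
                    )
                )
        try:
            return StrideRecord(
                clip=clip,
                stride_index=stride_index,
                events=tuple(events),
                stride_length_px=params.stride_length_px,
                shoulder_height_px=params.shoulder_height_px,
            )
        except ValidationError as err:
            last_err = err
    raise GenerationError(
        f"no valid stride after {_MAX_RETRIES} draws for clip {clip.clip_id}: {last_err}"
    )


def generate_neck_series(
    params: GaitParams, rng: np.random.Generator, start_frame: int = 0
) -> pd.DataFrame:
    """Per-frame neck angles over one stride window: two cosine
    oscillations per stride plus Gaussian digitization noise.

    Returns a frame/angle_deg table whose frames span [start, start + T).
    """
    n = int(round(params.stride_duration_s * params.fps))
    t = np.arange(n) / params.fps
    angles = (
        params.neck_mean_deg
        + params.neck_amplitude_deg
        * np.cos(4.0 * np.pi * t / params.stride_duration_s + params.neck_phase)
        + rng.normal(0.0, params.neck_noise_sd_deg, size=n)
    )
    return pd.DataFrame({"frame": np.arange(n) + start_frame, "angle_deg": angles})


_CONDITIONS = (
    ("healthy", False, False),
    ("gsd", True, False),
    ("snare", False, True),
    ("gsd_snare", True, True),
)


def generate_cohort(
    n_individuals_per_condition: int,
    base: GaitParams | None = None,
    effects: ConditionEffects | None = None,
    seed: int = 0,
    strides_per_individual: tuple[int, int] = (1, 8),
) -> tuple[list[StrideRecord], pd.DataFrame]:
    """A four-condition cohort of simulated strides and neck series.

    Per individual: a random intercept per metric, condition deltas
    applied on top, and a uniform 1-8 strides (one clip per individual).
    Fully reproducible from ``seed``.

    Returns ``(stride_records, neck_table)`` in the pipeline's input
    schemas.
    """
    base = base or GaitParams()
    effects = effects or ConditionEffects()
    rng = np.random.default_rng(seed)
    isd, ssd = effects.individual_sd, effects.stride_sd

    limbs = list(effects.injured_limb_weights)
    weights = np.array([effects.injured_limb_weights[l] for l in limbs], dtype=float)
    weights /= weights.sum()

    records: list[StrideRecord] = []
    neck_rows: list[pd.DataFrame] = []
    lo, hi = strides_per_individual
    for cond_name, gsd, snare in _CONDITIONS:
        for i in range(n_individuals_per_condition):
            ind_id = f"ind_{cond_name}_{i:02d}"
            clip_id = f"clip_{cond_name}_{i:02d}"
            injured = limbs[rng.choice(len(limbs), p=weights)] if snare else None
            clip = ClipMeta(
                clip_id=clip_id,
                individual_id=ind_id,
                fps=base.fps,
                gsd_present=gsd,
                snare_present=snare,
                injured_limb=injured,
            )
            # individual-level deviations (random intercepts)
            dev = {k: rng.normal(0.0, sd) for k, sd in isd.items()}
            rel_len_i = (
                base.stride_length_px / base.shoulder_height_px
                + dev.get("rel_stride_length", 0.0)
                + (effects.snare_delta_rel_stride_length if snare else 0.0)
                + (effects.gsd_delta_rel_stride_length if gsd else 0.0)
            )
            duration_i = base.stride_duration_s + dev.get("stride_duration_s", 0.0)
            phase_i = (
                base.limb_phase_pct
                + dev.get("limb_phase_pct", 0.0)
                + (effects.snare_delta_limb_phase_pct if snare else 0.0)
                + (effects.gsd_delta_limb_phase_pct if gsd else 0.0)
            )
            duty_i = dict(base.duty_factor)
            if injured is not None:
                duty_i[injured] = max(0.05, duty_i[injured] - effects.injured_side_df_reduction)
            neck_mean_i = base.neck_mean_deg + dev.get("neck_mean_deg", 0.0)
            neck_amp_i = max(0.5, base.neck_amplitude_deg + dev.get("neck_amplitude_deg", 0.0))

            n_strides = int(rng.integers(lo, hi + 1))
            for s in range(n_strides):
                rel_len_s = max(0.2, rel_len_i + rng.normal(0.0, ssd.get("rel_stride_length", 0.0)))
                duration_s = max(0.5, duration_i + rng.normal(0.0, ssd.get("stride_duration_s", 0.0)))
                params_s = replace(
                    base,
                    stride_duration_s=duration_s,
                    limb_phase_pct=float(np.clip(phase_i, 0.0, 99.0)),
                    duty_factor=duty_i,
                    stride_length_px=rel_len_s * base.shoulder_height_px,
                )
                record = generate_stride_events(params_s, rng, clip, stride_index=s)
                records.append(record)
                w0, _ = record.window
                neck_params = replace(
                    params_s, neck_mean_deg=neck_mean_i, neck_amplitude_deg=neck_amp_i
                )
                neck = generate_neck_series(
                    neck_params, rng, start_frame=int(round(w0 * base.fps))
                )
                neck.insert(0, "stride_index", s)
                neck.insert(0, "clip_id", clip_id)
                neck_rows.append(neck)

    neck_table = pd.concat(neck_rows, ignore_index=True)
    return records, neck_table
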