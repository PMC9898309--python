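"""Per-stride spatiotemporal limb kinematics.

Seven metrics describe one walking stride:

* **relative stride length** — stride length / shoulder height, both in
  pixels from the same frame, so the ratio is parallax-safe;
* **stride duration** — seconds between successive touchdowns of a limb;
  the stride's value is the mean over the four limbs;
* **relative speed** — relative stride length / mean stride duration
  (shoulder heights per second);
* **limb phase** — percent of the hindlimb's stride duration separating a
  hindlimb touchdown from the ipsilateral forelimb touchdown, averaged
  over the left and right pairs; the x-axis of the Hildebrand diagram;
* **duty factor** — per limb, contact time / that limb's stride duration;
* **mean NSL** — time-averaged number of supporting limbs over the
  reference-limb stride window (0–4), computed by an exact event-boundary
  sweep, with the support-time profile over 0..4 limbs as a by-product;
* **ipsilateral DFAI** — duty-factor asymmetry index between the left and
  right limb pairs, in percent of their average; 0 is perfect
  contralateral symmetry, and under the injured-limb convention negative
  values always mean less contact time on the injured side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LIMB_ORDER, LimbId, StrideRecord, ValidationError


@dataclass(frozen=True)
class LimbKinematics:
    """The seven spatiotemporal metrics for one stride."""

    relative_stride_length: float
    mean_stride_duration_s: float
    relative_speed: float
    limb_phase_pct: float
    mean_nsl: float
    duty_factor: dict[LimbId, float]
    ipsilateral_dfai_pct: float
    limb_phase_left_pct: float
    limb_phase_right_pct: float
    support_fractions: tuple[float, float, float, float, float]

    @property
    def mean_duty_factor(self) -> float:
        return float(np.mean(list(self.duty_factor.values())))


def relative_stride_length(stride_length_px: float, shoulder_height_px: float) -> float:
    """Stride length normalized by shoulder height (dimensionless)."""
    if stride_length_px <= 0 or shoulder_height_px <= 0:
        raise ValueError(
            "stride_length_px and shoulder_height_px must be > 0, got "
            f"({stride_length_px}, {shoulder_height_px})"
        )
    return stride_length_px / shoulder_height_px


def stride_duration(stride: StrideRecord, limb: LimbId) -> float:
    """Seconds between the limb's initial and subsequent touchdown."""
    tds = stride.touchdowns(limb)
    if len(tds) < 2:
        raise ValidationError(f"limb {limb.value} has fewer than two touchdowns")
    fps = stride.clip.fps
    return tds[1].time(fps) - tds[0].time(fps)


def mean_stride_duration(stride: StrideRecord) -> float:
    """Mean of the four per-limb stride durations, seconds."""
    return float(np.mean([stride_duration(stride, limb) for limb in LIMB_ORDER]))


def relative_speed(rel_stride_length: float, mean_duration_s: float) -> float:
    """Relative stride length per second (shoulder heights / s)."""
    if mean_duration_s <= 0:
        raise ValueError(f"mean stride duration must be > 0, got {mean_duration_s}")
    return rel_stride_length / mean_duration_s


def _pair_phase(stride: StrideRecord, hind: LimbId) -> float:
    """Limb phase of one ipsilateral pair, percent of the hindlimb period."""
    fps = stride.clip.fps
    t_hind = stride.touchdowns(hind)[0].time(fps)
    period = stride_duration(stride, hind)
    fore_tds = [e.time(fps) for e in stride.touchdowns(hind.ipsilateral)]
    if not fore_tds:
        raise ValidationError(f"no {hind.ipsilateral.value} touchdown available")
    # first forelimb touchdown at or after the hindlimb touchdown; if both
    # digitized fore TDs precede it, the modulo wraps the earlier one forward
    later = [t for t in fore_tds if t >= t_hind]
    t_fore = min(later) if later else fore_tds[0]
    return ((t_fore - t_hind) % period) / period * 100.0


def limb_phase(stride: StrideRecord) -> tuple[float, float, float]:
    """(mean, left-pair, right-pair) limb phase in percent, each in [0, 100).

    The stride's limb phase is the mean of the left and right hind-fore
    pair phases (symmetrical-gait assumption); the per-pair values are
    returned for diagnostics.
    """
    left = _pair_phase(stride, LimbId.LH)
    right = _pair_phase(stride, LimbId.RH)
    return (left + right) / 2.0, left, right


def duty_factor(stride: StrideRecord, limb: LimbId) -> float:
    """Contact time over the limb's own stride duration, in (0, 1)."""
    fps = stride.clip.fps
    t1, t2 = (e.time(fps) for e in stride.touchdowns(limb))
    lo = stride.contact_liftoff(limb).time(fps)
    if not (t1 < lo < t2):
        raise ValidationError(
            f"limb {limb.value}: liftoff must fall strictly inside the touchdown bracket"
        )
    return (lo - t1) / (t2 - t1)


class _ContactPattern:
    """Periodic contact pattern of one limb: in contact on
    [TD + k*T, LO + k*T) for every integer k, with T the limb's own period."""

    def __init__(self, stride: StrideRecord, limb: LimbId) -> None:
        fps = stride.clip.fps
        self.td = stride.touchdowns(limb)[0].time(fps)
        self.lo = stride.contact_liftoff(limb).time(fps)
        self.period = stride_duration(stride, limb)
        self.contact_len = self.lo - self.td

    def in_contact(self, t: float) -> bool:
        return ((t - self.td) % self.period) < self.contact_len

    def breakpoints(self, w0: float, w1: float) -> list[float]:
        """All contact-state transition times strictly inside [w0, w1)."""
        ks = np.arange(
            np.floor((w0 - self.lo) / self.period) - 1,
            np.ceil((w1 - self.td) / self.period) + 1,
        )
        pts = []
        for k in ks:
            for t in (self.td + k * self.period, self.lo + k * self.period):
                if w0 < t < w1:
                    pts.append(t)
        return pts


def mean_nsl(stride: StrideRecord) -> tuple[float, tuple[float, ...]]:
    """Time-averaged number of supporting limbs over the stride window.

    Exact event-boundary sweep (no frame sampling): contact intervals of
    all four limbs are intersected over the reference-limb window
    [TD1, TD2); each limb's pattern is extended periodically with its own
    period where the window extends past its digitized events.

    Returns ``(mean_nsl, support_fractions)`` where ``support_fractions[k]``
    is the fraction of the window spent on exactly k supporting limbs
    (k = 0..4); the fractions sum to 1.
    """
    w0, w1 = stride.window
    if w1 <= w0:
        raise ValueError("stride window has non-positive length")

    patterns = [_ContactPattern(stride, limb) for limb in LIMB_ORDER]
    cuts = sorted({w0, w1}.union(t for p in patterns for t in p.breakpoints(w0, w1)))

    frac = np.zeros(5)
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = (a + b) / 2.0
        n = sum(p.in_contact(mid) for p in patterns)
        frac[n] += b - a
        total += (b - a) * n
    frac /= w1 - w0
    return total / (w1 - w0), tuple(frac)


def ipsilateral_dfai(
    duty: dict[LimbId, float], injured_limb: LimbId | None = None
) -> float:
    """Ipsilateral duty-factor asymmetry index, percent in [-100, 100].

    ``(L_df - R_df) / (0.5 (L_df + R_df)) * 100`` with L_df/R_df the side
    means of fore and hind duty factors.  With an injured limb, that
    limb's side is taken first instead, so negative values always mean a
    lower duty factor on the injured side.
    """
    for limb, d in duty.items():
        if not 0.0 < d < 1.0:
            raise ValueError(f"duty factor for {limb.value} must be in (0, 1), got {d}")
    l_df = (duty[LimbId.LH] + duty[LimbId.LF]) / 2.0
    r_df = (duty[LimbId.RH] + duty[LimbId.RF]) / 2.0
    first, second = (l_df, r_df)
    if injured_limb is not None and injured_limb.side == "R":
        first, second = r_df, l_df
    return (first - second) / (0.5 * (first + second)) * 100.0


def compute_stride_metrics(stride: StrideRecord) -> LimbKinematics:
    """All seven spatiotemporal metrics for one stride."""
    rsl = relative_stride_length(stride.stride_length_px, stride.shoulder_height_px)
    dur = mean_stride_duration(stride)
    phase, phase_l, phase_r = limb_phase(stride)
    duty = {limb: duty_factor(stride, limb) for limb in LIMB_ORDER}
    nsl, frac = mean_nsl(stride)
    dfai = ipsilateral_dfai(duty, stride.clip.injured_limb)
    return LimbKinematics(
        relative_stride_length=rsl,
        mean_stride_duration_s=dur,
        relative_speed=relative_speed(rsl, dur),
        limb_phase_pct=phase,
        mean_nsl=nsl,
        duty_factor=duty,
        ipsilateral_dfai_pct=dfai,
        limb_phase_left_pct=phase_l,
        limb_phase_right_pct=phase_r,
        support_fractions=frac,
    )


def metrics_table(strides: list[StrideRecord]) -> pd.DataFrame:
    """Per-stride metrics table consumed by the comparison stage.

    One row per stride with identifying keys, condition flags, the seven
    metrics, the four duty factors and the support-phase fractions.
    """
    rows = []
    for s in strides:
        k = compute_stride_metrics(s)
        row = {
            "clip_id": s.clip.clip_id,
            "individual_id": s.clip.individual_id,
            "stride_index": s.stride_index,
            "condition": s.clip.condition.value,
            "gsd_present": int(s.clip.gsd_present),
            "snare_present": int(s.clip.snare_present),
            "relative_stride_length": k.relative_stride_length,
            "mean_stride_duration_s": k.mean_stride_duration_s,
            "relative_speed": k.relative_speed,
            "limb_phase_pct": k.limb_phase_pct,
            "limb_phase_left_pct": k.limb_phase_left_pct,
            "limb_phase_right_pct": k.limb_phase_right_pct,
            "mean_nsl": k.mean_nsl,
            "ipsilateral_dfai_pct": k.ipsilateral_dfai_pct,
            "mean_duty_factor": k.mean_duty_factor,
        }
        for limb in LIMB_ORDER:
            row[f"duty_factor_{limb.value}"] = k.duty_factor[limb]
        for n in range(5):
            row[f"support_fraction_{n}"] = k.support_fractions[n]
        rows.append(row)
    return pd.DataFrame(rows)
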