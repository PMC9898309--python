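"""Domain types for digitized walking-gait data.

The unit of analysis is the *stride*: one full limb cycle bounded by two
successive touchdowns of a reference limb (left hindlimb by default).  A
stride is digitized as touchdown (TD) and liftoff (LO) events, one video
frame number each, for all four limbs, plus two in-frame pixel distances
(stride length and shoulder height) used to form dimensionless ratios.

Frames are the stored ground truth; times in seconds are always derived as
``frame / fps``.  Simultaneous events on different limbs are legal and are
ordered by the fixed limb order LH < LF < RH < RF for reproducibility.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class LimbId(enum.Enum):
    """The four limbs. Ipsilateral pairs are (LH, LF) and (RH, RF)."""

    LH = "LH"  # left hindlimb
    LF = "LF"  # left forelimb
    RH = "RH"  # right hindlimb
    RF = "RF"  # right forelimb

    @property
    def side(self) -> str:
        return "L" if self.value[0] == "L" else "R"

    @property
    def is_hind(self) -> bool:
        return self.value[1] == "H"

    @property
    def ipsilateral(self) -> "LimbId":
        """The other limb on the same side (hind <-> fore)."""
        other = {"LH": "LF", "LF": "LH", "RH": "RF", "RF": "RH"}
        return LimbId(other[self.value])


#: Fixed tie-break order for simultaneous events.
LIMB_ORDER = (LimbId.LH, LimbId.LF, LimbId.RH, LimbId.RF)


class EventKind(enum.Enum):
    TD = "TD"  # touchdown: foot contacts the ground
    LO = "LO"  # liftoff: foot leaves the ground


class TravelDirection(enum.Enum):
    LEFT_TO_RIGHT = "L2R"
    RIGHT_TO_LEFT = "R2L"


class Condition(enum.Enum):
    """Health condition category derived from the two presence flags."""

    HEALTHY = "healthy"
    GSD = "gsd"
    SNARE = "snare"
    GSD_SNARE = "gsd_snare"


class ValidationError(ValueError):
    """A record violates a stated invariant."""


class SchemaError(ValueError):
    """An input table is missing or mistypes a required column."""


@dataclass(frozen=True, order=True)
class FootfallEvent:
    """One limb touchdown or liftoff at a video frame.

    Ordering is (frame, limb order, kind) so that simultaneous events sort
    deterministically.
    """

    frame: int
    _limb_rank: int = field(init=False, repr=False, compare=True)
    _kind_rank: int = field(init=False, repr=False, compare=True)
    limb: LimbId = field(compare=False, default=LimbId.LH)
    kind: EventKind = field(compare=False, default=EventKind.TD)

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"event frame must be >= 0, got {self.frame}")
        object.__setattr__(self, "_limb_rank", LIMB_ORDER.index(self.limb))
        object.__setattr__(self, "_kind_rank", 0 if self.kind is EventKind.TD else 1)

    def time(self, fps: float) -> float:
        return self.frame / fps


@dataclass(frozen=True)
class ClipMeta:
    """Per-clip metadata shared by all strides digitized from one video."""

    clip_id: str
    individual_id: str
    fps: float
    gsd_present: bool = False
    snare_present: bool = False
    injured_limb: LimbId | None = None
    travel_direction: TravelDirection = TravelDirection.LEFT_TO_RIGHT

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"clip {self.clip_id}: fps must be > 0, got {self.fps}")
        if self.snare_present and self.injured_limb is None:
            raise ValidationError(
                f"clip {self.clip_id}: snare_present requires injured_limb"
            )
        if not self.snare_present and self.injured_limb is not None:
            raise ValidationError(
                f"clip {self.clip_id}: injured_limb given without snare_present"
            )

    @property
    def condition(self) -> Condition:
        return condition_category(self)


def condition_category(meta: ClipMeta) -> Condition:
    """Map the (GSD, snare) presence flags to the four-level condition."""
    if meta.gsd_present and meta.snare_present:
        return Condition.GSD_SNARE
    if meta.gsd_present:
        return Condition.GSD
    if meta.snare_present:
        return Condition.SNARE
    return Condition.HEALTHY


@dataclass(frozen=True)
class StrideRecord:
    """One reference-limb stride: its footfall events and pixel measures.

    Invariants (enforced at construction):

    * every limb has exactly two touchdowns, with exactly one liftoff
      strictly between them (contact, swing, next contact); additional
      liftoffs outside the bracket are allowed (a limb may be digitized
      lifting off again after its second touchdown);
    * the stride window is the half-open interval [TD1, TD2) of the
      reference limb — the closing touchdown belongs to the next stride;
    * both pixel distances are positive.
    """

    clip: ClipMeta
    stride_index: int
    events: tuple[FootfallEvent, ...]
    stride_length_px: float
    shoulder_height_px: float
    reference_limb: LimbId = LimbId.LH

    def __post_init__(self) -> None:
        if self.stride_length_px <= 0:
            raise ValidationError(self._tag(f"stride_length_px must be > 0, got {self.stride_length_px}"))
        if self.shoulder_height_px <= 0:
            raise ValidationError(self._tag(f"shoulder_height_px must be > 0, got {self.shoulder_height_px}"))
        object.__setattr__(self, "events", tuple(sorted(self.events)))
        for limb in LIMB_ORDER:
            tds = self.touchdowns(limb)
            if len(tds) != 2:
                raise ValidationError(
                    self._tag(f"limb {limb.value} has {len(tds)} touchdowns, expected 2")
                )
            inner = [e for e in self.liftoffs(limb) if tds[0].frame < e.frame < tds[1].frame]
            if len(inner) != 1:
                raise ValidationError(
                    self._tag(
                        f"limb {limb.value} needs exactly one liftoff strictly between "
                        f"its touchdowns (frames {tds[0].frame}..{tds[1].frame}), found {len(inner)}"
                    )
                )

    def _tag(self, msg: str) -> str:
        return f"clip {self.clip.clip_id} stride {self.stride_index}: {msg}"

    def touchdowns(self, limb: LimbId) -> list[FootfallEvent]:
        return [e for e in self.events if e.limb is limb and e.kind is EventKind.TD]

    def liftoffs(self, limb: LimbId) -> list[FootfallEvent]:
        return [e for e in self.events if e.limb is limb and e.kind is EventKind.LO]

    def contact_liftoff(self, limb: LimbId) -> FootfallEvent:
        """The liftoff bracketed by the limb's two touchdowns."""
        t1, t2 = self.touchdowns(limb)
        return next(e for e in self.liftoffs(limb) if t1.frame < e.frame < t2.frame)

    @property
    def window(self) -> tuple[float, float]:
        """Half-open stride window [TD1, TD2) of the reference limb, seconds."""
        t1, t2 = self.touchdowns(self.reference_limb)
        return t1.time(self.clip.fps), t2.time(self.clip.fps)


@dataclass(frozen=True)
class NeckLandmarks:
    """The three digitized body landmarks in one frame, pixel coordinates:
    base of the tail, withers (apex of the thoracic spinous processes) and
    apex of the occipital bone."""

    frame: int
    tail_base: tuple[float, float]
    withers: tuple[float, float]
    occiput: tuple[float, float]

    def __post_init__(self) -> None:
        pts = (self.tail_base, self.withers, self.occiput)
        for i in range(3):
            for j in range(i + 1, 3):
                if pts[i] == pts[j]:
                    raise ValidationError(
                        f"frame {self.frame}: neck landmarks must be pairwise distinct"
                    )
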