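"""Hildebrand limb-phase gait classification for symmetrical walking gaits.

Limb phase partitions symmetrical gaits into four bands, half-open and
closed on the left: [0, 25) lateral sequence lateral couplets (LSLC),
[25, 50) lateral sequence diagonal couplets (LSDC), [50, 75) diagonal
sequence diagonal couplets (DSDC) and [75, 100) diagonal sequence lateral
couplets (DSLC).  Phases at (or within a tolerance of) the anchors 0, 25,
50 and 75 additionally carry a named gait: pace, lateral-sequence
singlefoot, trot and diagonal-sequence singlefoot.  The compact Hildebrand
descriptor "DD:PP" pairs mean duty factor percent with limb phase percent
(a typical giraffe walk is 66:13).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class GaitBand(enum.Enum):
    LSLC = "LSLC"  # lateral sequence, lateral couplets
    LSDC = "LSDC"  # lateral sequence, diagonal couplets
    DSDC = "DSDC"  # diagonal sequence, diagonal couplets
    DSLC = "DSLC"  # diagonal sequence, lateral couplets


class NamedGait(enum.Enum):
    PACE = "pace"
    LATERAL_SINGLEFOOT = "lateral_singlefoot"
    TROT = "trot"
    DIAGONAL_SINGLEFOOT = "diagonal_singlefoot"


_BANDS = (GaitBand.LSLC, GaitBand.LSDC, GaitBand.DSDC, GaitBand.DSLC)
_ANCHORS = {
    0.0: NamedGait.PACE,
    25.0: NamedGait.LATERAL_SINGLEFOOT,
    50.0: NamedGait.TROT,
    75.0: NamedGait.DIAGONAL_SINGLEFOOT,
}

#: Default half-width, in percentage points, within which a limb phase is
#: close enough to an anchor to carry the named gait.
DEFAULT_TOLERANCE_PCT = 2.0


@dataclass(frozen=True)
class GaitClass:
    band: GaitBand
    named_gait: NamedGait | None = None


def classify_gait(
    limb_phase_pct: float, tolerance_pct: float = DEFAULT_TOLERANCE_PCT
) -> GaitClass:
    """Assign a limb phase in [0, 100) to its band and, near an anchor,
    its named gait.  The pace anchor at 0 also matches by wrap-around
    (phases >= 100 - tolerance)."""
    if not 0.0 <= limb_phase_pct < 100.0:
        raise ValueError(f"limb phase must be in [0, 100), got {limb_phase_pct}")
    if tolerance_pct < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance_pct}")
    band = _BANDS[int(limb_phase_pct // 25.0)]
    named = None
    for anchor, gait in _ANCHORS.items():
        dist = abs(limb_phase_pct - anchor)
        if anchor == 0.0:
            dist = min(dist, 100.0 - limb_phase_pct)
        if dist <= tolerance_pct:
            named = gait
            break
    return GaitClass(band=band, named_gait=named)


def hildebrand_descriptor(mean_duty_factor: float, limb_phase_pct: float) -> str:
    """Compact "duty factor % : limb phase %" gait descriptor, e.g. 66:13."""
    return f"{round(mean_duty_factor * 100):d}:{round(limb_phase_pct):d}"
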