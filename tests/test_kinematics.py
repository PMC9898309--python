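"""Spatiotemporal metric definitions, invariants and the NSL oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitkit import (
    ClipMeta,
    LimbId,
    ValidationError,
    compute_stride_metrics,
    duty_factor,
    ipsilateral_dfai,
    limb_phase,
    mean_nsl,
    mean_stride_duration,
    relative_speed,
    relative_stride_length,
    stride_duration,
)
from gaitkit.core import LIMB_ORDER

from conftest import build_stride, nsl_by_sampling, uniform_stride


class TestRelativeStrideLength:
    @pytest.mark.parametrize("a,b,expected", [(500, 500, 1.0), (630, 500, 1.26)])
    def test_ratio(self, a, b, expected):
        assert relative_stride_length(a, b) == pytest.approx(expected)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            relative_stride_length(0, 500)

    @given(
        a=st.floats(1.0, 1e4), b=st.floats(1.0, 1e4),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_uniform_rescaling(self, a, b, k):
        assert relative_stride_length(k * a, k * b) == pytest.approx(
            relative_stride_length(a, b), rel=1e-9
        )


class TestStrideDuration:
    def test_equal_durations_mean(self):
        stride = uniform_stride(period_frames=60)
        assert mean_stride_duration(stride) == pytest.approx(2.0)

    def test_mean_of_unequal_durations(self):
        # LH/LF at 60 frames (2.0 s), RH/RF at 66 frames (2.2 s) -> 2.1 s
        frames = {
            LimbId.LH: (0, 40, 60),
            LimbId.LF: (9, 49, 69),
            LimbId.RH: (30, 74, 96),
            LimbId.RF: (39, 83, 105),
        }
        stride = build_stride(frames)
        assert stride_duration(stride, LimbId.LH) == pytest.approx(2.0)
        assert stride_duration(stride, LimbId.RH) == pytest.approx(2.2)
        assert mean_stride_duration(stride) == pytest.approx(2.1)

    def test_69_frames_at_30fps_is_2_3_seconds(self):
        stride = uniform_stride(period_frames=69)
        assert stride_duration(stride, LimbId.LH) == pytest.approx(69 / 30)


class TestRelativeSpeed:
    @pytest.mark.parametrize(
        "rsl,dur,expected2dp", [(1.26, 2.31, 0.55), (1.13, 2.18, 0.52), (1.0, 1.0, 1.0)]
    )
    def test_printed_value_reproduction(self, rsl, dur, expected2dp):
        assert round(relative_speed(rsl, dur), 2) == pytest.approx(expected2dp)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            relative_speed(1.0, 0.0)


class TestLimbPhase:
    def test_simultaneous_ipsilateral_touchdowns_is_pace(self):
        stride = uniform_stride(phase_pct=0.0)
        mean, left, right = limb_phase(stride)
        assert mean == 0.0 and left == 0.0 and right == 0.0

    def test_nine_of_sixty_frames_is_fifteen_percent(self):
        stride = uniform_stride(period_frames=60, phase_pct=15.0)
        mean, left, right = limb_phase(stride)
        assert mean == pytest.approx(15.0)
        assert left == pytest.approx(15.0) and right == pytest.approx(15.0)

    def test_fore_touchdown_one_full_period_late_wraps_to_zero(self):
        frames = {
            LimbId.LH: (0, 40, 60),
            LimbId.LF: (60, 100, 120),  # exactly one LH period after LH TD
            LimbId.RH: (30, 70, 90),
            LimbId.RF: (90, 130, 150),
        }
        mean, left, right = limb_phase(build_stride(frames))
        assert left == pytest.approx(0.0)
        assert right == pytest.approx(0.0)

    def test_time_origin_invariance(self):
        stride = uniform_stride(period_frames=66, phase_pct=13.0)
        shifted = build_stride(
            {
                limb: tuple(
                    f + 250
                    for f in (
                        stride.touchdowns(limb)[0].frame,
                        stride.contact_liftoff(limb).frame,
                        stride.touchdowns(limb)[1].frame,
                    )
                )
                for limb in LIMB_ORDER
            }
        )
        assert limb_phase(shifted)[0] == pytest.approx(limb_phase(stride)[0])


class TestDutyFactor:
    def test_two_thirds_contact(self):
        # TD 0, LO 40, TD2 60 at 30 fps: 40/60 contact
        stride = build_stride(
            {
                LimbId.LH: (0, 40, 60),
                LimbId.LF: (9, 49, 69),
                LimbId.RH: (30, 70, 90),
                LimbId.RF: (39, 79, 99),
            }
        )
        assert duty_factor(stride, LimbId.LH) == pytest.approx(2 / 3)

    def test_midpoint_liftoff_is_half(self):
        stride = uniform_stride(period_frames=60, duty=0.5)
        assert duty_factor(stride, LimbId.LH) == pytest.approx(0.5)

    def test_liftoff_at_closing_touchdown_rejected(self):
        with pytest.raises(ValidationError):
            build_stride(
                {
                    LimbId.LH: (0, 60, 60),
                    LimbId.LF: (9, 49, 69),
                    LimbId.RH: (30, 70, 90),
                    LimbId.RF: (39, 79, 99),
                }
            )


class TestMeanNsl:
    def test_common_phase_gives_four_times_duty(self):
        # all four limbs down together for 0.6 of the cycle, airborne otherwise
        frames = {limb: (100, 136, 160) for limb in LIMB_ORDER}
        nsl, frac = mean_nsl(build_stride(frames))
        assert nsl == pytest.approx(4 * 0.6, abs=1e-9)
        assert frac[4] == pytest.approx(0.6, abs=1e-9)
        assert frac[0] == pytest.approx(0.4, abs=1e-9)

    @pytest.mark.parametrize("duty,phase", [(0.66, 13.0), (0.66, 15.0), (0.5, 25.0), (0.8, 10.0)])
    def test_equals_sum_of_duty_factors_for_periodic_strides(self, duty, phase):
        stride = uniform_stride(period_frames=300, duty=duty, phase_pct=phase)
        nsl, frac = mean_nsl(stride)
        duty_sum = sum(duty_factor(stride, limb) for limb in LIMB_ORDER)
        assert nsl == pytest.approx(duty_sum, abs=1e-9)
        assert sum(frac) == pytest.approx(1.0, abs=1e-12)

    @given(
        periods=st.lists(st.integers(50, 80), min_size=4, max_size=4),
        lo_fracs=st.lists(st.floats(0.2, 0.9), min_size=4, max_size=4),
        offsets=st.lists(st.integers(0, 40), min_size=4, max_size=4),
    )
    @settings(max_examples=40, deadline=None)
    def test_event_sweep_matches_sampling_oracle(self, periods, lo_fracs, offsets):
        frames = {}
        for limb, period, frac, off in zip(LIMB_ORDER, periods, lo_fracs, offsets):
            td1 = 100 + off
            lo = td1 + max(1, min(period - 1, int(round(frac * period))))
            frames[limb] = (td1, lo, td1 + period)
        stride = build_stride(frames)
        nsl, _ = mean_nsl(stride)
        assert nsl == pytest.approx(nsl_by_sampling(stride, 10_000), abs=8e-4)

    def test_support_fractions_partition_window(self):
        stride = uniform_stride(period_frames=66, duty=0.66, phase_pct=13.0)
        _, frac = mean_nsl(stride)
        assert sum(frac) == pytest.approx(1.0, abs=1e-12)
        assert all(f >= 0 for f in frac)


class TestIpsilateralDfai:
    def _duty(self, l, r):
        return {LimbId.LH: l, LimbId.LF: l, LimbId.RH: r, LimbId.RF: r}

    def test_contralateral_symmetry_is_zero(self):
        assert ipsilateral_dfai(self._duty(0.66, 0.66)) == 0.0

    def test_left_minus_right_convention(self):
        assert ipsilateral_dfai(self._duty(0.66, 0.60)) == pytest.approx(9.5238, abs=1e-3)

    def test_injured_right_limb_flips_orientation(self):
        duty = self._duty(0.66, 0.60)
        assert ipsilateral_dfai(duty, LimbId.RH) == pytest.approx(-9.5238, abs=1e-3)
        # injured left limb keeps left-first orientation
        assert ipsilateral_dfai(duty, LimbId.LH) == pytest.approx(9.5238, abs=1e-3)

    @given(l=st.floats(0.05, 0.95), r=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_left_right_swap(self, l, r):
        assert ipsilateral_dfai(self._duty(l, r)) == pytest.approx(
            -ipsilateral_dfai(self._duty(r, l)), abs=1e-9
        )

    def test_duty_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ipsilateral_dfai(self._duty(1.0, 0.6))


class TestComputeStrideMetrics:
    def test_relative_speed_consistency_by_construction(self):
        k = compute_stride_metrics(uniform_stride(period_frames=69, phase_pct=13.0))
        assert k.relative_speed == pytest.approx(
            k.relative_stride_length / k.mean_stride_duration_s
        )
        assert 0 <= k.mean_nsl <= 4
        assert 0 <= k.limb_phase_pct < 100
        assert all(0 < d < 1 for d in k.duty_factor.values())
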