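"""Domain types, CSV round trips and record validation."""

import pandas as pd
import pytest

from gaitkit import (
    ClipMeta,
    Condition,
    EventKind,
    FootfallEvent,
    LimbId,
    NeckLandmarks,
    SchemaError,
    StrideRecord,
    ValidationError,
    condition_category,
)
from gaitkit.io import read_events_table, read_neck_table, write_events_table

from conftest import uniform_stride


class TestLimbId:
    def test_four_distinct_limbs_with_ipsilateral_pairs(self):
        assert len(LimbId) == 4
        assert LimbId.LH.ipsilateral is LimbId.LF
        assert LimbId.RF.ipsilateral is LimbId.RH
        assert LimbId.LH.side == "L" and LimbId.RF.side == "R"


@pytest.mark.parametrize(
    "gsd,snare,expected",
    [
        (False, False, Condition.HEALTHY),
        (True, False, Condition.GSD),
        (False, True, Condition.SNARE),
        (True, True, Condition.GSD_SNARE),
    ],
)
def test_condition_category_enumeration(gsd, snare, expected):
    meta = ClipMeta(
        "c", "i", 30.0, gsd_present=gsd, snare_present=snare,
        injured_limb=LimbId.LH if snare else None,
    )
    assert condition_category(meta) is expected


class TestClipMeta:
    def test_snare_requires_injured_limb(self):
        with pytest.raises(ValidationError, match="injured_limb"):
            ClipMeta("c", "i", 30.0, snare_present=True)

    def test_injured_limb_requires_snare(self):
        with pytest.raises(ValidationError, match="injured_limb"):
            ClipMeta("c", "i", 30.0, injured_limb=LimbId.LH)

    def test_nonpositive_fps_rejected(self):
        with pytest.raises(ValidationError, match="fps"):
            ClipMeta("c", "i", 0.0)


class TestStrideValidation:
    def test_valid_stride_has_sixteen_events(self):
        stride = uniform_stride()
        assert len(stride.events) == 16
        for limb in LimbId:
            assert len(stride.touchdowns(limb)) == 2
            assert len(stride.liftoffs(limb)) == 2

    def test_missing_second_touchdown_names_the_limb(self):
        stride = uniform_stride()
        events = tuple(
            e for e in stride.events
            if not (e.limb is LimbId.RH and e.kind is EventKind.TD
                    and e is stride.touchdowns(LimbId.RH)[1])
        )
        with pytest.raises(ValidationError, match="RH"):
            StrideRecord(
                clip=stride.clip, stride_index=0, events=events,
                stride_length_px=630, shoulder_height_px=500,
            )

    def test_liftoff_on_touchdown_frame_rejected(self):
        stride = uniform_stride()
        bad = []
        for e in stride.events:
            if e.limb is LimbId.LF and e.kind is EventKind.LO and e is stride.contact_liftoff(LimbId.LF):
                bad.append(FootfallEvent(frame=stride.touchdowns(LimbId.LF)[1].frame,
                                         limb=LimbId.LF, kind=EventKind.LO))
            else:
                bad.append(e)
        with pytest.raises(ValidationError, match="LF"):
            StrideRecord(clip=stride.clip, stride_index=0, events=tuple(bad),
                         stride_length_px=630, shoulder_height_px=500)

    @pytest.mark.parametrize("field,value", [("stride_length_px", 0.0), ("shoulder_height_px", -5.0)])
    def test_nonpositive_pixel_measures_rejected(self, field, value):
        stride = uniform_stride()
        kwargs = dict(stride_length_px=630.0, shoulder_height_px=500.0)
        kwargs[field] = value
        with pytest.raises(ValidationError, match=field):
            StrideRecord(clip=stride.clip, stride_index=0, events=stride.events, **kwargs)

    def test_negative_frame_rejected(self):
        with pytest.raises(ValidationError, match="frame"):
            FootfallEvent(frame=-1, limb=LimbId.LH, kind=EventKind.TD)

    def test_stride_window_is_reference_limb_touchdown_interval(self):
        stride = uniform_stride(period_frames=60)
        w0, w1 = stride.window
        assert w0 == pytest.approx(100 / 30.0)
        assert w1 == pytest.approx(160 / 30.0)


class TestNeckLandmarks:
    def test_coincident_points_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            NeckLandmarks(0, (1.0, 1.0), (1.0, 1.0), (3.0, 4.0))


class TestEventsCsvRoundTrip:
    def test_write_then_read_reproduces_all_fields(self, tmp_path):
        strides = [
            uniform_stride(stride_index=0),
            uniform_stride(
                period_frames=66, duty=0.7, phase_pct=13.0, stride_index=1,
                clip=ClipMeta("clip1", "ind1", 30.0, gsd_present=True,
                              snare_present=True, injured_limb=LimbId.RF),
            ),
        ]
        path = tmp_path / "events.csv"
        write_events_table(strides, path)
        back = read_events_table(path)
        assert len(back) == 2
        for orig, rec in zip(strides, back):
            assert rec.clip == orig.clip
            assert rec.events == orig.events
            assert rec.stride_length_px == orig.stride_length_px
            assert rec.shoulder_height_px == orig.shoulder_height_px

    def test_missing_column_raises_schema_error_naming_it(self, tmp_path):
        path = tmp_path / "events.csv"
        write_events_table([uniform_stride()], path)
        df = pd.read_csv(path).drop(columns=["shoulder_height_px"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="shoulder_height_px"):
            read_events_table(path)

    def test_missing_touchdown_in_file_names_clip_and_limb(self, tmp_path):
        path = tmp_path / "events.csv"
        write_events_table([uniform_stride()], path)
        df = pd.read_csv(path)
        rh_td = df[(df.limb == "RH") & (df.event == "TD")].index[-1]
        df.drop(index=rh_td).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="clip0.*RH|RH"):
            read_events_table(path)

    def test_nonpositive_fps_in_file_rejected(self, tmp_path):
        path = tmp_path / "events.csv"
        write_events_table([uniform_stride()], path)
        df = pd.read_csv(path)
        df["fps"] = 0
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="fps"):
            read_events_table(path)


class TestNeckCsv:
    def test_requires_landmarks_or_angle_column(self, tmp_path):
        path = tmp_path / "neck.csv"
        pd.DataFrame({"clip_id": ["c"], "stride_index": [0], "frame": [0]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="angle_deg"):
            read_neck_table(path)

    def test_angle_table_accepted(self, tmp_path):
        path = tmp_path / "neck.csv"
        pd.DataFrame(
            {"clip_id": ["c"], "stride_index": [0], "frame": [0], "angle_deg": [188.0]}
        ).to_csv(path, index=False)
        df = read_neck_table(path)
        assert df["angle_deg"].iloc[0] == 188.0
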