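"""Sequence collapsing, diel classification and nocturnal timing."""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armadiel.errors import ContractError, ValidationError
from armadiel.ingest import (
    CameraDeployment,
    DielClass,
    PhotoRecord,
    build_events,
    classify_diel,
    collapse_sequences,
    filter_nocturnal_for_timing,
    minutes_after_sunset,
    read_photos_csv,
    write_events_csv,
)
from armadiel.solar import GeoPoint, anchor_solar_day

CST = timezone(timedelta(minutes=-360))
FAYETTEVILLE = GeoPoint(36.066, -94.158)
ANCHOR = anchor_solar_day(2020, 12, FAYETTEVILLE, -360)


def photos_at(*offsets_minutes: float, t0: datetime | None = None) -> list[PhotoRecord]:
    t0 = t0 or datetime(2020, 12, 3, 10, 0, tzinfo=CST)
    return [
        PhotoRecord("cam1", t0 + timedelta(minutes=m), "armadillo") for m in offsets_minutes
    ]


def at_clock(hour: int, minute: int, second: int = 0, day: int = 3) -> datetime:
    return datetime(2020, 12, day, hour, minute, second, tzinfo=CST)


class TestCollapseSequences:
    def test_single_burst_is_one_event(self):
        events = collapse_sequences(photos_at(0.0, 1 / 60, 2 / 60))
        assert len(events) == 1
        assert events[0].n_photos == 3

    def test_gap_beyond_threshold_splits(self):
        events = collapse_sequences(photos_at(0.0, 6.0))
        assert len(events) == 2

    def test_chaining_rule_extends_past_first_photo_window(self):
        # 0, +4, +8 minutes: each within 5 min of the previous photo
        events = collapse_sequences(photos_at(0.0, 4.0, 8.0))
        assert len(events) == 1
        assert events[0].n_photos == 3

    def test_event_timed_at_first_photo(self):
        t0 = datetime(2020, 12, 3, 10, 0, tzinfo=CST)
        events = collapse_sequences(photos_at(0.0, 2.0, 9.0, t0=t0))
        assert events[0].event_time == t0
        assert events[1].event_time == t0 + timedelta(minutes=9)

    def test_unsorted_photos_rejected(self):
        photos = photos_at(5.0, 0.0)
        with pytest.raises(ValidationError):
            collapse_sequences(photos)

    def test_mixed_cameras_rejected(self):
        photos = photos_at(0.0) + [
            PhotoRecord("cam2", datetime(2020, 12, 3, 11, 0, tzinfo=CST), "armadillo")
        ]
        with pytest.raises(ValidationError):
            collapse_sequences(photos)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        gaps=st.lists(st.floats(min_value=0.0, max_value=30.0), min_size=1, max_size=40),
        threshold=st.floats(min_value=0.5, max_value=10.0),
    )
    def test_partition_and_idempotence(self, gaps, threshold):
        """Events partition the photos; re-collapsing first-photo times with
        the same gap is a fixed point."""
        offsets = [0.0]
        for g in gaps:
            offsets.append(offsets[-1] + g)
        photos = photos_at(*offsets)
        events = collapse_sequences(photos, gap_minutes=threshold)
        assert sum(e.n_photos for e in events) == len(photos)
        assert len(events) <= len(photos)
        starts = [PhotoRecord("cam1", e.event_time, "armadillo") for e in events]
        again = collapse_sequences(starts, gap_minutes=threshold)
        assert [e.event_time for e in again] == [e.event_time for e in events]
        assert all(e.n_photos == 1 for e in again)


class TestClassifyDiel:
    def test_event_at_sunrise_instant_is_day(self):
        assert classify_diel(ANCHOR.sunrise_local, ANCHOR) is DielClass.DAY

    def test_event_at_sunset_instant_is_night(self):
        assert classify_diel(ANCHOR.sunset_local, ANCHOR) is DielClass.NIGHT

    def test_one_minute_around_sunset(self):
        before = ANCHOR.sunset_local - timedelta(minutes=1)
        after = ANCHOR.sunset_local + timedelta(minutes=1)
        assert classify_diel(before, ANCHOR) is DielClass.DAY
        assert classify_diel(after, ANCHOR) is DielClass.NIGHT

    def test_midnight_is_night(self):
        assert classify_diel(at_clock(0, 0), ANCHOR) is DielClass.NIGHT

    def test_classification_uses_anchor_clock_times_not_event_date(self):
        # anchor is Dec 15; an event on Dec 3 is judged by the anchor's clock
        noon = at_clock(12, 0)
        assert classify_diel(noon, ANCHOR) is DielClass.DAY

    def test_every_event_gets_exactly_one_class(self):
        for hour in range(24):
            assert classify_diel(at_clock(hour, 0), ANCHOR) in (
                DielClass.DAY,
                DielClass.NIGHT,
            )


class TestMinutesAfterSunset:
    def test_one_minute_after_sunset(self):
        t = ANCHOR.sunset_local + timedelta(minutes=1)
        assert minutes_after_sunset(t, ANCHOR) == pytest.approx(1.0, abs=1e-9)

    def test_two_hours_after_sunset(self):
        t = ANCHOR.sunset_local + timedelta(hours=2)
        assert minutes_after_sunset(t, ANCHOR) == pytest.approx(120.0, abs=1e-9)

    def test_after_midnight_measured_from_previous_evening(self):
        # 05:00 with a 17:10 sunset is 6h50m + 5h = 710 minutes
        sunset_clock = ANCHOR.sunset_clock_minutes
        t = at_clock(5, 0)
        expected = (1440.0 - sunset_clock) + 300.0
        assert minutes_after_sunset(t, ANCHOR) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(710.0, abs=10.0)  # sunset near 17:10 CST

    def test_day_event_is_contract_error(self):
        with pytest.raises(ContractError):
            minutes_after_sunset(at_clock(12, 0), ANCHOR)


def test_filter_nocturnal_keeps_exactly_night_events():
    from armadiel.ingest import DetectionEvent

    def ev(diel):
        return DetectionEvent("s", "c", at_clock(12, 0), 1, diel_class=diel)

    mixed = [ev(DielClass.DAY)] * 3 + [ev(DielClass.NIGHT)] * 2
    kept = filter_nocturnal_for_timing(mixed)
    assert len(kept) == 2
    assert all(e.diel_class is DielClass.NIGHT for e in kept)
    assert filter_nocturnal_for_timing([ev(DielClass.DAY)]) == []


class TestBuildEvents:
    @staticmethod
    def deployment():
        return {
            "cam1": CameraDeployment(
                "cam1", "siteA", FAYETTEVILLE, date(2020, 10, 1), date(2021, 3, 30)
            )
        }

    @staticmethod
    def photo_frame(rows):
        return pd.DataFrame(
            {
                "camera_id": [r[0] for r in rows],
                "timestamp_local": [r[1] for r in rows],
                "species": [r[2] for r in rows],
            }
        )

    def test_species_filter_ignores_other_labels(self):
        df = self.photo_frame(
            [
                ("cam1", at_clock(12, 0), "armadillo"),
                ("cam1", at_clock(12, 0, 30), "deer"),
            ]
        )
        events = build_events(df, self.deployment(), "armadillo")
        assert len(events) == 1
        assert events[0].n_photos == 1

    def test_unknown_camera_rejected(self):
        df = self.photo_frame([("ghost", at_clock(12, 0), "armadillo")])
        with pytest.raises(ValidationError):
            build_events(df, self.deployment(), "armadillo")

    def test_photo_outside_deployment_window_rejected(self):
        df = self.photo_frame(
            [("cam1", datetime(2021, 5, 1, 12, 0, tzinfo=CST), "armadillo")]
        )
        with pytest.raises(ValidationError):
            build_events(df, self.deployment(), "armadillo")

    def test_night_events_get_timing_and_day_events_do_not(self):
        df = self.photo_frame(
            [
                ("cam1", at_clock(12, 0), "armadillo"),
                ("cam1", at_clock(22, 0), "armadillo"),
            ]
        )
        events = build_events(df, self.deployment(), "armadillo")
        by_class = {e.diel_class: e for e in events}
        assert by_class[DielClass.DAY].minutes_after_sunset is None
        assert by_class[DielClass.NIGHT].minutes_after_sunset > 0

    def test_events_csv_round_trip(self, tmp_path):
        df = self.photo_frame(
            [
                ("cam1", at_clock(12, 0), "armadillo"),
                ("cam1", at_clock(22, 0), "armadillo"),
            ]
        )
        events = build_events(df, self.deployment(), "armadillo")
        out = tmp_path / "events.csv"
        write_events_csv(events, out)
        back = pd.read_csv(out)
        assert list(back["diel_class"]) == [e.diel_class.value for e in events]
        assert back["minutes_after_sunset"].notna().sum() == 1


def test_read_photos_csv_requires_utc_offset(tmp_path):
    p = tmp_path / "photos.csv"
    p.write_text(
        "camera_id,timestamp_iso8601,species\ncam1,2020-12-03T12:00:00,armadillo\n"
    )
    with pytest.raises(ValidationError):
        read_photos_csv(p)


def test_read_photos_csv_mixed_offsets_reconciled_through_utc(tmp_path):
    # the same instant written in CST and CDT must collapse to one event
    p = tmp_path / "photos.csv"
    p.write_text(
        "camera_id,timestamp_iso8601,species\n"
        "cam1,2020-10-20T12:00:00-06:00,armadillo\n"
        "cam1,2020-10-20T13:00:30-05:00,armadillo\n"
    )
    df = read_photos_csv(p)
    dep = {
        "cam1": CameraDeployment(
            "cam1", "siteA", FAYETTEVILLE, date(2020, 10, 1), date(2021, 3, 30)
        )
    }
    events = build_events(df, dep, "armadillo")
    assert len(events) == 1
    assert events[0].n_photos == 2
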