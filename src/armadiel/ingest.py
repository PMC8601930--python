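"""Photo records -> independent detection events with diel class and timing.

Camera-trap photos arrive as labeled rows (camera, timestamp, species).  The
pipeline collapses consecutive photos of the same species at the same camera
into independent detection events using a chaining rule: a photo joins the
current event iff it falls within ``gap_minutes`` (default 5) of the previous
photo in that event.  Each event is timed at its first photo, classified DAY
or NIGHT against the monthly 15th-day solar anchor for the camera's location,
and, when nocturnal, given a minutes-after-sunset value measured from the
governing sunset (the same evening for post-sunset events, the previous
evening for after-midnight events).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError, ValidationError
from .solar import GeoPoint, SolarDay, anchor_solar_day, solar_events

DEFAULT_GAP_MINUTES = 5.0

__all__ = [
    "DielClass",
    "PhotoRecord",
    "CameraDeployment",
    "DetectionEvent",
    "collapse_sequences",
    "classify_diel",
    "minutes_after_sunset",
    "filter_nocturnal_for_timing",
    "build_events",
    "read_photos_csv",
    "read_deployments_csv",
    "events_to_frame",
    "write_events_csv",
]


class DielClass(str, enum.Enum):
    DAY = "DAY"
    NIGHT = "NIGHT"


@dataclass(frozen=True)
class PhotoRecord:
    """One labeled camera photo; the timestamp carries its own UTC offset."""

    camera_id: str
    timestamp_local: datetime
    species: str

    def __post_init__(self) -> None:
        if self.timestamp_local.tzinfo is None:
            raise ValidationError(f"photo timestamp {self.timestamp_local} lacks a UTC offset")
        if not self.species:
            raise ValidationError("photo species label is empty")


@dataclass(frozen=True)
class CameraDeployment:
    """One camera placement: site membership, location and active date range."""

    camera_id: str
    site_id: str
    point: GeoPoint
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValidationError(
                f"camera {self.camera_id}: start {self.start_date} after end {self.end_date}"
            )
        if self.trap_nights < 1:
            raise ValidationError(f"camera {self.camera_id}: fewer than one trap night")

    @property
    def trap_nights(self) -> int:
        """Whole nights of effort (end - start)."""
        return (self.end_date - self.start_date).days


@dataclass(frozen=True)
class DetectionEvent:
    """One independent detection, timed at the first photo of its sequence."""

    site_id: str
    camera_id: str
    event_time: datetime
    n_photos: int
    diel_class: DielClass | None = None
    minutes_after_sunset: float | None = None

    @property
    def month(self) -> tuple[int, int]:
        """(year, month) of the event's calendar date in its own offset."""
        return (self.event_time.year, self.event_time.month)


def collapse_sequences(
    photos: Sequence[PhotoRecord],
    gap_minutes: float = DEFAULT_GAP_MINUTES,
    site_id: str = "",
) -> list[DetectionEvent]:
    """Collapse sorted photos of one camera/species into detection events.

    Chaining rule: a photo extends the current event iff its timestamp is at
    most ``gap_minutes`` after the *previous* photo of that event, so a slow
    animal triggering every 4 minutes stays one event regardless of total
    span.  Events partition the photos and are timed at their first photo.

    Raises
    ------
    ValidationError
        If photos are unsorted or span more than one camera or species.
    """
    if gap_minutes <= 0:
        raise ValidationError(f"gap_minutes must be positive, got {gap_minutes}")
    if not photos:
        return []
    if len({p.camera_id for p in photos}) > 1:
        raise ValidationError("collapse_sequences requires a single camera_id")
    if len({p.species for p in photos}) > 1:
        raise ValidationError("collapse_sequences requires a single species")

    gap = timedelta(minutes=gap_minutes)
    events: list[DetectionEvent] = []
    first = photos[0]
    prev_ts = first.timestamp_local
    count = 1
    for photo in photos[1:]:
        if photo.timestamp_local < prev_ts:
            raise ValidationError("photos must be sorted ascending by timestamp")
        if photo.timestamp_local - prev_ts <= gap:
            count += 1
        else:
            events.append(
                DetectionEvent(site_id, first.camera_id, first.timestamp_local, count)
            )
            first = photo
            count = 1
        prev_ts = photo.timestamp_local
    events.append(DetectionEvent(site_id, first.camera_id, first.timestamp_local, count))
    return events


def _clock_minutes_in_offset(t: datetime, utc_offset_minutes: int) -> tuple[float, date]:
    """Clock time (fractional minutes past midnight) and calendar date of `t`
    expressed in the given fixed offset."""
    local = t.astimezone(timezone(timedelta(minutes=utc_offset_minutes)))
    minutes = local.hour * 60.0 + local.minute + local.second / 60.0 + local.microsecond / 6e7
    return minutes, local.date()


def classify_diel(event_time: datetime, anchor: SolarDay) -> DielClass:
    """DAY iff anchor-sunrise <= event clock time < anchor-sunset.

    Comparison is between clock times (the monthly-anchor convention): the
    event instant is converted into the anchor's UTC offset and its wall-clock
    time compared with the anchor's unrounded sunrise/sunset clock times.  The
    sunrise boundary is inclusive to DAY and the sunset boundary exclusive, a
    half-open convention that classifies every instant exactly once.
    """
    t, _ = _clock_minutes_in_offset(event_time, anchor.utc_offset_minutes)
    if anchor.sunrise_clock_minutes <= t < anchor.sunset_clock_minutes:
        return DielClass.DAY
    return DielClass.NIGHT


def minutes_after_sunset(event_time: datetime, anchor: SolarDay) -> float:
    """Minutes from the governing sunset to a nocturnal event.

    Events after sunset and before midnight are measured from the same
    evening's (anchor) sunset; events after midnight and before sunrise are
    measured from the previous evening's sunset, i.e. across midnight.

    Raises
    ------
    ContractError
        If the event time classifies as DAY under the same anchor.
    """
    t, _ = _clock_minutes_in_offset(event_time, anchor.utc_offset_minutes)
    sunrise = anchor.sunrise_clock_minutes
    sunset = anchor.sunset_clock_minutes
    if sunrise <= t < sunset:
        raise ContractError("minutes_after_sunset called on a DAY-classified event")
    if t >= sunset:
        return t - sunset
    # after midnight, before sunrise: governed by the previous evening's sunset
    return (1440.0 - sunset) + t


def filter_nocturnal_for_timing(events: Iterable[DetectionEvent]) -> list[DetectionEvent]:
    """Keep exactly the NIGHT-classified events (the timing-model subset)."""
    return [e for e in events if e.diel_class is DielClass.NIGHT]


def _classify_events(
    events: Iterable[DetectionEvent],
    point: GeoPoint,
    utc_offset_minutes: int,
    per_date: bool = False,
) -> list[DetectionEvent]:
    """Attach diel class and nocturnal timing, caching one anchor per month.

    `per_date=True` switches to classifying against each event's own date's
    solar times instead of the monthly anchor (off by default).
    """
    tz = timezone(timedelta(minutes=utc_offset_minutes))
    anchors: dict[tuple[int, int] | date, SolarDay] = {}
    out: list[DetectionEvent] = []
    for ev in events:
        local_ts = ev.event_time.astimezone(tz)
        local_date = local_ts.date()
        key = local_date if per_date else (local_date.year, local_date.month)
        if key not in anchors:
            if per_date:
                anchors[key] = solar_events(local_date, point, utc_offset_minutes)
            else:
                anchors[key] = anchor_solar_day(
                    local_date.year, local_date.month, point, utc_offset_minutes
                )
        anchor = anchors[key]
        diel = classify_diel(local_ts, anchor)
        mas = minutes_after_sunset(local_ts, anchor) if diel is DielClass.NIGHT else None
        # event_time normalized to the pipeline's fixed offset so the stored
        # month always matches the anchor month used for classification
        out.append(
            replace(ev, event_time=local_ts, diel_class=diel, minutes_after_sunset=mas)
        )
    return out


def build_events(
    photos: pd.DataFrame,
    deployments: dict[str, CameraDeployment],
    species: str,
    gap_minutes: float = DEFAULT_GAP_MINUTES,
    utc_offset_minutes: int = -360,
    per_date_classification: bool = False,
    validate_deployment_window: bool = True,
) -> list[DetectionEvent]:
    """Full ingest: filter species, collapse per camera, classify, time.

    `photos` is the raw photo table (camera_id, timestamp_local as tz-aware
    datetimes, species).  Rows for other species are ignored; photos from
    cameras absent from `deployments` are a validation error, as are photos
    outside their camera's active window (when validation is enabled).
    """
    target = photos.loc[photos["species"] == species]
    events: list[DetectionEvent] = []
    for camera_id, grp in target.groupby("camera_id", sort=True):
        if camera_id not in deployments:
            raise ValidationError(f"photo references unknown camera {camera_id!r}")
        dep = deployments[camera_id]
        grp = grp.sort_values("timestamp_local")
        records = [
            PhotoRecord(str(camera_id), ts.to_pydatetime(), species)
            for ts in grp["timestamp_local"]
        ]
        if validate_deployment_window:
            for rec in records:
                d = rec.timestamp_local.date()
                if not (dep.start_date <= d <= dep.end_date):
                    raise ValidationError(
                        f"photo at {rec.timestamp_local.isoformat()} outside deployment "
                        f"window of camera {camera_id!r} ({dep.start_date}..{dep.end_date})"
                    )
        cam_events = collapse_sequences(records, gap_minutes, site_id=dep.site_id)
        events.extend(
            _classify_events(cam_events, dep.point, utc_offset_minutes, per_date_classification)
        )
    events.sort(key=lambda e: (e.site_id, e.camera_id, e.event_time))
    return events


# ---------------------------------------------------------------------------
# CSV interfaces

def read_photos_csv(path: str | Path) -> pd.DataFrame:
    """Photo table with columns camera_id, timestamp_iso8601, species."""
    df = pd.read_csv(path, dtype={"camera_id": str, "species": str})
    required = {"camera_id", "timestamp_iso8601", "species"}
    if not required.issubset(df.columns):
        raise ValidationError(f"photo CSV missing columns {sorted(required - set(df.columns))}")
    raw = df["timestamp_iso8601"].astype(str)
    if raw.str.fullmatch(r".*([+-]\d{2}:?\d{2}|Z)").sum() != len(raw):
        raise ValidationError("photo timestamps must carry a UTC offset")
    # mixed offsets (e.g. across a DST transition) are reconciled through UTC
    ts = pd.to_datetime(raw, utc=True, format="ISO8601")
    return pd.DataFrame(
        {"camera_id": df["camera_id"], "timestamp_local": ts, "species": df["species"]}
    )


def read_deployments_csv(path: str | Path) -> dict[str, CameraDeployment]:
    """Deployment table keyed by camera_id."""
    df = pd.read_csv(path, dtype={"camera_id": str, "site_id": str})
    required = {"camera_id", "site_id", "latitude", "longitude", "start_date", "end_date"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"deployment CSV missing columns {sorted(required - set(df.columns))}"
        )
    out: dict[str, CameraDeployment] = {}
    for row in df.itertuples(index=False):
        if row.camera_id in out:
            raise ValidationError(f"duplicate camera_id {row.camera_id!r} in deployments")
        out[row.camera_id] = CameraDeployment(
            camera_id=row.camera_id,
            site_id=row.site_id,
            point=GeoPoint(float(row.latitude), float(row.longitude)),
            start_date=pd.Timestamp(row.start_date).date(),
            end_date=pd.Timestamp(row.end_date).date(),
        )
    return out


def events_to_frame(events: Sequence[DetectionEvent]) -> pd.DataFrame:
    """Events as a tidy table (month stamped as 'YYYY-MM')."""
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in events],
            "camera_id": [e.camera_id for e in events],
            "event_time_iso8601": [e.event_time.isoformat() for e in events],
            "n_photos": [e.n_photos for e in events],
            "month": [f"{e.month[0]:04d}-{e.month[1]:02d}" for e in events],
            "diel_class": [e.diel_class.value if e.diel_class else "" for e in events],
            "minutes_after_sunset": [e.minutes_after_sunset for e in events],
        }
    )


def write_events_csv(events: Sequence[DetectionEvent], path: str | Path) -> None:
    df = events_to_frame(events)
    df["minutes_after_sunset"] = [
        "" if m is None else f"{m:.3f}" for m in df["minutes_after_sunset"]
    ]
    df.to_csv(path, index=False)
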