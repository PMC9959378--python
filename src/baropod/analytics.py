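"""App-side run analytics: pressures, steps, cadence, GPS metrics, surveys.

The statistics mirror what the companion mobile app archives for every run:
average per-foot pressure, a left/right balance ratio, step count and cadence
recovered from the pressure stream, and GPS distance / average speed.

Definitions used here:

* **average pressure** — the mean over *transmitted* frames of the per-frame
  mean of the 16 sensor percents.  Gated (suppressed) frames never reach the
  app, so they do not enter the statistic.
* **step detection** — a step event at each upward crossing of the per-frame
  maximum through ``on_threshold``.  Because the noise gate removes
  swing-phase frames entirely, an inter-frame gap longer than the refractory
  window counts as a drop below threshold (the detector resets); crossings
  inside the refractory window of the previous event are suppressed.
* **distance** — summed haversine between consecutive fixes on a sphere of
  radius 6,371,000 m; average speed is distance over elapsed time.
* **survey aggregation** — per-aspect arithmetic means and the grand mean of
  a raters × aspects table on the 1–5 scale, reported to 2 decimals
  (half-up), matching how user-study tables are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .firmware import PercentVector

__all__ = [
    "GpsPoint",
    "RunSession",
    "RunSummary",
    "SurveyTable",
    "SurveySummary",
    "EmptyDataError",
    "OrderingError",
    "average_pressure",
    "detect_steps",
    "track_metrics",
    "summarize_run",
    "summarize_survey",
    "haversine_m",
    "read_gps_csv",
    "read_gpx",
    "read_survey_csv",
    "table4_survey",
]

EARTH_RADIUS_M = 6_371_000.0


class EmptyDataError(ValueError):
    """An operation received no data to work on."""


class OrderingError(ValueError):
    """Timestamps are not monotonically increasing."""


@dataclass(frozen=True)
class GpsPoint:
    lat: float
    lon: float
    t_ms: int

    def __post_init__(self) -> None:
        if not abs(self.lat) <= 90:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not abs(self.lon) <= 180:
            raise ValueError(f"longitude out of range: {self.lon}")


@dataclass
class RunSession:
    """Decoded per-foot percent streams plus GPS track and metadata."""

    left: list[PercentVector]
    right: list[PercentVector]
    gps_track: list[GpsPoint] = field(default_factory=list)
    started_at: int = 0
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RunSummary:
    avg_pressure_left: float
    avg_pressure_right: float
    balance_ratio: float
    step_count: int
    cadence_spm: float
    distance_m: float
    avg_speed_m_s: float
    duration_ms: int

    def as_dict(self) -> dict:
        return {
            "avg_pressure_left": self.avg_pressure_left,
            "avg_pressure_right": self.avg_pressure_right,
            "balance_ratio": self.balance_ratio,
            "step_count": self.step_count,
            "cadence_spm": self.cadence_spm,
            "distance_m": self.distance_m,
            "avg_speed_m_s": self.avg_speed_m_s,
            "duration_ms": self.duration_ms,
        }


def _check_ordered(stream: Sequence[PercentVector]) -> None:
    for a, b in zip(stream, stream[1:]):
        if b.timestamp_ms <= a.timestamp_ms:
            raise OrderingError(
                f"timestamps not strictly increasing: {a.timestamp_ms} -> {b.timestamp_ms}"
            )


def average_pressure(stream: Sequence[PercentVector]) -> float:
    """Mean over frames of the per-frame mean of the 16 sensor percents."""
    if not stream:
        raise EmptyDataError("cannot average an empty frame stream")
    return float(np.mean([np.mean(v.values) for v in stream]))


def detect_steps(
    stream: Sequence[PercentVector],
    on_threshold: int = 20,
    refractory_ms: float = 150.0,
) -> list[int]:
    """Step-onset timestamps from upward threshold crossings of the frame max.

    See the module docstring for the gap-reset rule that makes the detector
    robust to gated (absent) swing-phase frames.
    """
    _check_ordered(stream)
    events: list[int] = []
    prev_below = True  # stream start counts as below threshold
    prev_t: int | None = None
    for v in stream:
        m = max(v.values)
        gap_reset = prev_t is not None and v.timestamp_ms - prev_t > refractory_ms
        if m >= on_threshold and (prev_below or gap_reset):
            if not events or v.timestamp_ms - events[-1] > refractory_ms:
                events.append(v.timestamp_ms)
        prev_below = m < on_threshold
        prev_t = v.timestamp_ms
    return events


def haversine_m(p: GpsPoint, q: GpsPoint) -> float:
    """Great-circle distance in meters on the mean Earth sphere."""
    lat1, lon1, lat2, lon2 = map(np.radians, (p.lat, p.lon, q.lat, q.lon))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def track_metrics(track: Sequence[GpsPoint]) -> tuple[float, float]:
    """Total haversine distance (m) and average speed (m/s) of a GPS track."""
    if len(track) < 2:
        raise EmptyDataError("track_metrics needs at least 2 GPS points")
    times = [p.t_ms for p in track]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise OrderingError("GPS timestamps must be strictly increasing")
    distance = sum(haversine_m(a, b) for a, b in zip(track, track[1:]))
    elapsed_s = (times[-1] - times[0]) / 1000.0
    return distance, distance / elapsed_s


def summarize_run(
    session: RunSession,
    on_threshold: int = 20,
    refractory_ms: float = 150.0,
) -> RunSummary:
    """Assemble the archived per-run statistics from a decoded session."""
    for foot, stream in (("left", session.left), ("right", session.right)):
        if not stream:
            raise EmptyDataError(f"session has an empty {foot}-foot stream")
    left_avg = average_pressure(session.left)
    right_avg = average_pressure(session.right)
    balance = left_avg / (left_avg + right_avg) if (left_avg + right_avg) else 0.5

    all_t = [v.timestamp_ms for v in session.left] + [
        v.timestamp_ms for v in session.right
    ]
    duration_ms = max(all_t) - min(all_t)
    steps = len(detect_steps(session.left, on_threshold, refractory_ms)) + len(
        detect_steps(session.right, on_threshold, refractory_ms)
    )
    cadence = steps / duration_ms * 60_000.0 if duration_ms > 0 else 0.0

    if len(session.gps_track) >= 2:
        distance_m, avg_speed = track_metrics(session.gps_track)
    else:
        distance_m, avg_speed = 0.0, 0.0
    return RunSummary(
        avg_pressure_left=left_avg,
        avg_pressure_right=right_avg,
        balance_ratio=balance,
        step_count=steps,
        cadence_spm=cadence,
        distance_m=distance_m,
        avg_speed_m_s=avg_speed,
        duration_ms=duration_ms,
    )


# ---------------------------------------------------------------------------
# Survey aggregation

@dataclass(frozen=True)
class SurveyTable:
    """Raters × aspects integer ratings on the 1–5 scale."""

    ratings: np.ndarray
    aspects: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings, dtype=int)
        object.__setattr__(self, "ratings", r)
        if r.size == 0:
            raise EmptyDataError("survey table is empty")
        if r.ndim != 2 or r.shape[1] != len(self.aspects):
            raise ValueError(
                f"ratings shape {r.shape} does not match {len(self.aspects)} aspects"
            )
        if np.any((r < 1) | (r > 5)):
            raise ValueError("all ratings must be integers in [1, 5]")


@dataclass(frozen=True)
class SurveySummary:
    aspect_means: dict[str, float]
    overall_mean: float


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_survey(table: SurveyTable) -> SurveySummary:
    """Per-aspect means and the grand mean over all ratings, to 2 decimals."""
    means = table.ratings.mean(axis=0)
    overall = float(table.ratings.mean())
    return SurveySummary(
        aspect_means={
            aspect: _round2(float(m)) for aspect, m in zip(table.aspects, means)
        },
        overall_mean=_round2(overall),
    )


# ---------------------------------------------------------------------------
# IO

def read_gps_csv(path: str | Path) -> list[GpsPoint]:
    """Read a GPS track CSV with header ``t_ms,lat,lon``."""
    df = pd.read_csv(path)
    missing = {"t_ms", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"GPS CSV missing columns: {sorted(missing)}")
    return [
        GpsPoint(lat=float(r.lat), lon=float(r.lon), t_ms=int(r.t_ms))
        for r in df.itertuples()
    ]


def read_gpx(path: str | Path) -> list[GpsPoint]:
    """Read track points from a GPX 1.1 file; times become ms since the first fix."""
    from datetime import datetime

    from lxml import etree

    tree = etree.parse(str(path))
    points: list[tuple[float, float, datetime]] = []
    for trkpt in tree.iter("{*}trkpt"):
        time_el = trkpt.find("{*}time")
        if time_el is None or time_el.text is None:
            raise ValueError("GPX track point without a <time> element")
        stamp = datetime.fromisoformat(time_el.text.replace("Z", "+00:00"))
        points.append((float(trkpt.get("lat")), float(trkpt.get("lon")), stamp))
    if not points:
        raise EmptyDataError(f"no track points found in {path}")
    t0 = points[0][2]
    return [
        GpsPoint(lat=lat, lon=lon, t_ms=int((t - t0).total_seconds() * 1000))
        for lat, lon, t in points
    ]


def read_survey_csv(path: str | Path) -> SurveyTable:
    """Read a rating table CSV; the first column identifies the rater."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("survey CSV needs a rater column plus at least one aspect")
    aspects = tuple(df.columns[1:])
    return SurveyTable(ratings=df[list(aspects)].to_numpy(dtype=int), aspects=aspects)


def table4_survey() -> SurveyTable:
    """The packaged ten-user system-test rating fixture."""
    return read_survey_csv(Path(__file__).parent / "data" / "table4.csv")
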