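"""Domain types, file schemas, configuration and logging for the singing/swimming pipeline.

The pipeline analyses passive-acoustic observations of fin whale (*Balaenoptera
physalus*) singers: streams of detected 20 Hz song notes and time-stamped
acoustic localizations, both attributed to individual singers upstream.  This
module defines the in-memory types every stage shares, the CSV schemas used on
disk, and the single configuration object that holds every analysis threshold.

Times are UTC epoch seconds internally; files may carry either an ISO-8601
timestamp column or an epoch-seconds column.  Positions are WGS84 decimal
degrees, or planar kilometres when ``AnalysisConfig.coordinate_system`` is
``"planar"`` (synthetic scenarios).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NoteEvent",
    "Song",
    "Bout",
    "TrackLocation",
    "TrackSegment",
    "SingerTrack",
    "BoutModelFit",
    "AnalysisConfig",
    "PairedTestResult",
    "AdditiveModelResult",
    "ValidationError",
    "read_notes",
    "read_locations",
    "write_track_table",
    "read_track_table",
    "notes_to_frame",
    "locations_to_frame",
    "get_logger",
    "setup_logging",
]


class ValidationError(ValueError):
    """Raised when an input table or configuration violates a schema invariant."""


# --------------------------------------------------------------------------
# logging
# --------------------------------------------------------------------------

_LOGGER_NAME = "finsong"


def setup_logging(verbosity: int = 0) -> None:
    """Configure structured logging to stderr.

    verbosity 0 → WARNING, 1 → INFO, ≥2 → DEBUG.
    """
    level = logging.WARNING - 10 * min(int(verbosity), 2)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger = logging.getLogger(_LOGGER_NAME)
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def get_logger(child: str | None = None) -> logging.Logger:
    name = _LOGGER_NAME if child is None else f"{_LOGGER_NAME}.{child}"
    return logging.getLogger(name)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoteEvent:
    """One detected 20 Hz note.

    Attributes
    ----------
    singer_id : str
        Opaque singer identifier (attribution happens upstream).
    start : float
        Note onset, UTC epoch seconds.
    duration : float
        Note duration in seconds, > 0 (20 Hz notes last about a second).
    """

    singer_id: str
    start: float
    duration: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError(
                f"note duration must be > 0, got {self.duration!r}"
            )

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Song:
    """A series of regularly spaced 20 Hz notes (at least ``min_notes`` of them).

    ``duration`` runs from the start of the first note to the end of the last.
    """

    singer_id: str
    start: float
    end: float
    note_count: int

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError("song must have positive duration")

    @property
    def duration(self) -> float:
        """Seconds from first-note start to last-note end."""
        return self.end - self.start

    @property
    def duration_min(self) -> float:
        return self.duration / 60.0


@dataclass
class Bout:
    """A maximal run of songs whose inter-song-intervals all fall below the BEC."""

    singer_id: str
    songs: list[Song]

    def __post_init__(self) -> None:
        if not self.songs:
            raise ValidationError("a bout contains at least one song")

    @property
    def start(self) -> float:
        return self.songs[0].start

    @property
    def end(self) -> float:
        return self.songs[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TrackLocation:
    """One acoustic localization of a singer."""

    singer_id: str
    time: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValidationError(f"latitude out of range: {self.lat!r}")
        if not (-180.0 <= self.lon <= 360.0):
            raise ValidationError(f"longitude out of range: {self.lon!r}")


@dataclass
class TrackSegment:
    """The span between two successive localizations, with derived kinematics.

    ``duty_cycle`` is the percentage of the trailing window (at most
    ``AnalysisConfig.duty_window_min`` minutes, clipped to the segment span)
    during which the singer was singing; it is filled in by
    :mod:`finsong.track_kinematics` once songs are available.
    """

    start_loc: TrackLocation
    end_loc: TrackLocation
    distance: float  # km
    elapsed: float  # hours
    speed: float  # km / h
    duty_cycle: Optional[float] = None  # percent, [0, 100]
    window_used: Optional[float] = None  # minutes, <= duty window


@dataclass
class SingerTrack:
    """Everything known about one singer: locations, segments, songs, bouts."""

    singer_id: str
    locations: list[TrackLocation]
    segments: list[TrackSegment] = field(default_factory=list)
    songs: list[Song] = field(default_factory=list)
    bouts: list[Bout] = field(default_factory=list)
    track_length: float = 0.0  # km, sum of segment distances
    track_duration: float = 0.0  # hours, first to last location
    total_singing_duration: float = 0.0  # hours, first song start to last song end


@dataclass
class BoutModelFit:
    """Biexponential fit to the inter-song-interval log-frequency distribution.

    The model is ``y(t) = a_f exp(-lambda_f t) + a_s exp(-lambda_s t)`` with the
    fast process (short within-bout rests) first and the slow process (long
    between-bout gaps) second; ``lambda_f > lambda_s > 0``.
    """

    a_f: float
    lambda_f: float  # per minute
    a_s: float
    lambda_s: float  # per minute
    bec: float  # minutes, operational (rounded) bout-ending criterion
    bec_exact: float = float("nan")
    residual_norm: float = float("nan")
    converged: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a_f * np.exp(-self.lambda_f * t) + self.a_s * np.exp(
            -self.lambda_s * t
        )


@dataclass(frozen=True)
class PairedTestResult:
    """Matched-pairs t-test summary."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_pairs: int
    degenerate: bool = False  # zero-variance differences


@dataclass
class SmoothTermResult:
    """One retained smooth term of an additive model."""

    name: str
    edf: float
    f_statistic: float
    p_value: float
    # partial-effect curve sampled at the observed predictor values, sorted
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    effect: np.ndarray = field(default_factory=lambda: np.empty(0))
    ci_low: np.ndarray = field(default_factory=lambda: np.empty(0))
    ci_high: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class AdditiveModelResult:
    """Backward-eliminated additive model for one response variable."""

    response: str
    retained: list[str]
    eliminated: list[str]
    terms: list[SmoothTermResult]
    adjusted_r2: float
    intercept_only: bool = False
    response_transformed: bool = False

    def term(self, name: str) -> SmoothTermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Every analysis threshold, with the study's operational values as defaults.

    Attributes
    ----------
    min_notes : int
        Minimum number of regularly spaced 20 Hz notes that make a song.
    ini_min_s, ini_max_s : float
        The typical inter-note-interval band (seconds); used as a regularity
        diagnostic, not an exclusion.
    note_break_s : float
        Inter-note-interval (start-to-start, seconds) above which the note
        stream is split: intervals greater than this end the candidate song.
    duty_window_min : float
        Trailing window (minutes) over which the per-segment duty-cycle is
        computed.
    robust_threshold_pct : float
        Duty-cycle at or above which singing is classed "robust".
    speed_split_kmh : float
        Swimming speed (km/h) at or above which a segment is classed "fast".
    default_bec_min : float
        Operational bout-ending criterion (minutes) used when no fit is
        available.
    min_locations, min_track_duration_h : track inclusion filter.
    coordinate_system : "wgs84" (haversine distances) or "planar"
        (locations carry x/y kilometres in the lat/lon slots).
    """

    min_notes: int = 3
    ini_min_s: float = 9.0
    ini_max_s: float = 20.0
    note_break_s: float = 30.0
    duty_window_min: float = 30.0
    robust_threshold_pct: float = 70.0
    speed_split_kmh: float = 7.0
    default_bec_min: float = 35.0
    min_locations: int = 3
    min_track_duration_h: float = 1.0
    bec_bin_width_min: float = 1.0
    coordinate_system: str = "wgs84"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            ("min_notes", self.min_notes),
            ("ini_min_s", self.ini_min_s),
            ("ini_max_s", self.ini_max_s),
            ("note_break_s", self.note_break_s),
            ("duty_window_min", self.duty_window_min),
            ("robust_threshold_pct", self.robust_threshold_pct),
            ("speed_split_kmh", self.speed_split_kmh),
            ("default_bec_min", self.default_bec_min),
            ("min_locations", self.min_locations),
            ("min_track_duration_h", self.min_track_duration_h),
            ("bec_bin_width_min", self.bec_bin_width_min),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValidationError(f"{name} must be positive, got {value!r}")
        if not (self.ini_min_s < self.ini_max_s < self.note_break_s):
            raise ValidationError(
                "threshold ordering violated: require "
                f"ini_min_s < ini_max_s < note_break_s, got "
                f"{self.ini_min_s} / {self.ini_max_s} / {self.note_break_s}"
            )
        if self.coordinate_system not in ("wgs84", "planar"):
            raise ValidationError(
                f"coordinate_system must be 'wgs84' or 'planar', "
                f"got {self.coordinate_system!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        section = data.get("analysis", data)
        kwargs = {k: v for k, v in section.items() if k in known}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"analysis": dataclasses.asdict(self)}, fh)


# --------------------------------------------------------------------------
# CSV readers / writers
# --------------------------------------------------------------------------

_EPOCH_COLS = ("epoch_s", "start_epoch_s", "time_epoch_s")
_ISO_COLS = ("start_iso8601", "time_iso8601", "iso8601")


def _column(df: pd.DataFrame, *candidates: str) -> Optional[str]:
    """Schema-tolerant column lookup: first matching name, case-insensitive."""
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand.lower() in lower:
            return lower[cand.lower()]
    return None


def _parse_times(df: pd.DataFrame, epoch_names, iso_names, path) -> np.ndarray:
    epoch_col = _column(df, *epoch_names)
    if epoch_col is not None:
        t = pd.to_numeric(df[epoch_col], errors="coerce").to_numpy(float)
    else:
        iso_col = _column(df, *iso_names)
        if iso_col is None:
            raise ValidationError(
                f"{path}: need one of {epoch_names + iso_names} time columns"
            )
        stamps = pd.to_datetime(df[iso_col], utc=True, errors="coerce")
        t = stamps.astype("int64").to_numpy(float) / 1e9
        t[stamps.isna().to_numpy()] = np.nan
    bad = np.flatnonzero(~np.isfinite(t))
    if bad.size:
        raise ValidationError(f"{path}: malformed time in data row {bad[0] + 1}")
    return t


def read_notes(path, schema: dict | None = None) -> list[NoteEvent]:
    """Read a note-event table: columns singer_id, start (ISO-8601 or epoch
    seconds) and duration_s.

    Notes are returned sorted by (singer, start).  Overlapping notes for one
    singer are rejected — a detector cannot report two simultaneous notes from
    the same animal.
    """
    df = pd.read_csv(path, comment="#")
    if schema:
        df = df.rename(columns=schema)
    sid_col = _column(df, "singer_id", "singer", "whale_id")
    dur_col = _column(df, "duration_s", "duration")
    if sid_col is None or dur_col is None:
        raise ValidationError(f"{path}: missing singer_id or duration_s column")
    t = _parse_times(df, _EPOCH_COLS + ("start_s",), _ISO_COLS, path)
    dur = pd.to_numeric(df[dur_col], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(dur) | (dur <= 0))
    if bad.size:
        raise ValidationError(
            f"{path}: invalid duration in data row {bad[0] + 1} "
            f"(value {df[dur_col].iloc[bad[0]]!r})"
        )
    sids = df[sid_col].astype(str).to_numpy()
    order = np.lexsort((t, sids))
    notes = [NoteEvent(sids[i], float(t[i]), float(dur[i])) for i in order]
    for a, b in zip(notes, notes[1:]):
        if a.singer_id == b.singer_id and b.start < a.end:
            raise ValidationError(
                f"{path}: overlapping notes for singer {a.singer_id} "
                f"at t={a.start:.3f} and t={b.start:.3f}"
            )
    return notes


def read_locations(path, schema: dict | None = None) -> list[TrackLocation]:
    """Read a localization table: singer_id, time (ISO-8601 or epoch s), lat, lon.

    Times must be strictly increasing within each singer (duplicate timestamps
    rejected: two simultaneous positions are contradictory).
    """
    df = pd.read_csv(path, comment="#")
    if schema:
        df = df.rename(columns=schema)
    sid_col = _column(df, "singer_id", "singer", "whale_id")
    lat_col = _column(df, "lat", "latitude", "y_km")
    lon_col = _column(df, "lon", "longitude", "x_km")
    if sid_col is None or lat_col is None or lon_col is None:
        raise ValidationError(f"{path}: missing singer_id / lat / lon columns")
    t = _parse_times(df, _EPOCH_COLS + ("time_s",), _ISO_COLS, path)
    lat = pd.to_numeric(df[lat_col], errors="coerce").to_numpy(float)
    lon = pd.to_numeric(df[lon_col], errors="coerce").to_numpy(float)
    for arr, name in ((lat, lat_col), (lon, lon_col)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ValidationError(
                f"{path}: malformed {name} in data row {bad[0] + 1}"
            )
    sids = df[sid_col].astype(str).to_numpy()
    order = np.lexsort((t, sids))
    locs = [
        TrackLocation(sids[i], float(t[i]), float(lat[i]), float(lon[i]))
        for i in order
    ]
    for a, b in zip(locs, locs[1:]):
        if a.singer_id == b.singer_id and b.time <= a.time:
            raise ValidationError(
                f"{path}: non-increasing times for singer {a.singer_id} "
                f"at t={a.time:.3f}"
            )
    return locs


_TRACK_COLUMNS = [
    "singer_id",
    "n_locations",
    "track_length_km",
    "track_duration_h",
    "total_singing_duration_h",
    "speed_mean_kmh",
    "speed_sd_kmh",
    "speed_median_kmh",
    "speed_min_kmh",
    "speed_max_kmh",
    "duty_cycle_mean_pct",
    "duty_cycle_sd_pct",
    "duty_cycle_median_pct",
    "duty_cycle_min_pct",
    "duty_cycle_max_pct",
    "song_duration_mean_min",
    "song_duration_sd_min",
    "song_duration_median_min",
    "song_duration_min_min",
    "song_duration_max_min",
]


def _stats(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return (np.nan,) * 5
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else np.nan
    return (
        float(np.mean(arr)),
        sd,
        float(np.median(arr)),
        float(np.min(arr)),
        float(np.max(arr)),
    )


def track_table(tracks: Iterable[SingerTrack]) -> pd.DataFrame:
    """One row per singer track, mirroring a per-track supplementary listing."""
    rows = []
    for tr in tracks:
        speeds = [s.speed for s in tr.segments]
        duties = [s.duty_cycle for s in tr.segments if s.duty_cycle is not None]
        song_durs = [s.duration_min for s in tr.songs]
        row = dict(
            singer_id=tr.singer_id,
            n_locations=len(tr.locations),
            track_length_km=tr.track_length,
            track_duration_h=tr.track_duration,
            total_singing_duration_h=tr.total_singing_duration,
        )
        for prefix, vals, unit in (
            ("speed", speeds, "kmh"),
            ("duty_cycle", duties, "pct"),
            ("song_duration", song_durs, "min"),
        ):
            mean, sd, med, lo, hi = _stats(vals)
            row[f"{prefix}_mean_{unit}"] = mean
            row[f"{prefix}_sd_{unit}"] = sd
            row[f"{prefix}_median_{unit}"] = med
            row[f"{prefix}_min_{unit}"] = lo
            row[f"{prefix}_max_{unit}"] = hi
        rows.append(row)
    return pd.DataFrame(rows, columns=_TRACK_COLUMNS)


def write_track_table(tracks: Iterable[SingerTrack], path) -> None:
    """Write the per-track summary table (header-only file for an empty cohort)."""
    track_table(tracks).to_csv(path, index=False, float_format="%.6f")


def read_track_table(path) -> pd.DataFrame:
    """Read a per-track table, tolerating extra columns and any column order."""
    df = pd.read_csv(path, comment="#")
    lower = {c.lower(): c for c in df.columns}
    rename = {lower[c.lower()]: c for c in _TRACK_COLUMNS if c.lower() in lower}
    return df.rename(columns=rename)


# --------------------------------------------------------------------------
# frame helpers (fast paths for cohort-scale data)
# --------------------------------------------------------------------------


def notes_to_frame(notes: Iterable[NoteEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "singer_id": [n.singer_id for n in notes],
            "start_s": [n.start for n in notes],
            "duration_s": [n.duration for n in notes],
        }
    )


def locations_to_frame(locs: Iterable[TrackLocation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "singer_id": [p.singer_id for p in locs],
            "time_s": [p.time for p in locs],
            "lat": [p.lat for p in locs],
            "lon": [p.lon for p in locs],
        }
    )
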