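"""Track geometry, per-segment swimming speed and trailing singing duty-cycle.

A singer's track is the sequence of its acoustic localizations; a segment is
the span between two successive localizations.  Each segment carries the swim
speed (great-circle distance over elapsed time) and a duty-cycle: the
percentage of the trailing 30 min of the segment during which the singer was
singing.  Duty-cycle is pure interval arithmetic over assembled song spans —
silence is silence regardless of bout bookkeeping, so inter-bout silences
inside a window count as non-singing time.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .types_io import (
    AnalysisConfig,
    SingerTrack,
    Song,
    TrackLocation,
    TrackSegment,
    ValidationError,
    get_logger,
)

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "location_distance_km",
    "build_segments",
    "segment_duty_cycle",
    "attach_duty_cycles",
    "classify_duty_cycle",
    "classify_speed_regime",
    "transition_pattern",
    "track_summaries",
    "filter_tracks",
]

log = get_logger("tracks")

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a spherical Earth (R = 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def location_distance_km(
    a: TrackLocation, b: TrackLocation, cfg: AnalysisConfig | None = None
) -> float:
    """Distance between two localizations under the configured geometry.

    In planar mode the lat/lon slots carry y/x kilometres.
    """
    cfg = cfg or AnalysisConfig()
    if cfg.coordinate_system == "planar":
        return float(np.hypot(a.lat - b.lat, a.lon - b.lon))
    return haversine_km(a.lat, a.lon, b.lat, b.lon)


def build_segments(
    locations: Sequence[TrackLocation], cfg: AnalysisConfig | None = None
) -> list[TrackSegment]:
    """One segment per successive pair of localizations (geometry only).

    Speed is distance over elapsed time; duty-cycles are attached separately
    once songs are available.
    """
    cfg = cfg or AnalysisConfig()
    if len(locations) < 2:
        raise ValidationError("need at least two locations to build segments")
    segs: list[TrackSegment] = []
    for a, b in zip(locations, locations[1:]):
        elapsed_h = (b.time - a.time) / 3600.0
        if elapsed_h <= 0:
            raise ValidationError(
                f"zero or negative elapsed time between locations at t={a.time}"
            )
        dist = location_distance_km(a, b, cfg)
        segs.append(
            TrackSegment(
                start_loc=a,
                end_loc=b,
                distance=dist,
                elapsed=elapsed_h,
                speed=dist / elapsed_h,
            )
        )
    return segs


def _overlap_sum(songs: Sequence[Song], w0: float, w1: float) -> float:
    """Total seconds of song inside the window [w0, w1] (interval intersection)."""
    total = 0.0
    for s in songs:
        lo = max(s.start, w0)
        hi = min(s.end, w1)
        if hi > lo:
            total += hi - lo
    return total


def segment_duty_cycle(
    segment: TrackSegment,
    songs: Sequence[Song],
    cfg: AnalysisConfig | None = None,
) -> float:
    """Percent of the segment's trailing window spent singing.

    The window is the last ``duty_window_min`` minutes of the segment,
    intersected with the segment span (segments shorter than the window use
    their full span; ``window_used`` records the minutes actually used).
    Songs straddling a window edge contribute only their overlap.
    """
    cfg = cfg or AnalysisConfig()
    w1 = segment.end_loc.time
    w0 = max(w1 - cfg.duty_window_min * 60.0, segment.start_loc.time)
    if w1 <= w0:
        raise ValidationError("duty-cycle window has zero length")
    singing = _overlap_sum(songs, w0, w1)
    duty = 100.0 * singing / (w1 - w0)
    segment.duty_cycle = float(np.clip(duty, 0.0, 100.0))
    segment.window_used = (w1 - w0) / 60.0
    return segment.duty_cycle


def attach_duty_cycles(
    segments: Iterable[TrackSegment],
    songs: Sequence[Song],
    cfg: AnalysisConfig | None = None,
) -> None:
    cfg = cfg or AnalysisConfig()
    for seg in segments:
        segment_duty_cycle(seg, songs, cfg)


def classify_duty_cycle(duty_pct: float, cfg: AnalysisConfig | None = None) -> str:
    """'robust' singing at or above the 70% duty-cycle threshold, else 'intermittent'."""
    cfg = cfg or AnalysisConfig()
    return "robust" if duty_pct >= cfg.robust_threshold_pct else "intermittent"


def classify_speed_regime(speed_kmh: float, cfg: AnalysisConfig | None = None) -> str:
    """'fast' at or above the 7 km/h split, else 'slow'."""
    cfg = cfg or AnalysisConfig()
    return "fast" if speed_kmh >= cfg.speed_split_kmh else "slow"


def transition_pattern(
    track: SingerTrack, cfg: AnalysisConfig | None = None
) -> str:
    """Summarize the track's slow/fast regime sequence.

    constant regime → ``stayed_slow`` / ``stayed_fast``; exactly one change →
    ``switched_to_fast`` / ``switched_to_slow``; two or more changes →
    ``alternating``.  Tracks with fewer than two segments are ``undefined``.
    """
    cfg = cfg or AnalysisConfig()
    if len(track.segments) < 2:
        log.warning(
            "transition pattern undefined for %s (<2 segments)", track.singer_id
        )
        return "undefined"
    regimes = [classify_speed_regime(s.speed, cfg) for s in track.segments]
    changes = sum(a != b for a, b in zip(regimes, regimes[1:]))
    if changes == 0:
        return f"stayed_{regimes[0]}"
    if changes == 1:
        return f"switched_to_{regimes[-1]}"
    return "alternating"


def track_summaries(track: SingerTrack) -> SingerTrack:
    """Fill track-level summaries in place and return the track.

    track-length: sum of segment distances (km); track-duration: first to last
    location (h); total-singing-duration: start of the first song in the first
    bout to the end of the last song in the last bout (h) — for a single-bout
    singer this equals the bout duration.
    """
    track.track_length = float(sum(s.distance for s in track.segments))
    if track.locations:
        track.track_duration = (
            track.locations[-1].time - track.locations[0].time
        ) / 3600.0
    if track.songs:
        track.total_singing_duration = (
            track.songs[-1].end - track.songs[0].start
        ) / 3600.0
    else:
        track.total_singing_duration = 0.0
    return track


def filter_tracks(
    tracks: Iterable[SingerTrack], cfg: AnalysisConfig | None = None
) -> tuple[list[SingerTrack], list[tuple[str, str]]]:
    """Apply the inclusion filter: at least ``min_locations`` localizations and
    a track duration of at least ``min_track_duration_h`` hours.

    Returns (included tracks, exclusion log of (singer_id, reason)).
    """
    cfg = cfg or AnalysisConfig()
    included: list[SingerTrack] = []
    excluded: list[tuple[str, str]] = []
    for tr in tracks:
        if len(tr.locations) < cfg.min_locations:
            reason = (
                f"only {len(tr.locations)} locations "
                f"(need >= {cfg.min_locations})"
            )
            excluded.append((tr.singer_id, reason))
            log.info("excluding %s: %s", tr.singer_id, reason)
            continue
        if tr.track_duration < cfg.min_track_duration_h:
            reason = (
                f"duration {tr.track_duration:.2f} h "
                f"(need >= {cfg.min_track_duration_h} h)"
            )
            excluded.append((tr.singer_id, reason))
            log.info("excluding %s: %s", tr.singer_id, reason)
            continue
        included.append(tr)
    return included, excluded
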