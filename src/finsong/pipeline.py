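"""End-to-end orchestration: note and localization tables in, cohort analysis out.

The stages run in the order the method does: song assembly per singer, pooled
inter-song-interval distribution and the bout-ending criterion, bout
segmentation, track segments with speeds and trailing duty-cycles, track-level
summaries and the inclusion filter, then cohort statistics, the speed x
duty-cycle histogram, the matched-pairs singing/non-singing speed test and the
additive models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import behavior_stats, bout_analysis, song_assembly, track_kinematics
from .types_io import (
    AdditiveModelResult,
    AnalysisConfig,
    BoutModelFit,
    PairedTestResult,
    SingerTrack,
    TrackLocation,
    ValidationError,
    get_logger,
    track_table,
)

__all__ = ["PipelineResult", "run_pipeline", "build_tracks"]

log = get_logger("pipeline")


@dataclass
class PipelineResult:
    tracks: list[SingerTrack]
    excluded: list[tuple[str, str]]
    bec: float
    bout_fit: Optional[BoutModelFit]
    intervals_min: list[float]
    summary: behavior_stats.CohortSummary
    histogram: Optional[behavior_stats.SpeedDutyHistogram]
    paired: Optional[PairedTestResult]
    models: dict[str, AdditiveModelResult] = field(default_factory=dict)
    track_means: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def track_table(self) -> pd.DataFrame:
        return track_table(self.tracks)

    def report(self, cfg: AnalysisConfig | None = None) -> str:
        return behavior_stats.report(
            self.tracks,
            cfg,
            models=self.models,
            paired=self.paired,
            bec=self.bec,
        )


def build_tracks(
    notes: pd.DataFrame, locations: pd.DataFrame, cfg: AnalysisConfig
) -> tuple[list[SingerTrack], list[float]]:
    """Assemble per-singer tracks (songs, segments, duty-cycles) and pool the
    inter-song-intervals across singers.  Bouts are not yet assigned — the BEC
    needs the pooled intervals first."""
    songs_by = song_assembly.assemble_songs_frame(notes, cfg)
    tracks: list[SingerTrack] = []
    intervals: list[float] = []
    for sid, grp in locations.groupby("singer_id", sort=True):
        sid = str(sid)
        grp = grp.sort_values("time_s")
        locs = [
            TrackLocation(sid, float(r.time_s), float(r.lat), float(r.lon))
            for r in grp.itertuples()
        ]
        songs = songs_by.get(sid, [])
        track = SingerTrack(singer_id=sid, locations=locs, songs=songs)
        if len(locs) >= 2:
            track.segments = track_kinematics.build_segments(locs, cfg)
            track_kinematics.attach_duty_cycles(track.segments, songs, cfg)
        track_kinematics.track_summaries(track)
        intervals.extend(song_assembly.inter_song_intervals(songs))
        tracks.append(track)
    singers_without_locations = set(songs_by) - {t.singer_id for t in tracks}
    for sid in sorted(singers_without_locations):
        log.info("singer %s has notes but no locations; track skipped", sid)
    return tracks, intervals


def run_pipeline(
    notes: pd.DataFrame,
    locations: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    fit_models: bool = True,
) -> PipelineResult:
    """Run the full analysis on note and localization frames."""
    cfg = cfg or AnalysisConfig()
    tracks, intervals = build_tracks(notes, locations, cfg)

    bec, bout_fit = bout_analysis.estimate_bec(intervals, cfg)
    for tr in tracks:
        tr.bouts = bout_analysis.segment_bouts(tr.songs, bec)

    included, excluded = track_kinematics.filter_tracks(tracks, cfg)
    if not included:
        raise ValidationError("no tracks pass the inclusion filter")
    log.info(
        "pipeline: %d/%d tracks included, BEC %.0f min",
        len(included),
        len(tracks),
        bec,
    )

    summary = behavior_stats.cohort_summary(included)
    seg_rows = [
        dict(speed_kmh=s.speed, duty_cycle_pct=s.duty_cycle)
        for tr in included
        for s in tr.segments
        if s.duty_cycle is not None
    ]
    histogram = (
        behavior_stats.speed_duty_histogram(pd.DataFrame(seg_rows))
        if seg_rows
        else None
    )

    pairs = [
        p
        for p in (behavior_stats.singing_nonsinging_speeds(tr) for tr in included)
        if p is not None
    ]
    paired = None
    if len(pairs) >= 2:
        paired = behavior_stats.paired_speed_test(
            [p[0] for p in pairs], [p[1] for p in pairs]
        )

    track_means = behavior_stats.track_means_table(included)
    models: dict[str, AdditiveModelResult] = {}
    if fit_models:
        for response in ("duty_cycle", "song_duration"):
            try:
                models[response] = behavior_stats.fit_additive_model(
                    track_means, response
                )
            except ValidationError as exc:
                log.warning("additive model for %s skipped: %s", response, exc)

    return PipelineResult(
        tracks=included,
        excluded=excluded,
        bec=bec,
        bout_fit=bout_fit,
        intervals_min=intervals,
        summary=summary,
        histogram=histogram,
        paired=paired,
        models=models,
        track_means=track_means,
    )
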