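"""Segment geometry, duty-cycles and regime classification."""

import math

import numpy as np
import pytest

from finsong import (
    AnalysisConfig,
    SingerTrack,
    TrackLocation,
    ValidationError,
    build_segments,
    classify_duty_cycle,
    classify_speed_regime,
    filter_tracks,
    haversine_km,
    segment_duty_cycle,
    track_summaries,
    transition_pattern,
)
from finsong.track_kinematics import attach_duty_cycles
from finsong.types_io import Song


def law_of_cosines_km(lat1, lon1, lat2, lon2, r=6371.0):
    """Independent great-circle oracle (spherical law of cosines)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    arg = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return r * math.acos(min(1.0, max(-1.0, arg)))


def planar_cfg():
    return AnalysisConfig(coordinate_system="planar")


class TestSegments:
    def test_planar_speed(self):
        locs = [
            TrackLocation("w", 0.0, 0.0, 0.0),
            TrackLocation("w", 3600.0, 0.0, 10.0),  # 10 km east, 1 h later
        ]
        (seg,) = build_segments(locs, planar_cfg())
        assert seg.distance == pytest.approx(10.0)
        assert seg.speed == pytest.approx(10.0)
        assert seg.elapsed == pytest.approx(1.0)

    def test_great_circle_distance(self):
        # one degree of longitude at 60 N: ~55.6 km
        locs = [
            TrackLocation("w", 0.0, 60.0, -30.0),
            TrackLocation("w", 4 * 3600.0, 60.0, -29.0),
        ]
        (seg,) = build_segments(locs, AnalysisConfig())
        oracle = law_of_cosines_km(60.0, -30.0, 60.0, -29.0)
        assert seg.distance == pytest.approx(oracle, abs=1e-6)
        assert seg.distance == pytest.approx(55.6, abs=0.2)
        assert seg.speed == pytest.approx(seg.distance / 4.0)

    def test_speed_oracle_over_random_pairs(self):
        """Haversine agrees with the independent oracle to 1 m over random pairs."""
        rng = np.random.default_rng(0)
        lat = rng.uniform(-80, 80, size=(1000, 2))
        lon = rng.uniform(-180, 180, size=(1000, 2))
        for (la1, la2), (lo1, lo2) in zip(lat, lon):
            d = haversine_km(la1, lo1, la2, lo2)
            o = law_of_cosines_km(la1, lo1, la2, lo2)
            assert abs(d - o) < 1e-3  # 1 metre

    def test_segment_count(self):
        locs = [TrackLocation("w", t * 3600.0, 0.0, t * 0.1) for t in range(6)]
        assert len(build_segments(locs, planar_cfg())) == 5

    def test_zero_elapsed_error(self):
        locs = [TrackLocation("w", 0.0, 0.0, 0.0), TrackLocation("w", 0.0, 0.0, 1.0)]
        with pytest.raises(ValidationError):
            build_segments(locs, planar_cfg())

    def test_distance_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.uniform([-80, -180], [80, 180])
            b = rng.uniform([-80, -180], [80, 180])
            assert haversine_km(*a, *b) == pytest.approx(
                haversine_km(*b, *a), rel=1e-12
            )


def make_segment(t0, t1):
    return build_segments(
        [TrackLocation("w", t0, 0.0, 0.0), TrackLocation("w", t1, 0.0, 10.0)],
        planar_cfg(),
    )[0]


class TestDutyCycle:
    def test_window_fully_covered(self):
        seg = make_segment(0.0, 7200.0)
        songs = [Song("w", 0.0, 7200.0, note_count=100)]
        assert segment_duty_cycle(seg, songs) == pytest.approx(100.0)
        assert seg.window_used == pytest.approx(30.0)

    def test_half_covered_window(self):
        seg = make_segment(0.0, 7200.0)
        # 15 min of song inside the trailing 30 min window
        songs = [Song("w", 7200.0 - 1800.0, 7200.0 - 900.0, note_count=50)]
        assert segment_duty_cycle(seg, songs) == pytest.approx(50.0)

    def test_short_segment_uses_full_span(self):
        seg = make_segment(0.0, 1200.0)  # 20 min segment
        songs = [Song("w", 0.0, 600.0, note_count=30)]
        assert segment_duty_cycle(seg, songs) == pytest.approx(50.0)
        assert seg.window_used == pytest.approx(20.0)

    def test_song_straddling_window_edge(self):
        seg = make_segment(0.0, 7200.0)
        w0 = 7200.0 - 1800.0
        songs = [Song("w", w0 - 600.0, w0 + 600.0, note_count=60)]
        assert segment_duty_cycle(seg, songs) == pytest.approx(100.0 * 600 / 1800)

    def test_rasterization_oracle(self):
        """Interval arithmetic matches a 1 s rasterization within 0.1 points."""
        rng = np.random.default_rng(7)
        cfg = AnalysisConfig(coordinate_system="planar")
        for _ in range(200):
            t1 = rng.uniform(2400.0, 10800.0)
            seg = make_segment(0.0, t1)
            songs = []
            t = rng.uniform(0, 600)
            while t < t1:
                dur = rng.uniform(30, 1500)
                songs.append(Song("w", t, min(t + dur, t1 + 900), 10))
                t += dur + rng.uniform(60, 900)
            duty = segment_duty_cycle(seg, songs, cfg)
            w0 = max(t1 - 1800.0, 0.0)
            grid = np.arange(w0, t1, 1.0)
            sung = np.zeros_like(grid, dtype=bool)
            for s in songs:
                sung |= (grid >= s.start) & (grid < s.end)
            oracle = 100.0 * sung.mean()
            assert duty == pytest.approx(oracle, abs=0.1)

    def test_time_translation_invariant(self):
        rng = np.random.default_rng(3)
        shift = 86400.0 * 1000
        seg_a = make_segment(0.0, 7200.0)
        seg_b = make_segment(shift, shift + 7200.0)
        songs_a = [Song("w", 100.0, 2000.0, 10), Song("w", 6000.0, 7100.0, 10)]
        songs_b = [Song("w", s.start + shift, s.end + shift, 10) for s in songs_a]
        assert segment_duty_cycle(seg_a, songs_a) == pytest.approx(
            segment_duty_cycle(seg_b, songs_b), rel=1e-12
        )


class TestClassification:
    @pytest.mark.parametrize(
        "duty,expected",
        [(88.0, "robust"), (48.0, "intermittent"), (70.0, "robust"), (69.9, "intermittent")],
    )
    def test_duty_classes(self, duty, expected):
        assert classify_duty_cycle(duty) == expected

    @pytest.mark.parametrize(
        "speed,expected",
        [(6.9, "slow"), (7.0, "fast"), (14.1, "fast"), (1.0, "slow")],
    )
    def test_speed_regimes(self, speed, expected):
        assert classify_speed_regime(speed) == expected


def track_with_speeds(speeds_kmh):
    """Planar track engineered to have the given per-segment speeds."""
    locs = [TrackLocation("w", 0.0, 0.0, 0.0)]
    x = 0.0
    for i, v in enumerate(speeds_kmh):
        x += v  # one hour per segment
        locs.append(TrackLocation("w", (i + 1) * 3600.0, 0.0, x))
    tr = SingerTrack("w", locs)
    tr.segments = build_segments(locs, planar_cfg())
    return track_summaries(tr)


class TestTransitionPattern:
    @pytest.mark.parametrize(
        "speeds,expected",
        [
            ([3, 4, 5, 6], "stayed_slow"),
            ([9, 10, 11], "stayed_fast"),
            ([3, 4, 9, 10], "switched_to_fast"),
            ([9, 8, 3, 2], "switched_to_slow"),
            ([3, 9, 3, 9], "alternating"),
        ],
    )
    def test_patterns(self, speeds, expected):
        assert transition_pattern(track_with_speeds(speeds)) == expected

    def test_single_segment_undefined(self):
        assert transition_pattern(track_with_speeds([5])) == "undefined"


class TestTrackSummaries:
    def test_collinear_track_length(self):
        tr = track_with_speeds([10, 10])
        assert tr.track_length == pytest.approx(20.0)
        assert tr.track_duration == pytest.approx(2.0)

    def test_single_bout_singing_duration_equals_bout_duration(self):
        from finsong import segment_bouts

        tr = track_with_speeds([5, 5, 5])
        tr.songs = [
            Song("w", 0.0, 600.0, 30),
            Song("w", 900.0, 1500.0, 30),
            Song("w", 1800.0, 2400.0, 30),
        ]
        tr.bouts = segment_bouts(tr.songs, 35.0)
        track_summaries(tr)
        assert len(tr.bouts) == 1
        assert tr.total_singing_duration == pytest.approx(
            tr.bouts[0].duration / 3600.0
        )

    def test_oracle_recomputation(self, cohort_result):
        for tr in cohort_result.tracks[:10]:
            assert tr.track_length == pytest.approx(
                sum(s.distance for s in tr.segments), rel=1e-12
            )
            assert tr.track_duration == pytest.approx(
                (tr.locations[-1].time - tr.locations[0].time) / 3600.0, rel=1e-12
            )
            # segment elapsed times partition the track duration
            assert sum(s.elapsed for s in tr.segments) == pytest.approx(
                tr.track_duration, rel=1e-9
            )

    def test_window_used_bounds(self, cohort_result):
        for tr in cohort_result.tracks:
            for s in tr.segments:
                assert s.window_used <= 30.0 + 1e-9
                if s.elapsed >= 0.5:
                    assert s.window_used == pytest.approx(30.0)
                assert 0.0 <= s.duty_cycle <= 100.0


class TestFilterTracks:
    def test_too_few_locations(self):
        tr = track_with_speeds([5])  # 2 locations
        kept, excluded = filter_tracks([tr])
        assert kept == []
        assert excluded[0][0] == "w"
        assert "locations" in excluded[0][1]

    def test_too_short_duration(self):
        locs = [
            TrackLocation("w", t * 600.0, 0.0, t * 0.1) for t in range(3)
        ]  # 3 locations, 20 min
        tr = SingerTrack("w", locs)
        tr.segments = build_segments(locs, planar_cfg())
        track_summaries(tr)
        kept, excluded = filter_tracks([tr])
        assert kept == []
        assert "duration" in excluded[0][1]

    def test_boundary_included(self):
        locs = [
            TrackLocation("w", t * 1800.0, 0.0, t * 5.0) for t in range(3)
        ]  # 3 locations, exactly 1.0 h
        tr = SingerTrack("w", locs)
        tr.segments = build_segments(locs, planar_cfg())
        track_summaries(tr)
        kept, excluded = filter_tracks([tr])
        assert len(kept) == 1
        assert excluded == []
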