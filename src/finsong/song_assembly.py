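"""Assemble a singer's 20 Hz note stream into songs.

A song is a run of at least ``min_notes`` regularly spaced notes.  The note
stream is scanned left to right; successive notes stay in the same candidate
song while the start-to-start interval between them does not exceed
``note_break_s`` (30 s by default — the one hard rule; the 9–20 s band is the
typical spacing and is reported as a regularity diagnostic, not enforced).
Candidates with fewer than ``min_notes`` notes are discarded: isolated notes
and lone pairs are not songs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types_io import AnalysisConfig, NoteEvent, Song, ValidationError

__all__ = [
    "assemble_songs",
    "assemble_songs_frame",
    "song_durations",
    "inter_song_intervals",
    "regularity_fraction",
]


def _note_arrays(notes) -> tuple[str, np.ndarray, np.ndarray]:
    if isinstance(notes, pd.DataFrame):
        sids = notes["singer_id"].astype(str).to_numpy()
        starts = notes["start_s"].to_numpy(float)
        durs = notes["duration_s"].to_numpy(float)
    else:
        notes = list(notes)
        sids = np.array([n.singer_id for n in notes])
        starts = np.array([n.start for n in notes], dtype=float)
        durs = np.array([n.duration for n in notes], dtype=float)
    if len(starts) == 0:
        return "", starts, durs
    if len(set(sids)) > 1:
        raise ValidationError(
            "assemble_songs operates on one singer's notes; got "
            f"{sorted(set(sids))}"
        )
    if np.any(np.diff(starts) < 0):
        raise ValidationError("notes must be sorted by start time")
    ends = starts + durs
    if np.any(starts[1:] < ends[:-1]):
        raise ValidationError("overlapping notes are invalid input")
    return str(sids[0]), starts, durs


def assemble_songs(
    notes: Sequence[NoteEvent] | pd.DataFrame, cfg: AnalysisConfig | None = None
) -> list[Song]:
    """Greedy left-to-right song assembly for a single singer.

    Parameters
    ----------
    notes
        The singer's notes, sorted and non-overlapping; either a sequence of
        :class:`NoteEvent` or a frame with columns singer_id/start_s/duration_s.
    cfg
        Thresholds; defaults to :class:`AnalysisConfig`'s study values.

    Returns
    -------
    list of Song, time-ordered and non-overlapping.  Empty input yields an
    empty list.
    """
    cfg = cfg or AnalysisConfig()
    singer_id, starts, durs = _note_arrays(notes)
    if starts.size == 0:
        return []
    # split wherever the start-to-start interval exceeds the break threshold
    gaps = np.diff(starts)
    cut = np.flatnonzero(gaps > cfg.note_break_s)
    bounds = np.concatenate(([0], cut + 1, [starts.size]))
    songs: list[Song] = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        count = int(i1 - i0)
        if count >= cfg.min_notes:
            songs.append(
                Song(
                    singer_id=singer_id,
                    start=float(starts[i0]),
                    end=float(starts[i1 - 1] + durs[i1 - 1]),
                    note_count=count,
                )
            )
    return songs


def assemble_songs_frame(
    notes: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> dict[str, list[Song]]:
    """Assemble songs for every singer in a multi-singer note frame."""
    cfg = cfg or AnalysisConfig()
    out: dict[str, list[Song]] = {}
    for sid, grp in notes.groupby("singer_id", sort=True):
        grp = grp.sort_values("start_s")
        out[str(sid)] = assemble_songs(grp, cfg)
    return out


def song_durations(songs: Iterable[Song]) -> list[float]:
    """Song durations in minutes (first-note start to last-note end)."""
    return [s.duration_min for s in songs]


def inter_song_intervals(songs: Sequence[Song]) -> list[float]:
    """Silences between successive songs, in minutes.

    Interval *i* runs from the end of song *i* to the start of song *i+1*.
    Fewer than two songs yield an empty list.
    """
    if len(songs) < 2:
        return []
    out = []
    for a, b in zip(songs, songs[1:]):
        gap = (b.start - a.end) / 60.0
        if gap <= 0:
            raise ValidationError(
                f"songs overlap or touch at t={a.end:.3f} for {a.singer_id}"
            )
        out.append(gap)
    return out


def regularity_fraction(
    notes: Sequence[NoteEvent] | pd.DataFrame, song: Song, cfg: AnalysisConfig | None = None
) -> float:
    """Fraction of a song's inter-note-intervals inside the typical 9–20 s band.

    Diagnostic only: values well below 1 flag irregular (fragmented) songs.
    """
    cfg = cfg or AnalysisConfig()
    _, starts, _ = _note_arrays(notes)
    inside = (starts >= song.start) & (starts <= song.end)
    starts = starts[inside]
    if starts.size < 2:
        return float("nan")
    ini = np.diff(starts)
    ok = (ini >= cfg.ini_min_s) & (ini <= cfg.ini_max_s)
    return float(np.mean(ok))
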