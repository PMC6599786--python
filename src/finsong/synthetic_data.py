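"""Synthetic fin whale singer cohorts with the statistical structure the
analysis assumes, plus a hydrophone-array observation model.

Each simulated singer alternates, semi-Markov fashion, between two behavioral
states:

* ``slow_singing`` — slow correlated-random-walk movement (lognormal speeds,
  median ~5 km/h) while singing long stereotyped songs separated by 3-10 min
  rests, for a trailing duty-cycle in the high (75-90%) band;
* ``fast_transit`` — faster movement (median ~12 km/h) during which the singer
  either sings fragmented songs (shortened durations, lengthened rests, duty
  0-30%) or goes silent entirely, producing the inter-bout gaps.

Duty-cycle and hence song duration are decreasing functions of the current
state speed, so downstream models have a known negative speed coupling to
recover; seasonal modulation peaks in early winter.  A configurable fraction
of singers never leaves the slow state, and half of the mixed singers go
silent instead of singing fragmented songs while fast.

Movement is planar (kilometres) internally; geographic output converts through
a local tangent plane.  The optional observation model turns true positions
and song times into per-array arrival times and back into localizations by
time-difference-of-arrival (TDOA) least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .types_io import AnalysisConfig, TrackLocation, ValidationError, get_logger

__all__ = [
    "BehaviorParams",
    "ArrayGeometry",
    "SingerSim",
    "CohortData",
    "simulate_singer",
    "decimate_locations",
    "observe_toa",
    "localize_tdoa",
    "generate_cohort",
]

log = get_logger("synthetic")

KM_PER_DEG_LAT = 111.195  # spherical Earth, R = 6371 km


@dataclass
class BehaviorParams:
    """Generative parameters for one singer cohort.

    Speeds are km/h, durations follow the field's scales: rests of 3-10 min
    within bouts, inter-bout gaps of at least 40 min, inter-note-intervals of
    9-20 s.  Duty-cycle targets are fractions in [0, 1]; per-state values are
    ``base - speed_coef * speed`` plus seasonal modulation and noise, clipped
    to the state's range.
    """

    # slow singing state
    slow_speed_median_kmh: float = 5.0
    slow_speed_sigma: float = 0.35
    slow_duty_base: float = 0.97
    slow_duty_speed_coef: float = 0.025
    slow_duty_range: tuple[float, float] = (0.70, 0.93)
    slow_dwell_mean_h: float = 4.0
    slow_dwell_min_h: float = 1.0
    # fast transit state
    fast_speed_median_kmh: float = 12.0
    fast_speed_sigma: float = 0.25
    fast_duty_base: float = 0.32
    fast_duty_speed_coef: float = 0.02
    fast_duty_range: tuple[float, float] = (0.0, 0.35)
    fast_dwell_min_h: float = 0.67  # 40 min: silent fast dwells are the gaps
    fast_dwell_mean_extra_h: float = 1.0
    fast_rest_multiplier: float = 2.5
    # song micro-structure
    ini_range_s: tuple[float, float] = (9.0, 20.0)
    note_duration_s: float = 1.0
    rest_range_min: tuple[float, float] = (3.0, 10.0)
    max_song_min: float = 30.0
    min_song_s: float = 20.0  # below this a song slot stays silent
    duty_noise_sd: float = 0.025
    # seasonality (peak of singing effort in early winter)
    seasonal_amp_duty: float = 0.04
    seasonal_peak_doy: float = 335.0
    doy_sigma_days: float = 55.0
    # movement
    heading_sigma_rad_per_min: float = 0.08
    step_s: float = 60.0
    # cohort mix
    slow_only_fraction: float = 0.31
    silent_fast_fraction: float = 0.5
    mixed_start_slow_prob: float = 0.38  # overall start-slow fraction ~ 0.57
    slow_only_speed_cap_kmh: float = 6.8
    # track durations (hours): lognormal, right-skewed like observed tracks
    duration_median_h: float = 9.5
    duration_sigma: float = 0.8
    duration_range_h: tuple[float, float] = (1.5, 70.0)
    year_range: tuple[int, int] = (2003, 2009)

    def validate(self) -> None:
        for name in (
            "slow_speed_median_kmh",
            "fast_speed_median_kmh",
            "slow_dwell_mean_h",
            "fast_dwell_min_h",
            "note_duration_s",
            "step_s",
            "duration_median_h",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("slow_duty_range", "fast_duty_range", "ini_range_s",
                     "rest_range_min", "duration_range_h"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be an ordered range")
        for name in ("slow_only_fraction", "silent_fast_fraction",
                     "mixed_start_slow_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a fraction in [0, 1]")


@dataclass
class ArrayGeometry:
    """Hydrophone array geometry for the TDOA observation model (planar km)."""

    positions_km: np.ndarray  # shape (n_arrays, 2)
    sound_speed_ms: float = 1500.0
    toa_noise_sd_s: float = 0.0

    def __post_init__(self) -> None:
        self.positions_km = np.asarray(self.positions_km, dtype=float)
        if self.positions_km.ndim != 2 or self.positions_km.shape[1] != 2:
            raise ValidationError("positions_km must be (n_arrays, 2)")


@dataclass
class SingerSim:
    """Output of one simulated singer."""

    singer_id: str
    path: pd.DataFrame  # t_s, x_km, y_km, state, speed_kmh
    notes: pd.DataFrame  # singer_id, start_s, duration_s
    dwells: pd.DataFrame  # t0_s, t1_s, state, speed_kmh, singing
    slow_only: bool
    silent_fast: bool
    start_time_s: float


def _seasonal(doy: float, p: BehaviorParams) -> float:
    return p.seasonal_amp_duty * math.cos(
        2.0 * math.pi * (doy - p.seasonal_peak_doy) / 365.25
    )


def _sing_span(
    rng: np.random.Generator,
    t0: float,
    t_end: float,
    duty_base: float,
    duty_coef: float,
    duty_range: tuple[float, float],
    speed: float,
    seasonal: float,
    rest_mult: float,
    p: BehaviorParams,
    notes_out: list[np.ndarray],
) -> float:
    """Fill [t0, t_end] with song/rest cycles; append note start arrays.

    Returns the earliest time the next song may start (the end of the final
    rest), so a rest always separates songs across a state-dwell boundary.
    """
    t = t0
    while t < t_end:
        d = duty_base - duty_coef * speed + seasonal + rng.normal(0.0, p.duty_noise_sd)
        d = float(np.clip(d, duty_range[0], duty_range[1]))
        rest_s = rng.uniform(*p.rest_range_min) * 60.0 * rest_mult
        if d <= 0.0:
            t += rest_s + 60.0  # silent slot
            continue
        span_s = min(d / (1.0 - d) * rest_s, p.max_song_min * 60.0)
        span_s = min(span_s, t_end - t)
        if span_s >= p.min_song_s:
            inis = rng.uniform(*p.ini_range_s, size=int(span_s / p.ini_range_s[0]) + 2)
            starts = t + np.concatenate(([0.0], np.cumsum(inis)))
            starts = starts[starts + p.note_duration_s <= t + span_s]
            if starts.size >= 3:
                notes_out.append(starts)
        t += span_s + rest_s
    return t


def simulate_singer(
    params: BehaviorParams,
    duration_h: float,
    seed: int | np.random.SeedSequence,
    singer_id: str = "Fin-000",
    start_time_s: float = 0.0,
    slow_only: bool = False,
    silent_fast: bool = False,
    start_slow: bool = True,
    doy: float = 335.0,
) -> SingerSim:
    """Simulate one singer: state alternation, movement and note emission.

    Deterministic under a fixed seed.  Returns the true 1-min-resolution path,
    the note events and the dwell (state) sequence.
    """
    params.validate()
    if not duration_h > 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)
    seasonal = _seasonal(doy, params)

    t = 0.0
    total_s = duration_h * 3600.0
    state = "slow" if (slow_only or start_slow) else "fast"
    xs = [0.0]
    ys = [0.0]
    ts = [0.0]
    st = [state]
    sp = [0.0]
    heading = rng.uniform(0.0, 2.0 * math.pi)
    x = y = 0.0
    notes_chunks: list[np.ndarray] = []
    dwell_rows = []
    dt = params.step_s
    next_song_t = 0.0  # rest carryover across dwell boundaries

    while t < total_s - 1.0:
        if state == "slow":
            dwell_s = max(
                params.slow_dwell_min_h,
                rng.exponential(params.slow_dwell_mean_h),
            ) * 3600.0
            speed = params.slow_speed_median_kmh * math.exp(
                rng.normal(0.0, params.slow_speed_sigma)
            )
            if slow_only:
                speed = min(speed, params.slow_only_speed_cap_kmh)
            singing = True
            rest_mult = 1.0
            duty = (
                params.slow_duty_base,
                params.slow_duty_speed_coef,
                params.slow_duty_range,
            )
        else:
            dwell_s = (
                params.fast_dwell_min_h
                + rng.exponential(params.fast_dwell_mean_extra_h)
            ) * 3600.0
            speed = params.fast_speed_median_kmh * math.exp(
                rng.normal(0.0, params.fast_speed_sigma)
            )
            singing = not silent_fast
            rest_mult = params.fast_rest_multiplier
            duty = (
                params.fast_duty_base,
                params.fast_duty_speed_coef,
                params.fast_duty_range,
            )
        dwell_s = min(dwell_s, total_s - t)
        t1 = t + dwell_s

        # movement: correlated random walk at 1-min steps
        n_steps = max(1, int(round(dwell_s / dt)))
        dh = rng.normal(0.0, params.heading_sigma_rad_per_min * math.sqrt(dt / 60.0),
                        size=n_steps)
        headings = heading + np.cumsum(dh)
        heading = float(headings[-1])
        step_km = speed * dt / 3600.0
        x_path = x + np.cumsum(step_km * np.cos(headings))
        y_path = y + np.cumsum(step_km * np.sin(headings))
        t_path = t + dt * np.arange(1, n_steps + 1)
        x, y = float(x_path[-1]), float(y_path[-1])
        ts.extend(t_path.tolist())
        xs.extend(x_path.tolist())
        ys.extend(y_path.tolist())
        st.extend([state] * n_steps)
        sp.extend([speed] * n_steps)

        if singing:
            next_song_t = _sing_span(
                rng, max(t, next_song_t), t1, duty[0], duty[1], duty[2],
                speed, seasonal, rest_mult, params, notes_chunks,
            )
        dwell_rows.append(
            dict(t0_s=t, t1_s=t1, state=state, speed_kmh=speed, singing=singing)
        )
        t = t1
        if not slow_only:
            state = "fast" if state == "slow" else "slow"

    note_starts = (
        np.concatenate(notes_chunks) if notes_chunks else np.empty(0)
    )
    note_starts = np.sort(note_starts) + start_time_s
    path = pd.DataFrame(
        {
            "t_s": np.asarray(ts) + start_time_s,
            "x_km": xs,
            "y_km": ys,
            "state": st,
            "speed_kmh": sp,
        }
    )
    notes = pd.DataFrame(
        {
            "singer_id": singer_id,
            "start_s": note_starts,
            "duration_s": params.note_duration_s,
        }
    )
    dwells = pd.DataFrame(dwell_rows)
    dwells[["t0_s", "t1_s"]] += start_time_s
    return SingerSim(
        singer_id=singer_id,
        path=path,
        notes=notes,
        dwells=dwells,
        slow_only=slow_only,
        silent_fast=silent_fast,
        start_time_s=start_time_s,
    )


def decimate_locations(
    path: pd.DataFrame, min_separation_km: float = 10.0
) -> pd.DataFrame:
    """Greedy thinning of a true path into localization events.

    Walks the path in time and emits a location whenever the straight-line
    distance from the last emitted location reaches ``min_separation_km``, so
    successive emitted locations are at least that far apart.  The first path
    point is always emitted.
    """
    t = path["t_s"].to_numpy(float)
    x = path["x_km"].to_numpy(float)
    y = path["y_km"].to_numpy(float)
    keep = [0]
    last = 0
    for i in range(1, t.size):
        if math.hypot(x[i] - x[last], y[i] - y[last]) >= min_separation_km:
            keep.append(i)
            last = i
    return path.iloc[keep].reset_index(drop=True)


def planar_to_wgs84(
    x_km: np.ndarray, y_km: np.ndarray, lat0: float, lon0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local tangent-plane conversion of planar offsets to latitude/longitude."""
    lat = lat0 + np.asarray(y_km) / KM_PER_DEG_LAT
    lon = lon0 + np.asarray(x_km) / (KM_PER_DEG_LAT * math.cos(math.radians(lat0)))
    return lat, lon


# --------------------------------------------------------------------------
# hydrophone-array observation model (TDOA plumbing)
# --------------------------------------------------------------------------


def observe_toa(
    positions_km: np.ndarray,
    emission_times_s: np.ndarray,
    geom: ArrayGeometry,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Arrival times of each emission at each array.

    arrival[i, j] = emission time i + range(i, j) / c + Gaussian noise.
    """
    pos = np.atleast_2d(np.asarray(positions_km, dtype=float))
    times = np.atleast_1d(np.asarray(emission_times_s, dtype=float))
    rng = np.random.default_rng(seed)
    d_km = np.linalg.norm(
        pos[:, None, :] - geom.positions_km[None, :, :], axis=2
    )
    arrivals = times[:, None] + d_km * 1000.0 / geom.sound_speed_ms
    if geom.toa_noise_sd_s > 0:
        arrivals = arrivals + rng.normal(0.0, geom.toa_noise_sd_s, arrivals.shape)
    return arrivals


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    if len(points) < 3:
        return True
    p0 = points[0]
    v = points[1:] - p0
    cross = np.abs(v[:, 0, None] * v[None, :, 1] - v[:, 1, None] * v[None, :, 0])
    scale = max(np.abs(v).max(), 1.0)
    return bool(cross.max() < tol * scale * scale)


@dataclass
class TdoaSolution:
    position_km: np.ndarray
    emission_time_s: float
    residual_rms_s: float
    low_confidence: bool


def localize_tdoa(
    arrivals_s: np.ndarray,
    geom: ArrayGeometry,
    x0_km: Sequence[float] = (0.0, 0.0),
) -> TdoaSolution:
    """Locate one emission from its arrival times at ≥3 arrays.

    Nonlinear least squares over (x, y, emission time) on the absolute arrival
    residuals — equivalent to solving the arrival-time differences while also
    recovering the emission time.  Degenerate geometry (collinear arrays) is
    flagged low-confidence rather than rejected.
    """
    arrivals = np.asarray(arrivals_s, dtype=float)
    n = arrivals.size
    if n < 3:
        raise ValidationError("TDOA localization needs at least 3 arrays")
    if geom.positions_km.shape[0] != n:
        raise ValidationError("arrival count must match the array count")
    c_kms = geom.sound_speed_ms / 1000.0

    def resid(p):
        x, y, t0 = p
        d = np.hypot(geom.positions_km[:, 0] - x, geom.positions_km[:, 1] - y)
        return t0 + d / c_kms - arrivals

    t0_guess = float(arrivals.min()) - 1.0
    sol = least_squares(resid, [x0_km[0], x0_km[1], t0_guess], method="lm")
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    flag = _collinear(geom.positions_km) or not sol.success
    return TdoaSolution(
        position_km=sol.x[:2].copy(),
        emission_time_s=float(sol.x[2]),
        residual_rms_s=rms,
        low_confidence=bool(flag),
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass
class CohortData:
    """A full synthetic dataset in the pipeline's CSV schemas."""

    notes: pd.DataFrame  # singer_id, start_s, duration_s
    locations: pd.DataFrame  # singer_id, time_s, lat, lon  (or y_km/x_km planar)
    truth: pd.DataFrame  # per-singer generating metadata
    params: BehaviorParams
    seed: int
    coordinate_system: str = "wgs84"
    sims: list[SingerSim] = field(default_factory=list)


def _start_epoch(rng: np.random.Generator, p: BehaviorParams) -> tuple[float, int, float]:
    """Draw a track start time: year uniform, day-of-year wrapped-normal around
    the early-winter singing peak."""
    year = int(rng.integers(p.year_range[0], p.year_range[1] + 1))
    doy = (p.seasonal_peak_doy + rng.normal(0.0, p.doy_sigma_days)) % 365.0
    t0 = datetime(year, 1, 1, tzinfo=timezone.utc) + timedelta(
        days=float(doy), hours=float(rng.uniform(0, 24))
    )
    return t0.timestamp(), year, float(doy)


def generate_cohort(
    n_tracks: int = 163,
    params: BehaviorParams | None = None,
    seed: int = 0,
    coordinate_system: str = "wgs84",
    keep_sims: bool = False,
) -> CohortData:
    """Generate a heterogeneous cohort of singers (notes + locations).

    Per-singer draws: about 31% of singers never leave the slow state; of the
    rest, half go silent while fast (their silent fast dwells are the
    inter-bout gaps) and half sing fragmented songs.  Deterministic under the
    seed.
    """
    params = params or BehaviorParams()
    params.validate()
    if n_tracks < 1:
        raise ValidationError("n_tracks must be >= 1")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_tracks)

    notes_frames = []
    loc_frames = []
    truth_rows = []
    sims: list[SingerSim] = []
    for k in range(n_tracks):
        sid = f"Fin-{k + 1:03d}"
        slow_only = bool(master.random() < params.slow_only_fraction)
        silent_fast = (not slow_only) and bool(
            master.random() < params.silent_fast_fraction
        )
        start_slow = True if slow_only else bool(
            master.random() < params.mixed_start_slow_prob
        )
        duration_h = float(
            np.clip(
                params.duration_median_h
                * math.exp(master.normal(0.0, params.duration_sigma)),
                *params.duration_range_h,
            )
        )
        start_s, year, doy = _start_epoch(master, params)
        sim = simulate_singer(
            params,
            duration_h,
            child_seeds[k],
            singer_id=sid,
            start_time_s=start_s,
            slow_only=slow_only,
            silent_fast=silent_fast,
            start_slow=start_slow,
            doy=doy,
        )
        locs = decimate_locations(sim.path)
        if coordinate_system == "wgs84":
            lat0 = float(master.uniform(45.0, 60.0))
            lon0 = float(master.uniform(-45.0, -15.0))
            lat, lon = planar_to_wgs84(
                locs["x_km"].to_numpy(), locs["y_km"].to_numpy(), lat0, lon0
            )
        else:
            lat, lon = locs["y_km"].to_numpy(), locs["x_km"].to_numpy()
        loc_frames.append(
            pd.DataFrame(
                {
                    "singer_id": sid,
                    "time_s": locs["t_s"].to_numpy(),
                    "lat": lat,
                    "lon": lon,
                }
            )
        )
        notes_frames.append(sim.notes)
        truth_rows.append(
            dict(
                singer_id=sid,
                slow_only=slow_only,
                silent_fast=silent_fast,
                start_slow=start_slow,
                duration_h=duration_h,
                year=year,
                doy=doy,
                n_notes=len(sim.notes),
            )
        )
        if keep_sims:
            sims.append(sim)

    return CohortData(
        notes=pd.concat(notes_frames, ignore_index=True),
        locations=pd.concat(loc_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        params=params,
        seed=seed,
        coordinate_system=coordinate_system,
        sims=sims,
    )


def write_cohort_csv(cohort: CohortData, out_dir) -> tuple[str, str]:
    """Write the cohort in the pipeline's CSV schemas; returns the two paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    notes_path = os.path.join(out_dir, "notes.csv")
    locs_path = os.path.join(out_dir, "locations.csv")
    header = f"# synthetic cohort, seed={cohort.seed}\n"
    for path, df in ((notes_path, cohort.notes), (locs_path, cohort.locations)):
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.6f")
    return notes_path, locs_path
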