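"""Self-contained property computations used by the acceptance checks.

Each function recomputes one verifiable property of the pipeline from
scratch — closed-form BEC arithmetic against a brute-force misassignment
minimizer, BEC recovery from seeded two-exponential mixtures, duty-cycle
interval arithmetic against a one-second rasterization, great-circle speeds
against an independent spherical oracle, the paired-test algebraic identity,
and full end-to-end recovery of the generative speed coupling on synthetic
cohorts.  They are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import bout_analysis
from .behavior_stats import decreasing_partial_effect, paired_speed_test
from .pipeline import run_pipeline
from .synthetic_data import BehaviorParams, generate_cohort
from .track_kinematics import haversine_km
from .types_io import AnalysisConfig, BoutModelFit, Song, TrackLocation


def bec_closed_form(
    a_f: float = 800.0, lambda_f: float = 0.2, a_s: float = 20.0,
    lambda_s: float = 0.01,
) -> dict:
    """Closed-form BEC versus brute-force minimization of misassigned mass."""
    fit = BoutModelFit(a_f, lambda_f, a_s, lambda_s, bec=np.nan, converged=True)
    bout_analysis.bec_from_fit(fit, round_to_min=False)
    # Brute force: integrate each component's mass on a fine grid and find
    # the threshold minimizing slow-mass-below + fast-mass-above.
    fine = np.linspace(0.0, 3000.0, 600_001)
    dt = fine[1] - fine[0]
    fast = a_f * np.exp(-lambda_f * fine)
    slow = a_s * np.exp(-lambda_s * fine)
    slow_cum = np.concatenate(([0.0], np.cumsum(slow) * dt))
    fast_cum = np.concatenate(([0.0], np.cumsum(fast) * dt))
    grid = np.linspace(0.01, 200.0, 400_000)
    idx = np.searchsorted(fine, grid)
    mis = slow_cum[idx] + (fast_cum[-1] - fast_cum[idx])
    brute = float(grid[np.argmin(mis)])
    return {
        "closed_form_min": float(fit.bec_exact),
        "brute_force_min": brute,
        "agree_3_sig_figs": abs(brute - fit.bec_exact) / fit.bec_exact < 5e-4,
    }


def bec_recovery(
    n_datasets: int = 100,
    n_intervals: int = 5000,
    p_fast: float = 0.8,
    mean_fast_min: float = 5.0,
    mean_slow_min: float = 100.0,
    seed: int = 0,
) -> dict:
    """Median relative BEC error over seeded two-exponential mixtures.

    The truth is the crossing of the binned count amplitudes implied by the
    generating mixture (bin width 1 min), which for exponential components is
    exact at bin centres.
    """
    lam_f, lam_s = 1.0 / mean_fast_min, 1.0 / mean_slow_min
    w = 1.0  # bin width, minutes
    a_f = p_fast * n_intervals * (math.exp(lam_f * w / 2) - math.exp(-lam_f * w / 2))
    a_s = (1 - p_fast) * n_intervals * (
        math.exp(lam_s * w / 2) - math.exp(-lam_s * w / 2)
    )
    true_bec = math.log(a_f / a_s) / (lam_f - lam_s)
    ss = np.random.SeedSequence(seed)
    errors = []
    n_fail = 0
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        n_f = int(p_fast * n_intervals)
        sample = np.concatenate(
            [
                rng.exponential(mean_fast_min, n_f),
                rng.exponential(mean_slow_min, n_intervals - n_f),
            ]
        )
        try:
            t, logy = bout_analysis.interval_log_frequency(sample, w)
            fit = bout_analysis.fit_biexponential(
                t, 10 ** logy, seed=int(rng.integers(2**31))
            )
            bout_analysis.bec_from_fit(fit, round_to_min=False)
            errors.append(abs(fit.bec_exact - true_bec) / true_bec)
        except (bout_analysis.BoutFitError, Exception):
            n_fail += 1
    return {
        "true_bec_min": true_bec,
        "median_relative_error": float(np.median(errors)) if errors else np.inf,
        "n_fitted": len(errors),
        "n_failed": n_fail,
    }


def duty_cycle_oracle(n_layouts: int = 1000, seed: int = 0) -> dict:
    """Max discrepancy (percentage points) between the production interval-
    arithmetic duty-cycle and a 1 s rasterization, over random song layouts.

    Scenario times are whole seconds so the 1 s raster represents the layout
    exactly; any discrepancy beyond float rounding is then a genuine
    interval-arithmetic defect rather than raster quantization.
    """
    from .track_kinematics import build_segments, segment_duty_cycle

    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig(coordinate_system="planar")
    worst = 0.0
    for _ in range(n_layouts):
        t1 = float(rng.integers(1200, 10800))
        locs = [
            TrackLocation("w", 0.0, 0.0, 0.0),
            TrackLocation("w", t1, 0.0, 5.0),
        ]
        (seg,) = build_segments(locs, cfg)
        songs = []
        t = float(rng.integers(0, 900))
        while t < t1 + 600.0:
            dur = float(rng.integers(20, 1800))
            songs.append(Song("w", t, t + dur, 10))
            t += dur + float(rng.integers(30, 900))
        duty = segment_duty_cycle(seg, songs, cfg)
        w0 = max(t1 - cfg.duty_window_min * 60.0, 0.0)
        grid = np.arange(w0 + 0.5, t1, 1.0)  # midpoints of 1 s cells
        sung = np.zeros(grid.shape, dtype=bool)
        for s in songs:
            sung |= (grid >= s.start) & (grid < s.end)
        oracle = 100.0 * float(np.mean(sung)) if grid.size else 0.0
        worst = max(worst, abs(duty - oracle))
    return {"max_discrepancy_pp": worst, "n_layouts": n_layouts}


def speed_oracle(n_pairs: int = 1000, seed: int = 0) -> dict:
    """Max disagreement (km) between haversine and an independent great-circle
    formula (Vincenty arctan form on the sphere) over random coordinate pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        lat1, lat2 = rng.uniform(-85.0, 85.0, 2)
        lon1, lon2 = rng.uniform(-180.0, 180.0, 2)
        p1, p2 = math.radians(lat1), math.radians(lat2)
        dl = math.radians(lon2 - lon1)
        # Vincenty great-circle formula on the sphere: numerically stable at
        # all separations, independent of the haversine implementation
        num = math.hypot(
            math.cos(p2) * math.sin(dl),
            math.cos(p1) * math.sin(p2)
            - math.sin(p1) * math.cos(p2) * math.cos(dl),
        )
        den = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
        oracle = 6371.0 * math.atan2(num, den)
        worst = max(worst, abs(haversine_km(lat1, lon1, lat2, lon2) - oracle))
    return {"max_error_km": worst, "n_pairs": n_pairs}


def paired_test_identity(seed: int = 0) -> dict:
    """Matched-pairs t equals the one-sample t on differences; identical
    vectors give t = 0, p = 1."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    a = rng.normal(6.0, 2.0, 24)
    b = rng.normal(6.0, 2.0, 24)
    res = paired_speed_test(a, b)
    d = a - b
    t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
    p_oracle = 2.0 * stats.t.sf(abs(t_oracle), d.size - 1)
    same = paired_speed_test(a, a)
    return {
        "t_discrepancy": abs(res.t_statistic - t_oracle),
        "p_discrepancy": abs(res.p_value - p_oracle),
        "identical_t": same.t_statistic,
        "identical_p": same.p_value,
    }


@dataclass
class EndToEndOutcome:
    seed: int
    duty_speed_p: float
    duty_speed_decreasing: bool
    song_speed_p: float
    song_speed_decreasing: bool
    bec_min: float
    high_mode_fraction: float
    low_mode_fraction: float
    n_tracks: int


def end_to_end_seed(
    seed: int, n_tracks: int = 163, params: BehaviorParams | None = None
) -> EndToEndOutcome:
    """Generate one cohort, run the full pipeline, and report whether the
    additive models recover the generative negative speed coupling."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = generate_cohort(n_tracks=n_tracks, params=params, seed=seed)
        result = run_pipeline(
            cohort.notes, cohort.locations, AnalysisConfig(rng_seed=seed)
        )
    out = {}
    for name in ("duty_cycle", "song_duration"):
        model = result.models.get(name)
        if model is None or "speed" not in model.retained:
            out[name] = (1.0, False)
        else:
            term = model.term("speed")
            out[name] = (term.p_value, decreasing_partial_effect(term))
    hist = result.histogram
    return EndToEndOutcome(
        seed=seed,
        duty_speed_p=out["duty_cycle"][0],
        duty_speed_decreasing=out["duty_cycle"][1],
        song_speed_p=out["song_duration"][0],
        song_speed_decreasing=out["song_duration"][1],
        bec_min=result.bec,
        high_mode_fraction=hist.high_mode_fraction if hist else np.nan,
        low_mode_fraction=hist.low_mode_fraction if hist else np.nan,
        n_tracks=len(result.tracks),
    )
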