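"""Cohort statistics and models for singing effort versus swimming speed.

Tracks are the unit of analysis — each singer is represented once, by its
per-track mean values; segments are never pooled across singers for anything
reported as track-level.  This module provides

* cohort descriptive statistics (mean of track means, s.e.m., means of
  per-track minima/maxima, s.d., median, range),
* the 2-D swimming-speed x duty-cycle histogram (log10 counts) with its
  bimodality summary (high-duty 75-90% and low-duty 0-5% mode fractions),
* the matched-pairs t-test comparing each singer's mean speed while singing
  (bout spans) against while not singing (inter-bout spans),
* the lognormal Johnson (SL) transform used to symmetrize skewed variables,
* penalized-spline additive models (Gaussian errors, identity link) of duty-
  cycle and song duration against swimming speed, number of songs, day-of-year
  (cyclic seasonal smooth) and year, with backward elimination at alpha=0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .track_kinematics import classify_speed_regime, transition_pattern
from .types_io import (
    AdditiveModelResult,
    AnalysisConfig,
    PairedTestResult,
    SingerTrack,
    SmoothTermResult,
    ValidationError,
    get_logger,
)

__all__ = [
    "CohortSummary",
    "TransformFit",
    "SpeedDutyHistogram",
    "cohort_summary",
    "speed_duty_histogram",
    "paired_speed_test",
    "singing_nonsinging_speeds",
    "fit_johnson_sl",
    "johnson_transform",
    "fit_additive_model",
    "decreasing_partial_effect",
    "track_means_table",
    "regime_breakdown",
    "report",
]

log = get_logger("stats")

ELIMINATION_ALPHA = 0.05
SKEW_THRESHOLD = 0.5  # |skewness| above which a variable is Johnson-transformed


# --------------------------------------------------------------------------
# cohort descriptive statistics
# --------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Track-level descriptive statistics; one row per behavioral variable."""

    table: pd.DataFrame
    n_tracks: int

    def row(self, variable: str) -> pd.Series:
        return self.table.loc[variable]


_TRACK_SCALARS = {
    "track_length_km": lambda tr: tr.track_length,
    "track_duration_h": lambda tr: tr.track_duration,
    "total_singing_duration_h": lambda tr: tr.total_singing_duration,
    "n_locations": lambda tr: float(len(tr.locations)),
}

_TRACK_SERIES = {
    "speed_kmh": lambda tr: [s.speed for s in tr.segments],
    "duty_cycle_pct": lambda tr: [
        s.duty_cycle for s in tr.segments if s.duty_cycle is not None
    ],
    "song_duration_min": lambda tr: [s.duration_min for s in tr.songs],
}


def cohort_summary(tracks: Sequence[SingerTrack]) -> CohortSummary:
    """Descriptive statistics over per-track values.

    For per-segment / per-song variables the track is first reduced to its own
    mean (and min / max), and statistics are taken over those track values:
    mean of means, s.e.m. of the track means, mean of track minima and maxima,
    s.d., median and range of the track means.  A single-track cohort has an
    undefined s.e.m. (reported as NaN).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("empty cohort")
    rows = {}
    for name, getter in _TRACK_SCALARS.items():
        vals = np.array([getter(tr) for tr in tracks], dtype=float)
        rows[name] = _summary_row(vals, vals, vals)
    for name, getter in _TRACK_SERIES.items():
        means, mins, maxs = [], [], []
        for tr in tracks:
            vals = np.asarray(getter(tr), dtype=float)
            if vals.size == 0:
                continue
            means.append(vals.mean())
            mins.append(vals.min())
            maxs.append(vals.max())
        rows[name] = _summary_row(
            np.asarray(means), np.asarray(mins), np.asarray(maxs)
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    return CohortSummary(table=table, n_tracks=len(tracks))


def _summary_row(means: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> dict:
    n = means.size
    if n == 0:
        return {
            k: np.nan
            for k in (
                "mean_of_means sem mean_min mean_max sd median range_low "
                "range_high n".split()
            )
        }
    sem = float(np.std(means, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    sd = float(np.std(means, ddof=1)) if n > 1 else np.nan
    return {
        "mean_of_means": float(np.mean(means)),
        "sem": sem,
        "mean_min": float(np.mean(mins)),
        "mean_max": float(np.mean(maxs)),
        "sd": sd,
        "median": float(np.median(means)),
        "range_low": float(np.min(means)),
        "range_high": float(np.max(means)),
        "n": n,
    }


# --------------------------------------------------------------------------
# speed x duty-cycle histogram
# --------------------------------------------------------------------------


@dataclass
class SpeedDutyHistogram:
    """2-D histogram of segment (speed, duty-cycle) pairs.

    ``log10_counts`` is NaN where the cell is empty (no log of zero).  The
    bimodality summary reports the fraction of segments in the high-duty
    (75-90%) and low-duty (0-5%) duty-cycle bands.
    """

    speed_edges: np.ndarray
    duty_edges: np.ndarray
    counts: np.ndarray  # shape (n_speed_bins, n_duty_bins)
    log10_counts: np.ndarray
    n_segments: int
    high_mode_fraction: float  # duty-cycle in [75, 90] %
    low_mode_fraction: float  # duty-cycle in [0, 5] %


def speed_duty_histogram(
    segments,
    speed_bin: float = 1.0,
    duty_bin: float = 5.0,
    high_band: tuple[float, float] = (75.0, 90.0),
    low_band: tuple[float, float] = (0.0, 5.0),
) -> SpeedDutyHistogram:
    """Histogram all (speed, duty-cycle) pairs on a speed x duty grid.

    ``segments`` may be TrackSegment objects or a frame with columns
    ``speed_kmh`` / ``duty_cycle_pct``.
    """
    if isinstance(segments, pd.DataFrame):
        speeds = segments["speed_kmh"].to_numpy(float)
        duties = segments["duty_cycle_pct"].to_numpy(float)
    else:
        segments = list(segments)
        speeds = np.array([s.speed for s in segments], dtype=float)
        duties = np.array(
            [s.duty_cycle if s.duty_cycle is not None else np.nan for s in segments],
            dtype=float,
        )
    ok = np.isfinite(speeds) & np.isfinite(duties)
    speeds, duties = speeds[ok], duties[ok]
    if speeds.size == 0:
        raise ValidationError("no (speed, duty-cycle) pairs to histogram")
    s_max = max(speed_bin, float(np.ceil(speeds.max() / speed_bin)) * speed_bin)
    speed_edges = np.arange(0.0, s_max + 0.5 * speed_bin, speed_bin)
    duty_edges = np.arange(0.0, 100.0 + 0.5 * duty_bin, duty_bin)
    counts, _, _ = np.histogram2d(
        speeds, np.clip(duties, 0, 100 - 1e-9), bins=(speed_edges, duty_edges)
    )
    log10_counts = np.full_like(counts, np.nan, dtype=float)
    np.log10(counts, out=log10_counts, where=counts > 0)
    high = np.mean((duties >= high_band[0]) & (duties <= high_band[1]))
    low = np.mean((duties >= low_band[0]) & (duties <= low_band[1]))
    return SpeedDutyHistogram(
        speed_edges=speed_edges,
        duty_edges=duty_edges,
        counts=counts,
        log10_counts=log10_counts,
        n_segments=int(speeds.size),
        high_mode_fraction=float(high),
        low_mode_fraction=float(low),
    )


# --------------------------------------------------------------------------
# matched-pairs speed comparison
# --------------------------------------------------------------------------


def singing_nonsinging_speeds(track: SingerTrack) -> tuple[float, float] | None:
    """Time-weighted mean segment speed inside bout spans vs inter-bout spans.

    Returns None for singers without at least one inter-bout-interval (a
    single-bout singer offers no non-singing period to compare) or whose
    segments never overlap one of the two span types.
    """
    if len(track.bouts) < 2:
        return None
    sing_spans = [(b.start, b.end) for b in track.bouts]
    gap_spans = [
        (a.end, b.start) for a, b in zip(track.bouts, track.bouts[1:])
    ]

    def weighted_mean(spans) -> tuple[float, float]:
        num = den = 0.0
        for seg in track.segments:
            t0, t1 = seg.start_loc.time, seg.end_loc.time
            w = sum(max(0.0, min(t1, e) - max(t0, s)) for s, e in spans)
            num += seg.speed * w
            den += w
        return num, den

    num_s, den_s = weighted_mean(sing_spans)
    num_g, den_g = weighted_mean(gap_spans)
    if den_s <= 0 or den_g <= 0:
        return None
    return num_s / den_s, num_g / den_g


def paired_speed_test(
    singing: Sequence[float], nonsinging: Sequence[float]
) -> PairedTestResult:
    """Classic matched-pairs t-test on per-singer mean speeds.

    Equivalent to the one-sample t-test on the differences; df = n - 1,
    two-sided p.  Zero-variance differences are degenerate: identical vectors
    give t = 0, p = 1; constant nonzero differences are flagged.
    """
    a = np.asarray(list(singing), dtype=float)
    b = np.asarray(list(nonsinging), dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValidationError("need at least two pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        mean = float(np.mean(d))
        if mean == 0.0:
            return PairedTestResult(0.0, n - 1, 1.0, n, degenerate=False)
        return PairedTestResult(
            float("inf") if mean > 0 else float("-inf"),
            n - 1,
            0.0,
            n,
            degenerate=True,
        )
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        float(res.statistic), int(n - 1), float(res.pvalue), n
    )


# --------------------------------------------------------------------------
# Johnson SL transform
# --------------------------------------------------------------------------


@dataclass
class TransformFit:
    """Lognormal Johnson (SL) transform ``z = gamma + delta * ln((x - xi) / lam)``."""

    xi: float  # location
    lam: float  # scale (> 0; 1 for the percentile fit, scale folded into gamma)
    gamma: float  # shape
    delta: float  # shape (> 0)

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        arg = (x - self.xi) / self.lam
        if np.any(arg <= 0):
            raise ValidationError(
                "values at or below the fitted location xi cannot be transformed"
            )
        return self.gamma + self.delta * np.log(arg)


def johnson_transform(fit: TransformFit, x) -> np.ndarray:
    return fit.transform(x)


def fit_johnson_sl(
    values: Sequence[float], z0: float = 0.524, floor_xi_at_zero: bool = True
) -> tuple[TransformFit, np.ndarray]:
    """Fit the Johnson SL transform by percentile matching.

    Sample quantiles at the standard-normal points -3*z0, -z0, z0, 3*z0 give
    the spreads m, n, p of the classical percentile method; the SL solution is

        delta = 2 z0 / ln(m/p),
        gamma = delta * ln[(m/p - 1) / (p * sqrt(m/p))],
        xi    = (x_{z0} + x_{-z0})/2 - (p/2) * (m/p + 1)/(m/p - 1).

    The percentile location estimate from only four quantile points is noisy,
    so it is refined by the classic three-parameter-lognormal criterion of
    zeroing the skewness of ``ln(x - xi)`` (bounded below the sample minimum);
    the shape parameters are then matched to the +-z0 quantiles given xi.  For
    nonnegative quantities (durations, speeds) a negative fitted location is
    floored at zero.

    Raises on samples that are too small (< 20), not positively skewed in the
    percentile sense (m <= p), or not entirely above the fitted location.
    """
    from scipy.optimize import brentq, minimize_scalar

    x = np.asarray(list(values), dtype=float)
    if x.size < 20:
        raise ValidationError("Johnson SL fit needs at least 20 values")
    if np.ptp(x) == 0:
        raise ValidationError("constant sample has no Johnson SL transform")
    zp = stats.norm.cdf([-3 * z0, -z0, z0, 3 * z0])
    x_m3, x_m1, x_p1, x_p3 = np.quantile(x, zp)
    m = x_p3 - x_p1
    p = x_p1 - x_m1
    if p <= 0 or m / p <= 1.0:
        raise ValidationError(
            "sample is not positively skewed at the matching percentiles; "
            "SL transform inapplicable"
        )
    ratio = m / p
    xi0 = 0.5 * (x_p1 + x_m1) - 0.5 * p * (ratio + 1.0) / (ratio - 1.0)
    xmin = float(x.min())
    hi = xmin - 1e-9 * max(abs(xmin), 1.0)
    iqr = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    lo = min(xi0, xmin) - 3.0 * iqr

    def log_skew(xi):
        return stats.skew(np.log(x - xi))

    try:
        if log_skew(lo) * log_skew(hi) < 0:
            xi = float(brentq(log_skew, lo, hi, xtol=1e-10 * max(iqr, 1.0)))
        else:
            res = minimize_scalar(
                lambda v: abs(log_skew(v)), bounds=(lo, hi), method="bounded"
            )
            xi = float(res.x)
    except Exception:
        xi = min(xi0, hi)
    if floor_xi_at_zero and xi < 0 and xmin > 0:
        xi = 0.0
    lp1, lm1 = np.log(x_p1 - xi), np.log(x_m1 - xi)
    delta = 2.0 * z0 / (lp1 - lm1)
    gamma = -delta * 0.5 * (lp1 + lm1)
    if np.any(x <= xi) or not delta > 0:
        raise ValidationError(
            f"fitted location xi={xi:.4g} is not below all sample values"
        )
    fit = TransformFit(xi=float(xi), lam=1.0, gamma=float(gamma), delta=float(delta))
    return fit, fit.transform(x)


def _maybe_transform(values: np.ndarray, name: str) -> tuple[np.ndarray, bool]:
    """Johnson-transform a variable when it is materially right-skewed."""
    skew = stats.skew(values)
    if skew <= SKEW_THRESHOLD:
        return values, False
    try:
        _, z = fit_johnson_sl(values)
        log.info("Johnson SL transform applied to %s (skew %.2f)", name, skew)
        return z, True
    except ValidationError as exc:
        log.warning("Johnson transform of %s failed (%s); left untransformed", name, exc)
        return values, False


# --------------------------------------------------------------------------
# additive models
# --------------------------------------------------------------------------


def track_means_table(tracks: Sequence[SingerTrack]) -> pd.DataFrame:
    """Per-track modelling table: mean duty-cycle, mean song duration, mean
    speed, number of songs, day-of-year and year (from the first location)."""
    rows = []
    for tr in tracks:
        duties = [s.duty_cycle for s in tr.segments if s.duty_cycle is not None]
        durs = [s.duration_min for s in tr.songs]
        speeds = [s.speed for s in tr.segments]
        if not duties or not durs or not speeds:
            continue
        t0 = datetime.fromtimestamp(tr.locations[0].time, tz=timezone.utc)
        rows.append(
            dict(
                singer_id=tr.singer_id,
                duty_cycle=float(np.mean(duties)),
                song_duration=float(np.mean(durs)),
                speed=float(np.mean(speeds)),
                n_songs=float(len(tr.songs)),
                doy=float(t0.timetuple().tm_yday),
                year=float(t0.year),
            )
        )
    return pd.DataFrame(rows)


_PREDICTORS = ("speed", "n_songs", "doy", "year")


def _build_smoothers(table: pd.DataFrame, names: Sequence[str]):
    from statsmodels.gam.smooth_basis import (
        GenericSmoothers,
        UnivariateBSplines,
        UnivariateCubicCyclicSplines,
    )

    smoothers = []
    for name in names:
        x = table[name].to_numpy(float)
        if name == "doy":
            sm = UnivariateCubicCyclicSplines(
                x, df=5, variable_name=name, constraints="center"
            )
        else:
            df = min(5, max(3, len(np.unique(x)) - 2))
            sm = UnivariateBSplines(
                x, df=df, degree=3, variable_name=name, constraints="center"
            )
        smoothers.append(sm)
    xmat = np.column_stack([table[n].to_numpy(float) for n in names])
    return GenericSmoothers(xmat, smoothers)


def _fit_gam(y: np.ndarray, table: pd.DataFrame, names: Sequence[str], alphas):
    from statsmodels.gam.api import GLMGam

    smoother = _build_smoothers(table, names)
    model = GLMGam(y, np.ones((y.size, 1)), smoother=smoother, alpha=list(alphas))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return model, res


def _select_alphas(y: np.ndarray, table: pd.DataFrame, names: Sequence[str]):
    from statsmodels.gam.api import GLMGam

    smoother = _build_smoothers(table, names)
    model = GLMGam(y, np.ones((y.size, 1)), smoother=smoother, alpha=[1.0] * len(names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(maxiter=5)  # initializes the scale attributes used below
        # Nelder-Mead: deterministic, unlike the basinhopping default
        alphas = model.select_penweight(method="nm", disp=False)[0]
    return {n: float(a) for n, a in zip(names, alphas)}


def _fit_rss_edf(y: np.ndarray, table: pd.DataFrame, names, alphas):
    """Residual sum of squares and total effective d.f. of a GAM fit."""
    if not names:
        return float(((y - y.mean()) ** 2).sum()), 1.0, None
    model, res = _fit_gam(y, table, names, alphas)
    resid = y - res.fittedvalues
    return float(resid @ resid), float(np.asarray(res.edf).sum()), res


def _term_tests(
    y: np.ndarray, table: pd.DataFrame, names: list[str], alphas: dict
) -> list[tuple[float, float, float]]:
    """Approximate F-test for each smooth by model comparison.

    Term *i* is tested by refitting without it (penalties of the remaining
    smooths unchanged) and comparing residual sums of squares, with degrees
    of freedom taken from the change in total effective d.f. — the classic
    approximate significance test for penalized additive terms.  Returns
    (F, p, edf_drop) per term.
    """
    n = y.size
    rss_full, edf_full, _ = _fit_rss_edf(y, table, names, [alphas[m] for m in names])
    df_resid = max(n - edf_full, 1.0)
    out = []
    for name in names:
        rest = [m for m in names if m != name]
        rss_red, edf_red, _ = _fit_rss_edf(
            y, table, rest, [alphas[m] for m in rest]
        )
        df_term = max(edf_full - edf_red, 0.5)
        f_stat = ((rss_red - rss_full) / df_term) / (rss_full / df_resid)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_term, df_resid))
        if not np.isfinite(p):
            p = 1.0
        out.append((float(f_stat), p, float(df_term)))
    return out


def fit_additive_model(
    table: pd.DataFrame,
    response: str,
    alpha: float = ELIMINATION_ALPHA,
    min_rows: int = 40,
) -> AdditiveModelResult:
    """Penalized-spline additive model with backward elimination.

    The response (``duty_cycle`` or ``song_duration``) and the speed predictor
    are Johnson-SL-transformed when right-skewed.  Smooth terms: swimming
    speed, number of songs and year as penalized B-splines, day-of-year as a
    cyclic cubic spline (the seasonal peak straddles the year end).  Penalty
    weights are chosen once on the full model by GCV; the least significant
    smooth (largest Wald p >= ``alpha``) is then removed one at a time and the
    model refit until every retained term is significant.
    """
    if response not in table.columns:
        raise ValidationError(f"response {response!r} not in table")
    table = table.dropna(subset=[response, *(_c for _c in _PREDICTORS if _c in table)])
    if len(table) < min_rows:
        raise ValidationError(
            f"need at least {min_rows} tracks to fit an additive model, "
            f"got {len(table)}"
        )
    y_raw = table[response].to_numpy(float)
    y, y_transformed = _maybe_transform(y_raw, response)

    table = table.copy()
    sp, sp_transformed = _maybe_transform(table["speed"].to_numpy(float), "speed")
    speed_original = table["speed"].to_numpy(float).copy()
    table["speed"] = sp

    names = [
        n
        for n in _PREDICTORS
        if n in table.columns and len(np.unique(table[n])) >= 4
    ]
    dropped_degenerate = [
        n for n in _PREDICTORS if n in table.columns and n not in names
    ]
    for n in dropped_degenerate:
        log.info("predictor %s dropped: fewer than 4 unique values", n)

    alphas = _select_alphas(y, table, names)
    eliminated: list[str] = list(dropped_degenerate)
    current = list(names)
    tests: list[tuple[float, float, float]] = []
    while current:
        tests = _term_tests(y, table, current, alphas)
        pvals = [t[1] for t in tests]
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            break
        log.info(
            "eliminating smooth %s (p=%.3g)", current[worst], pvals[worst]
        )
        eliminated.append(current.pop(worst))
    if not current:
        return AdditiveModelResult(
            response=response,
            retained=[],
            eliminated=eliminated,
            terms=[],
            adjusted_r2=0.0,
            intercept_only=True,
            response_transformed=y_transformed,
        )

    model, res = _fit_gam(y, table, current, [alphas[n] for n in current])

    # per-term effective d.f.: slice the model edf by smoother columns
    dims = [s.dim_basis for s in model.smoother.smoothers]
    offsets = np.concatenate(([1], 1 + np.cumsum(dims)))  # 1 intercept column
    edf = np.asarray(res.edf, dtype=float)
    terms: list[SmoothTermResult] = []
    for i, name in enumerate(current):
        sl = slice(int(offsets[i]), int(offsets[i + 1]))
        term_edf = float(edf[sl].sum())
        f_stat, p_val, _ = tests[i]
        effect, se = res.partial_values(i)
        effect = np.asarray(effect, dtype=float)
        effect_center = effect.mean()  # partial effects are reported centered
        effect = effect - effect_center
        x = model.smoother.smoothers[i].x
        if name == "speed" and sp_transformed:
            x = speed_original  # report the curve against untransformed speed
        order = np.argsort(x)
        terms.append(
            SmoothTermResult(
                name=name,
                edf=term_edf,
                f_statistic=f_stat,
                p_value=p_val,
                x=np.asarray(x)[order],
                effect=effect[order],
                ci_low=(effect - 1.96 * se)[order],
                ci_high=(effect + 1.96 * se)[order],
            )
        )

    resid = y - res.fittedvalues
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    edf_tot = float(edf.sum())
    n = y.size
    adj_r2 = 1.0 - (ss_res / max(n - edf_tot, 1.0)) / (ss_tot / (n - 1))
    return AdditiveModelResult(
        response=response,
        retained=list(current),
        eliminated=eliminated,
        terms=terms,
        adjusted_r2=float(adj_r2),
        response_transformed=y_transformed,
    )


def decreasing_partial_effect(
    term: SmoothTermResult,
    n_grid: int = 9,
    q_range: tuple[float, float] = (0.15, 0.85),
    se_slack: float = 0.25,
) -> bool:
    """Finite-difference sign test for a monotone-decreasing partial effect.

    The fitted curve is sampled at evenly spaced quantiles of the predictor —
    not at every observation, where near-tied x values produce numerically
    meaningless wiggles, and not in the extreme tails, where a penalized
    spline has data support on only one side and its boundary flare says
    nothing about the trend.  Every finite difference must be negative, up to
    a slack of ``se_slack`` times the local pointwise standard error: a rise
    far inside the fit's own uncertainty is numerical flatness, not a trend
    reversal.  The curve must also show a strict overall decrease.
    """
    qs = np.linspace(q_range[0], q_range[1], n_grid)
    xq = np.quantile(term.x, qs)
    yq = np.interp(xq, term.x, term.effect)
    if term.ci_high.size == term.x.size:
        se = np.interp(xq, term.x, (term.ci_high - term.ci_low) / 3.92)
    else:
        se = np.zeros_like(xq)
    tol = se_slack * 0.5 * (se[:-1] + se[1:])
    return bool(np.all(np.diff(yq) < tol) and yq[0] > yq[-1])


# --------------------------------------------------------------------------
# regime / transition breakdown and the cohort report
# --------------------------------------------------------------------------


def regime_breakdown(
    tracks: Sequence[SingerTrack], cfg: AnalysisConfig | None = None
) -> dict:
    """Start-regime fractions, transition-pattern breakdown and the fraction
    of singers that never reached the fast regime."""
    cfg = cfg or AnalysisConfig()
    usable = [tr for tr in tracks if len(tr.segments) >= 1]
    start_slow = [
        tr
        for tr in usable
        if classify_speed_regime(tr.segments[0].speed, cfg) == "slow"
    ]
    start_fast = [tr for tr in usable if tr not in start_slow]
    never_fast = [
        tr
        for tr in usable
        if all(classify_speed_regime(s.speed, cfg) == "slow" for s in tr.segments)
    ]

    def patterns(group):
        pats = [transition_pattern(tr, cfg) for tr in group if len(tr.segments) >= 2]
        total = max(len(pats), 1)
        return {p: pats.count(p) / total for p in sorted(set(pats))}

    return {
        "n_tracks": len(usable),
        "start_slow_fraction": len(start_slow) / max(len(usable), 1),
        "start_fast_fraction": len(start_fast) / max(len(usable), 1),
        "never_fast_fraction": len(never_fast) / max(len(usable), 1),
        "start_slow_patterns": patterns(start_slow),
        "start_fast_patterns": patterns(start_fast),
    }


def report(
    tracks: Sequence[SingerTrack],
    cfg: AnalysisConfig | None = None,
    models: dict[str, AdditiveModelResult] | None = None,
    paired: PairedTestResult | None = None,
    bec: float | None = None,
) -> str:
    """Human-readable Markdown summary of the whole analysis."""
    cfg = cfg or AnalysisConfig()
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("cannot report on an empty cohort")
    summary = cohort_summary(tracks)
    segs = [
        dict(speed_kmh=s.speed, duty_cycle_pct=s.duty_cycle)
        for tr in tracks
        for s in tr.segments
        if s.duty_cycle is not None
    ]
    hist = speed_duty_histogram(pd.DataFrame(segs)) if segs else None
    breakdown = regime_breakdown(tracks, cfg)

    lines = ["# Singing / swimming cohort report", ""]
    lines.append(f"Tracks analysed: {summary.n_tracks}")
    n_segments = sum(len(tr.segments) for tr in tracks)
    n_songs = sum(len(tr.songs) for tr in tracks)
    lines.append(f"Track segments (speed, duty-cycle pairs): {n_segments}")
    lines.append(f"Songs: {n_songs}")
    if bec is not None:
        lines.append(f"Bout-ending criterion: {bec:.0f} min")
    lines += ["", "## Track-level descriptive statistics", ""]
    lines.append(summary.table.round(3).to_markdown())
    lines += ["", "## Speed regimes and transitions", ""]
    lines.append(
        f"- started slow (< {cfg.speed_split_kmh:g} km/h): "
        f"{100 * breakdown['start_slow_fraction']:.0f}%"
    )
    lines.append(
        f"- never reached {cfg.speed_split_kmh:g} km/h: "
        f"{100 * breakdown['never_fast_fraction']:.0f}%"
    )
    for label, key in (
        ("started slow", "start_slow_patterns"),
        ("started fast", "start_fast_patterns"),
    ):
        pats = ", ".join(
            f"{p}: {100 * f:.0f}%" for p, f in breakdown[key].items()
        )
        lines.append(f"- {label} transitions: {pats or 'n/a'}")
    if hist is not None:
        lines += ["", "## Duty-cycle bimodality", ""]
        lines.append(
            f"- high-duty mode (75-90%): {100 * hist.high_mode_fraction:.0f}% "
            f"of {hist.n_segments} segments"
        )
        lines.append(
            f"- low-duty mode (0-5%): {100 * hist.low_mode_fraction:.0f}%"
        )
    if paired is not None:
        lines += ["", "## Singing vs non-singing swimming speed", ""]
        lines.append(
            f"matched-pairs t({paired.degrees_of_freedom}) = "
            f"{paired.t_statistic:.3f}, p = {paired.p_value:.4f} "
            f"(n = {paired.n_pairs} singers)"
        )
    for name, model in (models or {}).items():
        lines += ["", f"## Additive model: {name}", ""]
        if model.intercept_only:
            lines.append("no predictor survived backward elimination")
            continue
        lines.append(
            f"retained: {', '.join(model.retained)}; "
            f"eliminated: {', '.join(model.eliminated) or 'none'}; "
            f"adjusted r2 = {model.adjusted_r2:.2f}"
        )
        lines.append("")
        lines.append("| term | edf | statistic | p |")
        lines.append("|---|---|---|---|")
        for t in model.terms:
            lines.append(
                f"| {t.name} | {t.edf:.1f} | {t.f_statistic:.1f} | {t.p_value:.2g} |"
            )
    return "\n".join(lines) + "\n"
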