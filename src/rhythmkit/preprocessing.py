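"""Raw channels -> analysis signals.

Produces the three signals the rhythm analysis runs on: integrated total
acceleration ("activity"), integrated vertical acceleration (a proxy for
"sleep"), and artifact-cleaned heart rate, all on the common 1-min grid,
plus linear interpolation of sparse mood entries onto that grid.

Heart-rate cleaning follows the neighbour rule: a sample over 150% or under
50% of the previous recorded value is replaced by the mean of its immediate
neighbours.  Integration removes the global series mean and sums an
overlapping 6-h window shifted one sample at a time; the window is centred
so the operation is phase-preserving (a trailing window would delay every
channel by +3 h, contaminating cross-modality phase differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from rhythmkit.synthetic import MINUTES_PER_DAY, MoodEntry, ParticipantRecording

__all__ = [
    "CleanReport",
    "AnalysisSignals",
    "clean_hr",
    "total_acceleration",
    "integrate_signal",
    "interpolate_gaps",
    "interpolate_mood",
    "build_analysis_signals",
    "day_coverage",
]


@dataclass(frozen=True)
class CleanReport:
    """Accounting of the HR neighbour-rule pass."""

    n_adjusted: int
    fraction_adjusted: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_adjusted <= 1.0:
            raise ValueError("fraction_adjusted must lie in [0, 1]")


@dataclass
class AnalysisSignals:
    """Activity, sleep and cleaned HR on one 1-min grid (NaN only inside
    gaps longer than the interpolation limit)."""

    t_min: np.ndarray
    activity: np.ndarray
    sleep: np.ndarray
    hr: np.ndarray
    clean_report: CleanReport

    def __post_init__(self) -> None:
        n = len(self.t_min)
        if not (len(self.activity) == len(self.sleep) == len(self.hr) == n):
            raise ValueError("analysis signals must share one time base")


def clean_hr(hr: np.ndarray) -> tuple[np.ndarray, CleanReport]:
    """Single-pass spike removal on a heart-rate series.

    Each sample (except the first and last) is compared with the original
    value at the preceding time instance; if it exceeds 150% or falls below
    50% of it, it is replaced by the mean of the original preceding and
    succeeding values.  Decisions are made against the *original* series —
    no convergence loop is run.  NaN samples are skipped and never flagged.
    """
    x = np.asarray(hr, dtype=float)
    if len(x) < 3:
        raise ValueError("clean_hr requires a series of length >= 3")
    out = x.copy()
    prev = x[:-2]
    cur = x[1:-1]
    nxt = x[2:]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = cur / prev
        flag = (ratio > 1.5) | (ratio < 0.5)
    flag &= np.isfinite(prev) & np.isfinite(cur) & np.isfinite(nxt)
    out[1:-1] = np.where(flag, 0.5 * (prev + nxt), cur)
    n_finite = int(np.isfinite(x).sum())
    n_adj = int(flag.sum())
    frac = n_adj / n_finite if n_finite else 0.0
    return out, CleanReport(n_adjusted=n_adj, fraction_adjusted=frac, n_samples=n_finite)


def total_acceleration(
    accel_x: np.ndarray, accel_y: np.ndarray, accel_z: np.ndarray
) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration axes."""
    x, y, z = (np.asarray(a, dtype=float) for a in (accel_x, accel_y, accel_z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("acceleration axes must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def _window_bounds(n: int, w: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(n)
    if mode == "centered":
        lo = np.maximum(t - (w - 1) // 2, 0)
        hi = np.minimum(t + w // 2, n - 1)
    elif mode == "trailing":
        lo = np.maximum(t - w + 1, 0)
        hi = t
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return lo, hi


def integrate_signal(
    x: np.ndarray,
    window_hours: float = 6.0,
    samples_per_minute: float = 1.0,
    mode: Literal["centered", "trailing"] = "centered",
) -> np.ndarray:
    """Moving-window integration of a mean-removed signal.

    Removes the global series mean, then sums an overlapping window of
    ``window_hours`` shifted one sample at a time.  Output length equals
    input length; edges use shrinking windows.  ``mode='centered'``
    (default) preserves the phase of periodic components; ``'trailing'``
    delays them by half the window.  NaN runs are treated as separate
    segments: each maximal finite run is integrated on its own and NaNs are
    kept in place.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = int(round(window_hours * 60.0 * samples_per_minute))
    if w < 1 or w >= n:
        raise ValueError("integration window must be positive and shorter than the series")
    out = np.full(n, np.nan)
    mean = np.nanmean(x)
    finite = np.isfinite(x)
    # integrate each maximal finite run separately (long gaps split the recording)
    edges = np.flatnonzero(np.diff(finite.astype(int)) != 0) + 1
    bounds = np.concatenate([[0], edges, [n]])
    for lo_b, hi_b in zip(bounds[:-1], bounds[1:]):
        if not finite[lo_b]:
            continue
        seg = x[lo_b:hi_b] - mean
        m = len(seg)
        cs = np.concatenate([[0.0], np.cumsum(seg)])
        lo, hi = _window_bounds(m, min(w, m), mode)
        out[lo_b:hi_b] = cs[hi + 1] - cs[lo]
    return out


def interpolate_gaps(x: np.ndarray, max_gap_minutes: int = 60) -> np.ndarray:
    """Linearly fill interior NaN runs no longer than ``max_gap_minutes``
    samples; longer runs (and edge runs) stay NaN."""
    x = np.asarray(x, dtype=float).copy()
    finite = np.isfinite(x)
    if finite.all() or not finite.any():
        return x
    idx = np.arange(len(x))
    filled = np.interp(idx, idx[finite], x[finite])
    # identify NaN runs and their lengths
    run_start = None
    for i in range(len(x) + 1):
        missing = i < len(x) and not finite[i]
        if missing and run_start is None:
            run_start = i
        elif not missing and run_start is not None:
            run = slice(run_start, i)
            interior = run_start > 0 and i < len(x)
            if interior and (i - run_start) <= max_gap_minutes:
                x[run] = filled[run]
            run_start = None
    return x


def interpolate_mood(
    times_min: Sequence[int] | np.ndarray,
    values: Sequence[float] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation of mood entries to the 1-min grid.

    Returns ``(t_grid, y)`` covering every integer minute from the first to
    the last entry, bridging overnight no-prompt gaps linearly.  Grid points
    outside the entry span are excluded (no extrapolation).
    """
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("interpolate_mood requires at least 2 entries")
    if not np.all(np.diff(t) > 0):
        raise ValueError("mood entry timestamps must be strictly increasing")
    grid = np.arange(int(np.ceil(t[0])), int(np.floor(t[-1])) + 1, dtype=np.int64)
    return grid, np.interp(grid, t, v)


def day_coverage(t_min: np.ndarray, x: np.ndarray) -> dict[int, float]:
    """Fraction of finite samples per calendar day (day = t_min // 1440)."""
    days = np.asarray(t_min) // MINUTES_PER_DAY
    out: dict[int, float] = {}
    for d in np.unique(days):
        sel = days == d
        out[int(d)] = float(np.isfinite(np.asarray(x)[sel]).mean())
    return out


def build_analysis_signals(
    rec: ParticipantRecording,
    window_hours: float = 6.0,
    mode: Literal["centered", "trailing"] = "centered",
    max_gap_minutes: int = 60,
    vertical_axis: str = "z",
) -> AnalysisSignals:
    """Full preprocessing of one recording.

    Activity = integrated Euclidean norm of the three axes; sleep =
    integrated vertical axis; HR = neighbour-rule cleaned series.  Gaps up
    to ``max_gap_minutes`` are linearly interpolated before integration;
    longer gaps split the integration into segments and remain NaN (the
    daily-fit coverage rule downstream excludes affected days).
    """
    total = total_acceleration(rec.accel["x"], rec.accel["y"], rec.accel["z"])
    vertical = np.asarray(rec.accel[vertical_axis], dtype=float)
    hr_clean, report = clean_hr(rec.hr)

    total = interpolate_gaps(total, max_gap_minutes)
    vertical = interpolate_gaps(vertical, max_gap_minutes)
    hr_filled = interpolate_gaps(hr_clean, max_gap_minutes)

    activity = integrate_signal(total, window_hours=window_hours, mode=mode)
    sleep = integrate_signal(vertical, window_hours=window_hours, mode=mode)

    return AnalysisSignals(
        t_min=rec.t_min,
        activity=activity,
        sleep=sleep,
        hr=hr_filled,
        clean_report=report,
    )
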