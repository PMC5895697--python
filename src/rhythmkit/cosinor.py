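"""Daily cosinor fits and cross-modality phase differences.

The cosinor model fits a fixed-period (24 h) sinusoid

    y(t) = M + a*cos(2*pi*t/24) + b*sin(2*pi*t/24)

by linear least squares; amplitude = sqrt(a^2 + b^2), MESOR = M, and phase
is reported as the clock time of the fitted peak, 24/(2*pi)*atan2(b, a)
mapped into [0, 24).  One fit per calendar day; daily fits are then
averaged (phases circularly, MESOR/amplitude arithmetically) and wrapped
phase differences between modalities — HR−activity, HR−sleep,
activity−sleep — summarize each participant's internal synchrony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from rhythmkit.synthetic import MINUTES_PER_DAY

__all__ = [
    "SinusoidFit",
    "DiurnalSummary",
    "fit_daily_sinusoid",
    "fit_signal_days",
    "average_daily_fits",
    "circular_mean_hours",
    "phase_difference",
    "summarize_participant",
    "MODALITIES",
]

MODALITIES = ("activity", "sleep", "hr")

_OMEGA = 2.0 * np.pi / 24.0  # rad per hour at the diurnal period


def _wrap24(hours: float) -> float:
    """Map to [0, 24); guards the float corner case (-eps % 24) == 24.0."""
    h = float(hours) % 24.0
    return 0.0 if h >= 24.0 else h


@dataclass(frozen=True)
class SinusoidFit:
    """One day's fitted sinusoid.  ``phase_hours`` is NaN (undefined) for
    zero-variance days; ``goodness`` is the fraction of variance explained
    by the fit, in [0, 1]."""

    phase_hours: float
    mesor: float
    amplitude: float
    day_index: int
    goodness: float

    @property
    def phase_defined(self) -> bool:
        return math.isfinite(self.phase_hours)


@dataclass
class DiurnalSummary:
    """Per-participant averaged daily fits and wrapped phase differences.

    ``modalities`` maps each of activity/sleep/hr to a dict with keys
    avg_phase, avg_mesor, avg_amplitude, n_days; a modality with no valid
    day is absent.  Differences are in hours, wrapped to [-12, 12);
    positive d_hr_act means HR peaks after activity.
    """

    participant_id: str
    group: str
    modalities: dict[str, dict[str, float]]
    d_hr_act: float
    d_hr_slp: float
    d_act_slp: float


def fit_daily_sinusoid(
    t_min: np.ndarray,
    y: np.ndarray,
    day_index: int = 0,
    min_coverage: float = 0.75,
) -> SinusoidFit | None:
    """Least-squares 24-h sinusoid fit to one day of samples.

    ``t_min`` are minutes since the cohort epoch; the phase is expressed as
    clock time of the fitted peak.  Returns None when fewer than
    ``min_coverage`` of the day's minutes carry finite samples.  A
    zero-variance day yields amplitude 0 with phase NaN (undefined).
    """
    t_min = np.asarray(t_min, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < min_coverage * MINUTES_PER_DAY:
        return None
    t_h = (t_min[ok] / 60.0) % 24.0
    yy = y[ok]
    design = np.column_stack(
        [np.ones_like(t_h), np.cos(_OMEGA * t_h), np.sin(_OMEGA * t_h)]
    )
    coef, *_ = np.linalg.lstsq(design, yy, rcond=None)
    mesor, a, b = (float(c) for c in coef)
    amplitude = math.hypot(a, b)
    resid = yy - design @ coef
    tss = float(np.sum((yy - yy.mean()) ** 2))
    goodness = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    goodness = min(max(goodness, 0.0), 1.0)
    scale = max(1.0, abs(mesor), float(np.std(yy)))
    if amplitude <= 1e-12 * scale:
        return SinusoidFit(
            phase_hours=float("nan"),
            mesor=mesor,
            amplitude=0.0,
            day_index=day_index,
            goodness=goodness,
        )
    phase = _wrap24(math.atan2(b, a) / _OMEGA)
    return SinusoidFit(
        phase_hours=phase,
        mesor=mesor,
        amplitude=amplitude,
        day_index=day_index,
        goodness=goodness,
    )


def fit_signal_days(
    t_min: np.ndarray,
    y: np.ndarray,
    min_coverage: float = 0.75,
) -> list[SinusoidFit]:
    """Fit each calendar day (t_min // 1440) of a signal; days failing the
    coverage rule are skipped."""
    t_min = np.asarray(t_min)
    y = np.asarray(y, dtype=float)
    days = t_min // MINUTES_PER_DAY
    fits: list[SinusoidFit] = []
    for d in np.unique(days):
        sel = days == d
        fit = fit_daily_sinusoid(
            t_min[sel], y[sel], day_index=int(d), min_coverage=min_coverage
        )
        if fit is not None:
            fits.append(fit)
    return fits


def circular_mean_hours(phases_hours: Sequence[float]) -> float:
    """Mean of clock phases on the 24-h circle (e.g. {23, 1} -> 0)."""
    p = np.asarray(phases_hours, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        return float("nan")
    ang = p * _OMEGA
    return _wrap24(np.angle(np.mean(np.exp(1j * ang))) / _OMEGA)


def average_daily_fits(
    fits: Sequence[SinusoidFit],
    phase_method: Literal["circular", "phasor"] = "circular",
) -> tuple[float, float, float]:
    """(avg_phase, avg_mesor, avg_amplitude) across daily fits.

    Phases are averaged on the 24-h circle (days with undefined phase are
    excluded from the phase mean only); MESOR and amplitude are arithmetic
    means.  ``phase_method='phasor'`` instead averages the complex phasors
    amplitude*exp(i*phase) — the literal "average of the daily sinusoids" —
    returning the argument of the mean phasor (amplitudes stay arithmetic).
    """
    if len(fits) == 0:
        raise ValueError("average_daily_fits requires at least one fit")
    mesor = float(np.mean([f.mesor for f in fits]))
    amplitude = float(np.mean([f.amplitude for f in fits]))
    defined = [f for f in fits if f.phase_defined]
    if not defined:
        return float("nan"), mesor, amplitude
    if phase_method == "circular":
        phase = circular_mean_hours([f.phase_hours for f in defined])
    elif phase_method == "phasor":
        phasor = np.mean(
            [f.amplitude * np.exp(1j * f.phase_hours * _OMEGA) for f in defined]
        )
        phase = _wrap24(np.angle(phasor) / _OMEGA)
    else:
        raise ValueError(f"unknown phase_method {phase_method!r}")
    return phase, mesor, amplitude


def phase_difference(phase_a_hours: float, phase_b_hours: float) -> float:
    """Wrapped phase difference a − b in hours, in [-12, 12); positive
    means a peaks after b.  NaN inputs propagate."""
    if not (math.isfinite(phase_a_hours) and math.isfinite(phase_b_hours)):
        return float("nan")
    return float((phase_a_hours - phase_b_hours + 12.0) % 24.0 - 12.0)


def summarize_participant(
    signals,
    participant_id: str = "",
    group: str = "",
    min_coverage: float = 0.75,
    phase_method: Literal["circular", "phasor"] = "circular",
    difference_method: Literal["of_averages", "average_of_daily"] = "of_averages",
) -> DiurnalSummary:
    """Average daily fits per modality and the three wrapped differences.

    By default differences are computed between the averaged phases;
    ``difference_method='average_of_daily'`` instead circularly averages
    the per-day differences over days where both modalities have a defined
    phase.  A modality with zero valid days is omitted and every
    difference involving it is NaN.
    """
    series = {"activity": signals.activity, "sleep": signals.sleep, "hr": signals.hr}
    fits = {
        m: fit_signal_days(signals.t_min, x, min_coverage=min_coverage)
        for m, x in series.items()
    }
    modalities: dict[str, dict[str, float]] = {}
    for m, f in fits.items():
        if not f:
            continue
        phase, mesor, amplitude = average_daily_fits(f, phase_method=phase_method)
        modalities[m] = {
            "avg_phase": phase,
            "avg_mesor": mesor,
            "avg_amplitude": amplitude,
            "n_days": len(f),
        }

    def diff(ma: str, mb: str) -> float:
        if ma not in modalities or mb not in modalities:
            return float("nan")
        if difference_method == "of_averages":
            return phase_difference(
                modalities[ma]["avg_phase"], modalities[mb]["avg_phase"]
            )
        by_day_a = {f.day_index: f for f in fits[ma] if f.phase_defined}
        by_day_b = {f.day_index: f for f in fits[mb] if f.phase_defined}
        common = sorted(set(by_day_a) & set(by_day_b))
        if not common:
            return float("nan")
        daily = [
            phase_difference(by_day_a[d].phase_hours, by_day_b[d].phase_hours)
            for d in common
        ]
        # circular mean on the 24-h circle, re-wrapped to [-12, 12)
        mean = circular_mean_hours(daily)
        return float((mean + 12.0) % 24.0 - 12.0)

    return DiurnalSummary(
        participant_id=participant_id,
        group=group,
        modalities=modalities,
        d_hr_act=diff("hr", "activity"),
        d_hr_slp=diff("hr", "sleep"),
        d_act_slp=diff("activity", "sleep"),
    )
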