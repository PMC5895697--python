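"""Magnitude-squared coherence between physiology and mood.

For signals x, y on the common 1-min grid the magnitude-squared coherence

    C_xy(f) = |G_xy(f)|^2 / (G_xx(f) * G_yy(f))

is estimated from Welch-averaged cross- and autospectral densities.  A
value of 1 indicates an ideal linear system at that frequency, 0 no linear
relation; frequencies are reported in cycles/day, so the diurnal rhythm
sits at 1 and the ultradian component of interest at 4.  Defaults: 24-h
Hann segments with 50% overlap (7 segments over the 4-day standard window,
1 cycle/day resolution).  Coherence from a single segment is identically 1
and therefore refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectralDensities",
    "CoherenceSpectrum",
    "welch_densities",
    "msc",
    "band_summary",
    "n_segments",
]

SAMPLES_PER_DAY = 1440.0  # 1-min grid expressed in samples per day


@dataclass
class SpectralDensities:
    """Welch-averaged spectral densities on a cycles/day grid."""

    freq: np.ndarray
    G_xx: np.ndarray
    G_yy: np.ndarray
    G_xy: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        if np.any(self.G_xx < 0) or np.any(self.G_yy < 0):
            raise ValueError("autospectral densities must be non-negative")


@dataclass
class CoherenceSpectrum:
    """C_xy(f) in [0, 1]; NaN where an autospectrum vanishes (undefined)."""

    freq: np.ndarray
    C_xy: np.ndarray
    pair: tuple[str, str] = ("", "")
    participant_id: str = ""
    n_segments: int = 0


def n_segments(n: int, nperseg: int, noverlap: int) -> int:
    if n < nperseg:
        return 0
    return 1 + (n - nperseg) // (nperseg - noverlap)


def _welch_params(
    segment_hours: float, overlap_fraction: float
) -> tuple[int, int]:
    nperseg = int(round(segment_hours * 60.0))
    noverlap = int(round(overlap_fraction * nperseg))
    if not 0 <= noverlap < nperseg:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    return nperseg, noverlap


def welch_densities(
    x: np.ndarray,
    y: np.ndarray,
    segment_hours: float = 24.0,
    overlap_fraction: float = 0.5,
    window_shape: str = "hann",
    detrend_linear: bool = False,
) -> SpectralDensities:
    """Welch auto- and cross-spectral densities of two 1-min-grid series.

    Each segment is mean-removed (optionally linearly detrended), tapered
    and transformed; densities are averaged across segments.  At least two
    segments are required.  The zero-frequency bin is dropped (mean removal
    leaves it meaningless).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("series must be gap-free (interpolate first)")
    nperseg, noverlap = _welch_params(segment_hours, overlap_fraction)
    k = n_segments(len(x), nperseg, noverlap)
    if k < 2:
        raise ValueError(
            f"need >= 2 Welch segments, got {k}; coherence from one segment "
            "is identically 1"
        )
    detrend = "linear" if detrend_linear else "constant"
    common = dict(
        fs=SAMPLES_PER_DAY,
        window=window_shape,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=detrend,
    )
    freq, gxx = sps.welch(x, **common)
    _, gyy = sps.welch(y, **common)
    _, gxy = sps.csd(x, y, **common)
    keep = freq > 0
    return SpectralDensities(
        freq=freq[keep],
        G_xx=gxx[keep],
        G_yy=gyy[keep],
        G_xy=gxy[keep],
        n_segments=k,
    )


def msc(
    x: np.ndarray,
    y: np.ndarray,
    segment_hours: float = 24.0,
    overlap_fraction: float = 0.5,
    window_shape: str = "hann",
    detrend_linear: bool = False,
    pair: tuple[str, str] = ("", ""),
    participant_id: str = "",
) -> CoherenceSpectrum:
    """Magnitude-squared coherence C_xy = |G_xy|^2 / (G_xx * G_yy).

    Values are clipped to [0, 1] only against floating-point overshoot
    (< 1e-12; the Cauchy–Schwarz bound holds exactly for the averaged
    densities).  Frequencies where an autospectrum vanishes are NaN
    (undefined), never 0.
    """
    dens = welch_densities(
        x,
        y,
        segment_hours=segment_hours,
        overlap_fraction=overlap_fraction,
        window_shape=window_shape,
        detrend_linear=detrend_linear,
    )
    denom = dens.G_xx * dens.G_yy
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(dens.G_xy) ** 2 / denom
    c = np.where(denom > 0, c, np.nan)
    overshoot = np.nanmax(c) - 1.0 if np.isfinite(c).any() else 0.0
    if overshoot > 1e-9:
        raise FloatingPointError(
            f"coherence exceeded 1 by {overshoot:.3e}; inconsistent densities"
        )
    c = np.clip(c, 0.0, 1.0)
    return CoherenceSpectrum(
        freq=dens.freq,
        C_xy=c,
        pair=pair,
        participant_id=participant_id,
        n_segments=dens.n_segments,
    )


def band_summary(spectrum: CoherenceSpectrum, band: tuple[float, float]) -> float:
    """Mean coherence over grid frequencies within [f_lo, f_hi] cycles/day
    (inclusive).  An empty band is an error."""
    f_lo, f_hi = band
    if f_lo > f_hi:
        raise ValueError("band must satisfy f_lo <= f_hi")
    sel = (spectrum.freq >= f_lo - 1e-12) & (spectrum.freq <= f_hi + 1e-12)
    if not np.any(sel):
        raise ValueError(f"no grid frequencies in band [{f_lo}, {f_hi}] cycles/day")
    vals = spectrum.C_xy[sel]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("coherence undefined everywhere in the requested band")
    return float(vals.mean())
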