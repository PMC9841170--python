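"""Spectral estimation: Welch PSD, Daniell smoothing, band power and coherence.

The estimators follow the classical pipeline for stationary EEG segments:
the record is split into long overlapping windows (default 100 s with 50 s
overlap, Bartlett taper), segment periodograms are averaged, and the
resulting spectra are additionally smoothed in the frequency domain with an
unweighted (Daniell) moving average.  The magnitude coherence

    C(f) = |Gxy(f)| / sqrt(Gxx(f) * Gyy(f))

is formed from the smoothed auto- and cross-spectra and lies in [0, 1];
it quantifies frequency-resolved *linear* coupling between two EEG leads.

Smoothing is applied to Gxx, Gyy and Gxy *before* the ratio is taken:
coherence computed from a single raw periodogram is identically 1, so the
ratio is only meaningful after averaging over segments and/or frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as _sig

from .exceptions import ParameterError

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "SpectrumEstimate",
    "CrossSpectrum",
    "CoherenceEstimate",
    "welch_psd",
    "daniell_smooth",
    "band_power",
    "coherence",
    "band_coherence",
]


@dataclass(frozen=True)
class Band:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ParameterError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: Canonical analysis bands.  Two deltas are kept deliberately: the wide
#: 0–4 Hz convention used for staging/methods and the 0.1–0.5 Hz "slow"
#: band in which the blood–brain-barrier-opening power contrast lives.
DEFAULT_BANDS: Mapping[str, Band] = {
    "theta": Band("theta", 4.0, 8.0),
    "delta_wide": Band("delta_wide", 0.0, 4.0),
    "delta_slow": Band("delta_slow", 0.1, 0.5),
    "theta_staging": Band("theta_staging", 5.0, 10.0),
    "alpha": Band("alpha", 8.0, 12.0),
}


@dataclass
class SpectrumEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray  # Hz, strictly increasing, [0, Nyquist]
    psd: np.ndarray          # signal-units^2 / Hz, >= 0
    params: dict = field(default_factory=dict)

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class CrossSpectrum:
    frequencies: np.ndarray
    csd: np.ndarray  # complex cross-spectral density; Gxy = conj(Gyx)
    params: dict = field(default_factory=dict)


@dataclass
class CoherenceEstimate:
    frequencies: np.ndarray
    coherence: np.ndarray  # C(f) in [0, 1]
    n_segments: int
    daniell_bandwidth_hz: float
    params: dict = field(default_factory=dict)


def _segment_params(n: int, sampling_interval_s: float, window_s: float,
                    overlap_s: float) -> tuple[int, int]:
    if sampling_interval_s <= 0:
        raise ParameterError("sampling_interval_s must be positive")
    if not 0 <= overlap_s < window_s:
        raise ParameterError("need 0 <= overlap_s < window_s")
    nperseg = int(round(window_s / sampling_interval_s))
    noverlap = int(round(overlap_s / sampling_interval_s))
    if nperseg < 2:
        raise ParameterError("window_s too short for the sampling interval")
    if n < nperseg:
        raise ParameterError(
            f"record of {n} samples is shorter than one "
            f"{window_s}-s window ({nperseg} samples)"
        )
    return nperseg, noverlap


def welch_psd(x, sampling_interval_s: float, window_s: float = 100.0,
              overlap_s: float = 50.0, taper: str = "bartlett") -> SpectrumEstimate:
    """Welch PSD: tapered overlapping segments, periodograms averaged.

    One-sided density convention: the integral over [0, Nyquist] equals the
    (tapered) signal variance.  Per-segment mean removal only — no linear
    detrending, which would destroy the 0.1-Hz band of interest.
    """
    x = np.asarray(x, dtype=float)
    nperseg, noverlap = _segment_params(len(x), sampling_interval_s,
                                        window_s, overlap_s)
    fs = 1.0 / sampling_interval_s
    f, p = _sig.welch(x, fs=fs, window=taper, nperseg=nperseg,
                      noverlap=noverlap, detrend="constant",
                      scaling="density")
    return SpectrumEstimate(
        frequencies=f, psd=p,
        params=dict(window_s=window_s, overlap_s=overlap_s, taper=taper,
                    daniell_bandwidth_hz=0.0,
                    n_segments=_n_segments(len(x), nperseg, noverlap)),
    )


def _n_segments(n: int, nperseg: int, noverlap: int) -> int:
    step = nperseg - noverlap
    return (n - nperseg) // step + 1


def _daniell_kernel_bins(bandwidth_hz: float, df: float) -> int:
    if bandwidth_hz < df:
        raise ParameterError(
            f"Daniell bandwidth {bandwidth_hz} Hz is below the grid "
            f"spacing {df} Hz"
        )
    nbins = int(round(bandwidth_hz / df))
    if nbins % 2 == 0:  # centered window needs odd length
        nbins += 1
    return max(nbins, 1)


def _moving_average(values: np.ndarray, nbins: int) -> np.ndarray:
    """Centered unweighted moving average; edges use truncated windows."""
    if nbins <= 1:
        return values.copy()
    kernel = np.ones(nbins)
    summed = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones(len(values)), kernel, mode="same")
    return summed / counts


def daniell_smooth(spectrum: SpectrumEstimate, bandwidth_hz: float) -> SpectrumEstimate:
    """Daniell smoothing: unweighted moving average over a frequency window.

    With the default 0.01-Hz grid (100-s windows) the conventional 0.03-Hz
    and 0.13-Hz bandwidths correspond to 3- and 13-bin windows.
    """
    nbins = _daniell_kernel_bins(bandwidth_hz, spectrum.df)
    smoothed = _moving_average(np.asarray(spectrum.psd, dtype=float), nbins)
    params = dict(spectrum.params)
    params["daniell_bandwidth_hz"] = bandwidth_hz
    return SpectrumEstimate(frequencies=spectrum.frequencies.copy(),
                            psd=smoothed, params=params)


def band_power(spectrum: SpectrumEstimate, band: Band) -> float:
    """Integrated PSD over [f_lo, f_hi] (trapezoid, interpolated edges)."""
    f = np.asarray(spectrum.frequencies, dtype=float)
    p = np.asarray(spectrum.psd, dtype=float)
    if band.f_lo < f[0] - 1e-12 or band.f_hi > f[-1] + 1e-12:
        raise ParameterError(
            f"band [{band.f_lo}, {band.f_hi}] Hz outside spectrum span "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    lo = max(band.f_lo, f[0])
    hi = min(band.f_hi, f[-1])
    inner = f[(f > lo) & (f < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


def csd_estimate(x, y, sampling_interval_s: float, window_s: float = 100.0,
                 overlap_s: float = 50.0, taper: str = "bartlett") -> CrossSpectrum:
    """Segment-averaged one-sided cross-spectral density Gxy(f)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have the same length")
    nperseg, noverlap = _segment_params(len(x), sampling_interval_s,
                                        window_s, overlap_s)
    fs = 1.0 / sampling_interval_s
    f, pxy = _sig.csd(x, y, fs=fs, window=taper, nperseg=nperseg,
                      noverlap=noverlap, detrend="constant",
                      scaling="density")
    return CrossSpectrum(frequencies=f, csd=pxy,
                         params=dict(window_s=window_s, overlap_s=overlap_s,
                                     taper=taper))


def coherence(x, y, sampling_interval_s: float, window_s: float = 100.0,
              overlap_s: float = 50.0, daniell_hz: float = 0.13,
              taper: str = "bartlett") -> CoherenceEstimate:
    """Magnitude coherence C(f) = |Gxy| / sqrt(Gxx Gyy).

    Gxx, Gyy and Gxy are estimated by Welch segment averaging, then each is
    Daniell-smoothed (default 0.13-Hz window) before forming the ratio.
    The result is clipped to [0, 1] against floating-point overshoot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have the same length")
    nperseg, noverlap = _segment_params(len(x), sampling_interval_s,
                                        window_s, overlap_s)
    k = _n_segments(len(x), nperseg, noverlap)
    df = 1.0 / (nperseg * sampling_interval_s)
    nbins = _daniell_kernel_bins(daniell_hz, df) if daniell_hz > 0 else 1
    if k < 2 and nbins < 2:
        raise ParameterError(
            "coherence from a single segment with no frequency smoothing "
            "is identically 1; use >= 2 segments or a Daniell bandwidth"
        )
    fs = 1.0 / sampling_interval_s
    kw = dict(fs=fs, window=taper, nperseg=nperseg, noverlap=noverlap,
              detrend="constant", scaling="density")
    f, gxx = _sig.welch(x, **kw)
    _, gyy = _sig.welch(y, **kw)
    _, gxy = _sig.csd(x, y, **kw)
    gxx = _moving_average(gxx, nbins)
    gyy = _moving_average(gyy, nbins)
    gxy = (_moving_average(gxy.real, nbins)
           + 1j * _moving_average(gxy.imag, nbins))
    denom = np.sqrt(gxx * gyy)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(gxy) / denom
    c = np.where(denom > 0, c, 0.0)
    c = np.clip(c, 0.0, 1.0)
    return CoherenceEstimate(frequencies=f, coherence=c, n_segments=k,
                             daniell_bandwidth_hz=daniell_hz,
                             params=dict(window_s=window_s,
                                         overlap_s=overlap_s, taper=taper))


def band_coherence(estimate: CoherenceEstimate, band: Band) -> float:
    """Unweighted mean of C(f) over the band's frequency bins."""
    f = np.asarray(estimate.frequencies, dtype=float)
    if band.f_lo < f[0] - 1e-12 or band.f_hi > f[-1] + 1e-12:
        raise ParameterError(
            f"band [{band.f_lo}, {band.f_hi}] Hz outside coherence span"
        )
    mask = (f >= band.f_lo) & (f <= band.f_hi)
    if not mask.any():
        raise ParameterError("band contains no frequency bins")
    return float(np.mean(estimate.coherence[mask]))
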