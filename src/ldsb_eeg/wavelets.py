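"""Continuous wavelet transform, ridge skeleton, and oscillatory patterns.

The skeleton of the complex-Morlet CWT — the curves of frequency-local
power maxima tracked over time — localizes transient rhythms: a θ burst
appears as a ridge segment confined to 4–8 Hz, and its lifetime is the
pattern duration T.

The default mother wavelet is the complex Morlet with center frequency
``omega0 = 6`` (the standard choice for EEG rhythm analysis), for which
frequency f corresponds to scale a ≈ omega0 / (2*pi*f) and the e-folding
cone of influence extends sqrt(2)·a on each edge.

Detection thresholds are set relative to the data: the default pattern
power floor is half the median ridge power inside the band, so that the
threshold crosses the smeared edge of a burst near its half-power point
and durations are estimated without systematic edge bias; a minimum
duration of two cycles of the band center frequency discards spurious
single-oscillation maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .exceptions import ParameterError
from .spectral import Band

__all__ = [
    "WaveletSurface",
    "Ridge",
    "PatternSet",
    "cwt",
    "skeleton",
    "detect_patterns",
    "mean_duration",
    "default_frequency_grid",
]


def default_frequency_grid(f_min: float = 0.05, f_max: float = 30.0,
                           n_voices: int = 30) -> np.ndarray:
    """Log-spaced CWT frequency grid (default 30 voices, 0.05–30 Hz)."""
    if not 0 < f_min < f_max:
        raise ParameterError("need 0 < f_min < f_max")
    return np.geomspace(f_min, f_max, n_voices)


@dataclass
class WaveletSurface:
    """|W(f, t)|^2 power surface on (frequencies x times) grids."""

    frequencies: np.ndarray  # Hz, strictly increasing
    times: np.ndarray        # s
    power: np.ndarray        # (n_freq, n_time), >= 0
    coi_s: np.ndarray        # cone-of-influence half-width per frequency (s)
    params: dict = field(default_factory=dict)


@dataclass
class Ridge:
    """One skeleton curve: per-time frequency indices and powers."""

    time_idx: np.ndarray
    freq_idx: np.ndarray
    power: np.ndarray


@dataclass
class PatternEvent:
    band: str
    t_start: float
    t_end: float
    peak_frequency: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class PatternSet:
    events: list[PatternEvent]
    band: Band | None = None
    record_duration_s: float | None = None

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.t_end <= ev.t_start:
                raise ParameterError("pattern events need t_end > t_start")
            if (self.record_duration_s is not None
                    and ev.t_end > self.record_duration_s + 1e-9):
                raise ParameterError("pattern event beyond the record span")

    @property
    def durations(self) -> np.ndarray:
        return np.array([ev.duration for ev in self.events])


def cwt(signal, sampling_interval_s: float, freqs,
        omega0: float = 6.0) -> WaveletSurface:
    """Complex-Morlet CWT power surface.

    The implementation uses pywt's ``cmor`` family with bandwidth B = 2 and
    center frequency C = omega0 / (2*pi), i.e. the analytic Morlet
    exp(i*omega0*t)*exp(-t^2/2) up to normalization.  pywt's scaling yields
    a time-averaged surface that is flat in frequency for white noise (the
    1/f-corrected convention); frequencies whose wavelet support crosses
    the Nyquist frequency lose power to truncation.
    """
    x = np.asarray(signal, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ParameterError("empty frequency grid")
    nyq = 0.5 / sampling_interval_s
    if np.any(freqs <= 0) or np.any(freqs > nyq):
        raise ParameterError(f"frequencies must lie in (0, {nyq}] Hz")
    if np.any(np.diff(freqs) <= 0):
        raise ParameterError("frequency grid must be strictly increasing")
    center = omega0 / (2.0 * np.pi)
    wavelet = f"cmor2.0-{center!r}"
    scales = pywt.frequency2scale(wavelet, freqs * sampling_interval_s)
    coef, _ = pywt.cwt(x, scales, wavelet,
                       sampling_period=sampling_interval_s, method="fft")
    power = np.abs(coef) ** 2
    times = np.arange(len(x)) * sampling_interval_s
    coi_s = np.sqrt(2.0) * omega0 / (2.0 * np.pi * freqs)
    return WaveletSurface(frequencies=freqs, times=times, power=power,
                          coi_s=coi_s,
                          params=dict(omega0=omega0,
                                      sampling_interval_s=sampling_interval_s))


def skeleton(surface: WaveletSurface, noise_floor: float = 0.0,
             link_tolerance: int = 1) -> list[Ridge]:
    """Extract ridges: per-time local maxima across frequency, linked in time.

    A maximum continues an active ridge if its frequency index is within
    ``link_tolerance`` bins of the ridge's last point; otherwise it starts
    a new ridge.
    """
    p = surface.power
    nf, nt = p.shape
    if nf < 3:
        raise ParameterError("need at least 3 frequency bins for maxima")
    interior = p[1:-1]
    is_max = (interior > p[:-2]) & (interior >= p[2:]) & (interior > noise_floor)

    ridges: list[Ridge] = []
    active: list[list[list[int]]] = []  # [time_idx, freq_idx, power] triples
    active_f: list[int] = []
    for t in range(nt):
        maxima = np.flatnonzero(is_max[:, t]) + 1
        used = np.zeros(len(maxima), dtype=bool)
        new_active, new_f = [], []
        for ridge, f_last in zip(active, active_f):
            if len(maxima):
                j = int(np.argmin(np.abs(maxima - f_last)))
                if not used[j] and abs(int(maxima[j]) - f_last) <= link_tolerance:
                    fi = int(maxima[j])
                    ridge[0].append(t)
                    ridge[1].append(fi)
                    ridge[2].append(float(p[fi, t]))
                    used[j] = True
                    new_active.append(ridge)
                    new_f.append(fi)
                    continue
            ridges.append(ridge)  # ridge ends
        for j, fi in enumerate(maxima):
            if not used[j]:
                new_active.append([[t], [int(fi)], [float(p[fi, t])]])
                new_f.append(int(fi))
        active, active_f = new_active, new_f
    ridges.extend(active)
    return [Ridge(time_idx=np.array(r[0]), freq_idx=np.array(r[1]),
                  power=np.array(r[2])) for r in ridges]


def _band_ridge_powers(ridges: list[Ridge], surface: WaveletSurface,
                       band: Band) -> np.ndarray:
    f = surface.frequencies
    vals = []
    for r in ridges:
        fr = f[r.freq_idx]
        m = (fr >= band.f_lo) & (fr <= band.f_hi)
        vals.append(r.power[m])
    return np.concatenate(vals) if vals else np.array([])


def detect_patterns(ridges: list[Ridge], surface: WaveletSurface, band: Band,
                    min_duration_s: float | None = None,
                    power_floor: float | None = None,
                    floor_factor: float = 0.5,
                    low_floor_ratio: float = 0.3,
                    smooth_s: float | None = None,
                    merge_gap_s: float | None = None) -> PatternSet:
    """Band-confined ridge segments above a power floor -> pattern events.

    ``power_floor=None`` sets the floor to ``floor_factor`` times the
    median ridge power inside the band (half-power rule by default, so a
    smeared burst edge is crossed near its true boundary).
    ``min_duration_s=None`` defaults to two cycles of the band center.

    Detection uses hysteresis: event *edges* are located at the main
    floor, but an event only *breaks* where the (lightly smoothed) ridge
    power drops below ``low_floor_ratio`` times the floor — transient
    interference dips within one oscillatory event do not split it,
    while true silent gaps do.  Events on ridges interrupted for less
    than ``merge_gap_s`` (default one band-center cycle) are merged.
    """
    if min_duration_s is None:
        min_duration_s = 2.0 / band.center
    if smooth_s is None:
        smooth_s = 1.0 / band.center
    if merge_gap_s is None:
        merge_gap_s = 1.0 / band.center
    if power_floor is None:
        in_band = _band_ridge_powers(ridges, surface, band)
        power_floor = (floor_factor * float(np.median(in_band))
                       if in_band.size else np.inf)
        # refine: re-anchor the floor to ridge power *inside* detected
        # events, so quiet-gap ridge points cannot drag it down (the bias
        # would otherwise depend on the rhythm's duty cycle)
        first = detect_patterns(ridges, surface, band,
                                min_duration_s=min_duration_s,
                                power_floor=power_floor,
                                low_floor_ratio=low_floor_ratio,
                                smooth_s=smooth_s, merge_gap_s=merge_gap_s)
        if first.events:
            t_grid = surface.times
            f_grid = surface.frequencies
            ev_starts = np.array([ev.t_start for ev in first.events])
            ev_ends = np.array([ev.t_end for ev in first.events])
            inside = []
            for ridge in ridges:
                fr = f_grid[ridge.freq_idx]
                tr = t_grid[ridge.time_idx]
                k = np.searchsorted(ev_starts, tr, side="right") - 1
                sel = ((fr >= band.f_lo) & (fr <= band.f_hi) & (k >= 0)
                       & (tr <= ev_ends[np.clip(k, 0, None)]))
                if sel.any():
                    inside.append(ridge.power[sel])
            if inside:
                power_floor = floor_factor * float(
                    np.median(np.concatenate(inside)))
    low_floor = low_floor_ratio * power_floor
    f = surface.frequencies
    t = surface.times
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    n_sm = max(1, int(round(smooth_s / dt)))
    raw: list[PatternEvent] = []
    for ridge in ridges:
        fr = f[ridge.freq_idx]
        power = ridge.power
        if n_sm > 1 and len(power) > 1:
            kernel = np.ones(min(n_sm, len(power)))
            power = (np.convolve(power, kernel, mode="same")
                     / np.convolve(np.ones(len(power)), kernel, mode="same"))
        in_band = (fr >= band.f_lo) & (fr <= band.f_hi)
        ok_low = in_band & (power >= low_floor)
        ok_high = in_band & (power >= power_floor)
        if not ok_high.any():
            continue
        # maximal runs above the low floor, trimmed to main-floor edges
        padded = np.concatenate(([0], ok_low.astype(np.int8), [0]))
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for a, b in zip(starts, ends):
            seg_high = np.flatnonzero(ok_high[a:b])
            if seg_high.size == 0:
                continue
            a2 = a + seg_high[0]
            b2 = a + seg_high[-1] + 1
            t0 = t[ridge.time_idx[a2]]
            t1 = t[ridge.time_idx[b2 - 1]]
            seg_p = ridge.power[a2:b2]
            peak = fr[a2:b2][int(np.argmax(seg_p))]
            raw.append(PatternEvent(band=band.name, t_start=float(t0),
                                    t_end=float(t1),
                                    peak_frequency=float(peak)))
    raw.sort(key=lambda e: e.t_start)
    merged: list[PatternEvent] = []
    for ev in raw:
        if merged and ev.t_start - merged[-1].t_end <= merge_gap_s:
            prev = merged[-1]
            merged[-1] = PatternEvent(
                band=prev.band, t_start=prev.t_start,
                t_end=max(prev.t_end, ev.t_end),
                peak_frequency=prev.peak_frequency)
        else:
            merged.append(ev)
    events = [ev for ev in merged if ev.duration >= min_duration_s]
    return PatternSet(events=events, band=band,
                      record_duration_s=float(t[-1] + (t[1] - t[0])
                                              if len(t) > 1 else t[-1]))


def mean_duration(pattern_set: PatternSet) -> float:
    """Arithmetic mean pattern duration T (s); 0.0 for an empty set."""
    d = pattern_set.durations
    return float(d.mean()) if d.size else 0.0
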