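"""Rule-based rodent sleep staging on 10-s epochs.

Implements the visual scoring criteria as a deterministic decision cascade
on spectral power fractions and EMG amplitude:

* WAKE — desynchronized, high-frequency EEG (8–12 Hz fraction > 10%) with
  relatively high-amplitude EMG;
* NREM — synchronized high-amplitude slow activity, δ (0–4 Hz) fraction
  > 30% with lower EMG;
* REM — θ (5–10 Hz) fraction > 20% with low EMG.

The visual-scoring phrase "% of EEG waveforms/epoch" has no computable
definition; it is interpreted here as the spectral power fraction
(periodogram power in band / total power) of the epoch.  "High/low EMG" is
quantified as the epoch EMG RMS above/below the per-recording median
(configurable as an absolute threshold).  Epochs matching no rule inherit
the previous epoch's label; a first unscored epoch defaults to WAKE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .exceptions import ParameterError
from .synthetic import Recording
from .timeseries_io import epochize

__all__ = [
    "WAKE", "NREM", "REM",
    "StageFeatures", "StageLabel", "StagingThresholds",
    "epoch_features", "score_epoch", "score_recording",
]

WAKE, NREM, REM = "WAKE", "NREM", "REM"


@dataclass(frozen=True)
class StageFeatures:
    """Per-epoch spectral fractions and EMG amplitude."""

    delta_fraction: float   # 0–4 Hz power / total power
    theta_fraction: float   # 5–10 Hz
    alpha_fraction: float   # 8–12 Hz
    emg_rms: float


@dataclass(frozen=True)
class StageLabel:
    epoch_index: int
    label: str
    features: StageFeatures


@dataclass(frozen=True)
class StagingThresholds:
    """Decision thresholds; defaults follow the scoring criteria."""

    alpha_fraction: float = 0.10   # WAKE: 8–12 Hz fraction above this
    delta_fraction: float = 0.30   # NREM: 0–4 Hz fraction above this
    theta_fraction: float = 0.20   # REM: 5–10 Hz fraction above this
    emg_rms: float | None = None   # None -> per-recording median EMG RMS


def _fraction(f: np.ndarray, p: np.ndarray, lo: float, hi: float,
              total: float) -> float:
    mask = (f >= lo) & (f <= hi)
    if total <= 0:
        return 0.0
    return float(np.trapezoid(p[mask], f[mask]) / total)


def epoch_features(eeg_epoch, emg_epoch, sampling_interval_s: float,
                   epoch_s: float = 10.0) -> StageFeatures:
    """Spectral power fractions (0–4, 5–10, 8–12 Hz) and EMG RMS."""
    eeg = np.asarray(eeg_epoch, dtype=float)
    emg = np.asarray(emg_epoch, dtype=float)
    n_expected = int(round(epoch_s / sampling_interval_s))
    if len(eeg) != n_expected or len(emg) != n_expected:
        raise ParameterError(
            f"epoch must be {epoch_s} s = {n_expected} samples; got "
            f"EEG {len(eeg)}, EMG {len(emg)}"
        )
    f, p = _sig.periodogram(eeg, fs=1.0 / sampling_interval_s,
                            detrend="constant")
    total = float(np.trapezoid(p, f))
    return StageFeatures(
        delta_fraction=_fraction(f, p, 0.0, 4.0, total),
        theta_fraction=_fraction(f, p, 5.0, 10.0, total),
        alpha_fraction=_fraction(f, p, 8.0, 12.0, total),
        emg_rms=float(np.sqrt(np.mean(emg ** 2))),
    )


def score_epoch(features: StageFeatures, thresholds: StagingThresholds,
                emg_threshold: float, previous: str = WAKE) -> str:
    """Decision cascade WAKE -> NREM -> REM -> inherit-previous."""
    high_emg = features.emg_rms > emg_threshold
    if high_emg and features.alpha_fraction > thresholds.alpha_fraction:
        return WAKE
    if not high_emg and features.delta_fraction > thresholds.delta_fraction:
        return NREM
    if not high_emg and features.theta_fraction > thresholds.theta_fraction:
        return REM
    return previous


def score_recording(recording: Recording,
                    thresholds: StagingThresholds | None = None,
                    eeg_channel: str | None = None,
                    epoch_s: float = 10.0) -> list[StageLabel]:
    """Score consecutive non-overlapping epochs of a whole recording."""
    thresholds = thresholds or StagingThresholds()
    if recording.duration_s < epoch_s:
        raise ParameterError("recording shorter than one epoch")
    emg = recording.emg()  # raises ParameterError if no EMG channel
    if eeg_channel is None:
        eeg = recording.eeg_pair()[0]
    else:
        eeg = recording.channel(eeg_channel)
    dt = recording.sampling_interval_s
    feats = []
    for ep in epochize(recording, epoch_s):
        sl = ep.sample_slice
        feats.append(epoch_features(eeg[sl], emg[sl], dt, epoch_s))
    if thresholds.emg_rms is not None:
        emg_thr = thresholds.emg_rms
    else:
        emg_thr = float(np.median([f.emg_rms for f in feats]))
    labels = []
    prev = WAKE
    for i, f in enumerate(feats):
        lab = score_epoch(f, thresholds, emg_thr, previous=prev)
        labels.append(StageLabel(epoch_index=i, label=lab, features=f))
        prev = lab
    return labels
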