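"""Recording I/O (EDF and delimited text) and epoch slicing.

Time convention: seconds from record start, 0-based, half-open intervals
[start, start + duration).

CSV dialect: a first comment line ``# sampling_interval_s=<float>``, then a
header row of channel labels, then one column per channel — chosen so
fixtures stay diffable and round-trip exactly at full float precision.

EDF: the writer emits plain 16-bit EDF with per-channel physical ranges
auto-scaled to the data; reading goes through :func:`mne.io.read_raw_edf`.
EDF quantizes to 16 bits, so round-trips are exact only to ~ptp/2^16.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from .exceptions import FormatError, ParameterError
from .synthetic import Recording

__all__ = ["Epoch", "read_recording", "write_recording", "epochize"]


@dataclass
class Epoch:
    """A [start, start+duration) slice of a recording."""

    recording: Recording
    start_s: float
    duration_s: float = 10.0
    channels: list[str] | None = None  # None = all channels

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ParameterError("start_s must be >= 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.start_s + self.duration_s > self.recording.duration_s + 1e-9:
            raise ParameterError("epoch extends past the end of the recording")

    @property
    def sample_slice(self) -> slice:
        dt = self.recording.sampling_interval_s
        i0 = int(round(self.start_s / dt))
        return slice(i0, i0 + int(round(self.duration_s / dt)))

    def samples(self) -> np.ndarray:
        sl = self.sample_slice
        if self.channels is None:
            return self.recording.samples[:, sl]
        rows = [self.recording.channel_labels.index(c) for c in self.channels]
        return self.recording.samples[rows, sl]

    def channel(self, label: str) -> np.ndarray:
        return self.recording.channel(label)[self.sample_slice]


def epochize(recording: Recording, epoch_s: float,
             step_s: float | None = None) -> list[Epoch]:
    """Slice a recording into epochs of epoch_s at step_s spacing.

    The trailing partial epoch is discarded.  Default step equals the epoch
    length (non-overlapping); 100-s windows with a 50-s step give the
    overlapping segmentation the spectral estimators use.
    """
    if epoch_s <= 0:
        raise ParameterError("epoch_s must be > 0")
    if step_s is None:
        step_s = epoch_s
    if step_s <= 0:
        raise ParameterError("step_s must be > 0")
    total = recording.duration_s
    if epoch_s > total + 1e-9:
        raise ParameterError(
            f"epoch of {epoch_s} s exceeds the {total:.1f}-s record"
        )
    n = int(math.floor((total - epoch_s) / step_s + 1e-9)) + 1
    return [Epoch(recording, i * step_s, epoch_s) for i in range(n)]


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

def _write_csv(recording: Recording, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_interval_s={recording.sampling_interval_s!r}\n")
        fh.write(",".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.samples.T, delimiter=",", fmt="%.17g")


def _read_csv(path) -> Recording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#") or "sampling_interval_s" not in header:
            raise FormatError(
                f"{path}: missing '# sampling_interval_s=' comment line"
            )
        try:
            dt = float(header.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"{path}: bad sampling interval") from exc
        labels = [c.strip() for c in fh.readline().strip().split(",") if c.strip()]
        if not labels:
            raise FormatError(f"{path}: missing channel-label header row")
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed sample rows") from exc
    if data.size == 0 or data.shape[1] != len(labels):
        raise FormatError(
            f"{path}: sample columns ({data.shape[1] if data.size else 0}) "
            f"do not match channel labels ({len(labels)})"
        )
    return Recording(samples=data.T, sampling_interval_s=dt,
                     channel_labels=labels,
                     subject_id=os.path.splitext(os.path.basename(path))[0])


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(recording: Recording, path) -> None:
    """Minimal EDF writer: 16-bit samples, 1-s data records.

    The record is truncated to a whole number of seconds (EDF stores an
    integral number of fixed-duration data records).  Physical min/max are
    auto-scaled per channel to the data range.
    """
    dt = recording.sampling_interval_s
    spr = int(round(1.0 / dt))  # samples per 1-s record, per channel
    if abs(spr * dt - 1.0) > 1e-6:
        raise ParameterError(
            "EDF writer requires a sampling rate that is an integer number "
            "of samples per second"
        )
    n_records = recording.n_samples // spr
    if n_records == 0:
        raise ParameterError("recording shorter than one 1-s EDF record")
    ns = recording.n_channels
    data = recording.samples[:, :n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid a zero physical span on constant channels
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    now = datetime.now(timezone.utc)
    buf = io.BytesIO()
    buf.write(_edf_field("0", 8))                      # version
    buf.write(_edf_field(recording.subject_id or "X", 80))
    buf.write(_edf_field("recording", 80))
    buf.write(_edf_field(now.strftime("%d.%m.%y"), 8))
    buf.write(_edf_field(now.strftime("%H.%M.%S"), 8))
    buf.write(_edf_field(str(256 * (ns + 1)), 8))      # header bytes
    buf.write(_edf_field("", 44))                      # reserved
    buf.write(_edf_field(str(n_records), 8))
    buf.write(_edf_field("1", 8))                      # record duration (s)
    buf.write(_edf_field(str(ns), 4))
    for lab in recording.channel_labels:
        buf.write(_edf_field(lab, 16))
    for _ in range(ns):
        buf.write(_edf_field("synthetic", 80))         # transducer
    for _ in range(ns):
        buf.write(_edf_field("uV", 8))                 # physical dimension
    for v in phys_min:
        buf.write(_edf_field(f"{v:.8g}"[:8], 8))
    for v in phys_max:
        buf.write(_edf_field(f"{v:.8g}"[:8], 8))
    for _ in range(ns):
        buf.write(_edf_field(str(dig_min), 8))
    for _ in range(ns):
        buf.write(_edf_field(str(dig_max), 8))
    for _ in range(ns):
        buf.write(_edf_field("", 80))                  # prefiltering
    for _ in range(ns):
        buf.write(_edf_field(str(spr), 8))
    for _ in range(ns):
        buf.write(_edf_field("", 32))                  # reserved

    # data records: channel-sequential within each record
    blocks = digital.reshape(ns, n_records, spr)
    for r in range(n_records):
        for ch in range(ns):
            buf.write(blocks[ch, r].tobytes())
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def _read_edf(path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    data = raw.get_data()  # Volts for EEG-type channels
    # mne rescales channels it recognizes as physiological (unit uV -> V);
    # undo that to return the stored physical values.
    units = raw._orig_units if hasattr(raw, "_orig_units") else {}
    scales = np.ones(data.shape[0])
    for i, name in enumerate(raw.ch_names):
        unit = (units or {}).get(name, "")
        if str(unit).lower() in ("uv", "µv"):
            scales[i] = 1e6
    data = data * scales[:, None]
    return Recording(samples=data,
                     sampling_interval_s=1.0 / raw.info["sfreq"],
                     channel_labels=list(raw.ch_names),
                     subject_id=os.path.splitext(os.path.basename(path))[0])


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".edf":
        return "edf"
    if ext in (".csv", ".txt", ".tsv"):
        return "csv"
    raise ParameterError(f"cannot infer format from {path!r}; pass format=")


def write_recording(recording: Recording, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(recording, path)
    elif fmt == "csv":
        _write_csv(recording, path)
    else:
        raise ParameterError(f"unsupported format {fmt!r}")


def read_recording(path, format: str | None = None) -> Recording:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ParameterError(f"unsupported format {fmt!r}")
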