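"""Synthetic three-state rat EEG/EMG cohort generator.

The generator is a stand-in for the study animals: it produces two-lead
cortical EEG plus one EMG channel at 2 kHz for three brain states — active
wakefulness, NREM-dominated sleep, and a blood–brain-barrier-opening-like
(OBBB) state — with *known* injected ground truth for every quantity the
analysis pipeline later estimates:

* inter-lead magnitude coherence in the θ band (4–8 Hz),
* power of the slow 0.1-Hz oscillation (the δ 0.1–0.5 Hz contrast),
* θ-burst durations (oscillatory-pattern lifetimes),
* bilateral δ-band synchrony, infra-slow content, EMG tone,
* and per-epoch vigilance-stage labels.

Construction.  Each EEG lead is a sum of exactly variance-normalized,
mutually orthogonal band-limited processes:

=========== =============== ========================================
component   band (Hz)       cross-lead structure
=========== =============== ========================================
infra-slow  0.01–0.05       shared (global)
slow        0.08–0.12       shared (global 0.1-Hz oscillation)
delta       0.5–4           correlated with coefficient ``delta_coherence``
theta       4–8             burst-gated coherent pair at ``theta_coherence``
alpha       8–12            independent
background  2–3.5, 8.5+     independent 1/f
=========== =============== ========================================

The θ pair is built as x = sqrt(c)·s + sqrt(1−c)·n1 and
y = sqrt(c)·s + sqrt(1−c)·n2 with independent equal-power band-limited
sources, which gives population magnitude coherence C(f) = c in-band; a
shared on/off burst envelope (shifted-exponential durations) gates both
leads so the θ rhythm occurs in discrete oscillatory events.  The 1/f
background deliberately leaves spectral holes around the narrow injected
components so the injected coherence and power ratios are recoverable by
the estimators without bias from overlapping noise.

Every component is scaled to its exact target sample variance, so band
powers are deterministic per recording (mirroring the very small
between-animal SEMs of real state-averaged EEG band powers) while phases
and waveforms remain random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "StateProfile",
    "Recording",
    "GroundTruth",
    "GENERATOR_BANDS",
    "BACKGROUND_SUPPORT",
    "coherent_pair",
    "generate_recording",
    "generate_cohort",
    "concatenate_recordings",
    "default_profiles",
    "profiles_from_yaml",
    "WAKE_PROFILE",
    "SLEEP_PROFILE",
    "OBBB_PROFILE",
    "REM_PROFILE",
]

#: Frequency bands (Hz) of the injected narrowband components.
GENERATOR_BANDS: Mapping[str, tuple[float, float]] = {
    "infraslow": (0.01, 0.05),
    "slow": (0.08, 0.12),
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
}

#: Support of the 1/f background (Hz); the holes below 1.5 Hz and across
#: 3.5–8.5 Hz keep the slow/θ measurement bands free of independent noise,
#: and most background power sits above 8.5 Hz (desynchronized activity).
BACKGROUND_SUPPORT: tuple[tuple[float, float], ...] = ((2.0, 3.5), (8.5, 500.0))

_STAGES = ("WAKE", "NREM", "REM")

# Minimum burst duration / gap (s); durations are d_min + Exp(mean - d_min)
# so the mean is exact while no "pattern" is shorter than ~2 theta cycles.
_BURST_MIN_S = 0.4
_GAP_MIN_S = 0.5


@dataclass(frozen=True)
class StateProfile:
    """Ground-truth parameters of one brain state.

    ``band_powers`` maps component names (see :data:`GENERATOR_BANDS`) to
    variance fractions of the unit-total EEG; the remainder is 1/f
    background.  ``slow_power_boost`` multiplies the "slow" fraction, which
    is how the δ(0.1–0.5 Hz) group contrast is injected.
    """

    state_name: str
    band_powers: Mapping[str, float]
    theta_coherence: float
    slow_power_boost: float = 1.0
    emg_tone: float = 1.0
    burst_mean_duration_s: float = 1.2
    burst_duty: float = 0.35
    delta_coherence: float = 0.5
    stage: str = "WAKE"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_coherence <= 1.0:
            raise ParameterError("theta_coherence must be in [0, 1]")
        if not 0.0 <= self.delta_coherence <= 1.0:
            raise ParameterError("delta_coherence must be in [0, 1]")
        if self.slow_power_boost < 0:
            raise ParameterError("slow_power_boost must be >= 0")
        if self.emg_tone <= 0:
            raise ParameterError("emg_tone must be > 0")
        if self.burst_mean_duration_s <= 0:
            raise ParameterError("burst_mean_duration_s must be > 0")
        if not 0.0 < self.burst_duty < 1.0:
            raise ParameterError("burst_duty must be in (0, 1)")
        if self.stage not in _STAGES:
            raise ParameterError(f"stage must be one of {_STAGES}")
        unknown = set(self.band_powers) - set(GENERATOR_BANDS)
        if unknown:
            raise ParameterError(f"unknown band names: {sorted(unknown)}")
        if any(v < 0 for v in self.band_powers.values()):
            raise ParameterError("band-power fractions must be >= 0")
        total = sum(self.effective_band_powers().values())
        if total > 1.0 + 1e-9:
            raise ParameterError(
                f"effective band-power fractions sum to {total:.3f} > 1"
            )

    def effective_band_powers(self) -> dict[str, float]:
        """Variance fractions with the slow boost applied."""
        out = dict(self.band_powers)
        if "slow" in out:
            out["slow"] = out["slow"] * self.slow_power_boost
        return out

    @property
    def background_power(self) -> float:
        return 1.0 - sum(self.effective_band_powers().values())


@dataclass
class Recording:
    """A multichannel recording: channels x time, in arbitrary EEG units."""

    samples: np.ndarray
    sampling_interval_s: float
    channel_labels: Sequence[str]
    subject_id: str = "S00"
    state: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_interval_s <= 0:
            raise ParameterError("sampling_interval_s must be > 0")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ParameterError(
                "channel_labels length must match the number of channels"
            )
        self.channel_labels = list(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sampling_interval_s

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ParameterError(
                f"no channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.samples[idx]

    def eeg_pair(self) -> tuple[np.ndarray, np.ndarray]:
        eeg = [self.samples[i] for i, lab in enumerate(self.channel_labels)
               if "EEG" in lab.upper()]
        if len(eeg) < 2:
            raise ParameterError("recording does not contain two EEG channels")
        return eeg[0], eeg[1]

    def emg(self) -> np.ndarray:
        for i, lab in enumerate(self.channel_labels):
            if "EMG" in lab.upper():
                return self.samples[i]
        raise ParameterError("recording does not contain an EMG channel")


@dataclass
class GroundTruth:
    """Injected parameters of a generated recording (the test oracle)."""

    theta_coherence: float
    band_variances: dict[str, float]
    background_variance: float
    bursts: list[tuple[float, float]]
    stage_labels: list[str]
    burst_mean_duration_s: float
    delta_coherence: float = 0.0
    epoch_s: float = 10.0

    def __post_init__(self) -> None:
        for a, b in zip(self.bursts, self.bursts[1:]):
            if a[1] > b[0] + 1e-12:
                raise ParameterError("burst intervals must not overlap")
        bad = set(self.stage_labels) - set(_STAGES)
        if bad:
            raise ParameterError(f"stage labels must be in {_STAGES}: {bad}")

    @property
    def burst_durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.bursts])


# --------------------------------------------------------------------------
# low-level builders
# --------------------------------------------------------------------------

def _band_mask(freqs: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    return (freqs > max(f_lo, 1e-12)) & (freqs <= f_hi)


def _bandlimited_noise(rng: np.random.Generator, n: int, dt: float,
                       f_lo: float, f_hi: float) -> np.ndarray | None:
    """Unit-variance random-phase multisine confined to [f_lo, f_hi];
    None if the band contains no resolvable Fourier bins at this record
    length.

    All in-band Fourier amplitudes are equal and only phases are random
    (a Gaussian-like process by the CLT), so the spectral envelope — and
    with it any band-power split — is deterministic per realization.
    """
    freqs = np.fft.rfftfreq(n, dt)
    mask = _band_mask(freqs, f_lo, f_hi)
    if not mask.any():
        return None
    spec = np.zeros(len(freqs), dtype=complex)
    m = int(mask.sum())
    spec[mask] = np.exp(2j * np.pi * rng.uniform(size=m))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        return None
    return x / sd


def _background_noise(rng: np.random.Generator, n: int, dt: float,
                      alpha: float = 1.0) -> np.ndarray:
    """Unit-variance random-phase 1/f^alpha noise on
    :data:`BACKGROUND_SUPPORT` (deterministic spectral envelope)."""
    freqs = np.fft.rfftfreq(n, dt)
    nyq = 0.5 / dt
    amp = np.zeros(len(freqs))
    for f_lo, f_hi in BACKGROUND_SUPPORT:
        mask = _band_mask(freqs, f_lo, min(f_hi, nyq))
        amp[mask] = freqs[mask] ** (-alpha / 2.0)
    spec = amp * np.exp(2j * np.pi * rng.uniform(size=len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _coherent_band_pair(rng: np.random.Generator, n: int, dt: float,
                        f_lo: float, f_hi: float,
                        c: float) -> tuple[np.ndarray, np.ndarray] | None:
    """Two unit-variance band-limited signals with in-band coherence c."""
    s = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
    n1 = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
    n2 = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
    if s is None or n1 is None or n2 is None:
        return None
    a, b = np.sqrt(c), np.sqrt(1.0 - c)
    x = a * s + b * n1
    y = a * s + b * n2
    return x / x.std(), y / y.std()


def _burst_intervals(rng: np.random.Generator, length_s: float,
                     mean_dur_s: float, duty: float) -> list[tuple[float, float]]:
    """Alternating burst/gap renewal process with shifted-exponential laws."""
    exp_dur = max(mean_dur_s - _BURST_MIN_S, 1e-3)
    mean_gap = mean_dur_s * (1.0 - duty) / duty
    exp_gap = max(mean_gap - _GAP_MIN_S, 1e-3)
    out: list[tuple[float, float]] = []
    t = float(rng.uniform(0.0, mean_gap))  # random phase: start inside a gap
    while t < length_s:
        dur = _BURST_MIN_S + float(rng.exponential(exp_dur))
        end = min(t + dur, length_s)
        if end - t >= _BURST_MIN_S * 0.5:  # drop clipped slivers at the edge
            out.append((t, end))
        t += dur + _GAP_MIN_S + float(rng.exponential(exp_gap))
    return out


def _envelope_from_intervals(intervals: Sequence[tuple[float, float]],
                             n: int, dt: float) -> np.ndarray:
    env = np.zeros(n)
    for a, b in intervals:
        env[int(round(a / dt)):int(round(b / dt))] = 1.0
    return env


def _scaled(x: np.ndarray | None, variance: float) -> np.ndarray | float:
    if x is None or variance <= 0:
        return 0.0
    sd = x.std()
    if sd == 0:
        return 0.0
    return x * (np.sqrt(variance) / sd)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def coherent_pair(length_s: float, sampling_interval_s: float,
                  band: tuple[float, float], target_coherence: float,
                  seed: int) -> Recording:
    """Two-channel band-limited recording with known in-band coherence.

    Built as x = sqrt(c)·s + sqrt(1−c)·n1, y = sqrt(c)·s + sqrt(1−c)·n2 with
    s, n1, n2 independent equal-power band-limited sources, so the
    population magnitude coherence in-band equals ``target_coherence``.
    """
    if not 0.0 <= target_coherence <= 1.0:
        raise ParameterError("target_coherence must be in [0, 1]")
    f_lo, f_hi = band
    nyq = 0.5 / sampling_interval_s
    if not 0 <= f_lo < f_hi <= nyq:
        raise ParameterError(
            f"band [{f_lo}, {f_hi}] Hz must lie within (0, {nyq}] Hz"
        )
    if length_s <= 0:
        raise ParameterError("length_s must be > 0")
    n = int(round(length_s / sampling_interval_s))
    rng = np.random.default_rng(seed)
    pair = _coherent_band_pair(rng, n, sampling_interval_s, f_lo, f_hi,
                               target_coherence)
    if pair is None:
        raise ParameterError(
            "band contains no resolvable frequencies at this record length"
        )
    return Recording(samples=np.vstack(pair),
                     sampling_interval_s=sampling_interval_s,
                     channel_labels=["EEG-L", "EEG-R"],
                     subject_id="pair", state=None)


def generate_recording(profile: StateProfile, length_s: float, seed: int,
                       sampling_interval_s: float = 0.0005,
                       subject_id: str = "S00") -> tuple[Recording, GroundTruth]:
    """Generate one three-channel recording (EEG-L, EEG-R, EMG) + oracle.

    Identical (profile, length, seed) gives bit-identical output.  Records
    of >= 600 s are recommended so all injected bands are well resolved;
    bands unresolvable at the requested length are skipped with a warning.
    """
    if length_s <= 0:
        raise ParameterError("length_s must be > 0")
    dt = sampling_interval_s
    if dt <= 0:
        raise ParameterError("sampling_interval_s must be > 0")
    n = int(round(length_s / dt))
    rng = np.random.default_rng(seed)
    fractions = profile.effective_band_powers()

    left = np.zeros(n)
    right = np.zeros(n)
    realized: dict[str, float] = {}

    # shared global components ------------------------------------------------
    for name in ("infraslow", "slow"):
        v = fractions.get(name, 0.0)
        comp = _bandlimited_noise(rng, n, dt, *GENERATOR_BANDS[name])
        if comp is None and v > 0:
            warnings.warn(f"record too short to resolve the {name} band; "
                          "component skipped")
            realized[name] = 0.0
            continue
        comp = _scaled(comp, v)
        left += comp
        right += comp
        realized[name] = v if np.ndim(comp) else 0.0

    # bilateral delta with partial synchrony ---------------------------------
    v_delta = fractions.get("delta", 0.0)
    if v_delta > 0:
        f_lo, f_hi = GENERATOR_BANDS["delta"]
        shared = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
        ind_l = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
        ind_r = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
        if shared is None or ind_l is None or ind_r is None:
            warnings.warn("record too short to resolve the delta band")
            realized["delta"] = 0.0
        else:
            rho = profile.delta_coherence
            dl = np.sqrt(rho) * shared + np.sqrt(1 - rho) * ind_l
            dr = np.sqrt(rho) * shared + np.sqrt(1 - rho) * ind_r
            left += _scaled(dl, v_delta)
            right += _scaled(dr, v_delta)
            realized["delta"] = v_delta
    else:
        realized["delta"] = 0.0

    # burst-gated coherent theta pair ----------------------------------------
    # Each burst carries a tone at a random in-band frequency, shared by
    # both leads (the coherent part), mixed with independent in-band noise:
    # x = sqrt(c)*tone + sqrt(1-c)*n1, all gated by a common envelope.  The
    # tone carrier keeps the wavelet ridge of a burst contiguous, so
    # detected pattern durations track the injected ones.
    v_theta = fractions.get("theta", 0.0)
    bursts: list[tuple[float, float]] = []
    if v_theta > 0:
        f_lo, f_hi = GENERATOR_BANDS["theta"]
        n1 = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
        n2 = _bandlimited_noise(rng, n, dt, f_lo, f_hi)
        if n1 is None or n2 is None:
            warnings.warn("record too short to resolve the theta band")
            realized["theta"] = 0.0
        else:
            bursts = _burst_intervals(rng, length_s,
                                      profile.burst_mean_duration_s,
                                      profile.burst_duty)
            env = _envelope_from_intervals(bursts, n, dt)
            tone = np.zeros(n)
            tvec = np.arange(n) * dt
            margin = 0.15  # keep tone centers just inside the band edges
            for a, b in bursts:
                fb = rng.uniform(f_lo + margin, f_hi - margin)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                i0, i1 = int(round(a / dt)), int(round(b / dt))
                tone[i0:i1] = np.sqrt(2.0) * np.cos(
                    2.0 * np.pi * fb * tvec[i0:i1] + phase)
            if env.any():
                c = profile.theta_coherence
                a_c, b_c = np.sqrt(c), np.sqrt(1.0 - c)
                left += _scaled(env * (a_c * tone + b_c * n1), v_theta)
                right += _scaled(env * (a_c * tone + b_c * n2), v_theta)
                realized["theta"] = v_theta
            else:
                realized["theta"] = 0.0
    else:
        realized["theta"] = 0.0

    # independent alpha -------------------------------------------------------
    v_alpha = fractions.get("alpha", 0.0)
    if v_alpha > 0:
        f_lo, f_hi = GENERATOR_BANDS["alpha"]
        left += _scaled(_bandlimited_noise(rng, n, dt, f_lo, f_hi), v_alpha)
        right += _scaled(_bandlimited_noise(rng, n, dt, f_lo, f_hi), v_alpha)
        realized["alpha"] = v_alpha
    else:
        realized["alpha"] = 0.0

    # 1/f background ----------------------------------------------------------
    v_bg = profile.background_power
    left += _scaled(_background_noise(rng, n, dt), v_bg)
    right += _scaled(_background_noise(rng, n, dt), v_bg)

    # EMG ---------------------------------------------------------------------
    emg = rng.normal(size=n)
    emg *= profile.emg_tone / emg.std()

    n_epochs = int(length_s // 10.0)
    truth = GroundTruth(
        theta_coherence=profile.theta_coherence,
        band_variances=realized,
        background_variance=v_bg,
        bursts=bursts,
        stage_labels=[profile.stage] * n_epochs,
        burst_mean_duration_s=profile.burst_mean_duration_s,
        delta_coherence=profile.delta_coherence,
    )
    rec = Recording(samples=np.vstack([left, right, emg]),
                    sampling_interval_s=dt,
                    channel_labels=["EEG-L", "EEG-R", "EMG"],
                    subject_id=subject_id, state=profile.state_name)
    return rec, truth


def _subject_seed(master_seed: int, group_index: int, subject_index: int) -> int:
    """Deterministic per-recording seed via numpy's SeedSequence mixing."""
    ss = np.random.SeedSequence([int(master_seed), group_index, subject_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(profiles: Sequence[StateProfile], n_per_group: int,
                    length_s: float, seed: int,
                    sampling_interval_s: float = 0.0005,
                    ) -> list[tuple[Recording, GroundTruth]]:
    """Generate n_per_group recordings for each state profile.

    Per-recording seeds are derived deterministically from the master seed,
    so the same master seed reproduces the identical cohort.  Subject ids
    follow the pattern ``S<k>-<state>``: the same ``S<k>`` across states
    plays the role of the same animal recorded in each condition (the
    paired design used for the network-similarity protocol).
    """
    if not profiles:
        raise ParameterError("profiles must be non-empty")
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    out = []
    for g, profile in enumerate(profiles):
        for i in range(n_per_group):
            sid = f"S{i + 1:02d}-{profile.state_name}"
            rec, truth = generate_recording(
                profile, length_s, _subject_seed(seed, g, i),
                sampling_interval_s=sampling_interval_s, subject_id=sid)
            out.append((rec, truth))
    return out


def concatenate_recordings(pieces: Sequence[tuple[Recording, GroundTruth]],
                           subject_id: str = "mixed",
                           ) -> tuple[Recording, GroundTruth]:
    """Concatenate recordings in time (e.g. to build a mixed hypnogram).

    All pieces must share channel labels and sampling interval.  Burst
    intervals and stage labels are shifted/joined accordingly; scalar
    ground-truth fields are taken from the first piece.
    """
    if not pieces:
        raise ParameterError("nothing to concatenate")
    first_rec, first_truth = pieces[0]
    labels = list(first_rec.channel_labels)
    dt = first_rec.sampling_interval_s
    chunks, bursts, stage_labels = [], [], []
    offset = 0.0
    for rec, truth in pieces:
        if list(rec.channel_labels) != labels or rec.sampling_interval_s != dt:
            raise ParameterError("pieces have incompatible channel layouts")
        chunks.append(rec.samples)
        bursts.extend([(a + offset, b + offset) for a, b in truth.bursts])
        stage_labels.extend(truth.stage_labels)
        offset += rec.duration_s
    rec = Recording(samples=np.concatenate(chunks, axis=1),
                    sampling_interval_s=dt, channel_labels=labels,
                    subject_id=subject_id, state="mixed")
    truth = replace(first_truth, bursts=bursts, stage_labels=stage_labels)
    return rec, truth


# --------------------------------------------------------------------------
# canonical study profiles
# --------------------------------------------------------------------------
# The three states encode the group contrasts of the study: θ coherence
# 0.68 (wake) vs 0.52 (sleep) vs 0.53 (OBBB); δ(0.1–0.5 Hz) power ratios
# 4.91 : 3.84 : 11.85 expressed as slow_power_boost relative to sleep;
# θ-burst mean durations 1.47 / 1.18 / 1.16 s.  Wake θ is near-continuous
# (high duty) while sleep/OBBB θ is fragmented; NREM sleep and OBBB carry
# strong bilaterally synchronized δ and elevated infra-slow activity.

WAKE_PROFILE = StateProfile(
    state_name="wake",
    band_powers={"infraslow": 0.005, "slow": 0.02, "delta": 0.04,
                 "theta": 0.08, "alpha": 0.12},
    theta_coherence=0.68,
    slow_power_boost=4.91 / 3.84,
    emg_tone=2.0,
    burst_mean_duration_s=1.47,
    burst_duty=0.60,
    delta_coherence=0.20,
    stage="WAKE",
)

SLEEP_PROFILE = StateProfile(
    state_name="sleep",
    band_powers={"infraslow": 0.03, "slow": 0.02, "delta": 0.40,
                 "theta": 0.15, "alpha": 0.05},
    theta_coherence=0.52,
    slow_power_boost=1.0,
    emg_tone=0.7,
    burst_mean_duration_s=1.18,
    burst_duty=0.35,
    delta_coherence=0.70,
    stage="NREM",
)

OBBB_PROFILE = StateProfile(
    state_name="obbb",
    band_powers={"infraslow": 0.04, "slow": 0.02, "delta": 0.30,
                 "theta": 0.18, "alpha": 0.10},
    theta_coherence=0.53,
    slow_power_boost=11.85 / 3.84,
    emg_tone=1.8,
    burst_mean_duration_s=1.16,
    burst_duty=0.35,
    delta_coherence=0.90,
    stage="WAKE",
)

#: REM-like profile (θ-dominated, atonic EMG); used for staging tests —
#: the three-state study cohort itself is wake / sleep / obbb.
REM_PROFILE = StateProfile(
    state_name="rem",
    band_powers={"infraslow": 0.02, "slow": 0.02, "delta": 0.03,
                 "theta": 0.40, "alpha": 0.02},
    theta_coherence=0.60,
    slow_power_boost=1.0,
    emg_tone=0.5,
    burst_mean_duration_s=1.3,
    burst_duty=0.80,
    delta_coherence=0.30,
    stage="REM",
)


def default_profiles() -> dict[str, StateProfile]:
    """The canonical wake / sleep / obbb study profiles."""
    return {"wake": WAKE_PROFILE, "sleep": SLEEP_PROFILE, "obbb": OBBB_PROFILE}


def profiles_from_yaml(path) -> dict[str, StateProfile]:
    """Load state profiles from a YAML mapping of name -> profile fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError("profile YAML must be a mapping")
    out = {}
    for name, fields in raw.items():
        fields = dict(fields)
        fields.setdefault("state_name", name)
        out[name] = StateProfile(**fields)
    return out
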