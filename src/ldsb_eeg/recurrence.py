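"""Delay embedding and cross-recurrence quantification.

Two signals are projected into a common state space by Takens delay
embedding — the delay taken at the first minimum of the autocorrelation
function, the dimension from the false-nearest-neighbour (FNN) criterion —
and the binary cross-recurrence matrix

    CR(i, j) = 1  iff  ||A_i - B_j|| <= eps

is summarized by its diagonal-line structure:

* RR    recurrence rate (fraction of recurrent point pairs),
* DET   fraction of recurrent points lying on diagonals of length >= lmin,
* L     mean diagonal-line length (lines >= lmin),
* MDL   maximal diagonal-line length — the longest stretch over which the
        two phase trajectories evolve closely together,
* ENTR  Shannon entropy of the diagonal-length distribution (lines >= lmin).

The threshold eps is chosen by default to achieve a fixed 10% recurrence
rate (distance quantile), making indices comparable across brain states;
a fixed eps is also supported.  Signals are z-scored before embedding and
no Theiler exclusion is applied (recurrences between two *different*
signals need no autocorrelation guard).

RR, DET, L and ENTR follow the standard recurrence-quantification
definitions; the upstream study defines its additional indices in
unavailable supplementary material, so the standard set stands in for
them and is labelled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "EmbeddingParams",
    "CrossRecurrenceResult",
    "autocorr_delay",
    "fnn_dimension",
    "delay_embed",
    "cross_recurrence_matrix",
    "cra_indices",
    "cra_band_indices",
    "cra_band_index",
]


@dataclass(frozen=True)
class EmbeddingParams:
    delay: int      # tau, in samples
    dimension: int  # m

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dimension < 1:
            raise ParameterError("need delay >= 1 and dimension >= 1")


@dataclass
class CrossRecurrenceResult:
    rr: float
    det: float
    mean_diagonal: float   # L
    mdl: float             # maximal diagonal length, samples (fractional
                           # only after window averaging)
    entropy: float         # ENTR
    epsilon: float = float("nan")
    lmin: int = 2
    embedding: EmbeddingParams | None = None
    theiler: int = 0


def autocorr_delay(signal, max_lag: int) -> int:
    """Delay at the first local minimum of the sample autocorrelation.

    Falls back to the first zero crossing if no local minimum occurs below
    ``max_lag``, and to ``max_lag`` itself (with a warning) if neither is
    found — e.g. for a monotonically decaying AR(1) autocorrelation.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if max_lag >= n // 2:
        raise ParameterError("max_lag must be below half the signal length")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise DegenerateInputError("constant signal has no autocorrelation")
    # FFT-based autocovariance up to max_lag
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    acf = acov / denom
    for lag in range(1, max_lag):
        if acf[lag] < acf[lag - 1] and acf[lag] <= acf[lag + 1]:
            return lag
    crossings = np.flatnonzero(acf[: max_lag + 1] <= 0)
    if crossings.size:
        return int(crossings[0])
    warnings.warn("no autocorrelation minimum or zero crossing below "
                  f"max_lag={max_lag}; returning max_lag")
    return max_lag


def delay_embed(signal, dimension: int, delay: int) -> np.ndarray:
    """Takens delay embedding: point i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(signal, dtype=float)
    if dimension < 1 or delay < 1:
        raise ParameterError("need dimension >= 1 and delay >= 1")
    span = (dimension - 1) * delay
    n_points = len(x) - span
    if n_points <= 0:
        raise ParameterError(
            f"signal of length {len(x)} too short for m={dimension}, "
            f"tau={delay} embedding"
        )
    return np.column_stack([x[k * delay: k * delay + n_points]
                            for k in range(dimension)])


def fnn_dimension(signal, delay: int, m_max: int = 10, rtol: float = 10.0,
                  atol: float = 2.0, threshold: float = 0.01) -> int:
    """Smallest embedding dimension with a false-neighbour fraction below
    ``threshold`` (Kennel criterion).

    A nearest neighbour at dimension m is "false" if the extra coordinate
    at m+1 stretches the pair by more than ``rtol`` relative to its m-dim
    distance, or beyond ``atol`` times the signal's standard deviation.
    Returns ``m_max`` (with a warning) if the criterion is never met, as
    for stochastic signals with no finite-dimensional geometry.
    """
    x = np.asarray(signal, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant signal")
    if len(x) <= (m_max + 1) * delay + 1:
        raise ParameterError("signal too short for m_max embedding")
    for m in range(1, m_max + 1):
        emb_m = delay_embed(x, m, delay)
        emb_m1 = delay_embed(x, m + 1, delay)
        n = len(emb_m1)  # points valid at both m and m+1
        pts = emb_m[:n]
        tree = cKDTree(pts)
        # nearest non-identical neighbour with a small temporal guard
        k = min(n - 1, 2 + delay)
        dists, idxs = tree.query(pts, k=k + 1)
        nn = np.full(n, -1)
        nn_d = np.zeros(n)
        for col in range(1, k + 1):
            cand = idxs[:, col]
            ok = (nn < 0) & (np.abs(cand - np.arange(n)) > delay)
            nn[ok] = cand[ok]
            nn_d[ok] = dists[ok, col]
        valid = nn >= 0
        nn_v = nn[valid]
        d_m = nn_d[valid]
        extra = np.abs(emb_m1[valid, m] - emb_m1[nn_v, m])
        d_m1 = np.sqrt(d_m ** 2 + extra ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            stretch = np.where(d_m > 0, extra / np.maximum(d_m, 1e-300),
                               np.inf)
        false = (stretch > rtol) | (d_m1 > atol * sd)
        if valid.sum() and false.mean() < threshold:
            return m
    warnings.warn(f"false-neighbour fraction never dropped below "
                  f"{threshold}; capping dimension at m_max={m_max}")
    return m_max


def cross_recurrence_matrix(traj_a, traj_b, epsilon: float | None = None,
                            target_rr: float = 0.10,
                            ) -> tuple[np.ndarray, float]:
    """Binary cross-recurrence matrix and the threshold actually used.

    With ``epsilon=None`` the threshold is the ``target_rr`` quantile of
    the pairwise distances (fixed-recurrence-rate policy, default 10%).
    """
    a = np.atleast_2d(np.asarray(traj_a, dtype=float))
    b = np.atleast_2d(np.asarray(traj_b, dtype=float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ParameterError("trajectories must share the embedding dimension")
    d = cdist(a, b)
    if epsilon is None:
        if not 0 < target_rr < 1:
            raise ParameterError("target_rr must be in (0, 1)")
        epsilon = float(np.quantile(d, target_rr))
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    return d <= epsilon, float(epsilon)


def _diagonal_lengths(matrix: np.ndarray) -> np.ndarray:
    """Lengths of all maximal runs of ones along every diagonal."""
    m = np.asarray(matrix, dtype=bool)
    na, nb = m.shape
    lengths = []
    for off in range(-(na - 1), nb):
        diag = np.diagonal(m, offset=off)
        if not diag.any():
            continue
        padded = np.concatenate(([0], diag.astype(np.int8), [0]))
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        lengths.append(ends - starts)
    if not lengths:
        return np.array([], dtype=int)
    return np.concatenate(lengths)


def cra_indices(matrix, lmin: int = 2,
                epsilon: float = float("nan"),
                embedding: EmbeddingParams | None = None,
                ) -> CrossRecurrenceResult:
    """Diagonal-line indices RR, DET, L, MDL, ENTR of a recurrence matrix.

    An all-zero matrix yields RR = 0 and MDL = DET = L = ENTR = 0 by
    convention (not an error).
    """
    m = np.asarray(matrix, dtype=bool)
    if m.size == 0:
        raise ParameterError("matrix must be non-empty")
    if lmin < 1:
        raise ParameterError("lmin must be >= 1")
    rr = float(m.mean())
    lengths = _diagonal_lengths(m)
    if lengths.size == 0:
        return CrossRecurrenceResult(rr=rr, det=0.0, mean_diagonal=0.0,
                                     mdl=0, entropy=0.0, epsilon=epsilon,
                                     lmin=lmin, embedding=embedding)
    mdl = int(lengths.max())
    long_lines = lengths[lengths >= lmin]
    n_points = int(lengths.sum())  # == number of recurrent points
    if long_lines.size == 0:
        det, mean_l, entr = 0.0, 0.0, 0.0
    else:
        det = float(long_lines.sum() / n_points)
        mean_l = float(long_lines.mean())
        _, counts = np.unique(long_lines, return_counts=True)
        p = counts / counts.sum()
        entr = float(-(p * np.log(p)).sum())
    return CrossRecurrenceResult(rr=rr, det=det, mean_diagonal=mean_l,
                                 mdl=mdl, entropy=entr, epsilon=epsilon,
                                 lmin=lmin, embedding=embedding)


# --------------------------------------------------------------------------
# band-limited end-to-end index
# --------------------------------------------------------------------------

def _prepare_band_signal(x: np.ndarray, sampling_interval_s: float,
                         band: tuple[float, float],
                         analysis_fs: float) -> np.ndarray:
    """Decimate (anti-aliased) to analysis_fs, zero-phase bandpass, z-score."""
    fs = 1.0 / sampling_interval_s
    f_lo, f_hi = band
    if not 0 <= f_lo < f_hi <= 0.5 * analysis_fs:
        raise ParameterError(
            f"band [{f_lo}, {f_hi}] Hz invalid for analysis rate "
            f"{analysis_fs} Hz"
        )
    if analysis_fs < fs:
        up, down = 1, int(round(fs / analysis_fs))
        if abs(fs / down - analysis_fs) > 1e-6:
            raise ParameterError(
                "analysis_fs must divide the sampling rate evenly"
            )
        x = _sig.resample_poly(x, up, down)
    lo_n = max(f_lo, 1e-3) / (0.5 * analysis_fs)
    hi_n = min(f_hi / (0.5 * analysis_fs), 0.999)
    sos = _sig.butter(4, [lo_n, hi_n], btype="bandpass", output="sos")
    x = _sig.sosfiltfilt(sos, x)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("band-passed signal is constant")
    return (x - x.mean()) / sd


_INDEX_ATTRS = {"rr": "rr", "det": "det", "l": "mean_diagonal",
                "mean_diagonal": "mean_diagonal", "mdl": "mdl",
                "entr": "entropy", "entropy": "entropy"}


def cra_band_indices(x, y, sampling_interval_s: float,
                     band: tuple[float, float],
                     analysis_fs: float = 100.0,
                     window_s: float | None = None,
                     max_windows: int | None = None,
                     embedding: EmbeddingParams | None = None,
                     m_max: int = 8,
                     epsilon: float | None = None,
                     target_rr: float = 0.10,
                     lmin: int = 2) -> CrossRecurrenceResult:
    """All cross-recurrence indices of two channels within a band.

    Both signals are decimated to ``analysis_fs``, zero-phase band-passed,
    z-scored and delay-embedded (delay from the autocorrelation minimum,
    dimension from FNN, unless ``embedding`` is given).  With ``window_s``
    set, indices are computed per non-overlapping window and averaged
    (optionally over at most ``max_windows`` evenly spaced windows).
    MDL is reported in samples at the analysis rate (fractional after
    window averaging).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("channels must have the same length")
    xb = _prepare_band_signal(x, sampling_interval_s, band, analysis_fs)
    yb = _prepare_band_signal(y, sampling_interval_s, band, analysis_fs)
    if embedding is None:
        max_lag = max(2, min(len(xb) // 2 - 1,
                             int(2.0 * analysis_fs / max(band[0], 0.1))))
        tau = autocorr_delay(xb, max_lag)
        m = fnn_dimension(xb, tau, m_max=m_max)
        embedding = EmbeddingParams(delay=tau, dimension=m)
    if window_s is None:
        starts = [0]
        wlen = len(xb)
    else:
        wlen = int(round(window_s * analysis_fs))
        if wlen <= (embedding.dimension - 1) * embedding.delay + 1:
            raise ParameterError("window too short for the embedding")
        n_win = len(xb) // wlen
        if n_win == 0:
            raise ParameterError("record shorter than one window")
        idx = np.arange(n_win)
        if max_windows is not None and n_win > max_windows:
            idx = np.unique(np.linspace(0, n_win - 1, max_windows).round()
                            .astype(int))
        starts = [int(i) * wlen for i in idx]
    results = []
    for s0 in starts:
        xa = delay_embed(xb[s0:s0 + wlen], embedding.dimension,
                         embedding.delay)
        ya = delay_embed(yb[s0:s0 + wlen], embedding.dimension,
                         embedding.delay)
        mat, eps = cross_recurrence_matrix(xa, ya, epsilon=epsilon,
                                           target_rr=target_rr)
        results.append(cra_indices(mat, lmin=lmin, epsilon=eps,
                                   embedding=embedding))
    return CrossRecurrenceResult(
        rr=float(np.mean([r.rr for r in results])),
        det=float(np.mean([r.det for r in results])),
        mean_diagonal=float(np.mean([r.mean_diagonal for r in results])),
        mdl=float(np.mean([r.mdl for r in results])),
        entropy=float(np.mean([r.entropy for r in results])),
        epsilon=float(np.mean([r.epsilon for r in results])),
        lmin=lmin, embedding=embedding)


def cra_band_index(x, y, sampling_interval_s: float,
                   band: tuple[float, float], index: str = "mdl",
                   **kwargs) -> float:
    """One named cross-recurrence index (see :func:`cra_band_indices`)."""
    attr = _INDEX_ATTRS.get(index.lower())
    if attr is None:
        raise ParameterError(f"unknown index {index!r}")
    res = cra_band_indices(x, y, sampling_interval_s, band, **kwargs)
    return float(getattr(res, attr))
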