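"""Surrogate-data significance testing and group statistics.

AAFT (amplitude-adjusted Fourier transform) surrogates preserve a
signal's amplitude distribution exactly (the surrogate is a permutation
of the original samples) and its periodogram approximately, while
randomizing Fourier phases — destroying any (non)linear coupling to other
signals.  Testing an observed coupling statistic against the distribution
obtained by replacing one signal with its surrogates yields a one-sided
p-value for the null "the two systems are not linearly coupled":

    p = (1 + #{surrogate statistic >= observed}) / (n_surrogates + 1).

Group contrasts use the two-sided Mann-Whitney-Wilcoxon rank test (exact
null distribution for small groups, normal approximation with tie
correction otherwise), and summaries are reported as mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "SurrogateTestResult",
    "aaft_surrogate",
    "surrogate_test",
    "mww_test",
    "group_summary",
]


@dataclass
class SurrogateTestResult:
    observed: float
    surrogate_values: np.ndarray
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        # p <= alpha so that the minimal design (19 surrogates, observed
        # above all of them, p = 1/20) is decidable at alpha = 0.05
        return self.p_value <= self.alpha


def _phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize Fourier phases, preserving the amplitude spectrum."""
    n = len(x)
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec))
    phases[0] = 0.0  # keep the mean
    if n % 2 == 0:
        # Nyquist bin must stay real; randomize its sign only
        phases[-1] = rng.choice([0.0, np.pi])
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def aaft_surrogate(signal, seed=None, iaaft_iterations: int = 0) -> np.ndarray:
    """Amplitude-adjusted Fourier-transform surrogate of a signal.

    Steps: rank-remap the data onto a Gaussian, randomize the Gaussian
    copy's Fourier phases, then rank-remap back onto the original
    amplitude distribution — so ``sorted(surrogate) == sorted(signal)``
    exactly.  ``iaaft_iterations > 0`` applies that many iterative
    spectrum-adjustment refinements (IAAFT) after the initial AAFT pass.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 32:
        raise ParameterError("need at least 32 samples for a surrogate")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal has no surrogate")
    rng = np.random.default_rng(seed)
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    sorted_x = x[order]

    gauss = np.sort(rng.normal(size=n))
    y = gauss[ranks]                      # gaussianized copy of x
    y = _phase_randomize(y, rng)
    surr = sorted_x[np.argsort(np.argsort(y, kind="stable"), kind="stable")]

    target_amp = np.abs(np.fft.rfft(x))
    for _ in range(int(iaaft_iterations)):
        spec = np.fft.rfft(surr)
        with np.errstate(invalid="ignore", divide="ignore"):
            spec = target_amp * np.exp(1j * np.angle(spec))
        z = np.fft.irfft(spec, n=n)
        surr = sorted_x[np.argsort(np.argsort(z, kind="stable"), kind="stable")]
    return surr


def surrogate_test(statistic_fn, x, y, n_surr: int = 99,
                   seed=None, alpha: float = 0.05) -> SurrogateTestResult:
    """One-sided AAFT surrogate test of a bivariate coupling statistic.

    ``statistic_fn(x, y)`` is evaluated once on the originals and once per
    surrogate, with y replaced by an independently seeded AAFT surrogate.
    """
    if n_surr < 19:
        raise ParameterError(
            "need n_surr >= 19 to resolve significance at alpha = 0.05"
        )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = float(statistic_fn(x, y))
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_surr)
    values = np.empty(n_surr)
    for i, s in enumerate(seeds):
        try:
            values[i] = statistic_fn(x, aaft_surrogate(y, seed=int(s)))
        except Exception as exc:
            raise RuntimeError(
                f"statistic failed on surrogate {i}: {exc}"
            ) from exc
    p = (1 + int(np.sum(values >= observed))) / (n_surr + 1)
    return SurrogateTestResult(observed=observed, surrogate_values=values,
                               p_value=p, alpha=alpha)


def mww_test(group_a, group_b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact null distribution when both groups have <= 8 values and no ties
    across groups; normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("each group needs >= 3 values")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    return float(_st.mannwhitneyu(a, b, alternative="two-sided",
                                  method=method).pvalue)


def group_summary(values_by_group) -> pd.DataFrame:
    """Mean +/- SEM table (SEM = sd/sqrt(n), sd with n-1 denominator)."""
    rows = []
    for name, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ParameterError(f"group {name!r} needs >= 2 values")
        rows.append(dict(group=name, n=len(v), mean=float(v.mean()),
                         sem=float(v.std(ddof=1) / np.sqrt(len(v)))))
    return pd.DataFrame(rows).set_index("group")
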