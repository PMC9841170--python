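"""SNR feature extraction and the MLP similarity detector with Cs.

The EEG discriminant is not the raw trace but its windowed
signal-to-noise ratio: for each 60-s window, stepped by 1 s,

    SNR = mean(window) / sd(window)        (sd with n-1 denominator)

— at the native 0.5-ms sampling each window holds 120,000 points.  The
SNR series is cut into consecutive 90-sample fragments (1.5 min each),
which feed a feed-forward network with 90 linear inputs, four sigmoid
hidden layers of 500, 50, 500 and 50 units, and one linear output
clamped to [0, 1]: 1 = maximally similar to the positive training
fragments, 0 = maximally dissimilar.

The network is trained per subject on that subject's positive
(barrier-opening) fragments against negative (baseline wake) fragments
and applied to all *other* subjects (leave-one-subject-in training
protocol).  The summary statistic

    Cs = (# responses > 0.5) / (# responses)

is the fraction of test fragments the network recognizes as similar.
An alternative count-ratio form, Cs = sum_i N_i^s / sum_i N_i^d
(similar over *dissimilar* counts), cannot be a fraction of data and may
exceed 1; this module computes the fraction, and
:func:`cs_literal_ratio` exposes the count ratio for comparison.

SNR is invariant to positive rescaling of the EEG, hence so is Cs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "SnrSeries",
    "MLP_HIDDEN_LAYERS",
    "SimilarityDetector",
    "CsResult",
    "snr_series",
    "fragment_features",
    "train_detector",
    "network_response",
    "compute_cs",
    "cs_literal_ratio",
    "leave_one_subject_protocol",
]

#: Hidden-layer sizes of the similarity network (input 90, output 1).
MLP_HIDDEN_LAYERS: tuple[int, ...] = (500, 50, 500, 50)

FRAGMENT_LENGTH = 90  # SNR samples per network input (1.5 min at 1-s steps)


@dataclass
class SnrSeries:
    values: np.ndarray
    window_s: float = 60.0
    step_s: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("SNR series contains non-finite values")


def snr_series(signal, sampling_interval_s: float, window_s: float = 60.0,
               step_s: float = 1.0) -> SnrSeries:
    """Sliding-window mean/sd ratio of a raw signal.

    Window count is floor((length_s - window_s)/step_s) + 1.  A window
    with zero variance is degenerate and raises, naming the window.
    """
    x = np.asarray(signal, dtype=float)
    if sampling_interval_s <= 0 or window_s <= 0 or step_s <= 0:
        raise ParameterError("intervals must be positive")
    w = int(round(window_s / sampling_interval_s))
    step = int(round(step_s / sampling_interval_s))
    if len(x) < w:
        raise ParameterError("signal shorter than one SNR window")
    n_win = (len(x) - w) // step + 1
    # O(n) sliding moments via cumulative sums
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(n_win) * step
    s1 = c1[starts + w] - c1[starts]
    s2 = c2[starts + w] - c2[starts]
    mean = s1 / w
    var = (s2 - w * mean ** 2) / (w - 1)
    var = np.maximum(var, 0.0)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise DegenerateInputError(
            f"zero-variance SNR window at start index {bad[0] * step} "
            f"(t = {bad[0] * step_s:.1f} s)"
        )
    return SnrSeries(values=mean / np.sqrt(var), window_s=window_s,
                     step_s=step_s)


def fragment_features(series: SnrSeries, stride: int = FRAGMENT_LENGTH,
                      ) -> np.ndarray:
    """Consecutive 90-sample SNR fragments, shape (n_fragments, 90).

    Default stride 90 gives non-overlapping fragments (independent test
    units); a smaller stride yields overlapping training fragments.
    """
    v = series.values
    if len(v) < FRAGMENT_LENGTH:
        raise ParameterError(
            f"need >= {FRAGMENT_LENGTH} SNR values, got {len(v)}"
        )
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    starts = range(0, len(v) - FRAGMENT_LENGTH + 1, stride)
    return np.stack([v[s:s + FRAGMENT_LENGTH] for s in starts])


@dataclass
class SimilarityDetector:
    """Trained MLP + input standardization; responses clamped to [0, 1]."""

    model: MLPRegressor
    scaler: StandardScaler
    seed: int
    training_meta: dict = field(default_factory=dict)

    def respond(self, fragments: np.ndarray) -> np.ndarray:
        fragments = np.atleast_2d(np.asarray(fragments, dtype=float))
        if fragments.shape[1] != FRAGMENT_LENGTH:
            raise ParameterError(
                f"fragments must have length {FRAGMENT_LENGTH}, got "
                f"{fragments.shape[1]}"
            )
        out = self.model.predict(self.scaler.transform(fragments))
        return np.clip(out, 0.0, 1.0)


def train_detector(positive_fragments, negative_fragments,
                   hyperparams: Mapping | None = None,
                   seed: int = 0) -> SimilarityDetector:
    """Train the similarity MLP (targets: positive -> 1, negative -> 0).

    Deterministic given the seed.  Defaults: Adam, <= 200 epochs with
    plateau early stopping on the training loss.  At least 10 fragments
    per class are recommended; an absent class is an error.
    """
    pos = np.atleast_2d(np.asarray(positive_fragments, dtype=float))
    neg = np.atleast_2d(np.asarray(negative_fragments, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ParameterError("both fragment classes must be non-empty")
    if pos.shape[1] != FRAGMENT_LENGTH or neg.shape[1] != FRAGMENT_LENGTH:
        raise ParameterError(f"fragments must have length {FRAGMENT_LENGTH}")
    if len(pos) < 10 or len(neg) < 10:
        warnings.warn("fewer than 10 fragments in a class; the detector "
                      "may not generalize")
    hp = dict(max_iter=400, learning_rate_init=1e-3, tol=1e-6,
              n_iter_no_change=40, alpha=1e-4)
    n_restarts = 3
    if hyperparams:
        hp = dict(hp)
        hp.update(hyperparams)
        n_restarts = hp.pop("n_restarts", n_restarts)
    x = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    scaler = StandardScaler().fit(x)
    # Deep sigmoid stacks can collapse onto the constant-output solution
    # (vanishing gradients); that failure is visible on the training data
    # itself, so restart from a different deterministic initialization
    # when the fit does not separate its own training classes.
    best = None
    for attempt in range(n_restarts + 1):
        init_seed = int(np.random.SeedSequence([int(seed), attempt])
                        .generate_state(1)[0] & 0x7FFFFFFF)
        model = MLPRegressor(hidden_layer_sizes=MLP_HIDDEN_LAYERS,
                             activation="logistic", solver="adam",
                             random_state=init_seed, **hp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter
            model.fit(scaler.transform(x), y)
        pred = np.clip(model.predict(scaler.transform(x)), 0.0, 1.0)
        acc = float(np.mean((pred > 0.5) == (y > 0.5)))
        if best is None or acc > best[0]:
            best = (acc, attempt, model)
        if acc >= 0.9:
            break
    acc, attempt, model = best
    if acc < 0.9:
        warnings.warn(f"detector failed to separate its training classes "
                      f"(accuracy {acc:.2f} after {n_restarts + 1} starts)")
    meta = dict(n_positive=len(pos), n_negative=len(neg),
                n_epochs=model.n_iter_, loss_curve=list(model.loss_curve_),
                training_accuracy=acc, restarts_used=attempt)
    return SimilarityDetector(model=model, scaler=scaler, seed=int(seed),
                              training_meta=meta)


def network_response(detector: SimilarityDetector, fragment) -> float:
    """Forward pass for a single 90-sample fragment, clamped to [0, 1]."""
    return float(detector.respond(np.asarray(fragment, dtype=float)
                                  .reshape(1, -1))[0])


def compute_cs(responses, threshold: float = 0.5) -> float:
    """Fraction of responses above the similarity threshold."""
    r = np.asarray(responses, dtype=float)
    if r.size == 0:
        raise ParameterError("need at least one response")
    return float(np.mean(r > threshold))


def cs_literal_ratio(responses, threshold: float = 0.5) -> float:
    """Similar/dissimilar count ratio (the alternative Cs form).

    May exceed 1 and diverges when nothing is dissimilar; kept only for
    comparison with :func:`compute_cs`.
    """
    r = np.asarray(responses, dtype=float)
    if r.size == 0:
        raise ParameterError("need at least one response")
    n_sim = int(np.sum(r > threshold))
    n_dis = int(r.size - n_sim)
    return n_sim / n_dis if n_dis else float("inf")


@dataclass
class CsResult:
    """Leave-one-subject-in protocol output.

    ``table`` has one row per (training subject, evaluated state) with
    similar/dissimilar fragment counts and Cs; ``summary`` aggregates
    mean Cs +/- SEM per state over the trained networks.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    threshold: float = 0.5

    def state_mean(self, state: str) -> float:
        return float(self.summary.loc[state, "cs_mean"])


def leave_one_subject_protocol(
        fragments_by_subject: Mapping[str, Mapping[str, np.ndarray]],
        positive_state: str = "obbb",
        negative_state: str = "wake",
        train_fragments_by_subject: Mapping[str, Mapping[str, np.ndarray]]
        | None = None,
        threshold: float = 0.5,
        seed: int = 0,
        hyperparams: Mapping | None = None) -> CsResult:
    """Per-subject training, cross-subject evaluation of Cs per state.

    For each subject k, a detector is trained on k's positive-state
    fragments against k's negative-state fragments and evaluated on every
    other subject's fragments, state by state.  Subjects lacking either
    training class are skipped with a warning.  ``train_fragments_by_
    subject`` may supply denser (overlapping) training fragments; the
    evaluation always uses ``fragments_by_subject``.
    """
    subjects = list(fragments_by_subject)
    if train_fragments_by_subject is None:
        train_fragments_by_subject = fragments_by_subject
    trainable = [s for s in subjects
                 if positive_state in train_fragments_by_subject[s]
                 and negative_state in train_fragments_by_subject[s]]
    if len(trainable) < 3:
        raise ParameterError(
            "need >= 3 subjects with both training states, have "
            f"{len(trainable)}"
        )
    skipped = set(subjects) - set(trainable)
    if skipped:
        warnings.warn(f"subjects without both training classes skipped: "
                      f"{sorted(skipped)}")
    rows = []
    for i, subj in enumerate(trainable):
        det = train_detector(
            train_fragments_by_subject[subj][positive_state],
            train_fragments_by_subject[subj][negative_state],
            hyperparams=hyperparams,
            seed=int(np.random.SeedSequence([int(seed), i])
                     .generate_state(1)[0] & 0x7FFFFFFF))
        for state in sorted({st for s in subjects
                             for st in fragments_by_subject[s]}):
            resp = [det.respond(fragments_by_subject[other][state])
                    for other in subjects
                    if other != subj and state in fragments_by_subject[other]]
            if not resp:
                continue
            r = np.concatenate(resp)
            n_sim = int(np.sum(r > threshold))
            rows.append(dict(train_subject=subj, state=state,
                             n_similar=n_sim, n_dissimilar=len(r) - n_sim,
                             n_total=len(r), cs=n_sim / len(r)))
    table = pd.DataFrame(rows)
    summary = (table.groupby("state")["cs"]
               .agg(cs_mean="mean",
                    cs_sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
               if len(table) else pd.DataFrame())
    return CsResult(table=table, summary=summary, threshold=threshold)
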