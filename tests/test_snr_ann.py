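"""SNR features, the similarity MLP and the Cs statistic."""

import numpy as np
import pytest

from ldsb_eeg import snr_ann as sa
from ldsb_eeg.exceptions import DegenerateInputError, ParameterError


class TestSnrSeries:
    def test_small_window_closed_form(self):
        # window {1,2,3}: mean 2, sd 1 -> SNR 2
        x = np.array([1.0, 2.0, 3.0, 4.0])
        s = sa.snr_series(x, sampling_interval_s=1.0, window_s=3.0,
                          step_s=1.0)
        assert s.values[0] == pytest.approx(2.0)
        assert len(s.values) == 2

    def test_points_per_default_window(self):
        # 60-s window at the native 0.5-ms step
        assert int(round(60.0 / 0.0005)) == 120_000

    def test_window_count_formula(self, rng):
        x = rng.normal(size=int(200 / 0.01))
        s = sa.snr_series(x, 0.01, window_s=60.0, step_s=1.0)
        assert len(s.values) == (200 - 60) // 1 + 1

    def test_scale_invariance(self, rng):
        x = rng.normal(loc=0.3, size=int(120 / 0.01))
        a = sa.snr_series(x, 0.01).values
        b = sa.snr_series(173.0 * x, 0.01).values
        assert np.allclose(a, b)

    def test_zero_variance_window_named(self):
        x = np.concatenate([np.zeros(3000), np.random.default_rng(0)
                            .normal(size=3000)])
        with pytest.raises(DegenerateInputError, match="t = 0.0"):
            sa.snr_series(x, 0.01, window_s=10.0, step_s=1.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            sa.snr_series(np.ones(10), 1.0, window_s=60.0)


class TestFragments:
    def test_non_overlapping_count(self):
        s = sa.SnrSeries(values=np.arange(270.0))
        assert sa.fragment_features(s).shape == (3, 90)

    def test_fragment_spans_90_seconds(self):
        s = sa.SnrSeries(values=np.arange(180.0), step_s=1.0)
        frags = sa.fragment_features(s)
        assert frags.shape[1] * s.step_s == pytest.approx(90.0)  # 1.5 min

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            sa.fragment_features(sa.SnrSeries(values=np.arange(89.0)))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(42)
    pos = rng.normal(1.5, 1.0, size=(20, 90))
    neg = rng.normal(-1.5, 1.0, size=(20, 90))
    return pos, neg


class TestDetector:

    def test_training_accuracy_on_separable_clusters(self, separable):
        pos, neg = separable
        det = sa.train_detector(pos, neg, seed=1)
        acc = (np.sum(det.respond(pos) > 0.5)
               + np.sum(det.respond(neg) <= 0.5)) / 40
        assert acc >= 0.95

    def test_determinism_under_fixed_seed(self, separable):
        pos, neg = separable
        a = sa.train_detector(pos, neg, seed=3)
        b = sa.train_detector(pos, neg, seed=3)
        for wa, wb in zip(a.model.coefs_, b.model.coefs_):
            assert np.array_equal(wa, wb)

    def test_architecture(self, separable):
        pos, neg = separable
        det = sa.train_detector(pos, neg, seed=1)
        sizes = [c.shape for c in det.model.coefs_]
        assert sizes == [(90, 500), (500, 50), (50, 500), (500, 50),
                         (50, 1)]
        assert det.model.activation == "logistic"
        assert det.model.out_activation_ == "identity"

    def test_responses_clamped(self, separable, rng):
        pos, neg = separable
        det = sa.train_detector(pos, neg, seed=1)
        wild = rng.normal(scale=100.0, size=(30, 90))
        r = det.respond(wild)
        assert np.all((r >= 0.0) & (r <= 1.0))

    def test_wrong_fragment_length_rejected(self, separable):
        pos, neg = separable
        det = sa.train_detector(pos, neg, seed=1)
        with pytest.raises(ParameterError):
            sa.network_response(det, np.zeros(50))

    def test_empty_class_rejected(self):
        with pytest.raises(ParameterError):
            sa.train_detector(np.empty((0, 90)), np.zeros((10, 90)))

    def test_label_shuffle_removes_class_contrast(self, separable):
        """Negative control: with randomly shuffled training labels the
        detector carries no class information, so Cs(pos) ~ Cs(neg)."""
        pos, neg = separable
        rng = np.random.default_rng(0)
        deltas = []
        for trial in range(8):
            x = np.vstack([pos, neg])
            perm = rng.permutation(len(x))
            sh_pos, sh_neg = x[perm[:20]], x[perm[20:]]
            det = sa.train_detector(sh_pos, sh_neg, seed=100 + trial)
            rng2 = np.random.default_rng(500 + trial)
            test_pos = rng2.normal(1.5, 1.0, size=(40, 90))
            test_neg = rng2.normal(-1.5, 1.0, size=(40, 90))
            deltas.append(sa.compute_cs(det.respond(test_pos))
                          - sa.compute_cs(det.respond(test_neg)))
        assert abs(np.mean(deltas)) < 0.2


class TestCs:
    def test_half_similar(self):
        assert sa.compute_cs([0.9, 0.8, 0.1, 0.2]) == 0.5

    def test_all_similar(self):
        assert sa.compute_cs([1.0, 1.0, 1.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            sa.compute_cs([])

    def test_printed_group_means_imply_33_percent_increase(self):
        # the arithmetic behind the reported sleep-vs-wake contrast
        assert 100 * (0.56 - 0.42) / 0.42 == pytest.approx(33.3, abs=0.05)

    def test_literal_ratio_can_exceed_one(self):
        assert sa.cs_literal_ratio([0.9, 0.9, 0.9, 0.1]) == 3.0
        assert sa.cs_literal_ratio([0.9, 0.9]) == np.inf


class TestProtocol:
    def _fragments(self, rng, mean, n=12):
        return rng.normal(mean, 1.0, size=(n, 90))

    def test_identical_positives_transfer_perfectly(self):
        rng = np.random.default_rng(1)
        shared_pos = self._fragments(rng, 3.0)
        frags = {f"S{i}": {"obbb": shared_pos.copy(),
                           "wake": self._fragments(rng, -3.0)}
                 for i in range(4)}
        res = sa.leave_one_subject_protocol(frags, seed=0)
        assert res.state_mean("obbb") > 0.95

    def test_null_states_indistinguishable(self):
        """Positive and negative drawn from one distribution: the Cs gap
        between them stays small."""
        rng = np.random.default_rng(2)
        frags = {f"S{i}": {"obbb": self._fragments(rng, 0.0),
                           "wake": self._fragments(rng, 0.0)}
                 for i in range(4)}
        res = sa.leave_one_subject_protocol(frags, seed=1)
        assert abs(res.state_mean("obbb") - res.state_mean("wake")) < 0.3

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(3)
        frags = {"S0": {"obbb": self._fragments(rng, 1.0),
                        "wake": self._fragments(rng, -1.0)},
                 "S1": {"obbb": self._fragments(rng, 1.0)}}
        with pytest.raises(ParameterError):
            sa.leave_one_subject_protocol(frags)

    def test_subject_missing_a_class_is_skipped(self):
        rng = np.random.default_rng(4)
        frags = {f"S{i}": {"obbb": self._fragments(rng, 2.0),
                           "wake": self._fragments(rng, -2.0)}
                 for i in range(3)}
        frags["S9"] = {"obbb": self._fragments(rng, 2.0)}  # no negatives
        with pytest.warns(UserWarning, match="skipped"):
            res = sa.leave_one_subject_protocol(frags, seed=0)
        assert set(res.table["train_subject"]) == {"S0", "S1", "S2"}
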