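"""Delay embedding, FNN dimension and cross-recurrence quantification."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ldsb_eeg import recurrence as rq
from ldsb_eeg.exceptions import DegenerateInputError, ParameterError


def _brute_force_indices(matrix, lmin=2):
    """Independent oracle: exhaustive diagonal run-length scan."""
    m = np.asarray(matrix, dtype=bool)
    na, nb = m.shape
    lengths = []
    for off in range(-(na - 1), nb):
        i, j = (max(-off, 0), max(off, 0))
        run = 0
        while i < na and j < nb:
            if m[i, j]:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
            i += 1
            j += 1
        if run:
            lengths.append(run)
    lengths = np.array(lengths, dtype=int)
    rr = m.mean()
    if lengths.size == 0:
        return dict(rr=rr, det=0.0, l=0.0, mdl=0, entr=0.0)
    big = lengths[lengths >= lmin]
    if big.size == 0:
        return dict(rr=rr, det=0.0, l=0.0, mdl=int(lengths.max()), entr=0.0)
    _, counts = np.unique(big, return_counts=True)
    p = counts / counts.sum()
    return dict(rr=rr, det=big.sum() / lengths.sum(), l=big.mean(),
                mdl=int(lengths.max()), entr=float(-(p * np.log(p)).sum()))


class TestAutocorrDelay:
    def test_sine_first_minimum_at_half_period(self):
        x = np.sin(2 * np.pi * np.arange(3000) / 100.0)
        assert rq.autocorr_delay(x, 300) == 50

    def test_white_noise_small_delay(self, rng):
        assert rq.autocorr_delay(rng.normal(size=3000), 300) <= 5

    def test_ar1_falls_through_to_zero_crossing(self, rng):
        # AR(1) phi=0.9: monotone positive ACF, no local minimum early on
        n = 6000
        x = np.zeros(n)
        e = rng.normal(size=n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + e[i]
        tau = rq.autocorr_delay(x, 600)
        # theoretical ACF 0.9^k: sample ACF decays to ~0 near k ~ 30-60
        assert 5 <= tau <= 200

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateInputError):
            rq.autocorr_delay(np.ones(100), 20)


class TestDelayEmbed:
    def test_dimension_one_is_identity(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(rq.delay_embed(x, 1, 3)[:, 0], x)

    def test_point_count_formula(self):
        assert rq.delay_embed(np.arange(10), 3, 2).shape == (6, 3)

    def test_first_point_coordinates(self):
        emb = rq.delay_embed(np.arange(1, 11), 2, 3)
        assert tuple(emb[0]) == (1, 4)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            rq.delay_embed(np.arange(5), 3, 3)


class TestFnnDimension:
    def test_circle_needs_two_dimensions(self):
        # quarter-period delay unfolds a sine onto a circle
        x = np.sin(2 * np.pi * np.arange(3000) * 0.013)
        assert rq.fnn_dimension(x, delay=19) == 2

    def test_lorenz_attractor_needs_three(self):
        def lorenz(t, s):
            return [10 * (s[1] - s[0]), s[0] * (28 - s[2]) - s[1],
                    s[0] * s[1] - 8 / 3 * s[2]]

        sol = solve_ivp(lorenz, [0, 100], [1.0, 1.0, 1.0],
                        t_eval=np.arange(0, 100, 0.02), rtol=1e-8)
        x = sol.y[0][500:]
        assert rq.fnn_dimension(x, delay=6) == 3

    def test_white_noise_hits_dimension_cap(self, rng):
        with pytest.warns(UserWarning, match="m_max"):
            m = rq.fnn_dimension(rng.normal(size=2500), delay=1, m_max=6)
        assert m == 6


class TestCrossRecurrenceMatrix:
    def test_identical_trajectories_light_main_diagonal(self, rng):
        traj = rng.normal(size=(40, 2))
        mat, _ = rq.cross_recurrence_matrix(traj, traj, epsilon=1e-12)
        assert np.all(np.diag(mat))

    def test_separated_trajectories_all_zero(self, rng):
        a = rng.normal(size=(30, 2))
        mat, _ = rq.cross_recurrence_matrix(a, a + 100.0, epsilon=1.0)
        assert not mat.any()

    def test_fixed_rate_policy_hits_target(self, rng):
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(200, 3))
        mat, _ = rq.cross_recurrence_matrix(a, b, target_rr=0.10)
        assert mat.mean() == pytest.approx(0.10, abs=0.005)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ParameterError):
            rq.cross_recurrence_matrix(rng.normal(size=(10, 2)),
                                       rng.normal(size=(10, 3)))


class TestCraIndices:
    def test_identity_matrix_gives_full_diagonal(self, rng):
        traj = rng.normal(size=(50, 2))
        mat, _ = rq.cross_recurrence_matrix(traj, traj, epsilon=1e-12)
        res = rq.cra_indices(mat)
        assert res.mdl == 50
        assert res.det == 1.0

    def test_shifted_copy_gives_off_diagonal_run(self, rng):
        x = rng.normal(size=60)
        shift = 7
        a = rq.delay_embed(x, 2, 1)
        b = rq.delay_embed(np.roll(x, -shift), 2, 1)
        mat = (np.abs(a[:, None, :] - b[None, :, :]).max(axis=2) < 1e-12)
        res = rq.cra_indices(mat)
        assert res.mdl == len(a) - shift

    def test_all_zero_matrix_convention(self):
        res = rq.cra_indices(np.zeros((10, 10), dtype=bool))
        assert (res.rr, res.mdl, res.det, res.mean_diagonal,
                res.entropy) == (0.0, 0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize("draw", range(25))
    def test_agrees_with_brute_force_scanner(self, draw):
        rng = np.random.default_rng(500 + draw)
        mat = rng.random((30, 30)) < rng.uniform(0.05, 0.4)
        res = rq.cra_indices(mat)
        ref = _brute_force_indices(mat)
        assert res.rr == pytest.approx(ref["rr"])
        assert res.det == pytest.approx(ref["det"])
        assert res.mean_diagonal == pytest.approx(ref["l"])
        assert res.mdl == ref["mdl"]
        assert res.entropy == pytest.approx(ref["entr"])

    def test_swap_symmetry(self, rng):
        a = rng.normal(size=(40, 3))
        b = rng.normal(size=(45, 3))
        ma, eps = rq.cross_recurrence_matrix(a, b, target_rr=0.1)
        mb, _ = rq.cross_recurrence_matrix(b, a, epsilon=eps)
        assert np.array_equal(mb, ma.T)
        ra, rb = rq.cra_indices(ma), rq.cra_indices(mb)
        assert (ra.rr, ra.det, ra.mean_diagonal, ra.mdl, ra.entropy) == \
            (rb.rr, rb.det, rb.mean_diagonal, rb.mdl, rb.entropy)

    def test_mdl_monotone_in_epsilon(self, rng):
        a = rng.normal(size=(80, 2))
        b = rng.normal(size=(80, 2))
        mdls = []
        for eps in (0.1, 0.5, 1.0, 2.0, 4.0):
            mat, _ = rq.cross_recurrence_matrix(a, b, epsilon=eps)
            mdls.append(rq.cra_indices(mat).mdl)
        assert mdls == sorted(mdls)


class TestCraBandIndex:
    def test_identical_channels_give_maximal_mdl(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30000)
        mdl = rq.cra_band_index(x, x, 0.01, (4.0, 8.0), analysis_fs=50.0,
                                window_s=20.0, max_windows=1,
                                embedding=rq.EmbeddingParams(5, 3))
        # trajectory length = window - (m-1)*tau
        assert mdl == 20.0 * 50.0 - 2 * 5

    @pytest.mark.parametrize("seed", range(4))
    def test_coupled_pair_exceeds_independent(self, seed):
        from ldsb_eeg.synthetic import coherent_pair

        coupled = coherent_pair(120.0, 0.002, (4, 8), 0.9, seed=seed)
        rng = np.random.default_rng(1000 + seed)
        kw = dict(analysis_fs=50.0, window_s=30.0, max_windows=2,
                  embedding=rq.EmbeddingParams(2, 4))
        mdl_c = rq.cra_band_index(coupled.samples[0], coupled.samples[1],
                                  0.002, (4, 8), **kw)
        mdl_i = rq.cra_band_index(rng.normal(size=60000),
                                  rng.normal(size=60000),
                                  0.002, (4, 8), **kw)
        assert mdl_c > mdl_i
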