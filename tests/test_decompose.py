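"""PSTHs, NNMF factorization, component selection and the Gaussian rotation."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

import rftomo as rt
from rftomo.decompose import radial_gaussian
from rftomo.geometry import bar_center_distance
from rftomo.simulate import SpikeData


def planted_rank2(seed=0, T=200, s=126):
    """Two non-negative rank-1 terms: disjoint temporal supports, spatially
    localized (zero-reaching) weights — an identifiable factorization."""
    p1 = np.zeros(T)
    p1[20:60] = np.hanning(40)
    p2 = np.zeros(T)
    p2[100:160] = np.hanning(60)
    d = np.arange(s) % 21 - 10.0
    w1 = np.exp(-((d / 3.0) ** 2))
    w2 = np.exp(-(((d - 4) / 4.0) ** 2))
    R = np.outer(p1, w1).T + np.outer(p2, w2).T
    return R, (p1, p2), (w1, w2)


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def matched_cosine(P, truths):
    direct = min(cosine(P[:, 0], truths[0]), cosine(P[:, 1], truths[1]))
    swapped = min(cosine(P[:, 0], truths[1]), cosine(P[:, 1], truths[0]))
    return max(direct, swapped)


class TestBuildPSTH:
    def test_single_spike_rate(self, bar_set):
        spikes = SpikeData(
            stimulus_index=np.array([0]),
            replicate=np.array([0]),
            times=np.array([0.055]),
            n_replicates=1,
            stimulus_set=bar_set,
            window=(-0.1, 0.5),
        )
        R = rt.build_psth(spikes, bin_width=0.01)
        assert R.rates.sum() == pytest.approx(100.0)  # 1 spike / (1 rep x 10 ms)
        t_idx = np.argmin(np.abs(R.times - 0.055))
        assert R.rates[0, t_idx] == pytest.approx(100.0)

    def test_replicate_averaging_identity(self, bar_set):
        """Identical spike trains in 3 replicates give the 1-replicate PSTH."""
        t = np.array([0.05, 0.12, 0.31])
        one = SpikeData(
            np.zeros(3, int), np.zeros(3, int), t, 1, bar_set, window=(-0.1, 0.5)
        )
        three = SpikeData(
            np.zeros(9, int),
            np.repeat([0, 1, 2], 3),
            np.tile(t, 3),
            3,
            bar_set,
            window=(-0.1, 0.5),
        )
        np.testing.assert_allclose(
            rt.build_psth(one).rates, rt.build_psth(three).rates
        )

    def test_constant_rate_recovered_within_standard_error(self):
        neuron = dataclasses.replace(
            rt.p_like_neuron(center=(99.0, 99.0)), baseline_rate=50.0
        )
        ss = rt.build_stimulus_set(1, 1, bar_width=0.1, extent=0.5)
        spikes = rt.simulate_flash_responses(
            neuron, ss, n_replicates=200, seed=5, window=(0.0, 1.0)
        )
        R = rt.build_psth(spikes, bin_width=0.01)
        se = np.sqrt(50.0 / (200 * 0.01))
        # per-bin 3 SE with a multiplicity allowance (100 bins); the grand
        # mean is held to its own tighter standard error
        outside = np.abs(R.rates - 50.0) > 3 * se
        assert outside.mean() <= 0.03
        assert abs(R.rates.mean() - 50.0) <= 3 * se / np.sqrt(R.rates.size)

    def test_empty_spikes_warn_zero_matrix(self, bar_set):
        empty = SpikeData(
            np.empty(0, int), np.empty(0, int), np.empty(0), 1, bar_set
        )
        with pytest.warns(UserWarning, match="no spikes"):
            R = rt.build_psth(empty)
        assert np.all(R.rates == 0)


class TestNNMF:
    def test_rank1_input_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        profile = np.abs(rng.normal(size=150))
        weights = np.abs(rng.normal(size=60))
        R = rt.ResponseMatrix(np.outer(profile, weights).T, 0.01, (0.0, 1.5))
        comps = rt.nnmf_decompose(R, 2, seed=0, max_iter=5000, tol=1e-12)
        err = np.linalg.norm(comps.reconstruct() - R.rates) / np.linalg.norm(R.rates)
        assert err < 1e-6
        # a rank-1 input admits no genuine second component: the rank-2
        # approximation must itself be numerically rank 1
        sv = np.linalg.svd(comps.reconstruct(), compute_uv=False)
        assert sv[1] < 1e-6 * sv[0]

    def test_planted_two_component_recovery(self):
        R, profiles, weights = planted_rank2()
        comps = rt.nnmf_decompose(
            rt.ResponseMatrix(R, 0.01, (0.0, 2.0)), 2, seed=3, max_iter=5000, tol=1e-10
        )
        assert matched_cosine(comps.profiles, profiles) > 0.99
        assert matched_cosine(comps.weights.T, weights) > 0.99

    def test_error_non_increasing_in_k(self, m_cell_run):
        R = m_cell_run["psth"]
        errs = [
            rt.nnmf_decompose(R, k, seed=0).reconstruction_error for k in (2, 3, 4)
        ]
        assert errs[0] >= errs[1] >= errs[2]

    def test_profile_normalization_convention(self, m_cell_run):
        comps = m_cell_run["components"]
        np.testing.assert_allclose(comps.profiles.max(axis=0), 1.0)

    def test_invalid_inputs(self, bar_set):
        with pytest.raises(ValueError):
            rt.ResponseMatrix(-np.ones((4, 5)), 0.01, (0.0, 0.05))
        R = rt.ResponseMatrix(np.ones((6, 5)), 0.01, (0.0, 0.05))
        with pytest.raises(ValueError):
            rt.nnmf_decompose(R, 6, seed=0)  # k > min(s, T)

    def test_joint_channels_share_profiles(self):
        """Chromatic mode: one profile basis, per-channel weight blocks."""
        R, (p1, p2), (w1, w2) = planted_rank2(s=126)
        R_s = np.outer(p1, w1).T + np.outer(p2, 0.3 * w2).T
        responses = {
            "ML": rt.ResponseMatrix(R, 0.01, (0.0, 2.0)),
            "S": rt.ResponseMatrix(R_s, 0.01, (0.0, 2.0)),
        }
        comps, blocks = rt.nnmf_decompose_joint(responses, 2, seed=0, max_iter=3000)
        assert set(blocks) == {"ML", "S"}
        assert blocks["ML"].shape == blocks["S"].shape == (2, 126)
        assert comps.weights.shape == (2, 252)
        assert matched_cosine(comps.profiles, (p1, p2)) > 0.98


class TestSelectK:
    def test_pure_noise_returns_floor(self, pm_protocol):
        rng = np.random.default_rng(0)
        R = rt.ResponseMatrix(rng.uniform(0, 1, (126, 220)), 0.01, (-0.2, 2.0))
        assert rt.select_k(R, pm_protocol, seed=0) == 2

    def test_center_only_sustained_cell_returns_two(self, pm_protocol):
        """A sustained linear centre-only cell has exactly two meaningful
        components (evoked + maintained); the third fails the modulation
        criterion."""
        neuron = rt.NeuronSpec(
            kind="linear_dog",
            dog=rt.DoGParams(400, 0, 0.24, 0.72),
            center=(0.1, -0.05),
            baseline_rate=40.0,
            kernel_balance=0.2,
        )
        spikes = rt.simulate_flash_responses(neuron, pm_protocol, n_replicates=10, seed=1)
        R = rt.build_psth(spikes)
        assert rt.select_k(R, pm_protocol, seed=0) == 2

    def test_cell_with_surround_returns_at_most_three(self, pm_protocol):
        neuron = rt.NeuronSpec(
            kind="linear_dog",
            dog=rt.DoGParams(400, 24.4, 0.24, 0.72),
            center=(0.1, -0.05),
            baseline_rate=40.0,
            kernel_balance=0.2,
        )
        spikes = rt.simulate_flash_responses(neuron, pm_protocol, n_replicates=10, seed=3)
        R = rt.build_psth(spikes)
        assert 2 <= rt.select_k(R, pm_protocol, seed=0) <= 3


class TestGaussianRotation:
    def test_rotation_identity_random_F(self):
        """(P F^-1)(F W) == P W for random valid rotations."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            k = rng.integers(2, 4)
            F = np.eye(k) + rng.uniform(0, 0.5, (k, k)) * (1 - np.eye(k))
            P = np.abs(rng.normal(size=(80, k)))
            W = np.abs(rng.normal(size=(k, 30)))
            lhs = (P @ np.linalg.inv(F)) @ (F @ W)
            rhs = P @ W
            assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-10

    def test_exactly_gaussian_weights_give_identity_rotation(self, bar_set):
        d = bar_center_distance(bar_set, (0.1, 0.2))
        W = radial_gaussian(
            d[None, :], np.array([[1.0], [0.8]]), np.array([[0.05], [0.15]]),
            np.array([[0.3], [0.2]]),
        )
        P = np.abs(np.random.default_rng(0).normal(size=(220, 2)))
        comps = rt.ComponentSet(P, W, 0.01, (-0.2, 2.0))
        fit = rt.rotate_to_gaussian(comps, bar_set)
        np.testing.assert_allclose(fit.F, np.eye(2), atol=1e-4)
        assert fit.objective < 1e-8

    def test_planted_rotation_recovered(self, bar_set):
        """Forward-construct W = F0^-1 (Gaussian weights); the fit recovers
        F0 and the planted radii."""
        F0 = np.array([[1.0, 0.3], [0.2, 1.0]])
        g = np.array([1.0, 0.8])
        r = np.array([0.05, 0.15])
        b = np.array([0.5, 0.5])
        d = bar_center_distance(bar_set, (0.1, 0.2))
        G = radial_gaussian(d[None, :], g[:, None], r[:, None], b[:, None])
        W = np.linalg.solve(F0, G)
        assert W.min() >= 0
        P = np.abs(np.random.default_rng(1).normal(size=(220, 2)))
        fit = rt.rotate_to_gaussian(rt.ComponentSet(P, W, 0.01, (-0.2, 2.0)), bar_set)
        np.testing.assert_allclose(fit.F, F0, atol=1e-3)
        np.testing.assert_allclose(fit.radii, r, rtol=0.01)
        # algebraic identity holds for the returned fit
        lhs = fit.rotated_profiles @ fit.rotated_weights
        rhs = P @ W
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-10

    def test_two_component_fit_has_ten_free_parameters(self, m_cell_run):
        assert m_cell_run["fit"].n_free_parameters == 10

    def test_objective_not_worse_than_initialization(self, m_cell_run):
        fit = m_cell_run["fit"]
        assert fit.objective <= fit.objective_init

    def test_rotated_weights_nonnegative(self, m_cell_run):
        assert m_cell_run["fit"].rotated_weights.min() >= -1e-8

    def test_rotation_exposes_inhibition(self, m_cell_run):
        """The rotated surround profile goes negative; raw NNMF profiles
        cannot."""
        comps, fit = m_cell_run["components"], m_cell_run["fit"]
        assert comps.profiles.min() >= 0
        assert fit.rotated_profiles.min() < -0.01

    def test_center_recovered_within_one_bar_width(self, pm_protocol):
        truth = (0.1, -0.05)
        for seed in (0, 1, 2):
            spikes = rt.simulate_flash_responses(
                rt.m_like_neuron(center=truth), pm_protocol, n_replicates=3, seed=seed
            )
            comps = rt.nnmf_decompose(rt.build_psth(spikes), 2, seed=seed)
            fit = rt.rotate_to_gaussian(comps, pm_protocol)
            err = np.hypot(fit.center[0] - truth[0], fit.center[1] - truth[1])
            assert err < pm_protocol.bar_width

    def test_unsupported_k_rejected(self, bar_set):
        P = np.abs(np.random.default_rng(0).normal(size=(50, 4)))
        W = np.abs(np.random.default_rng(1).normal(size=(4, bar_set.s)))
        with pytest.raises(ValueError, match="k = 2 or 3"):
            rt.rotate_to_gaussian(rt.ComponentSet(P, W, 0.01, (0.0, 0.5)), bar_set)


class TestComponentF1:
    def test_pure_sinusoid_and_constant(self):
        t = np.arange(0, 2, 0.001)
        prof = np.column_stack([5 * (1 + np.sin(2 * np.pi * 5 * t)), np.ones_like(t)])
        comps = rt.ComponentSet(prof, np.ones((2, 4)), 0.001, (0.0, 2.0))
        amps, _ = rt.component_f1(comps, 5.0)
        assert amps[0] == pytest.approx(5.0, rel=0.01)
        assert amps[1] == pytest.approx(0.0, abs=1e-9)

    def test_halfwave_rectified_harmonics_vs_quadrature(self):
        """f1 = A/2 and f2 = 2A/(3 pi) for a half-wave rectified sinusoid,
        cross-checked against dense numerical Fourier integrals."""
        A, f = 4.0, 5.0
        t = np.arange(0, 2, 0.0005)
        prof = np.maximum(A * np.sin(2 * np.pi * f * t), 0.0)
        comps = rt.ComponentSet(prof[:, None], np.ones((1, 4)), 0.0005, (0.0, 2.0))
        (f1,), _ = rt.component_f1(comps, f)
        (f2,), _ = rt.component_f1(comps, 2 * f)
        assert f1 == pytest.approx(A / 2, rel=0.01)
        assert f2 == pytest.approx(2 * A / (3 * np.pi), rel=0.01)
        for freq, got in ((f, f1), (2 * f, f2)):
            re = quad(
                lambda x: max(A * np.sin(2 * np.pi * f * x), 0)
                * np.cos(2 * np.pi * freq * x),
                0.0, 0.2, limit=400,
            )[0]
            im = quad(
                lambda x: max(A * np.sin(2 * np.pi * f * x), 0)
                * np.sin(2 * np.pi * freq * x),
                0.0, 0.2, limit=400,
            )[0]
            oracle = 2 / 0.2 * np.hypot(re, im)
            assert got == pytest.approx(oracle, rel=0.01)

    def test_window_shorter_than_cycle_rejected(self):
        prof = np.ones((30, 1))
        comps = rt.ComponentSet(prof, np.ones((1, 4)), 0.01, (0.0, 0.3))
        with pytest.raises(ValueError, match="at least one full cycle"):
            rt.component_f1(comps, 2.0)

    def test_rotated_fit_uses_signed_profiles(self, m_cell_run):
        amps_raw, _ = rt.component_f1(m_cell_run["components"], 5.0)
        amps_rot, _ = rt.component_f1(m_cell_run["fit"], 5.0)
        assert amps_raw.shape == amps_rot.shape == (2,)
        assert np.all(amps_raw > 0)
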