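import numpy as np
import pytest

from bgsinfer import (
    GammaDFE,
    MatingSystem,
    PiecewiseHistory,
    SFSModelConfig,
    WindowedSFS,
    apply_polarization_error,
    expected_sfs,
    lnCL_sfs,
    window_history,
)
from bgsinfer.sfs_likelihood import estimate_epsilon_neutral


class TestPolarizationError:
    def test_identity_at_zero(self):
        xi = np.array([[0.9, 0.05, 0.03, 0.02]])
        np.testing.assert_array_equal(apply_polarization_error(xi, 0.0), xi)

    def test_worked_example_n4(self):
        xi = np.array([[0.0, 0.5, 0.3, 0.2]])
        out = apply_polarization_error(xi, 0.1)[0]
        np.testing.assert_allclose(out, [0.0, 0.47, 0.30, 0.23])

    def test_symmetric_spectrum_fixed_point(self):
        xi = np.array([[0.9, 0.04, 0.02, 0.04]])
        np.testing.assert_allclose(apply_polarization_error(xi, 0.3), xi)

    def test_mass_conserved_and_linear(self, rng):
        xi = rng.dirichlet(np.ones(10))[None, :]
        out = apply_polarization_error(xi, 0.2)
        assert out[0, 1:].sum() == pytest.approx(xi[0, 1:].sum())
        # linearity
        a = apply_polarization_error(2 * xi, 0.2)
        np.testing.assert_allclose(a, 2 * out)

    def test_bad_epsilon(self):
        with pytest.raises(ValueError):
            apply_polarization_error(np.ones((1, 4)), 0.6)


class TestExpectedSFS:
    def test_neutral_constant_shape(self):
        xi = expected_sfs(np.array([np.inf]), np.array([[1e4]]), 20, 7.5e-9)[0]
        seg = xi[1:]
        j = np.arange(1, 20)
        np.testing.assert_allclose(seg * j / seg[0], np.ones(19), rtol=1e-10)
        assert xi.sum() == pytest.approx(1.0)

    def test_theta_too_large_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            expected_sfs(np.array([np.inf]), np.array([[1e4]]), 20, 1e-3)

    def test_selfing_distortion_against_outcrossing(self):
        # selfing raises the relative weight of even bins (IBD doubling)
        dur = np.array([np.inf])
        m = MatingSystem(0.9)
        xi_s = expected_sfs(dur, np.array([[1e4 / (1 + m.F)]]), 20, 7.5e-9,
                            mating=m, n_diploids=10)[0]
        xi_o = expected_sfs(dur, np.array([[1e4]]), 20, 7.5e-9)[0]
        rel_s = xi_s[1:] / xi_s[1:].sum()
        rel_o = xi_o[1:] / xi_o[1:].sum()
        even = np.arange(1, 20) % 2 == 0
        assert rel_s[even].sum() > rel_o[even].sum()


class TestWindowHistory:
    def test_neutral_B_equals_demography(self, strong_dfe):
        hist = PiecewiseHistory((1e4, 2e3), (5e3,))
        B = np.ones((3, 2))
        dur, Ne = window_history(hist, B, strong_dfe, 1e4)
        assert np.isinf(dur[-1])
        np.testing.assert_allclose(Ne[:, :3], 1e4)
        np.testing.assert_allclose(Ne[:, 3], 2e3)

    def test_single_epoch_endpoint_contract(self, strong_dfe):
        hist = PiecewiseHistory((1e4,))
        B = np.full((2, 1), 0.8)
        dur, Ne = window_history(hist, B, strong_dfe, 1e4)
        assert Ne.shape == (2, 3)
        assert Ne[0, 0] > Ne[0, 1] > Ne[0, 2]  # monotone transition steps
        assert Ne[0, 2] == pytest.approx(0.8e4)

    def test_transition_truncated_when_T0_short(self, strong_dfe):
        hist = PiecewiseHistory((1e4, 1e3), (50.0,))
        B = np.full((1, 2), 0.8)
        with pytest.warns(UserWarning, match="truncat"):
            dur, Ne = window_history(hist, B, strong_dfe, 1e4)
        assert np.cumsum(dur[:-1])[-1] <= 50.0 + 1e-9 or dur[2] >= 0

    def test_selfing_rescales_all_rates(self, strong_dfe):
        hist = PiecewiseHistory((1e4,))
        B = np.full((1, 1), 1.0)
        m = MatingSystem(0.9)
        _, Ne0 = window_history(hist, B, strong_dfe, 1e4)
        _, NeS = window_history(hist, B, strong_dfe, 1e4, m)
        np.testing.assert_allclose(NeS, Ne0 / (1 + m.F))


class TestLnCLSFS:
    def test_empty_data_zero(self):
        data = WindowedSFS(np.zeros((3, 10)), 10)
        xi = np.full((3, 10), 0.1)
        assert lnCL_sfs(data, xi) == 0.0

    def test_additive_over_windows(self, rng):
        counts = rng.integers(0, 50, size=(4, 10)).astype(float)
        xi = rng.dirichlet(np.ones(10), size=4)
        data = WindowedSFS(counts, 10)
        total = lnCL_sfs(data, xi)
        parts = sum(lnCL_sfs(WindowedSFS(counts[i:i + 1], 10), xi[i:i + 1])
                    for i in range(4))
        assert total == pytest.approx(parts)

    def test_masking_removes_terms_exactly(self, rng):
        counts = rng.integers(1, 50, size=(2, 10)).astype(float)
        xi = rng.dirichlet(np.ones(10), size=2)
        data = WindowedSFS(counts, 10)
        masked = data.mask_top(2)
        assert masked.masked_bins == (8, 9)
        diff = lnCL_sfs(data, xi) - lnCL_sfs(masked, xi)
        expect = float(np.sum(counts[:, 8:] * np.log(xi[:, 8:])))
        assert diff == pytest.approx(expect)

    def test_zero_expectation_with_data_raises(self):
        data = WindowedSFS(np.array([[0.0, 5.0, 0.0, 0.0]]), 4)
        xi = np.array([[1.0, 0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="zero"):
            lnCL_sfs(data, xi)

    def test_truth_beats_perturbed_on_average(self, rng):
        # multinomial consistency smoke test
        xi0 = expected_sfs(np.array([np.inf]), np.array([[1e4]]), 10, 7.5e-9)[0]
        xi1 = expected_sfs(np.array([np.inf]), np.array([[1.1e4]]), 10, 7.5e-9)[0]
        wins = 0
        for rep in range(100):
            counts = rng.multinomial(5_000_000, xi0)[None, :].astype(float)
            data = WindowedSFS(counts, 10)
            if lnCL_sfs(data, xi0[None, :]) > lnCL_sfs(data, xi1[None, :]):
                wins += 1
        assert wins >= 95


class TestWindowedSFSContainer:
    def test_tsv_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 100, size=(5, 8)).astype(float)
        sfs = WindowedSFS(counts, 8)
        p = tmp_path / "sfs.tsv"
        sfs.to_tsv(p)
        back = WindowedSFS.from_tsv(p)
        np.testing.assert_allclose(back.counts, counts)
        assert back.n == 8

    def test_pairwise_diversity_single_site(self):
        counts = np.zeros((1, 4))
        counts[0, 2] = 1.0  # j = n/2 for n=4: weight 2*2*2/(4*3) = 2/3
        counts[0, 0] = 0.0
        sfs = WindowedSFS(counts, 4)
        assert sfs.pairwise_diversity() == pytest.approx(2 / 3)


class TestEpsilonEstimation:
    def test_recovery_and_zero(self, rng):
        n = 20
        hist = PiecewiseHistory((20_000.0, 8_000.0, 15_000.0), (10_000.0, 30_000.0))
        dur = np.diff(np.concatenate([[0.0], hist.T, [np.inf]]))
        for eps_true, lo, hi in ((0.05, 0.03, 0.07), (0.0, 0.0, 0.01)):
            xi = expected_sfs(dur, np.asarray(hist.N)[None, :], n, 7e-9,
                              epsilon=eps_true)[0]
            counts = rng.multinomial(30_000_000, xi).astype(float)
            eps_hat, _, _ = estimate_epsilon_neutral(counts, n, 7e-9, seed=2)
            assert lo <= eps_hat <= hi

    def test_symmetric_input_flagged(self):
        n = 10
        sym = np.concatenate([[1e6], np.full(n - 1, 1e3)])
        with pytest.warns(UserWarning, match="symmetric"):
            estimate_epsilon_neutral(sym, n, 7e-9, seed=1, max_evals=200)
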