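import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgsinfer import (
    GammaDFE,
    MatingSystem,
    PiecewiseHistory,
    bb_window,
    build_interpolators,
    bw_window,
    exponent_single,
    exponent_single_selfing,
    iterate_epoch_bmap,
    ne_transition,
    transition_times,
    truncation_bound,
)
from bgsinfer.bgs_theory import (
    RANDOM_MATING,
    PairwiseSummer,
    _bw_exponent_point_bruteforce,
    bb_integral,
    bmap_for_genome,
    bw_exponent_closed_form,
)


class TestGammaDFE:
    def test_pdf_normalized_and_mean(self):
        from scipy import integrate
        dfe = GammaDFE(1e-8, 0.0275, 0.55)
        # mass above s=2 is ~exp(-2 beta / s_mean), utterly negligible here
        total, _ = integrate.quad(dfe.pdf, 0, 2.0, points=[dfe.s_mean], limit=200)
        mean, _ = integrate.quad(lambda s: s * dfe.pdf(s), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, rel=1e-6)
        assert mean == pytest.approx(dfe.s_mean, rel=1e-6)

    def test_quad_nodes_integrate_pdf(self):
        dfe = GammaDFE(1e-8, 0.01, 3.0)
        s, w = dfe.quad_nodes(1e-4, 1.0)
        assert w.sum() == pytest.approx(dfe.truncated_mass(1e-4, 1.0), rel=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(mu=-1e-9, s_mean=0.01, beta=1.0),
        dict(mu=1e-9, s_mean=0.0, beta=1.0),
        dict(mu=1e-9, s_mean=0.01, beta=0.0),
        dict(mu=1e-9, s_mean=0.01, beta=1.0, h=1.5),
    ])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            GammaDFE(**bad)


class TestMatingSystem:
    def test_equilibrium_F(self):
        assert MatingSystem(0.0).F == 0.0
        assert MatingSystem(0.9).F == pytest.approx(9 / 11)
        assert MatingSystem(1.0).F == 1.0

    def test_rescalers_identity_at_zero(self):
        m = MatingSystem(0.0)
        assert m.r_eff(0.3) == 0.3
        assert m.h_eff(0.5) == 0.5

    def test_rescalers_selfing(self):
        m = MatingSystem(0.9)
        F = 9 / 11
        assert m.r_eff(0.1) == pytest.approx(0.1 * (1 - F))
        assert m.h_eff(0.5) == pytest.approx(0.5 * (1 - F) + F)


class TestSingleSiteExponents:
    """Closed-form limits of the per-site BGS kernels."""

    def test_zero_mutation_rate(self):
        assert exponent_single(0.0, 0.02, 0.5, 0.1) == 0.0

    def test_unlinked_reduction(self):
        mu, s, h = 1e-8, 0.02, 0.5
        expect = 8 * mu * s * h / (1 + s * h) ** 2
        assert exponent_single(mu, s, h, 0.5) == pytest.approx(expect, rel=1e-12)

    def test_tight_linkage_reduction(self):
        mu, s, h = 1e-8, 0.02, 0.5
        expect = mu * (1 + (s * h) ** 2) / (s * h)
        assert exponent_single(mu, s, h, 0.0) == pytest.approx(expect, rel=1e-12)

    def test_selfing_kernel_matches_random_mating_at_r0_F0(self):
        mu, s, h = 1e-8, 0.02, 0.5
        a = exponent_single(mu, s, h, 1e-9)
        b = exponent_single_selfing(mu, s, h, 1e-9, RANDOM_MATING)
        # both reduce to mu/(sh) up to O((sh)^2)
        assert b == pytest.approx(mu / (s * h), rel=1e-4)
        assert a == pytest.approx(b, rel=2 * (s * h) ** 2)

    def test_full_selfing_limit(self):
        # alpha=1 => h'=1, r'=0: term = mu / s exactly
        mu, s, r = 1e-8, 0.05, 0.1
        m = MatingSystem(1.0)
        assert exponent_single_selfing(mu, s, 0.5, r, m) == pytest.approx(mu / s)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            exponent_single(1e-8, 0.0, 0.5, 0.1)
        with pytest.raises(ValueError):
            exponent_single(1e-8, 0.02, 0.5, 0.7)

    @given(st.floats(1e-4, 0.99), st.floats(0.0, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_positive_and_decreasing_in_r(self, s, r):
        h = 0.5
        t = exponent_single(1e-8, s, h, r)
        assert t >= 0
        if r < 0.49:
            assert exponent_single(1e-8, s, h, r + 0.01) <= t * (1 + 1e-9)


class TestBwWindow:
    def test_zero_rate(self, strong_dfe):
        assert bw_window(0.0, 0.01, strong_dfe, 1e4) == 1.0

    def test_zero_R_limit_point_dfe(self):
        # exponent -> U/(2 s h) = mu L / (s h) for a point DFE
        U, s, h = 1e-4, 0.02, 0.5
        e = bw_exponent_closed_form(U, 0.0, s, h)
        assert e == pytest.approx(U / (2 * s * h), rel=1e-6)

    def test_against_discretization_oracle(self):
        for R in (0.002, 0.01, 0.05):
            e_cf = bw_exponent_closed_form(1e-4, R, 0.02, 0.5)
            e_bf = _bw_exponent_point_bruteforce(1e-4, R, 0.02, 0.5, n_grid=1500)
            assert e_cf == pytest.approx(e_bf, rel=1e-4)

    def test_selfing_rescaling(self):
        m = MatingSystem(0.9)
        e = bw_exponent_closed_form(1e-4, 0.01, 0.02, 0.5, m)
        a = 0.02 * m.h_eff(0.5)
        b = m.r_eff(0.01) * (1 - a)
        expect = 1e-4 * (b - a * np.log1p(b / a)) / b**2
        assert e == pytest.approx(expect, rel=1e-12)

    def test_full_bw_bounds(self, strong_dfe):
        b = bw_window(1e-4, 0.01, strong_dfe, 1e4)
        assert 0 < b < 1


class TestBbWindow:
    def test_mu_zero_gives_one(self, small_genome, strong_dfe):
        _, _, genome = small_genome
        from dataclasses import replace
        assert bb_window(genome, 0, replace(strong_dfe, mu=0.0), 1e4) == 1.0

    def test_interpolated_matches_quadrature(self, small_genome, fig1_dfe):
        _, _, genome = small_genome
        B, Bb, Bw = bmap_for_genome(genome, fig1_dfe, 10_000.0)
        for k in (0, 13, 57, 99):
            direct = bb_window(genome, k, fig1_dfe, 10_000.0)
            assert abs(Bb[k] - direct) < 1e-3  # grid tolerance in B

    def test_decomposition_and_range(self, small_genome, fig1_dfe):
        _, _, genome = small_genome
        B, Bb, Bw = bmap_for_genome(genome, fig1_dfe, 10_000.0)
        assert np.all((B > 0) & (B <= 1))
        np.testing.assert_allclose(B, Bb * Bw, rtol=1e-12)

    def test_unlinked_only_closed_form(self, strong_dfe):
        # all other windows on a different chromosome: exponent uses I(0.5)
        from bgsinfer.genome_model import WindowedGenome
        g = WindowedGenome(
            chrom=["a", "b", "b"], start=[0, 0, 10_000], end=[10_000, 10_000, 20_000],
            L=[0.0, 3_000.0, 1_000.0], callable=[1e4] * 3, R=[0.001] * 3,
            gpos=[5e-5, 5e-5, 1.5e-4], mu=strong_dfe.mu,
        )
        s_lo = truncation_bound(1e4, strong_dfe.h)
        expect = np.exp(-strong_dfe.mu * 4_000 * bb_integral(0.5, strong_dfe, s_lo))
        assert bb_window(g, 0, strong_dfe, 1e4) == pytest.approx(expect, rel=1e-6)

    def test_b_decreasing_in_mu_increasing_in_r(self, fig1_dfe):
        from dataclasses import replace
        s_lo = truncation_bound(1e4, 0.5)
        r = np.array([1e-4, 1e-3, 1e-2, 0.1, 0.5])
        vals = bb_integral(r, fig1_dfe, s_lo)
        assert np.all(np.diff(vals) < 0)  # exponent decreasing in r => B increasing


class TestInterpolators:
    def test_grid_node_exact(self, small_genome, fig1_dfe):
        _, _, genome = small_genome
        interp = build_interpolators(genome, fig1_dfe, 1e4)
        s_lo = truncation_bound(1e4, fig1_dfe.h)
        node = interp.r_grid[17]
        assert interp.bb_per_mu(node) == pytest.approx(
            bb_integral(node, fig1_dfe, s_lo), rel=1e-12)

    def test_random_queries_within_tolerance(self, small_genome, fig1_dfe, rng):
        _, _, genome = small_genome
        interp = build_interpolators(genome, fig1_dfe, 1e4)
        s_lo = truncation_bound(1e4, fig1_dfe.h)
        q = np.exp(rng.uniform(np.log(interp.r_grid[0]), np.log(0.5), size=100))
        direct = bb_integral(q, fig1_dfe, s_lo)
        # tolerance in B for a typical per-window rate
        mu_L = fig1_dfe.mu * 2_000
        err = np.abs(np.exp(-mu_L * interp.bb_per_mu(q)) - np.exp(-mu_L * direct))
        assert err.max() < 1e-3

    def test_clamp_warns(self, small_genome, fig1_dfe):
        _, _, genome = small_genome
        interp = build_interpolators(genome, fig1_dfe, 1e4)
        with pytest.warns(UserWarning, match="clamp"):
            interp.bb_per_mu(interp.r_grid[0] / 10)


class TestNeTransition:
    def test_endpoints(self, strong_dfe):
        assert ne_transition(0.0, 1e4, 0.8, strong_dfe, 1e4) == pytest.approx(1e4)
        assert ne_transition(1e9, 1e4, 0.8, strong_dfe, 1e4) == pytest.approx(8e3)

    def test_B_one_flat(self, strong_dfe):
        t = np.array([0.0, 100.0, 1e5])
        np.testing.assert_allclose(ne_transition(t, 1e4, 1.0, strong_dfe, 1e4), 1e4)

    def test_monotone_nonincreasing(self, strong_dfe):
        t = np.geomspace(1, 1e6, 50)
        ne = ne_transition(t, 1e4, 0.7, strong_dfe, 1e4)
        assert np.all(np.diff(ne) <= 1e-9)

    def test_unnormalized_literal_form(self, strong_dfe):
        # literal form converges to Nmax(1 - (1-B) * truncated mass)
        s_lo = truncation_bound(1e4, strong_dfe.h)
        P = strong_dfe.truncated_mass(s_lo, 1.0)
        ne = ne_transition(1e9, 1e4, 0.8, strong_dfe, 1e4, renormalize=False)
        assert ne == pytest.approx(1e4 * (1 - 0.2 * P), rel=1e-9)

    def test_transition_times_ordered_and_consistent(self, strong_dfe):
        t1, t2 = transition_times(strong_dfe, 1e4)
        assert 0 < t1 < t2
        # Ne at t1 is halfway between Nmax and B*Nmax
        ne = ne_transition(t1, 1e4, 0.8, strong_dfe, 1e4)
        assert ne == pytest.approx(1e4 - 0.5 * (1e4 - 8e3), rel=2e-3)


class TestIterateEpochBmap:
    def test_mu_zero_immediate(self, small_genome, strong_dfe):
        from dataclasses import replace
        _, _, genome = small_genome
        ebm = iterate_epoch_bmap(genome, replace(strong_dfe, mu=0.0),
                                 PiecewiseHistory((1e4,)))
        assert np.all(ebm.B == 1.0)

    def test_strong_selection_converges_fast(self, small_genome, strong_dfe):
        _, _, genome = small_genome
        ebm = iterate_epoch_bmap(genome, strong_dfe, PiecewiseHistory((1e4,)))
        assert ebm.n_iterations <= 3

    def test_equal_epochs_identical_bmaps(self, small_genome, strong_dfe):
        _, _, genome = small_genome
        ebm = iterate_epoch_bmap(genome, strong_dfe,
                                 PiecewiseHistory((1e4, 1e4), (5e3,)))
        np.testing.assert_allclose(ebm.B[:, 0], ebm.B[:, 1], rtol=1e-12)

    def test_to_frame_and_tsv(self, small_genome, strong_dfe, tmp_path):
        _, _, genome = small_genome
        ebm = iterate_epoch_bmap(genome, strong_dfe, PiecewiseHistory((1e4,)))
        df = ebm.to_frame(genome)
        assert set(df.columns) == {"chrom", "start", "end", "epoch", "Bb", "Bw", "B"}
        assert len(df) == len(genome)
        import pandas as pd
        p = tmp_path / "bmap.tsv"
        ebm.to_tsv(p, genome)
        back = pd.read_csv(p, sep="\t")
        np.testing.assert_allclose(back["B"].to_numpy(), df["B"].to_numpy())


def test_reduction_plot_helper(fig1_dfe):
    import matplotlib
    matplotlib.use("Agg")
    from bgsinfer.bgs_theory import plot_reduction_vs_r

    ax = plot_reduction_vs_r(fig1_dfe, 10_000.0, L=1e6)
    x, y = ax.lines[0].get_data()
    assert np.all(np.diff(y) <= 1e-12)  # reduction decays with distance
    assert 0 <= y[-1] < y[0] < 1
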