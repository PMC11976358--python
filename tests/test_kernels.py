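import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

import swarmlead as sl
from swarmlead.kernels import discretize_kernel

from conftest import (
    brute_force_alignment_m1,
    brute_force_alignment_m23,
    brute_force_attraction,
)


class TestDiscretizeKernel:
    def test_halfline_mass_dominates_for_standard_width(self):
        # with m = s/8 the analytic half-line mass is Phi(8), i.e. within
        # ~6e-16 of unity, comfortably above the 98% design constraint
        mass = sl.analytic_halfline_mass(1.0, 1.0 / 8.0)
        assert mass >= 0.98
        assert 1.0 - mass < 1e-14

    def test_discrete_mass_matches_erf_integral(self):
        g = sl.Grid(800, 40.0)  # dx = 0.05
        for s_i in (1.0, 0.5):
            m_i = s_i / 8.0
            *_, mass = discretize_kernel(s_i, m_i, g)
            analytic = 0.5 * (1.0 + erf(s_i / (np.sqrt(2.0) * m_i)))
            assert mass == pytest.approx(analytic, abs=1e-6)

    def test_weights_symmetric_about_center(self):
        g = sl.Grid(800, 40.0)
        offsets, weights, _ = discretize_kernel(1.0, 0.125, g)
        j_center = np.argmin(np.abs(offsets - 1.0))
        for d in range(1, 5):
            assert weights[j_center + d] == pytest.approx(
                weights[j_center - d], rel=1e-12
            )

    def test_reach_beyond_half_domain_rejected(self):
        g = sl.Grid(64, 4.0)
        with pytest.raises(ValueError, match="reach"):
            discretize_kernel(1.5, 1.5 / 8.0, g)


class TestOperatorOracle:
    """Vectorized nonlocal operators against direct double-loop quadrature."""

    def test_attraction_matches_brute_force(self, small_grid, default_params,
                                            random_state):
        k = sl.build_kernels(default_params, small_grid)
        got = sl.attraction_term(random_state.p, default_params, k, small_grid)
        want = brute_force_attraction(
            random_state.p, default_params, k, small_grid.n_cells
        )
        np.testing.assert_allclose(got[0], want[0], rtol=0, atol=1e-12)
        np.testing.assert_allclose(got[1], want[1], rtol=0, atol=1e-12)

    def test_alignment_m1_matches_brute_force(self, small_grid, random_state):
        p = sl.ModelParams(ql=1.3, alpha=2.5)
        k = sl.build_kernels(p, small_grid)
        s = random_state
        got = sl.alignment_follower_M1(s.u_plus, s.u_minus, s.v_plus, p, k, small_grid)
        want = brute_force_alignment_m1(
            s.u_plus, s.u_minus, s.v_plus, p, k, small_grid.n_cells
        )
        np.testing.assert_allclose(got[0], want[0], rtol=0, atol=1e-12)

    def test_alignment_m23_matches_brute_force(self, small_grid, random_state):
        p = sl.ModelParams(ql=0.8, alpha_plus=3.0, alpha_minus=0.5)
        k = sl.build_kernels(p, small_grid)
        s = random_state
        got = sl.alignment_follower_M23(
            s.u_plus, s.u_minus, s.v_plus, s.v_minus, p, k, small_grid
        )
        want = brute_force_alignment_m23(
            s.u_plus, s.u_minus, s.v_plus, s.v_minus, p, k, small_grid.n_cells
        )
        np.testing.assert_allclose(got[0], want[0], rtol=0, atol=1e-12)


class TestOperatorStructure:
    def test_uniform_density_gives_zero_attraction(self, small_grid, default_params):
        k = sl.build_kernels(default_params, small_grid)
        p_tot = np.full(small_grid.n_cells, 1.7)
        qa_p, qa_m = sl.attraction_term(p_tot, default_params, k, small_grid)
        np.testing.assert_allclose(qa_p, 0.0, atol=1e-14)
        np.testing.assert_allclose(qa_m, 0.0, atol=1e-14)

    def test_bump_ahead_discourages_turning(self, default_params):
        # density concentrated to the right of x makes a right-mover less
        # likely to turn: Qa+ < 0 there
        g = sl.Grid(64, 40.0)
        k = sl.build_kernels(default_params, g)
        p_tot = np.zeros(g.n_cells)
        i0 = 10
        p_tot[i0 + 2] = 5.0  # bump 1.25 units right, inside the sensing range
        qa_p, _ = sl.attraction_term(p_tot, default_params, k, g)
        assert qa_p[i0] < 0

    def test_antisymmetry_and_linearity(self, small_grid, rng):
        p = sl.ModelParams(qa=1.1, ql=0.9, alpha_plus=2.0, alpha_minus=0.3)
        k = sl.build_kernels(p, small_grid)
        fields = [rng.uniform(0, 1, small_grid.n_cells) for _ in range(4)]
        qa_p, qa_m = sl.attraction_term(sum(fields), p, k, small_grid)
        np.testing.assert_allclose(qa_p + qa_m, 0.0, atol=1e-14)
        ql_p, ql_m = sl.alignment_follower_M23(*fields, p, k, small_grid)
        np.testing.assert_allclose(ql_p + ql_m, 0.0, atol=1e-14)
        ql_p2, _ = sl.alignment_follower_M23(*[2 * f for f in fields], p, k, small_grid)
        np.testing.assert_allclose(ql_p2, 2 * ql_p, rtol=1e-13)

    def test_m1_leader_weight_is_linear(self, small_grid, rng):
        u_p = rng.uniform(0, 1, small_grid.n_cells)
        u_m = u_p.copy()  # cancel the follower part
        v_p = rng.uniform(0, 1, small_grid.n_cells)
        base = sl.ModelParams(ql=1.0, alpha=1.0)
        doubled = base.with_(alpha=2.0)
        k = sl.build_kernels(base, small_grid)
        q1, _ = sl.alignment_follower_M1(u_p, u_m, v_p, base, k, small_grid)
        q2, _ = sl.alignment_follower_M1(u_p, u_m, v_p, doubled, k, small_grid)
        np.testing.assert_allclose(q2, 2 * q1, rtol=1e-13)

    @settings(deadline=None, max_examples=15)
    @given(shift=st.integers(1, 63))
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(7)
        g = sl.Grid(64, 40.0)
        p = sl.ModelParams(qa=0.7, ql=1.1)
        k = sl.build_kernels(p, g)
        f = rng.uniform(0, 2, g.n_cells)
        qa = sl.attraction_term(f, p, k, g)[0]
        qa_shifted = sl.attraction_term(np.roll(f, shift), p, k, g)[0]
        np.testing.assert_allclose(qa_shifted, np.roll(qa, shift), atol=1e-13)

    def test_mirror_symmetry_of_alignment(self, small_grid, rng):
        # reflecting space, swapping orientations and conspicuousness
        # weights negates the (+) signal into the (-) one
        p = sl.ModelParams(ql=0.9, alpha_plus=2.0, alpha_minus=0.5)
        pm = p.with_(alpha_plus=0.5, alpha_minus=2.0)
        k = sl.build_kernels(p, small_grid)
        f = [rng.uniform(0, 1, small_grid.n_cells) for _ in range(4)]
        ql_p, ql_m = sl.alignment_follower_M23(*f, p, k, small_grid)
        R = lambda a: a[::-1]
        mirror = [R(f[1]), R(f[0]), R(f[3]), R(f[2])]
        ql_p_m, ql_m_m = sl.alignment_follower_M23(*mirror, pm, k, small_grid)
        np.testing.assert_allclose(ql_p_m, R(ql_m), atol=1e-13)
        np.testing.assert_allclose(ql_m_m, R(ql_p), atol=1e-13)


class TestLeaderAlignment:
    def test_m2_constant_bias_sign_and_value(self):
        # fine grid: the discrete kernel mass matches the erf integral there
        p = sl.ModelParams(ql=0.8, eta=2.5)
        k = sl.build_kernels(p, sl.Grid(800, 40.0))
        b_p, b_m = sl.alignment_leader_M2(p, k)
        assert b_p < 0 < b_m  # right-movers keep heading, left-movers turn
        analytic = 0.8 * 2.5 * sl.analytic_halfline_mass(p.sl, p.ml)
        assert -b_p == pytest.approx(analytic, abs=1e-6)

    def test_m2_bias_vanishes_without_cue(self, small_grid):
        p = sl.ModelParams(ql=0.8, eta=0.0)
        k = sl.build_kernels(p, small_grid)
        assert sl.alignment_leader_M2(p, k) == (0.0, 0.0)

    def test_m3_reduces_to_follower_form_without_cue(self, small_grid, rng):
        p = sl.ModelParams(ql=0.8, eta=0.0, alpha_plus=1.5, alpha_minus=0.5)
        k = sl.build_kernels(p, small_grid)
        f = [rng.uniform(0, 1, small_grid.n_cells) for _ in range(4)]
        lead = sl.alignment_leader_M3(*f, p, k, small_grid)
        foll = sl.alignment_follower_M23(*f, p, k, small_grid)
        np.testing.assert_array_equal(lead[0], foll[0])

    def test_m3_cue_is_a_uniform_offset(self, small_grid, rng):
        p0 = sl.ModelParams(ql=0.8, eta=0.0)
        p3 = p0.with_(eta=3.0)
        k = sl.build_kernels(p0, small_grid)
        f = [rng.uniform(0, 1, small_grid.n_cells) for _ in range(4)]
        base = sl.alignment_leader_M3(*f, p0, k, small_grid)
        biased = sl.alignment_leader_M3(*f, p3, k, small_grid)
        np.testing.assert_allclose(
            base[0] - biased[0], 0.8 * 3.0 * k.kappa_l, rtol=1e-12
        )
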