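import numpy as np
import pytest
from scipy.linalg import expm

import swarmlead as sl
from swarmlead.simulate import PopulationState, default_dt, step


def _gaussian_state(grid, M=5.0, x0=10.0, right_only=True):
    d = grid.wrap(grid.cell_centers - x0)
    pulse = M * np.exp(-0.5 * d**2)
    zero = np.zeros(grid.n_cells)
    if right_only:
        return PopulationState(pulse, zero.copy(), zero.copy(), zero.copy())
    return PopulationState(pulse / 2, pulse / 2, zero.copy(), zero.copy())


class TestStep:
    def test_pure_advection_is_exact_shift_at_unit_cfl(self):
        # with lambda1 = lambda2 = 0 and c*dt/dx = 1 the upwind scheme is
        # an exact one-cell shift per step
        g = sl.Grid(128, 40.0)
        p = sl.ModelParams(gamma=0.1, lambda1=0.0, lambda2=0.0, qa=0.0, ql=0.0)
        k = sl.build_kernels(p, g)
        state = _gaussian_state(g)
        dt = g.dx / p.gamma
        u0 = state.u_plus.copy()
        for n in range(10):
            state = step(state, p, k, g, dt, "M2")
        np.testing.assert_allclose(state.u_plus, np.roll(u0, 10), atol=1e-13)

    def test_advection_center_of_mass_speed(self):
        # mass-weighted mean of a non-wrapping pulse advances at gamma*t
        # exactly, independently of the CFL number
        g = sl.Grid(256, 40.0)
        p = sl.ModelParams(gamma=0.1, lambda1=0.0, lambda2=0.0, qa=0.0, ql=0.0)
        k = sl.build_kernels(p, g)
        state = _gaussian_state(g, x0=8.0)
        dt = 0.4 * g.dx / p.gamma
        n_steps = 50
        com0 = (state.u_plus * g.cell_centers).sum() / state.u_plus.sum()
        for _ in range(n_steps):
            state = step(state, p, k, g, dt, "M2")
        com1 = (state.u_plus * g.cell_centers).sum() / state.u_plus.sum()
        assert com1 - com0 == pytest.approx(p.gamma * n_steps * dt, rel=1e-10)

    def test_uniform_balanced_state_is_fixed_point(self):
        g = sl.Grid(64, 40.0)
        p = sl.ModelParams(qa=0.7, ql=0.9, eta=0.0)
        k = sl.build_kernels(p, g)
        state = PopulationState(*[np.full(g.n_cells, c) for c in (1.0, 1.0, 0.4, 0.4)])
        out = step(state, p, k, g, 0.1, "M3")
        for a, b in ((out.u_plus, 1.0), (out.u_minus, 1.0),
                     (out.v_plus, 0.4), (out.v_minus, 0.4)):
            np.testing.assert_allclose(a, b, rtol=1e-14)

    def test_turning_only_matches_linear_ode(self):
        # no transport, no interactions: each cell follows the exact 2x2
        # linear ODE with constant rate lam(0); the Euler error is O(dt)
        g = sl.Grid(8, 40.0)
        p = sl.ModelParams(gamma=1e-300, lambda1=0.3, lambda2=0.8, qa=0.0, ql=0.0)
        k = sl.build_kernels(p, g)
        lam = sl.turning_rate(0.0, p.lambda1, p.lambda2, p.y0)
        A = np.array([[-lam, lam], [lam, -lam]])
        rng = np.random.default_rng(1)
        u0 = rng.uniform(0.5, 2.0, (2, g.n_cells))
        t_end = 1.0
        errs = []
        for n_steps in (20, 40):
            dt = t_end / n_steps
            state = PopulationState(u0[0].copy(), u0[1].copy(),
                                    np.zeros(g.n_cells), np.zeros(g.n_cells))
            for _ in range(n_steps):
                state = step(state, p, k, g, dt, "M2")
            exact = expm(A * t_end) @ u0
            errs.append(np.abs(np.vstack([state.u_plus, state.u_minus]) - exact).max())
        assert errs[0] < 0.05
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.2)  # first order

    def test_cfl_violation_raises(self):
        g = sl.Grid(64, 40.0)
        p = sl.ModelParams(gamma=1.0)
        k = sl.build_kernels(p, g)
        with pytest.raises(ValueError, match="CFL"):
            step(_gaussian_state(g), p, k, g, 2.0 * g.dx, "M2")


class TestRuns:
    def test_mass_conservation_m2(self):
        g = sl.Grid(200, 40.0)
        p = sl.ModelParams(qa=0.5, ql=0.5, eta=2.0, beta_plus=0.3)
        fic = sl.InitialConditionSpec(M=5.0, x0=5.0, seed=1)
        lic = sl.InitialConditionSpec(M=5.0, x0=5.0, seed=2)
        r = sl.run_m2m3(p, fic, lic, sl.RunSpec(t_end=50.0, model="M2"), g)
        for species in ("u", "v"):
            m = r.mass_history(species)
            assert np.abs(m / m[0] - 1.0).max() < 1e-8

    def test_m1_leader_field_is_prescribed_not_evolved(self):
        g = sl.Grid(200, 40.0)
        p = sl.ModelParams(qa=0.5, ql=0.5, beta_plus=0.2)
        fic = sl.InitialConditionSpec(M=5.0, x0=6.5, seed=1)
        lic = sl.InitialConditionSpec(M=5.0, x0=6.5, amplitude=0.0, seed=2)
        r = sl.run_m1(p, fic, lic, sl.RunSpec(t_end=20.0, model="M1"), g)
        t_last = r.times[-1]
        vp, vm, center = sl.prescribed_leader_field(t_last, p, lic, g)
        np.testing.assert_array_equal(r.snapshots[-1].v_plus, vp)
        assert r.snapshots[-1].v_minus.max() == 0.0
        assert center == pytest.approx(6.5 + p.beta * t_last)
        assert r.leader_center_unwrapped[-1] == pytest.approx(center)

    def test_model_tag_mismatch_rejected(self):
        g = sl.Grid(64, 40.0)
        p = sl.ModelParams()
        ic = sl.InitialConditionSpec(M=1.0, x0=5.0, seed=0)
        with pytest.raises(ValueError):
            sl.run_m1(p, ic, ic, sl.RunSpec(t_end=1.0, model="M2"), g)
        with pytest.raises(ValueError):
            sl.run_m2m3(p, ic, ic, sl.RunSpec(t_end=1.0, model="M1"), g)

    def test_mirror_symmetry_of_trajectories(self):
        # reflecting space, swapping orientations, conspicuousness weights
        # and leader speeds, and negating the cue mirrors the trajectory
        g = sl.Grid(128, 40.0)
        p = sl.ModelParams(qa=0.6, ql=0.8, eta=1.2, alpha_plus=2.0,
                           alpha_minus=0.5, beta_plus=0.3, beta_minus=0.1)
        pm = p.with_(alpha_plus=0.5, alpha_minus=2.0, beta_plus=0.1,
                     beta_minus=0.3, eta=-1.2)
        rng = np.random.default_rng(4)
        f = [rng.uniform(0.2, 1.5, g.n_cells) for _ in range(4)]
        R = lambda a: a[::-1].copy()
        s = PopulationState(*[a.copy() for a in f])
        sm = PopulationState(R(f[1]), R(f[0]), R(f[3]), R(f[2]))
        spec = sl.RunSpec(t_end=10.0, model="M3", snapshot_every=1000)
        r = sl.run_m2m3(p, None, None, spec, g, initial_state=s)
        rm = sl.run_m2m3(pm, None, None, spec, g, initial_state=sm)
        a, b = r.snapshots[-1], rm.snapshots[-1]
        np.testing.assert_allclose(b.u_plus, R(a.u_minus), atol=1e-12)
        np.testing.assert_allclose(b.u_minus, R(a.u_plus), atol=1e-12)
        np.testing.assert_allclose(b.v_plus, R(a.v_minus), atol=1e-12)
        np.testing.assert_allclose(b.v_minus, R(a.v_plus), atol=1e-12)

    def test_reduces_to_single_population_model(self):
        # with no leaders the follower equations are the classic
        # single-population attraction/alignment model; compare against an
        # independently coded scalar stepper
        g = sl.Grid(100, 40.0)
        p = sl.ModelParams(qa=0.8, ql=1.1, eta=5.0)  # eta irrelevant: v = 0
        k = sl.build_kernels(p, g)
        rng = np.random.default_rng(9)
        u_p = rng.uniform(0.5, 2.0, g.n_cells)
        u_m = rng.uniform(0.5, 2.0, g.n_cells)
        zero = np.zeros(g.n_cells)
        state = PopulationState(u_p.copy(), u_m.copy(), zero.copy(), zero.copy())
        dt = default_dt(p, g, "M2")

        ref_p, ref_m = u_p.copy(), u_m.copy()
        n_steps = 25
        for _ in range(n_steps):
            state = step(state, p, k, g, dt, "M2")
            # reference single-population update
            total = ref_p + ref_m
            right = k.weights_a @ total[k.idx_a_p]
            left = k.weights_a @ total[k.idx_a_m]
            qa_plus = -p.qa * (right - left)
            both = lambda f: (k.weights_l @ f[k.idx_l_p] + k.weights_l @ f[k.idx_l_m])
            ql_plus = p.ql * (both(ref_m) - both(ref_p))
            lam_p = sl.turning_rate(qa_plus + ql_plus, p.lambda1, p.lambda2, p.y0)
            lam_m = sl.turning_rate(-qa_plus - ql_plus, p.lambda1, p.lambda2, p.y0)
            exch = -lam_p * ref_p + lam_m * ref_m
            new_p = ref_p - (p.gamma * dt / g.dx) * (ref_p - np.roll(ref_p, 1)) + dt * exch
            new_m = ref_m + (p.gamma * dt / g.dx) * (np.roll(ref_m, -1) - ref_m) - dt * exch
            ref_p, ref_m = new_p, new_m

        np.testing.assert_allclose(state.u_plus, ref_p, atol=1e-13)
        np.testing.assert_allclose(state.u_minus, ref_m, atol=1e-13)
        assert state.v_plus.max() == 0.0
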