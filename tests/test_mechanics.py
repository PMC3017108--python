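"""Cell-cell potentials, volumes, force consistency, overdamped motion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from cryptsim import fate as fate_mod
from cryptsim import make_fixture
from cryptsim.mechanics import (
    Forces,
    actual_volume,
    adhesion_energy,
    compression_energy,
    contact_area,
    evaluate_forces,
    hertz_energy,
    solve_motion,
    sphere_cap_volume,
    total_energy,
)
from cryptsim.params import ModelParams

radii_st = st.floats(min_value=2.0, max_value=8.0)


class TestContactArea:
    def test_tangent_spheres_have_zero_area(self):
        assert contact_area(5.0, 4.0, 9.0) == 0.0

    def test_equal_spheres_intersection_disc(self):
        """Exact geometry: disc radius² = R² - (d/2)² for equal spheres."""
        R, d = 5.0, 5.0
        assert contact_area(R, R, d) == pytest.approx(math.pi * (R**2 - (d / 2) ** 2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(radii_st, radii_st, st.floats(min_value=0.3, max_value=0.99))
    def test_symmetric_positive_continuous(self, r_i, r_j, frac):
        d = frac * (r_i + r_j)
        if d <= abs(r_i - r_j):
            return
        a_ij = contact_area(r_i, r_j, d)
        a_ji = contact_area(r_j, r_i, d)
        assert a_ij == pytest.approx(a_ji, rel=1e-12)
        assert a_ij >= 0.0

    def test_concentric_raises(self):
        with pytest.raises(ValueError):
            contact_area(5.0, 5.0, 0.0)


class TestEnergies:
    def test_adhesion_basics(self):
        assert adhesion_energy(0.0, 0.2) == 0.0
        assert adhesion_energy(20.0, 0.2) == pytest.approx(2 * adhesion_energy(10.0, 0.2))
        assert adhesion_energy(10.0, 0.2) < 0  # adhesion lowers the energy

    def test_adhesion_unit_arithmetic(self):
        """200 µN/m over a 10 µm² contact is 2e-15 N·m = 2 nN·µm."""
        eps_c = ModelParams().mech.eps_c   # 200 µN/m in internal units
        w_internal = abs(adhesion_energy(10.0, eps_c))      # nN·µm
        assert w_internal * 1e-15 == pytest.approx(2e-15)   # N·m

    def test_hertz_zero_at_tangency_and_monotone(self):
        assert hertz_energy(5.0, 5.0, 10.0, 1.0, 1 / 3) == 0.0
        assert hertz_energy(5.0, 5.0, 11.0, 1.0, 1 / 3) == 0.0
        e = [hertz_energy(5.0, 5.0, 10.0 - x, 1.0, 1 / 3) for x in (0.5, 1.0, 1.5)]
        assert e[0] < e[1] < e[2]

    def test_hertz_linear_in_modulus(self):
        w1 = hertz_energy(5.0, 6.0, 9.0, 1.0, 1 / 3)
        w2 = hertz_energy(5.0, 6.0, 9.0, 2.0, 1 / 3)
        assert w2 == pytest.approx(2 * w1)

    def test_hertz_force_matches_finite_difference(self):
        h = 1e-7
        for d in (8.0, 9.0, 10.5):
            fd = -(hertz_energy(5.0, 6.0, d + h, 1.0, 1 / 3)
                   - hertz_energy(5.0, 6.0, d - h, 1.0, 1 / 3)) / (2 * h)
            delta = 11.0 - d
            e_star = 1.0 / (2 * (1 - (1 / 3) ** 2))
            r_eff = 30.0 / 11.0
            analytic = (8.0 / 15.0) * e_star * math.sqrt(r_eff) * 2.5 * delta**1.5
            assert fd == pytest.approx(analytic, rel=1e-5)

    def test_compression_symmetric_and_zero_at_target(self):
        vt = 500.0
        assert compression_energy(vt, vt, 5.0) == 0.0
        assert compression_energy(vt, 0.9 * vt, 5.0) == pytest.approx(
            compression_energy(vt, 1.1 * vt, 5.0)
        )
        e = [compression_energy(vt, vt * (1 - x), 5.0) for x in (0.05, 0.1, 0.2)]
        assert e[0] < e[1] < e[2]

    def test_compression_domain_errors(self):
        with pytest.raises(ValueError):
            compression_energy(0.0, 100.0, 5.0)
        with pytest.raises(ValueError):
            compression_energy(500.0, -1.0, 5.0)


class TestActualVolume:
    def test_isolated_cell(self):
        R = 5.0
        assert actual_volume(R) == pytest.approx(4 / 3 * math.pi * R**3)

    def test_zero_overlap_neighbour(self):
        R = 5.0
        assert actual_volume(R, [(5.0, 10.0)]) == pytest.approx(
            4 / 3 * math.pi * R**3
        )

    def test_monte_carlo_oracle_two_neighbours(self, rng):
        """Sphere clipped at both contact planes vs MC integration.

        Each contact flattens the cell at the radical plane of the two
        spheres; the cell keeps its own side of the plane.
        """
        R, Rn, d = 5.0, 5.0, 8.0
        analytic = actual_volume(R, [(Rn, d), (Rn, d)])
        x_plane = 0.5 * d + (R**2 - Rn**2) / (2 * d)
        n = 2_000_000
        pts = rng.uniform(-R, R, (n, 3))
        inside = np.einsum("ij,ij->i", pts, pts) < R**2
        kept = inside & (pts[:, 0] < x_plane) & (pts[:, 0] > -x_plane)
        mc = kept.mean() * (2 * R) ** 3
        assert analytic == pytest.approx(mc, rel=0.005)

    def test_cap_volume_closed_form(self):
        # full sphere when the cap height reaches the diameter
        R = 3.0
        assert sphere_cap_volume(R, 2 * R) == pytest.approx(4 / 3 * math.pi * R**3)
        assert sphere_cap_volume(R, 0.0) == 0.0


class TestForceConsistency:
    def test_forces_are_exact_energy_gradients(self, mini_state):
        """Central-difference check of all position and radius gradients."""
        p = mini_state.params
        c = mini_state.cells
        sel = np.arange(0, len(c), max(1, len(c) // 6))[:6]
        eps = fate_mod.eps_knot_per_cell(c.state, p)
        res = evaluate_forces(c.pos, c.radius, c.v_target, eps,
                              np.zeros(len(c)), mini_state.net, p)

        def energy(pos, rad):
            return total_energy(pos, rad, c.v_target, eps, mini_state.net, p)

        h = 1e-6
        for i in sel:
            for a in range(3):
                pp, pm = c.pos.copy(), c.pos.copy()
                pp[i, a] += h
                pm[i, a] -= h
                fd = -(energy(pp, c.radius) - energy(pm, c.radius)) / (2 * h)
                assert res.force[i, a] == pytest.approx(fd, rel=1e-4, abs=1e-4)
            rp, rm = c.radius.copy(), c.radius.copy()
            rp[i] += h
            rm[i] -= h
            fd = -(energy(c.pos, rp) - energy(c.pos, rm)) / (2 * h)
            assert res.radius_force[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_newtons_third_law_two_cells(self):
        state = make_fixture("two_cell", seed=0)
        c = state.cells
        c.pos[1] = c.pos[0] + np.array([8.5, 0, 0])  # overlapping pair
        res = evaluate_forces(c.pos, c.radius, c.v_target,
                              np.zeros(2), np.zeros(2), state.net, state.params)
        assert np.allclose(res.force[0], -res.force[1], atol=1e-10)

    def test_isolated_cell_without_bm_feels_nothing(self):
        state = make_fixture("two_cell", seed=0)
        c = state.cells
        c.pos[1] = c.pos[0] + np.array([50.0, 0, 0])
        res = evaluate_forces(c.pos, c.radius, c.v_target,
                              np.zeros(2), np.full(2, 4.5), state.net, state.params)
        # no BM contact: no migration force is applied either
        assert np.allclose(res.force, 0.0, atol=1e-12)
        assert not res.bm_contact.any()


class TestMotion:
    def test_single_cell_overdamped_limit(self):
        """v = F / eta_BM for a lone cell under a constant force."""
        p = ModelParams()
        res = Forces(
            force=np.array([[3.0, 0.0, 0.0]]),
            radius_force=np.zeros(1),
            v_actual=np.array([p.v0]),
            pairs=np.empty((0, 2), np.int64),
            pair_area=np.zeros(0),
            n_knots=np.array([1]),
            knot_jacobian=np.zeros((1, 3, 3)),
            radius_stiffness=np.zeros(1),
            bm_contact=np.array([True]),
            zeta=np.zeros(1),
            theta=np.zeros(1),
            energy=0.0,
        )
        vel, drad = solve_motion(res, np.array([5.0]), 0.05, p)
        assert vel[0, 0] == pytest.approx(3.0 / p.mech.eta_bm, rel=1e-12)
        assert drad[0] == 0.0

    def test_pair_momentum_conservation(self):
        """Internal forces displace the pair centre of mass by nothing."""
        state = make_fixture("two_cell", seed=0)
        c = state.cells
        c.pos[1] = c.pos[0] + np.array([8.0, 0, 0])
        res = evaluate_forces(c.pos, c.radius, c.v_target,
                              np.zeros(2), np.zeros(2), state.net, state.params)
        vel, _ = solve_motion(res, c.radius, 0.05, state.params)
        assert np.allclose(vel[0] + vel[1], 0.0, atol=1e-10)

    def test_two_body_relaxation_matches_ode_oracle(self):
        """Euler stepping agrees with dense RK45 integration of the same system."""
        state = make_fixture("two_cell", seed=0)
        p = state.params
        c = state.cells
        c.pos[1] = c.pos[0] + np.array([8.0, 0, 0])
        y0 = np.concatenate([c.pos.ravel(), c.radius])

        def rhs(t, y):
            pos = y[:6].reshape(2, 3)
            rad = y[6:8]
            res = evaluate_forces(pos, rad, c.v_target, np.zeros(2),
                                  np.zeros(2), state.net, p)
            vel, drad = solve_motion(res, rad, 0.0, p)  # dt=0: pure friction
            return np.concatenate([vel.ravel(), drad])

        sol = solve_ivp(rhs, (0.0, 2.0), y0, rtol=1e-8, atol=1e-10,
                        dense_output=True)
        pos, rad = c.pos.copy(), c.radius.copy()
        dt = 0.01
        for _ in range(200):
            res = evaluate_forces(pos, rad, c.v_target, np.zeros(2),
                                  np.zeros(2), state.net, p)
            vel, drad = solve_motion(res, rad, dt, p)
            pos = pos + vel * dt
            rad = rad + drad * dt
        ref = sol.y[:, -1]
        d_euler = np.linalg.norm(pos[0] - pos[1])
        d_ode = np.linalg.norm(ref[:3] - ref[3:6])
        assert d_euler == pytest.approx(d_ode, rel=0.02)
        # relaxation moves the pair toward lower energy monotonically
        assert d_ode > 8.0  # compressed pair pushes apart

    def test_energy_non_increasing_without_migration(self, mini_state):
        state = mini_state
        p = state.params
        pos = state.cells.pos.copy()
        rad = state.cells.radius.copy()
        vt = state.cells.v_target.copy()
        eps = fate_mod.eps_knot_per_cell(state.cells.state, p)
        energies = [total_energy(pos, rad, vt, eps, state.net, p)]
        for _ in range(15):
            res = evaluate_forces(pos, rad, vt, eps, np.zeros(len(pos)),
                                  state.net, p)
            vel, drad = solve_motion(res, rad, p.engine.dt_max, p)
            scale = min(1.0, 0.5 / max(np.linalg.norm(vel, axis=1).max() * 0.05, 1e-9))
            pos = pos + vel * p.engine.dt_max * scale
            rad = rad + drad * p.engine.dt_max * scale
            energies.append(total_energy(pos, rad, vt, eps, state.net, p))
        diffs = np.diff(energies)
        assert np.all(diffs <= np.abs(np.array(energies[:-1])) * 1e-6 + 1e-6)
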