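"""Contact geometry, energies, analytic forces, velocity solve."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import podosim as ps
from podosim.mechanics import (actual_volume, body_forces, cell_cell_contact,
                               cell_substrate_contact, equilibrium_heights,
                               solve_velocities, total_energy)
from podosim.state import SimulationState

from conftest import make_test_cell


class TestCellCellContact:
    def test_tangency_zero(self, params):
        a = make_test_cell(params, (0, 0), cell_id=1)
        b = make_test_cell(params, (2 * params.r0, 0), cell_id=2)
        g = cell_cell_contact(a, b)
        assert g.delta == 0.0 and g.A == 0.0

    def test_equal_radii_symmetric_caps(self, params):
        R = params.r0
        delta = 1.2
        a = make_test_cell(params, (0, 0), cell_id=1)
        b = make_test_cell(params, (2 * R - delta, 0), cell_id=2)
        g = cell_cell_contact(a, b)
        assert g.h_i == pytest.approx(delta / 2)
        assert g.h_j == pytest.approx(delta / 2)
        assert g.h_i + g.h_j == pytest.approx(g.delta)

    def test_unequal_radii_vs_numeric_root(self, params):
        """r_contact equals the sphere-sphere intersection circle found by
        numeric root-finding on the two sphere equations."""
        Ri, Rj, d = 5.0, 4.0, 8.0
        a = make_test_cell(params, (0, 0), R=Ri, height=2.0, cell_id=1)
        b = make_test_cell(params, (d, 0), R=Rj, height=2.0, cell_id=2)
        g = cell_cell_contact(a, b)
        x = brentq(lambda x: (Ri**2 - x**2) - (Rj**2 - (d - x)**2), 0, d)
        r_num = math.sqrt(Ri**2 - x**2)
        assert g.r_contact == pytest.approx(r_num, rel=1e-12)
        assert g.A == pytest.approx(math.pi * r_num**2, rel=1e-12)

    def test_coincident_centres_error(self, params):
        a = make_test_cell(params, (0, 0), cell_id=1)
        b = make_test_cell(params, (0, 0), cell_id=2)
        with pytest.raises(ValueError):
            cell_cell_contact(a, b)


class TestSubstrateContact:
    def test_no_contact_at_full_height(self, params):
        c = make_test_cell(params, height=params.r0)
        assert cell_substrate_contact(c, params.r0).A == 0.0

    def test_hemisphere(self, params):
        c = make_test_cell(params, height=params.r0 / 2)
        g = cell_substrate_contact(c, 0.0)
        assert g.a_is == pytest.approx(c.R)

    def test_closed_form(self, params):
        c = make_test_cell(params, height=4.0)
        g = cell_substrate_contact(c, 4.0)
        assert g.a_is == pytest.approx(math.sqrt(4.75**2 - 16.0))


class TestActualVolume:
    def test_no_contacts_full_sphere(self, params):
        c = make_test_cell(params, height=params.r0)
        assert actual_volume(c, []) == pytest.approx(
            4 / 3 * math.pi * c.R**3)

    def test_hemisphere_cap(self, params):
        c = make_test_cell(params, height=params.r0)
        v = actual_volume(c, [c.R])
        assert v == pytest.approx(2 / 3 * math.pi * c.R**3)

    def test_monte_carlo_oracle(self, params):
        """Two caps h=1 on an R=5 sphere vs MC volume integration."""
        R, h = 5.0, 1.0
        c = make_test_cell(params, R=R, height=R)
        v = actual_volume(c, [h, h])
        rng = np.random.default_rng(7)
        pts = rng.uniform(-R, R, size=(400000, 3))
        inside = (pts**2).sum(axis=1) <= R * R
        # caps cut off at z > R - h and z < -(R - h)
        kept = inside & (np.abs(pts[:, 2]) <= R - h)
        v_mc = kept.mean() * (2 * R)**3
        assert v == pytest.approx(v_mc, rel=5e-3)


class TestForces:
    def _random_state(self, params, rng, n=4):
        """Moderately overlapping chains with overlaps away from tangency
        (the adhesion force, like JKR contact, switches on discontinuously
        at contact, so finite differences are taken in the smooth regime).
        """
        while True:
            radii = rng.uniform(4.3, 5.5, n)
            pos = [np.zeros(2)]
            for i in range(1, n):
                j = int(rng.integers(0, len(pos)))
                ang = rng.uniform(0, 2 * np.pi)
                d = (radii[i] + radii[j]) - rng.uniform(0.5, 2.5)
                pos.append(pos[j] + d * np.array([np.cos(ang), np.sin(ang)]))
            # every pair clearly away from tangency and from containment
            def pair_ok(i, k):
                d = np.hypot(*(pos[i] - pos[k]))
                return (abs(d - (radii[i] + radii[k])) > 0.3
                        and d > abs(radii[i] - radii[k]) + 0.5)

            if all(pair_ok(i, k) for i in range(n) for k in range(i)):
                break
        cells = []
        for i, p in enumerate(pos):
            R = radii[i]
            z = rng.uniform(0.55, 0.85) * R
            cells.append(make_test_cell(
                params, p, R=R, height=z, cell_id=i + 1,
                v_target=rng.uniform(0.9, 1.1) * 4 / 3 * math.pi * R**3))
        return SimulationState.from_cells(params, cells)

    def test_pure_repulsion_points_apart(self, params):
        p0 = params.replace(eps_cc=1e-12)
        a = make_test_cell(p0, (0, 0), cell_id=1)
        b = make_test_cell(p0, (8.0, 0), cell_id=2)
        st = SimulationState.from_cells(p0, [a, b])
        F, _, _ = body_forces(st)
        assert F[0, 0] < 0 < F[1, 0]

    def test_action_reaction(self, params, rng):
        st = self._random_state(params, rng)
        F, _, _ = body_forces(st)
        # substrate exerts no planar force: total planar force vanishes
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-9)

    def test_gradient_consistency_100_random_configurations(self, params):
        """Analytic forces vs central differences, 1e-5 relative."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(25):
            st = self._random_state(params, rng)
            F, FR, _ = body_forces(st)
            eps = 1e-6
            for i in range(st.n):
                for arr, an in ((st.x, F[i, 0]), (st.y, F[i, 1]),
                                (st.R, FR[i])):
                    o = arr[i]
                    arr[i] = o + eps
                    ep = total_energy(st)
                    arr[i] = o - eps
                    em = total_energy(st)
                    arr[i] = o
                    fd = -(ep - em) / (2 * eps)
                    assert an == pytest.approx(
                        fd, rel=1e-5, abs=2e-4), (i, an, fd)
                checked += 1
        assert checked >= 100

    def test_hertz_force_from_energy_derivative(self, params):
        """dE_D/d(delta) equals the Hertz force (4/3) E* sqrt(R_eff) d^1.5."""
        estar = params.e_star_cc()
        reff = 2.4
        delta = 0.5
        e = lambda d: (8 / 15) * estar * math.sqrt(reff) * d**2.5
        h = 1e-7
        fd = (e(delta + h) - e(delta - h)) / (2 * h)
        analytic = (4 / 3) * estar * math.sqrt(reff) * delta**1.5
        assert fd == pytest.approx(analytic, rel=1e-6)

    def test_equilibrium_spacing_stable_fixed_point(self, params):
        """Adhesion attracts at small overlap, Hertz repels at large."""
        def radial_force(d):
            a = make_test_cell(params, (0, 0), cell_id=1)
            b = make_test_cell(params, (d, 0), cell_id=2)
            st = SimulationState.from_cells(params, [a, b])
            F, _, _ = body_forces(st)
            return F[0, 0]  # force on the left cell; >0 means attraction

        R2 = 2 * params.r0
        assert radial_force(R2 - 0.2) > 0      # small overlap: approach
        assert radial_force(R2 - 4.5) < 0      # deep overlap: separate
        # a sign change in between: stable equilibrium spacing
        ds = np.linspace(R2 - 4.5, R2 - 0.2, 40)
        signs = np.sign([radial_force(d) for d in ds])
        assert (np.diff(signs) != 0).any()


class TestVelocitySolve:
    def test_single_cell_no_forces(self, params):
        st = SimulationState.from_cells(params, [make_test_cell(params)])
        F, FR, cache = body_forces(st)
        v, vR = solve_velocities(st, np.zeros((1, 2)), np.zeros(1), cache)
        np.testing.assert_allclose(v, 0.0)
        np.testing.assert_allclose(vR, 0.0)

    def test_single_podium_scalar_balance(self, params):
        st = SimulationState.from_cells(params, [make_test_cell(params)])
        _, _, cache = body_forces(st)
        traction = np.array([[1.5, 0.0]])
        v, _ = solve_velocities(st, np.zeros((1, 2)), np.zeros(1), cache,
                                traction)
        gamma_b = params.gamma_cs * math.pi * cache["a2"][0] + params.gamma_v
        assert v[0, 0] == pytest.approx(1.5 / gamma_b, rel=1e-9)

    def test_chain_matches_dense_direct_solve(self, params, rng):
        """5-cell overlapping chain: CG solution vs dense numpy solve."""
        cells = [make_test_cell(params, (8.0 * i, 0), cell_id=i + 1)
                 for i in range(5)]
        st = SimulationState.from_cells(params, cells)
        F = rng.normal(0, 2, (5, 2))
        _, _, cache = body_forces(st)
        v, _ = solve_velocities(st, F, np.zeros(5), cache)
        # dense assembly
        n = 5
        M = np.zeros((n, n))
        diag = params.gamma_cs * np.pi * cache["a2"] + params.gamma_v
        M[np.arange(n), np.arange(n)] = diag
        for k in range(cache["ii"].size):
            i, j = cache["ii"][k], cache["jj"][k]
            aij = np.pi * cache["rc2"][k]
            M[i, i] += params.gamma_cc * aij
            M[j, j] += params.gamma_cc * aij
            M[i, j] -= params.gamma_cc * aij
            M[j, i] -= params.gamma_cc * aij
        v_direct = np.linalg.solve(M, F)
        np.testing.assert_allclose(v, v_direct, rtol=1e-7, atol=1e-10)

    def test_momentum_balance(self, params, rng):
        """Sum of drag forces equals sum of applied forces."""
        cells = [make_test_cell(params, (8.0 * i, 0.5 * i), cell_id=i + 1)
                 for i in range(4)]
        st = SimulationState.from_cells(params, cells)
        F = rng.normal(0, 1, (4, 2))
        _, _, cache = body_forces(st)
        v, _ = solve_velocities(st, F, np.zeros(4), cache)
        diag = params.gamma_cs * np.pi * cache["a2"] + params.gamma_v
        drag = (diag[:, None] * v).sum(axis=0)  # pair friction cancels
        np.testing.assert_allclose(drag, F.sum(axis=0), rtol=1e-6)


class TestEquilibriumHeight:
    def test_balance_is_a_root_of_the_normal_gradient(self, params):
        R = np.array([params.r0])
        vt = np.array([params.v0])
        z = equilibrium_heights(params, R, vt, np.array([0.0]))
        assert 0 < z[0] < R[0]
        # numeric derivative of the 1-cell energy wrt height vanishes
        c = make_test_cell(params, height=float(z[0]))
        st = SimulationState.from_cells(params, [c])

        def energy_at(zz):
            st.z[0] = zz
            return total_energy(st)

        h = 1e-4
        grad = (energy_at(float(z[0]) + h) - energy_at(float(z[0]) - h)) / (2 * h)
        assert abs(grad) < 2e-2
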