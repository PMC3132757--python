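"""Podium life cycle: generation, angles, inactivation, tips, closed forms."""

import math

import numpy as np
import pytest

from podosim.podia import (eliminate_retracted, generation_probability,
                           lambda_inactivation_probability,
                           maybe_generate_podium, maybe_inactivate_podia,
                           sample_podium_angle, single_cell_equilibrium,
                           step_podium_tips)
from podosim.state import Podium, RegulatedValues

from conftest import make_test_cell


class TestGenerationProbability:
    def test_saturated_above_offset(self):
        assert generation_probability(4, 2.5) == 0.0

    def test_deficit_scaling(self, params):
        # acceptance scales linearly with the half-shifted podium deficit
        # and vanishes at the regime count (no churn for resting spindles)
        assert generation_probability(3, 3.5, params.gen_accept_scale) == 0.0
        assert generation_probability(2, 2.5, params.gen_accept_scale) == 0.0
        p1 = generation_probability(2, 3.5, params.gen_accept_scale)
        p2 = generation_probability(0, 3.5, params.gen_accept_scale)
        assert 0 < p1 < p2 <= 1.0
        assert p2 == pytest.approx(p1 * 3.0 / 1.0)

    def test_lambda_inactivation_clamp(self):
        assert lambda_inactivation_probability(4, 3.5) == 0.5
        assert lambda_inactivation_probability(3, 3.5) == 0.0
        assert lambda_inactivation_probability(6, 2.5) == 1.0

    def test_or_saturation(self, params, rng):
        """P_lambda = 1 makes inactivation certain regardless of r_ind."""
        cell = make_test_cell(params, podia=[(0.0, 10.0)] * 6)
        cell.reg = RegulatedValues(0.0, 0.0, 2.5)  # r_ind = 0
        # n_act - n_off = 3.5 -> P_lambda = 1 whenever the event fires
        for _ in range(50):
            maybe_inactivate_podia(cell, params, params.dt, rng)
            if not any(p.active for p in cell.podia):
                break
        assert not any(p.active for p in cell.podia)

    def test_no_inactivation_without_channels(self, params, rng):
        cell = make_test_cell(params, podia=[(0.0, 10.0), (2.0, 10.0)])
        cell.reg = RegulatedValues(0.0, 0.0, 3.5)  # r_ind = 0, below offset
        for _ in range(2000):
            maybe_inactivate_podia(cell, params, params.dt, rng)
        assert all(p.active for p in cell.podia)

    def test_exponential_survival_under_r_ind(self, params, rng):
        """r_ind = 2/d gives exponential podium survival, mean 0.5 d."""
        r_ind = 2.0 / 1440.0
        n = 4000
        p_r = -math.expm1(-r_ind * params.dt)
        draws = rng.random((n, 6000))
        hit = (draws < p_r)
        has = hit.any(axis=1)
        lifetimes = hit.argmax(axis=1)[has] + 1  # steps to inactivation
        mean_days = lifetimes.mean() * params.dt / 1440.0
        assert mean_days == pytest.approx(0.5, rel=0.05)


class TestAngleSampler:
    def test_uniform_with_no_podia(self, params, rng):
        angs = [sample_podium_angle([], params, rng) for _ in range(2000)]
        hist, _ = np.histogram(angs, bins=8, range=(0, 2 * math.pi))
        assert hist.min() > 150  # roughly uniform

    def test_zero_distance_always_rejected(self, params):
        from podosim.podia import _rejection_probability

        assert _rejection_probability(1.0, np.array([1.0]), params.c_a) == 1.0

    def test_outgrowth_mode_near_70_degrees(self, params, rng):
        """With two existing podia the nearest-angle histogram peaks near
        the experimentally observed 70 degrees."""
        n = 20000
        out = np.empty(n)
        for i in range(n):
            t0 = rng.uniform(0, 2 * math.pi)
            th = np.array([t0, t0 + rng.uniform(0, 2 * math.pi)])
            a = sample_podium_angle(th, params, rng)
            out[i] = np.min(np.abs(np.angle(np.exp(1j * (th - a)))))
        hist, edges = np.histogram(np.degrees(out), bins=np.arange(0, 185, 5))
        mode = edges[np.argmax(hist)] + 2.5
        assert 55.0 <= mode <= 85.0

    def test_generated_length_half_adhesion_radius(self, params, rng):
        cell = make_test_cell(params)
        cell.reg = RegulatedValues(0.0, 0.0, 3.5)
        for _ in range(3000):
            maybe_generate_podium(cell, params, params.dt, rng)
            if cell.podia:
                break
        assert cell.podia
        assert cell.podia[0].length == pytest.approx(cell.adhesion_radius / 2)

    def test_no_generation_in_phase_3(self, params, rng):
        cell = make_test_cell(params, phase=3)
        cell.reg = RegulatedValues(0.0, 0.0, 3.5)
        for _ in range(500):
            maybe_generate_podium(cell, params, params.dt, rng)
        assert not cell.podia


class TestTipDynamics:
    def test_steady_state_tip(self, params):
        cell = make_test_cell(params, podia=[(0.0, params.l_max)])
        step_podium_tips(cell, params, params.dt)
        assert cell.podia[0].length == pytest.approx(params.l_max)

    def test_elongation_matches_closed_form(self, params):
        """L(t) = (F_p/k)(1 - exp(-k t / gamma_p)) at dt = 0.01 min."""
        dt = 0.01
        cell = make_test_cell(params, podia=[(0.0, 0.0)])
        tau = params.gamma_p / params.k_spring
        t_end = tau
        n = int(round(t_end / dt))
        for _ in range(n):
            step_podium_tips(cell, params, dt)
        expected = params.l_max * (1.0 - math.exp(-(n * dt) / tau))
        assert cell.podia[0].length == pytest.approx(expected, rel=1e-6)

    def test_table_ratios(self, params):
        assert params.l_max == pytest.approx(25.0)
        assert params.tip_speed_max == pytest.approx(2.5 / (0.07 * 1e3 / 60))

    def test_tip_speed_decreases_with_length(self, params):
        """Maximum podium speed occurs directly after generation."""
        speeds = []
        for L in (0.0, 5.0, 15.0, 24.0):
            cell = make_test_cell(params, podia=[(0.0, L)])
            step_podium_tips(cell, params, params.dt)
            speeds.append((cell.podia[0].length - L) / params.dt)
        assert all(a > b for a, b in zip(speeds, speeds[1:]))

    def test_retraction_and_elimination(self, params):
        a = None
        cell = make_test_cell(params, podia=[Podium(0.0, 10.0, active=False)])
        a = cell.adhesion_radius
        # inactive long podium persists until below the adhesion radius
        eliminate_retracted(cell)
        assert len(cell.podia) == 1
        cell.podia[0].length = a / 2
        eliminate_retracted(cell)
        assert len(cell.podia) == 0
        # active podia are never eliminated
        cell.podia = [Podium(0.0, 0.1, active=True)]
        eliminate_retracted(cell)
        assert len(cell.podia) == 1


class TestSingleCellEquilibrium:
    def test_free_tip_limit(self, params):
        p0 = params.replace(gamma_cs=1e-12, gamma_v=1e-12)
        v, (L,) = single_cell_equilibrium(p0, 1, 0)
        assert v == pytest.approx(params.tip_speed_max, rel=1e-6)
        assert L == pytest.approx(0.0, abs=1e-6)

    def test_pinned_body_limit(self, params):
        p0 = params.replace(gamma_v=1e9)
        v, (L,) = single_cell_equilibrium(p0, 1, 0)
        assert v == pytest.approx(0.0, abs=1e-6)
        assert L == pytest.approx(25.0, rel=1e-6)

    def test_trailing_podium_slows_the_cell(self, params):
        v1, _ = single_cell_equilibrium(params, 1, 0)
        v2, (la, lt) = single_cell_equilibrium(params, 1, 1)
        assert v2 < v1
        assert lt < la

    def test_unsupported_configuration(self, params):
        with pytest.raises(ValueError):
            single_cell_equilibrium(params, 2, 0)

    def test_simulation_converges_to_closed_form(self, params):
        """Euler integration of the coupled tip/centre system reaches the
        closed-form speed and length within 0.5%."""
        import numpy as np
        from podosim.mechanics import equilibrium_heights

        z = float(equilibrium_heights(params, np.array([params.r0]),
                                      np.array([params.v0]),
                                      np.array([0.0]))[0])
        a2 = params.r0**2 - z**2
        gamma_b = params.gamma_cs * math.pi * a2 + params.gamma_v
        dt = 0.01
        x = 0.0          # body position
        tip = a2**0.5 / 2  # tip position: base offset, zero length
        base_off = a2**0.5 / 2
        t_end = 10 * params.gamma_p / params.k_spring
        for _ in range(int(t_end / dt)):
            L = tip - (x + base_off)
            v_tip = (params.f_p - params.k_spring * L) / params.gamma_p
            v_body = params.k_spring * L / gamma_b
            tip += dt * v_tip
            x += dt * v_body
        L = tip - (x + base_off)
        v_exp, (l_exp,) = single_cell_equilibrium(params, 1, 0)
        assert v_body == pytest.approx(v_exp, rel=5e-3)
        assert L == pytest.approx(l_exp, rel=5e-3)

    def test_trailing_configuration_moves_toward_active(self, params):
        """Net displacement is toward the active podium."""
        dt = 0.01
        base = 2.0
        x = 0.0
        tip_a = base    # active, ahead (+x)
        tip_t = -base - 10.0  # trailing tip behind with length 10
        for _ in range(20000):
            la = tip_a - (x + base)
            lt = (x - base) - tip_t
            v_tip_a = (params.f_p - params.k_spring * la) / params.gamma_p
            v_tip_t = (params.k_spring * lt) / params.gamma_p  # retracts
            gamma_b = 3.0
            v_body = (params.k_spring * la - params.k_spring * lt) / gamma_b
            tip_a += dt * v_tip_a
            tip_t += dt * v_tip_t
            x += dt * v_body
        assert x > 0.0
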