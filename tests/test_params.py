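"""Parameter loading, unit normalization, neighbor/shape geometry."""

import math

import numpy as np
import pytest

from podosim import ModelParameters, ParameterError, load_parameters
from podosim.state import (Podium, SimulationState, neighbor_count,
                           shape_distance)

from conftest import make_test_cell


class TestLoadParameters:
    def test_defaults_match_published_table(self, params):
        assert params.f_p == pytest.approx(2.5)
        assert params.k_spring == pytest.approx(0.1)
        assert params.r0 == pytest.approx(4.75)
        assert params.d_nn == pytest.approx(5.0)
        assert params.l_max == pytest.approx(25.0)
        # podium time constant ~11.7 min in internal units
        assert params.gamma_p / params.k_spring == pytest.approx(35.0 / 3.0)

    def test_override_in_table_units(self):
        p = load_parameters("[regulation]\nd_nn = 5\n")
        assert p.d_nn == pytest.approx(5.0)
        p = load_parameters("[podia]\nf_p = 3.0\nr_ind_lo = 4\n")
        assert p.f_p == pytest.approx(3.0)
        assert p.r_ind_lo == pytest.approx(4.0 / 1440.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError, match="unknown key"):
            load_parameters("[podia]\nbogus = 1\n")
        with pytest.raises(ParameterError, match="unknown config section"):
            load_parameters("[nonsense]\nx = 1\n")

    def test_negative_value_rejected(self):
        with pytest.raises(ParameterError, match="f_p"):
            load_parameters("[podia]\nf_p = -1\n")

    def test_unit_round_trip_six_digits(self, params):
        printed = {
            "eps_cc": 600.0, "eps_cs": 200.0, "e_young": 1.0, "k_bulk": 1.0,
            "gamma_cc": 2.8e9, "gamma_cs": 2.8e9, "gamma_r": 173e9,
            "gamma_v": 0.04, "lambda_np": 1440.0, "r_ind_lo": 2.0,
            "c_a": 3.0, "f_p": 2.5, "gamma_p": 0.07, "k_spring": 0.1,
            "r0": 4.75, "dvdt_lo": 1200.0, "m_inc": 20.0, "d_nn": 5.0,
        }
        table = params.to_table_units()
        for key, val in printed.items():
            assert table[key] == pytest.approx(val, rel=1e-6), key


class TestShapeDistance:
    def test_identical_position_zero(self, params):
        a = make_test_cell(params, (0, 0), cell_id=1)
        b = make_test_cell(params, (0, 0), cell_id=2)
        assert shape_distance(a, b, params) == 0.0

    def test_same_cell_error(self, params):
        a = make_test_cell(params, (0, 0), cell_id=1)
        with pytest.raises(ValueError):
            shape_distance(a, a, params)

    def test_two_bodies_circle_distance(self, params):
        # adhesion radius 4 um each via explicit height
        R = params.r0
        h = math.sqrt(R * R - 16.0)
        a = make_test_cell(params, (0, 0), height=h, cell_id=1)
        b = make_test_cell(params, (20, 0), height=h, cell_id=2)
        assert shape_distance(a, b, params) == pytest.approx(12.0, abs=1e-9)

    def test_podium_tip_vs_body(self, params):
        """Distance to a podium tip is reduced by the tip radius."""
        R = params.r0
        h = math.sqrt(R * R - 16.0)  # a = 4
        a_cell = make_test_cell(params, (0, 0), height=h,
                                podia=[(0.0, 10.0)], cell_id=1)
        b = make_test_cell(params, (30, 0), height=h, cell_id=2)
        # tip centre at a/2 + L = 12; b body edge at 30 - 4 = 26
        tip_r = params.cone_tip_frac * 4.0
        expect = 26.0 - 12.0 - tip_r
        assert shape_distance(a_cell, b, params) == pytest.approx(expect, abs=1e-6)

    def test_matches_dense_sampling_oracle(self, params, rng):
        """Exact capsule distance vs brute-force boundary sampling."""
        from podosim.geometry import min_shape_distance

        def sample_outline(cell, n=720):
            pts = []
            a = cell.adhesion_radius
            rt = cell.tip_radius(params)
            th = np.linspace(0, 2 * np.pi, n, endpoint=False)
            pts.append(cell.center + a * np.column_stack([np.cos(th), np.sin(th)]))
            for p in cell.podia:
                tip = cell.center + (a / 2 + p.length) * np.array(
                    [math.cos(p.angle), math.sin(p.angle)])
                pts.append(tip + rt * np.column_stack([np.cos(th), np.sin(th)]))
                # tangent flanks of the cone, sampled densely
                for lam in np.linspace(0, 1, 80):
                    c = cell.center * (1 - lam) + tip * lam
                    r = a * (1 - lam) + rt * lam
                    pts.append(c + r * np.column_stack([np.cos(th[::12]),
                                                        np.sin(th[::12])]))
            return np.vstack(pts)

        for _ in range(5):
            c1 = make_test_cell(params, rng.uniform(-5, 5, 2),
                                podia=[(rng.uniform(0, 2 * np.pi),
                                        rng.uniform(2, 20))], cell_id=1)
            c2 = make_test_cell(params, rng.uniform(15, 40, 2),
                                podia=[(rng.uniform(0, 2 * np.pi),
                                        rng.uniform(2, 20))], cell_id=2)
            exact = shape_distance(c1, c2, params)
            pts1, pts2 = sample_outline(c1), sample_outline(c2)
            d2 = np.sqrt(((pts1[:, None, :] - pts2[None, :, :])**2).sum(-1))
            brute = max(d2.min(), 0.0)
            assert exact == pytest.approx(brute, abs=0.05)


class TestNeighborCount:
    def test_out_of_range_zero(self, params):
        a = make_test_cell(params, (0, 0), cell_id=1)
        b = make_test_cell(params, (200, 0), cell_id=2)
        st = SimulationState.from_cells(params, [a, b])
        cells = st.cells()
        assert neighbor_count(cells[0], st) == 0

    def test_surface_gap_within_dnn(self, params):
        R = params.r0
        h = math.sqrt(R * R - 16.0)
        a = make_test_cell(params, (0, 0), height=h, cell_id=1)
        b = make_test_cell(params, (12, 0), height=h, cell_id=2)  # gap 4 um
        st = SimulationState.from_cells(params, [a, b])
        cells = st.cells()
        assert neighbor_count(cells[0], st) == 1
        assert neighbor_count(cells[1], st) == 1

    def test_three_collinear(self, params):
        R = params.r0
        h = math.sqrt(R * R - 16.0)
        cs = [make_test_cell(params, (x, 0), height=h, cell_id=i + 1)
              for i, x in enumerate((0.0, 12.0, 24.0))]
        st = SimulationState.from_cells(params, cs)
        cells = st.cells()
        counts = [neighbor_count(c, st) for c in cells]
        assert counts == [1, 2, 1]

    def test_symmetry_and_monotone_under_elongation(self, params):
        """Object API vs engine kernel, and elongation monotonicity."""
        from podosim.engine import _neighbor_counts

        R = params.r0
        h = math.sqrt(R * R - 16.0)
        prev = 0
        for L in (2.0, 15.0, 30.0):
            a = make_test_cell(params, (0, 0), height=h,
                               podia=[(0.0, L)], cell_id=1)
            b = make_test_cell(params, (40, 0), height=h, cell_id=2)
            st = SimulationState.from_cells(params, [a, b])
            cells = st.cells()
            na = neighbor_count(cells[0], st)
            nb = neighbor_count(cells[1], st)
            assert na == nb  # symmetric
            assert na >= prev  # monotone as the podium elongates toward b
            prev = na
            np.testing.assert_array_equal(_neighbor_counts(st), [na, nb])
        assert prev == 1


def test_parameter_validation_direct():
    with pytest.raises(ParameterError):
        ModelParameters(nu=0.6)
    with pytest.raises(ParameterError):
        ModelParameters(n_podia_lo=4, n_podia_hi=2)
    with pytest.raises(ParameterError):
        ModelParameters(p_groove=1.5)
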