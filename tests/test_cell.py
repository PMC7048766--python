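"""Closed-form membrane model: conductance, time constant, steady state,
and the exact first-order trace."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memvolt import (
    CellModel,
    MediumModel,
    analytic_tmp_trace,
    charging_time_constant,
    conductance_correction_factor,
    membrane_areal_conductance,
    rectangular_waveform,
    steady_state_tmp,
)


class TestCellModelValidation:
    def test_rejects_nonpositive_fields(self):
        with pytest.raises(ValueError):
            CellModel(-5.5e-6, 5e-9, 2.5e-7, 0.01, 0.5)
        with pytest.raises(ValueError):
            CellModel(5.5e-6, 5e-9, 2.5e-7, 0.0, 0.5)
        with pytest.raises(ValueError):
            CellModel(5.5e-6, 5e-9, -1e-7, 0.01, 0.5)

    def test_rejects_thick_membrane(self):
        with pytest.raises(ValueError, match="membrane_thickness"):
            CellModel(5.5e-6, 1e-6, 2.5e-7, 0.01, 0.5)

    def test_medium_requires_positive_conductivity(self):
        with pytest.raises(ValueError):
            MediumModel(0.0)
        with pytest.raises(ValueError):
            MediumModel(-0.1)


class TestMembraneArealConductance:
    def test_reference_cell_is_50_S_per_m2(self, cell):
        assert membrane_areal_conductance(cell) == pytest.approx(50.0)

    def test_perfect_insulator_gives_zero(self, cell):
        insulating = CellModel(
            cell.radius, cell.membrane_thickness, 0.0,
            cell.membrane_areal_capacitance, cell.intracellular_conductivity,
        )
        assert membrane_areal_conductance(insulating) == 0.0

    def test_doubling_thickness_halves_conductance(self, cell):
        thick = CellModel(
            cell.radius, 2 * cell.membrane_thickness, cell.membrane_conductivity,
            cell.membrane_areal_capacitance, cell.intracellular_conductivity,
        )
        assert membrane_areal_conductance(thick) == pytest.approx(
            0.5 * membrane_areal_conductance(cell)
        )


class TestChargingTimeConstant:
    @pytest.mark.parametrize(
        "sigma_e,expected",
        [(0.05, 6.6e-7), (0.1, 3.85e-7), (0.5, 1.65e-7)],
    )
    def test_reference_values(self, cell, sigma_e, expected):
        tau = charging_time_constant(cell, MediumModel(sigma_e))
        assert tau == pytest.approx(expected, rel=1e-9)

    def test_high_conductivity_limit(self, cell):
        # sigma_e -> inf leaves only the intracellular access term R*C_m/sigma_i
        tau = charging_time_constant(cell, MediumModel(1e9))
        assert tau == pytest.approx(1.1e-7, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(
        s_lo=st.floats(0.01, 5.0),
        factor=st.floats(1.001, 100.0),
    )
    def test_strictly_decreasing_in_sigma_e(self, cell, s_lo, factor):
        tau_lo = charging_time_constant(cell, MediumModel(s_lo))
        tau_hi = charging_time_constant(cell, MediumModel(s_lo * factor))
        assert tau_hi < tau_lo

    def test_increasing_in_radius_and_capacitance(self, cell, hepes):
        tau = charging_time_constant(cell, hepes)
        bigger = CellModel(
            2 * cell.radius, cell.membrane_thickness, cell.membrane_conductivity,
            cell.membrane_areal_capacitance, cell.intracellular_conductivity,
        )
        stiffer = CellModel(
            cell.radius, cell.membrane_thickness, cell.membrane_conductivity,
            2 * cell.membrane_areal_capacitance, cell.intracellular_conductivity,
        )
        assert charging_time_constant(bigger, hepes) == pytest.approx(2 * tau)
        assert charging_time_constant(stiffer, hepes) == pytest.approx(2 * tau)


class TestSteadyStateTMP:
    def test_pole_value_reference_cell(self, cell, hepes):
        # f_s * 1.5 * R * E with f_s about 0.9967 for the reference cell
        v = steady_state_tmp(cell, hepes, 8e5, 0.0)
        assert v == pytest.approx(6.578, rel=2e-4)
        f_s = conductance_correction_factor(cell, hepes)
        assert f_s == pytest.approx(0.9967, abs=1e-4)
        assert v == pytest.approx(f_s * 1.5 * cell.radius * 8e5, rel=1e-12)

    def test_equator_and_zero_field_vanish(self, cell, hepes):
        assert steady_state_tmp(cell, hepes, 8e5, np.pi / 2) == pytest.approx(0.0, abs=1e-12)
        assert steady_state_tmp(cell, hepes, 0.0, 0.3) == 0.0

    def test_antisymmetric_about_equator(self, cell, hepes):
        theta = np.linspace(0, np.pi, 33)
        v = steady_state_tmp(cell, hepes, 8e5, theta)
        np.testing.assert_allclose(v, -v[::-1], atol=1e-12)

    def test_maximal_at_poles_and_fs_bounded(self, cell):
        for sigma in (0.05, 0.1, 0.5):
            medium = MediumModel(sigma)
            f_s = conductance_correction_factor(cell, medium)
            assert 0 < f_s <= 1
            theta = np.linspace(0, np.pi, 101)
            v = np.abs(steady_state_tmp(cell, medium, 8e5, theta))
            assert v.argmax() in (0, 100)

    def test_rejects_theta_outside_range(self, cell, hepes):
        with pytest.raises(ValueError):
            steady_state_tmp(cell, hepes, 8e5, -0.5)


class TestAnalyticTrace:
    def test_one_time_constant_reaches_632_percent(self, cell, hepes):
        tau = charging_time_constant(cell, hepes)
        wf = rectangular_waveform(8e5, 10 * tau)
        t = np.linspace(0, 10 * tau, 5001)
        tr = analytic_tmp_trace(cell, hepes, wf, 0.0, t)
        vss = steady_state_tmp(cell, hepes, 8e5, 0.0)
        v_at_tau = np.interp(tau, t, tr.pole_vm())
        assert v_at_tau / vss == pytest.approx(1 - np.exp(-1), rel=1e-3)

    @pytest.mark.parametrize(
        "sigma_e,peak_fraction", [(0.05, 0.2614), (0.1, 0.4052)]
    )
    def test_200ns_peak_fractions(self, cell, sigma_e, peak_fraction):
        """A 200 ns pulse reaches only a conductivity-dependent fraction of
        the steady state; the 0.05 vs 0.1 S/m contrast is the mechanism of
        the conductivity effect."""
        medium = MediumModel(sigma_e)
        wf = rectangular_waveform(8e5, 200e-9)
        t = np.linspace(0, 200e-9, 2001)
        tr = analytic_tmp_trace(cell, medium, wf, 0.0, t)
        vss = steady_state_tmp(cell, medium, 8e5, 0.0)
        assert tr.pole_vm().max() / vss == pytest.approx(peak_fraction, abs=2e-4)

    def test_post_pulse_decay_with_same_tau(self, cell, hepes):
        tau = charging_time_constant(cell, hepes)
        wf = rectangular_waveform(8e5, 1e-6, 3e-6)
        t = np.linspace(0, 4e-6, 8001)
        v = analytic_tmp_trace(cell, hepes, wf, 0.0, t).pole_vm()
        v_end = np.interp(1e-6, t, v)
        v_later = np.interp(1e-6 + tau, t, v)
        assert v_later / v_end == pytest.approx(np.exp(-1), rel=1e-3)

    @settings(derandomize=True, max_examples=30)
    @given(k=st.floats(-3.0, 3.0))
    def test_linear_in_field_amplitude(self, cell, hepes, k):
        t = np.linspace(0, 1.2e-6, 301)
        theta = np.linspace(0, np.pi, 17)
        base = analytic_tmp_trace(
            cell, hepes, rectangular_waveform(1e5, 2e-7, 1e-6), theta, t
        )
        scaled = analytic_tmp_trace(
            cell, hepes, rectangular_waveform(k * 1e5, 2e-7, 1e-6), theta, t
        )
        np.testing.assert_allclose(scaled.vm, k * base.vm, rtol=1e-12, atol=1e-15)

    def test_peak_bounded_by_steady_state(self, cell):
        for sigma in (0.05, 0.5):
            medium = MediumModel(sigma)
            wf = rectangular_waveform(8e5, 200e-9, 1e-6)
            t = np.linspace(0, 1.2e-6, 4001)
            tr = analytic_tmp_trace(cell, medium, wf, 0.0, t)
            vss = steady_state_tmp(cell, medium, 8e5, 0.0)
            assert tr.pole_vm().max() < vss

    def test_angular_profile_is_cosine(self, cell, hepes):
        theta = np.linspace(0, np.pi, 41)
        t = np.linspace(0, 2e-7, 101)
        tr = analytic_tmp_trace(
            cell, hepes, rectangular_waveform(8e5, 2e-7), theta, t
        )
        np.testing.assert_allclose(
            tr.vm, tr.pole_vm()[:, None] * np.cos(theta)[None, :], atol=1e-15
        )

    def test_rejects_bad_grids(self, cell, hepes):
        wf = rectangular_waveform(8e5, 2e-7)
        with pytest.raises(ValueError, match="increasing"):
            analytic_tmp_trace(cell, hepes, wf, 0.0, np.array([0.0, 2e-9, 1e-9]))
        with pytest.raises(ValueError, match="beyond"):
            analytic_tmp_trace(cell, hepes, wf, 0.0, np.array([0.0, 3e-7]))
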