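"""Model-layer checks: constitutive relations, conservation, steady state,
and agreement between the batch kernel and an independent scipy integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cvgsa import models
from cvgsa.models import (InvalidParameterError, ModelConstants,
                          ParameterVector, SolverSettings, WaveformSet,
                          default_constants, discrete_measurements, elastance,
                          nominal_parameters, rhs_one_chamber,
                          rhs_two_chamber, simulate, valve_flow)


class TestElastance:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 0.03),            # activation zero at cycle start
        (0.3, 1.5),             # peak at end-systole
        (0.15, (1.5 + 0.03) / 2),  # half activation mid-rise
        (0.45, 0.03),           # baseline from end-pulse on
        (0.7, 0.03),
        (0.999, 0.03),
    ])
    def test_closed_form_values(self, t, expected):
        assert elastance(t, 1.5, 0.03, 0.3, 0.45) == pytest.approx(expected)

    def test_shift_moves_activation(self):
        # atrial timing: activation peaks shift seconds later (modulo tau)
        shift = 0.92
        assert elastance(shift + 0.045, 0.25, 0.15, 0.045, 0.09,
                         shift=shift) == pytest.approx(0.25)

    @given(st.floats(-5, 5))
    @settings(max_examples=200, deadline=None)
    def test_bounded_between_extrema(self, t):
        e = elastance(t, 1.5, 0.03, 0.3, 0.45)
        assert 0.03 - 1e-12 <= e <= 1.5 + 1e-12

    @pytest.mark.parametrize("kwargs", [
        dict(tau=-1.0), dict(tau_es=0.5, tau_ep=0.4), dict(tau_es=0.45),
    ])
    def test_invalid_timing_rejected(self, kwargs):
        args = dict(t=0.1, e_max=1.5, e_min=0.03, tau_es=0.3, tau_ep=0.45, tau=1.0)
        args.update(kwargs)
        with pytest.raises(InvalidParameterError):
            elastance(args["t"], args["e_max"], args["e_min"], args["tau_es"],
                      args["tau_ep"], args["tau"])


class TestValveFlow:
    @pytest.mark.parametrize("p_up, p_down, r, expected", [
        (10.0, 5.0, 0.1, 50.0),
        (5.0, 10.0, 0.1, 0.0),   # reverse bias blocks
        (7.0, 7.0, 0.5, 0.0),    # no gradient, no flow
    ])
    def test_diode_law(self, p_up, p_down, r, expected):
        assert valve_flow(p_up, p_down, r) == expected

    def test_never_negative_and_validates(self):
        rng = np.random.default_rng(0)
        p = rng.normal(50, 40, size=(100, 2))
        assert np.all(valve_flow(p[:, 0], p[:, 1], 0.03) >= 0)
        with pytest.raises(InvalidParameterError):
            valve_flow(1.0, 0.0, 0.0)


class TestParameterVector:
    def test_nominal_tables(self):
        pv1 = nominal_parameters("one_chamber")
        pv2 = nominal_parameters("two_chamber")
        assert len(pv1.values) == 9 and len(pv2.values) == 20
        assert pv1["R_s"] == 1.11 and pv2["C_svn"] == 20.5

    @pytest.mark.parametrize("updates", [
        {"R_s": -1.0}, {"tau_es": 0.5}, {"E_max": 0.0},
    ])
    def test_invariants_enforced(self, updates):
        with pytest.raises(InvalidParameterError):
            nominal_parameters("one_chamber").with_values(**updates)

    def test_default_bounds_bracket_nominal(self):
        b = models.default_bounds("two_chamber")
        nom = nominal_parameters("two_chamber").values
        assert np.all(b[:, 0] < nom) and np.all(nom < b[:, 1])
        assert np.allclose(b[:, 0], 0.5 * nom) and np.allclose(b[:, 1], 1.5 * nom)


class TestRhsConservation:
    def test_one_chamber_closed_loop(self):
        # dV_lv + C_sa dP_sa + C_sv dP_sv == 0 for any state: volume moves,
        # it is never created
        pv = nominal_parameters("one_chamber")
        rng = np.random.default_rng(1)
        for _ in range(50):
            state = rng.uniform([10, 20, 1], [400, 150, 30])
            t = rng.uniform(0, 1)
            dv, dpsa, dpsv = rhs_one_chamber(t, state, pv)
            assert dv + 1.13 * dpsa + 11.0 * dpsv == pytest.approx(0.0, abs=1e-9)

    def test_two_chamber_closed_loop(self):
        pv = nominal_parameters("two_chamber")
        c_sas, c_sat, c_svn = pv["C_sas"], pv["C_sat"], pv["C_svn"]
        rng = np.random.default_rng(2)
        for _ in range(50):
            state = rng.uniform([10, 5, 20, -50, 20, -50, 1],
                                [400, 80, 150, 400, 150, 400, 30])
            t = rng.uniform(0, 1)
            d = rhs_two_chamber(t, state, pv)
            total = d[0] + d[1] + c_sas * d[2] + c_sat * d[4] + c_svn * d[6]
            assert total == pytest.approx(0.0, abs=1e-9)

    def test_series_resistance_symmetry(self):
        # arteriolar and capillary resistances only enter as a series sum
        pv = nominal_parameters("two_chamber")
        swapped = pv.with_values(R_sar=pv["R_scp"], R_scp=pv["R_sar"])
        state = np.array([300.0, 30.0, 80.0, 100.0, 75.0, 90.0, 8.0])
        np.testing.assert_allclose(rhs_two_chamber(0.2, state, pv),
                                   rhs_two_chamber(0.2, state, swapped))

    def test_non_pumping_heart_relaxes_to_equilibrium(self):
        # with E_max == E_min the ventricle is a passive compliance and the
        # loop decays to a uniform pressure with zero flow
        p = np.array([0.5, 0.5, 0.3, 0.45, 0.033, 0.006, 1.11, 1.13, 11.0])
        sol = solve_ivp(lambda t, y: rhs_one_chamber(t, y, p), (0, 300),
                        [500.0, 70.0, 7.0], method="BDF", rtol=1e-10, atol=1e-10)
        v_lv, p_sa, p_sv = sol.y[:, -1]
        p_lv = 0.5 * v_lv
        assert p_lv == pytest.approx(p_sa, rel=1e-6)
        assert p_sa == pytest.approx(p_sv, rel=1e-6)

    def test_nan_state_surfaces(self):
        pv = nominal_parameters("one_chamber")
        with pytest.raises(FloatingPointError):
            rhs_one_chamber(0.0, np.array([np.nan, 70.0, 7.0]), pv)


class TestSimulate:
    def test_waveform_shape_and_sanity(self, nominal_waveform_1ch):
        w = nominal_waveform_1ch
        assert w.t.shape == (200,) and w.as_array().shape == (3, 200)
        assert np.all(np.diff(w.t) > 0)
        assert 0 < w.v_lv.min() < w.v_lv.max()
        assert w.p_lv.max() > w.p_art.min()  # systole drives the artery

    def test_two_chamber_waveform(self, nominal_waveform_2ch):
        w = nominal_waveform_2ch
        assert w.as_array().shape == (3, 200)
        assert 0 < w.v_lv.min() < w.v_lv.max()

    @pytest.mark.parametrize("model_id", ["one_chamber", "two_chamber"])
    def test_periodicity_of_saved_cycle(self, model_id):
        # cycle 14->15 vs the default 15->16: periodic steady state
        early = simulate(model_id, constants=ModelConstants(
            e_shift=default_constants(model_id).e_shift,
            n_cycles=15, n_transient=14))
        late = simulate(model_id)
        for a, b in [(early.p_lv, late.p_lv), (early.p_art, late.p_art),
                     (early.v_lv, late.v_lv)]:
            span = b.max() - b.min()
            assert np.max(np.abs(a - b)) / span < 1e-3

    def test_volume_conservation_over_saved_cycle(self):
        # integrate the full state with scipy and compare stressed volume at
        # the ends of the saved cycle
        pv = nominal_parameters("one_chamber")
        sol = solve_ivp(lambda t, y: rhs_one_chamber(t, y, pv), (0, 16),
                        [500.0, 70.0, 7.0], method="DOP853",
                        rtol=1e-10, atol=1e-10, t_eval=[15.0, 16.0])
        total = sol.y[0] + 1.13 * sol.y[1] + 11.0 * sol.y[2]
        assert abs(total[1] - total[0]) / total[0] < 1e-6

    def test_kernel_matches_scipy_reference(self, nominal_waveform_1ch):
        # independent route: DOP853 on the plain-numpy right-hand side
        pv = nominal_parameters("one_chamber")
        t_eval = nominal_waveform_1ch.t
        sol = solve_ivp(lambda t, y: rhs_one_chamber(t, y, pv), (0, 16),
                        [500.0, 70.0, 7.0], method="DOP853",
                        rtol=1e-10, atol=1e-10, t_eval=t_eval)
        p_lv_ref = elastance(t_eval, pv["E_max"], pv["E_min"], pv["tau_es"],
                             pv["tau_ep"]) * sol.y[0]
        for ours, ref in [(nominal_waveform_1ch.p_lv, p_lv_ref),
                          (nominal_waveform_1ch.p_art, sol.y[1]),
                          (nominal_waveform_1ch.v_lv, sol.y[0])]:
            span = ref.max() - ref.min()
            assert np.max(np.abs(ours - ref)) / span < 1e-5

    def test_model_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate("one_chamber", nominal_parameters("two_chamber"))

    def test_solver_settings_validate(self):
        with pytest.raises(InvalidParameterError):
            SolverSettings(rtol=0.0)
        with pytest.raises(InvalidParameterError):
            SolverSettings(points_per_cycle=1)


class TestMeasurements:
    def test_discrete_reduction(self):
        t = np.linspace(15, 16, 3, endpoint=False)
        w = WaveformSet(t, np.array([1.0, 2.0, 3.0]), np.array([5.0, 9.0, 7.0]),
                        np.array([100.0, 120.0, 110.0]))
        d = discrete_measurements(w)
        assert d.mean_p_lv == 2.0 and d.max_p_art == 9.0 and d.max_v_lv == 120.0

    def test_constant_channels(self):
        t = np.linspace(15, 16, 4, endpoint=False)
        c = np.full(4, 42.0)
        d = discrete_measurements(WaveformSet(t, c, c, c))
        assert d.mean_p_lv == d.max_p_art == d.max_v_lv == 42.0

    def test_waveform_validation(self):
        t = np.array([15.0, 14.0, 16.0])
        with pytest.raises(ValueError):
            WaveformSet(t, t, t, t)


def test_config_roundtrip(tmp_path):
    cfg = tmp_path / "model.yaml"
    cfg.write_text(
        "model_id: one_chamber\n"
        "parameters: {R_s: 1.2}\n"
        "constants: {n_cycles: 12, n_transient: 11}\n"
        "bounds: {R_s: [0.6, 1.8]}\n")
    pv, const, bounds = models.load_model_config(cfg)
    assert pv["R_s"] == 1.2
    assert const.n_cycles == 12
    i = pv.names.index("R_s")
    assert tuple(bounds[i]) == (0.6, 1.8)
    # untouched parameters keep the default multiplicative window
    j = pv.names.index("C_sa")
    assert bounds[j][0] == pytest.approx(0.5 * 1.13)
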