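"""Leak/rundown corrections, G-V extraction, Boltzmann fits, V_T, ΔpH shifts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hvprime as hv
from hvprime.errors import (
    DegenerateInputError,
    MethodInapplicableError,
    ParameterError,
    UnreliableCorrectionError,
)
from hvprime.gating_analysis import BoltzmannFit, GVCurve, IVCurve


def _boltz_iv(vh, s, vrev, v_lo=None, v_hi=None, dv=1.0, gmax=1.0):
    v_lo = vrev - 20.0 if v_lo is None else v_lo
    v_hi = vh + 3.0 * s if v_hi is None else v_hi
    V = np.arange(v_lo, v_hi, dv)
    I = gmax / (1.0 + np.exp((vh - V) / s)) * (V - vrev)
    return IVCurve(V, I)


class TestSubtractLeak:
    def test_pure_leak_is_removed(self, sym_solution):
        params = dataclasses.replace(hv.preset("leak_only"), noise_sd_pA=0.0)
        proto = hv.make_protocol("slow_ramp", V_from_mV=-80, rate_mV_per_s=20.0)
        rec = hv.simulate_recording(params, proto, sym_solution, sample_interval_ms=1.0)
        out = hv.subtract_leak(rec, (-80.0, -40.0))
        assert abs(out.provenance["g_leak_nS"] - 1.0) < 0.02
        assert np.max(np.abs(out.sweeps[0].current_pA)) < 1e-9

    def test_recovers_known_leak_under_gated_current(self, quiet_params, sym_solution):
        params = dataclasses.replace(quiet_params, g_leak_nS=1.0)
        proto = hv.make_protocol("slow_ramp", V_from_mV=-80, rate_mV_per_s=7.0)
        rec = hv.simulate_recording(params, proto, sym_solution, sample_interval_ms=1.0)
        out = hv.subtract_leak(rec, (-80.0, -40.0))
        assert out.provenance["g_leak_nS"] == pytest.approx(1.0, rel=0.02)

    def test_zero_leak_recovered_near_zero(self, quiet_params, sym_solution):
        proto = hv.make_protocol("slow_ramp", V_from_mV=-80, rate_mV_per_s=7.0)
        rec = hv.simulate_recording(quiet_params, proto, sym_solution, sample_interval_ms=1.0)
        out = hv.subtract_leak(rec, (-80.0, -40.0))
        assert abs(out.provenance["g_leak_nS"]) < 0.02

    def test_window_with_gated_current_sets_warning(self, quiet_params, sym_solution):
        params = dataclasses.replace(quiet_params, g_leak_nS=0.2)
        proto = hv.make_protocol("slow_ramp", V_from_mV=-80, V_to_mV=120, rate_mV_per_s=7.0)
        rec = hv.simulate_recording(params, proto, sym_solution, sample_interval_ms=1.0)
        bad = hv.subtract_leak(rec, (-80.0, 60.0))  # window reaches gated voltages
        assert bad.provenance["leak_window_warning"]
        good = hv.subtract_leak(rec, (-80.0, -40.0))
        assert not good.provenance["leak_window_warning"]

    def test_empty_window_rejected(self, tail_recording):
        with pytest.raises(ParameterError):
            hv.subtract_leak(tail_recording, (-300.0, -200.0))


class TestCorrectRundown:
    def _recording(self, tau, sym_solution, quiet_params, prepulse_mV=120.0):
        params = dataclasses.replace(quiet_params, rundown_tau_s=tau)
        proto = hv.make_protocol("tail_family", prepulse_mV=prepulse_mV,
                                 inter_sweep_interval_s=3.0)
        return hv.simulate_recording(params, proto, sym_solution, sample_interval_ms=0.5), proto

    def test_exponential_rundown_is_removed(self, sym_solution, quiet_params):
        rec, proto = self._recording(120.0, sym_solution, quiet_params)
        out = hv.correct_rundown(rec, prepulse_epoch=1)
        scales = out.provenance["rundown_scale_factors"]
        # generator decays as exp(-t/tau) with 3 s between sweeps
        for k, sc in enumerate(scales):
            assert sc == pytest.approx(np.exp(3.0 * k / 120.0), rel=1e-6)
        amps = []
        for s in out.sweeps:
            sl = proto.epoch_slice(1, s.sample_interval_ms)
            amps.append(np.mean(s.current_pA[sl][-60:]))
        assert np.ptp(amps) / np.mean(amps) < 0.02

    def test_no_rundown_gives_unit_scales(self, sym_solution, quiet_params):
        rec, _ = self._recording(None, sym_solution, quiet_params)
        out = hv.correct_rundown(rec, prepulse_epoch=1)
        np.testing.assert_allclose(out.provenance["rundown_scale_factors"], 1.0, atol=0.02)

    def test_subthreshold_prepulse_is_unreliable(self, sym_solution, quiet_params):
        rec, _ = self._recording(None, sym_solution, quiet_params, prepulse_mV=-80.0)
        with pytest.raises(UnreliableCorrectionError):
            hv.correct_rundown(rec, prepulse_epoch=1)


class TestTailGV:
    def test_printed_formula_arithmetic(self):
        """G = (I_test - I_tail)/(V_test - V_tail) on a hand-built sweep."""
        epochs = (
            hv.Epoch("hold", 50.0, -60.0, -60.0),
            hv.Epoch("step", 100.0, 80.0, 80.0),
            hv.Epoch("step", 100.0, -60.0, -60.0),
        )
        proto = hv.VoltageProtocol(epochs, holding_mV=-60.0)
        dt = 1.0
        cmd = proto.command(0, dt)
        cur = np.zeros_like(cmd)
        cur[proto.epoch_slice(1, dt)] = 100.0
        cur[proto.epoch_slice(2, dt)] = 40.0
        rec = hv.Recording(
            sweeps=[hv.Sweep(dt, cur, cmd)], protocol=proto,
            solution=hv.SolutionPair(6.0, 6.0),
        )
        gv = hv.tail_gv(rec, test_epoch=1, tail_epoch=2)
        assert gv.G_nS[0] == pytest.approx(60.0 / 140.0)

    def test_equal_test_and_tail_voltage_rejected(self, sym_solution):
        epochs = (
            hv.Epoch("hold", 50.0, -60.0, -60.0),
            hv.Epoch("step", 100.0, -60.0, -60.0),
            hv.Epoch("step", 100.0, -60.0, -60.0),
        )
        proto = hv.VoltageProtocol(epochs, holding_mV=-60.0)
        cmd = proto.command(0, 1.0)
        rec = hv.Recording([hv.Sweep(1.0, np.ones_like(cmd), cmd)], proto, sym_solution)
        with pytest.raises(DegenerateInputError):
            hv.tail_gv(rec, 1, 2)

    def test_round_trip_recovers_generator_gating(self, tail_recording, quiet_params):
        gv = hv.tail_gv(tail_recording, test_epoch=3, tail_epoch=4)
        fit = hv.fit_boltzmann(gv)
        assert fit.V_half_mV == pytest.approx(quiet_params.V_half_ref_mV, abs=0.1)
        assert fit.slope_mV == pytest.approx(quiet_params.slope_mV, abs=0.1)


class TestRampGV:
    def test_linear_iv_gives_constant_conductance(self):
        V = np.arange(-40.0, 120.0, 5.0)
        iv = IVCurve(V, 2.0 * (V - (-10.0)))
        gv = hv.ramp_gv(iv, V_rev_mV=-10.0)
        np.testing.assert_allclose(gv.G_nS, 2.0, atol=1e-12)

    def test_points_near_reversal_are_excluded(self):
        V = np.arange(-40.0, 120.0, 5.0)
        iv = IVCurve(V, 1.0 * V)
        gv = hv.ramp_gv(iv, V_rev_mV=0.0)
        assert np.all(np.abs(gv.V_mV) >= 10.0)

    def test_slow_ramp_round_trip(self, quiet_params, sym_solution):
        proto = hv.make_protocol("slow_ramp", V_from_mV=-60, V_to_mV=120, rate_mV_per_s=3.5)
        rec = hv.simulate_recording(quiet_params, proto, sym_solution, sample_interval_ms=1.0)
        iv = hv.iv_from_ramp(rec)
        fit = hv.fit_boltzmann(hv.ramp_gv(iv, V_rev_mV=0.0))
        assert fit.V_half_mV == pytest.approx(44.8, abs=0.5)


class TestFitBoltzmann:
    def test_noiseless_recovery_is_exact(self):
        V = np.linspace(-20.0, 110.0, 20)
        G = 1.0 / (1.0 + np.exp((44.8 - V) / 14.3))
        fit = hv.fit_boltzmann(GVCurve(V, G))
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.V_half_mV == pytest.approx(44.8, abs=1e-6)
        assert fit.slope_mV == pytest.approx(14.3, abs=1e-6)
        assert fit.rss < 1e-12

    def test_half_maximum_identity(self):
        V = np.linspace(-20.0, 110.0, 20)
        G = 2.0 / (1.0 + np.exp((30.0 - V) / 10.0))
        fit = hv.fit_boltzmann(GVCurve(V, G))
        assert fit.predict(fit.V_half_mV) == pytest.approx(fit.amplitude / 2.0, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            hv.fit_boltzmann(GVCurve([0, 10, 20, 30], [0.1, 0.3, 0.6, 0.9]))

    def test_normalized_curve_hides_gmax(self):
        V = np.linspace(-20.0, 110.0, 20)
        G = 1.0 / (1.0 + np.exp((44.8 - V) / 14.3))
        gv = hv.normalize_gv(GVCurve(V, G))
        fit = hv.fit_boltzmann(gv)
        assert fit.G_max_nS is None
        assert fit.V_half_mV == pytest.approx(44.8, abs=0.01)

    def test_normalize_then_average_recovers_common_gating(self):
        """Curves with different G_max but identical gating average to a
        normalized curve that fits back the shared (V_half, s)."""
        V = np.linspace(-20.0, 110.0, 25)
        shape = 1.0 / (1.0 + np.exp((44.8 - V) / 14.3))
        curves = [GVCurve(V, g * shape) for g in (0.5, 1.0, 3.0)]
        mean = hv.average_gvs(curves)
        assert np.max(mean.G_nS) == pytest.approx(1.0)
        fit = hv.fit_boltzmann(mean)
        assert fit.V_half_mV == pytest.approx(44.8, abs=1e-6)
        assert fit.slope_mV == pytest.approx(14.3, abs=1e-6)


class TestThreshold:
    def test_line_recovers_its_own_intercept(self):
        V = np.arange(0.0, 100.0, 2.0)
        iv = IVCurve(V, 3.0 * (V - 30.0))
        res = hv.vt_intercept(iv)
        assert res.V_T_mV == pytest.approx(30.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0)

    def test_subthreshold_only_curve_is_inapplicable(self):
        V = np.arange(-60.0, -20.0, 2.0)
        iv = IVCurve(V, np.zeros_like(V))
        with pytest.raises(MethodInapplicableError):
            hv.vt_intercept(iv)

    @pytest.mark.parametrize("k", [0.1, 10.0])
    def test_invariant_under_current_scaling(self, k):
        iv = _boltz_iv(44.8, 14.3, 0.0)
        base = hv.vt_intercept(iv).V_T_mV
        scaled = hv.vt_intercept(IVCurve(iv.V_mV, k * iv.I_pA)).V_T_mV
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_intercept_tracks_tangent_at_steepest_point(self):
        """Independent oracle: on a noiseless Boltzmann I-V the estimator's
        window straddles the curve's inflection, so its intercept matches the
        analytic tangent at the point of maximal slope."""
        for vh, s, vrev in [(44.8, 14.3, 0.0), (50.0, 10.0, -40.0), (30.0, 8.0, -60.0)]:
            V = np.linspace(vrev - 20.0, vh + 3 * s, 20001)
            I = 1.0 / (1.0 + np.exp((vh - V) / s)) * (V - vrev)
            dI = np.gradient(I, V)
            kstar = int(np.argmax(dI))
            oracle = V[kstar] - I[kstar] / dI[kstar]
            est = hv.vt_intercept(_boltz_iv(vh, s, vrev)).V_T_mV
            # the window fit is a chord, not the exact tangent: ~1 mV scale
            assert est == pytest.approx(oracle, abs=1.0)

    def test_closed_form_plug_in(self):
        fit = BoltzmannFit(1.0, 44.8, 14.3, 0, 0, 0, 0)
        res = hv.vt_from_fit(fit, V_rev_mV=0.0)
        assert res.a_dimensionless == pytest.approx(44.8 / (2 * 14.3), rel=1e-12)
        assert res.V_T_mV == pytest.approx(27.34, abs=0.01)

    def test_closed_form_equals_tangent_at_midpoint(self):
        """The closed form is algebraically the V-intercept of the I-V tangent
        at V_half; verify against a numerically computed tangent."""
        vh, s, vrev = 44.8, 14.3, -20.0
        eps = 1e-6
        def cur(v):
            return 1.0 / (1.0 + np.exp((vh - v) / s)) * (v - vrev)
        slope = (cur(vh + eps) - cur(vh - eps)) / (2 * eps)
        tangent_icpt = vh - cur(vh) / slope
        res = hv.vt_from_fit(BoltzmannFit(1.0, vh, s, 0, 0, 0, 0), vrev)
        assert res.V_T_mV == pytest.approx(tangent_icpt, abs=1e-6)

    def test_step_function_limit_approaches_midpoint(self):
        res = hv.vt_from_fit(BoltzmannFit(1.0, 44.8, 1e-6, 0, 0, 0, 0), 0.0)
        assert res.V_T_mV == pytest.approx(44.8, abs=1e-3)

    def test_reversal_at_midpoint_rejected(self):
        with pytest.raises(ParameterError):
            hv.vt_from_fit(BoltzmannFit(1.0, 44.8, 14.3, 0, 0, 0, 0), 44.8)

    @settings(derandomize=True, max_examples=50)
    @given(
        vh=st.floats(20.0, 80.0),
        s=st.floats(8.0, 20.0),
        vrev=st.floats(-60.0, 0.0),
    )
    def test_closed_form_threshold_lies_between_reversal_and_midpoint(self, vh, s, vrev):
        res = hv.vt_from_fit(BoltzmannFit(1.0, vh, s, 0, 0, 0, 0), vrev)
        assert vrev < res.V_T_mV < vh
        assert res.a_dimensionless > 0


class TestShiftAnalysis:
    @staticmethod
    def _vt(v):
        return hv.ThresholdResult(V_T_mV=v, method="intercept")

    def _symmetric(self, s_phi, ph_values=(5.5, 6.0, 6.5), v0=40.0):
        return [
            (self._vt(v0 + s_phi * (ph - 6.0)), hv.SolutionPair(ph, ph))
            for ph in ph_values
        ]

    def test_spruce_worked_example(self):
        """Shifts of -92 (ΔΔpH=+1) and +96 (ΔΔpH=-1) corrected by a 35 mV/pH
        symmetric shift give 59 mV per ΔpH unit."""
        vts = [
            (self._vt(30.0), hv.SolutionPair(6.0, 6.0)),
            (self._vt(30.0 - 92.0), hv.SolutionPair(5.0, 6.0)),
            (self._vt(30.0 + 96.0), hv.SolutionPair(7.0, 6.0)),
        ]
        res = hv.dpH_shift_analysis(vts, self._symmetric(-35.0))
        assert np.mean(np.abs(res.per_unit_shifts_mV)) == pytest.approx(94.0)
        assert res.corrected_per_dpH_mV == pytest.approx(59.0)

    def test_spikemoss_worked_example(self):
        vts = [
            (self._vt(20.0), hv.SolutionPair(6.0, 6.0)),
            (self._vt(20.0 - 76.0), hv.SolutionPair(5.0, 6.0)),
        ]
        res = hv.dpH_shift_analysis(vts, self._symmetric(-9.0))
        assert res.corrected_per_dpH_mV == pytest.approx(67.0)

    def test_zero_symmetric_shift_means_no_correction(self):
        vts = [
            (self._vt(10.0), hv.SolutionPair(6.0, 6.0)),
            (self._vt(-50.0), hv.SolutionPair(5.0, 6.0)),
        ]
        res = hv.dpH_shift_analysis(vts, self._symmetric(0.0))
        assert res.corrected_per_dpH_mV == pytest.approx(60.0)
        assert res.S_pHi_mV == pytest.approx(0.0)

    def test_requires_two_conditions_each(self):
        vts = [(self._vt(10.0), hv.SolutionPair(6.0, 6.0))]
        with pytest.raises(ParameterError):
            hv.dpH_shift_analysis(vts, self._symmetric(-35.0))
        with pytest.raises(ParameterError):
            hv.dpH_shift_analysis(
                [
                    (self._vt(10.0), hv.SolutionPair(6.0, 6.0)),
                    (self._vt(-50.0), hv.SolutionPair(5.0, 6.0)),
                ],
                [(self._vt(40.0), hv.SolutionPair(6.0, 6.0))],
            )

    def test_gradient_list_with_nonzero_symmetric_rejected(self):
        bad_sym = [
            (self._vt(40.0), hv.SolutionPair(6.0, 6.5)),
            (self._vt(20.0), hv.SolutionPair(6.0, 6.0)),
        ]
        vts = [
            (self._vt(10.0), hv.SolutionPair(6.0, 6.0)),
            (self._vt(-50.0), hv.SolutionPair(5.0, 6.0)),
        ]
        with pytest.raises(ParameterError):
            hv.dpH_shift_analysis(vts, bad_sym)

    def test_mixed_threshold_methods_warn(self):
        vts = [
            (hv.ThresholdResult(10.0, "closed_form", a_dimensionless=1.5), hv.SolutionPair(6.0, 6.0)),
            (self._vt(-50.0), hv.SolutionPair(5.0, 6.0)),
        ]
        res = hv.dpH_shift_analysis(vts, self._symmetric(-35.0))
        assert any("mixed" in w for w in res.warnings)
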