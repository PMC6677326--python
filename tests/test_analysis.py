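"""Analysis-layer tests: error metrics, foot detection, PWV, WIA."""

import numpy as np
import pytest

from circwave.analysis import (SignalTrace, detect_foot, error_metrics,
                               haemodynamic_indices, pulse_wave_velocity,
                               wave_intensity, wia_features)
from circwave.constitutive import MMHG

DT = 1e-3
RHO = 1050.0


def pulse_wave(n=850, t0=0.2, width=0.06, amp=10.0, dt=DT):
    """Smooth, exactly periodic pressure pulse (von-Mises-shaped bump)."""
    t = np.arange(n) * dt
    T = n * dt
    kappa = (T / (2.0 * np.pi * width)) ** 2
    return 100.0 + amp * np.exp(kappa * (np.cos(2 * np.pi * (t - t0) / T) - 1.0))


class TestErrorMetrics:
    def test_identical_traces_zero(self):
        a = SignalTrace(pulse_wave(), DT)
        eps, delta = error_metrics(a, a, "pressure")
        assert eps == 0.0 and delta == 0.0

    def test_constant_offset_closed_form(self):
        a = SignalTrace(np.full(100, 100.0), DT)
        b = SignalTrace(np.full(100, 101.0), DT)
        eps, delta = error_metrics(a, b, "pressure")
        assert eps == pytest.approx(1.0)
        assert delta == pytest.approx(100.0 / 101.0)  # ~1 %

    def test_flow_normalization_uses_reference_maximum(self):
        ref = SignalTrace(np.concatenate([np.full(50, 10.0), np.full(50, -2.0)]), DT)
        tl = SignalTrace(ref.samples + 0.5, DT)
        eps, delta = error_metrics(tl, ref, "flow")
        assert eps == pytest.approx(0.5)
        assert delta == pytest.approx(0.5 / 10.0 * 100.0)

    def test_rms_symmetric_relative_not(self):
        a = SignalTrace(pulse_wave(amp=10), DT)
        b = SignalTrace(pulse_wave(amp=12), DT)
        eps_ab, delta_ab = error_metrics(a, b, "pressure")
        eps_ba, delta_ba = error_metrics(b, a, "pressure")
        assert eps_ab == pytest.approx(eps_ba)
        assert delta_ab != delta_ba

    def test_zero_reference_pressure_rejected(self):
        a = SignalTrace(np.ones(10), DT)
        b = SignalTrace(np.concatenate([[0.0], np.ones(9)]), DT)
        with pytest.raises(ValueError):
            error_metrics(a, b, "pressure")


class TestFootDetection:
    def test_flat_then_parabolic_rise(self):
        # flat baseline, parabolic rise at t*, smooth return to baseline
        t = np.arange(850) * DT
        t_star = 0.3
        x = np.full(t.size, 80.0)
        rise = (t >= t_star) & (t < 0.55)
        x[rise] = 80.0 + 200.0 * (t[rise] - t_star) ** 2
        peak = 80.0 + 200.0 * 0.25**2
        fall = (t >= 0.55) & (t < 0.80)
        x[fall] = 80.0 + (peak - 80.0) * 0.5 * (
            1 + np.cos(np.pi * (t[fall] - 0.55) / 0.25))
        foot = detect_foot(SignalTrace(x, DT))
        assert foot == pytest.approx(t_star, abs=1.5 * DT)

    def test_shift_equivariance(self):
        p = SignalTrace(pulse_wave(), DT)
        tau = 0.11
        f0 = detect_foot(p)
        f1 = detect_foot(p.shifted(tau))
        assert (f1 - f0) % (p.samples.size * DT) == pytest.approx(tau, abs=1.5 * DT)

    def test_noise_robustness_with_smoothing(self):
        rng = np.random.default_rng(42)
        clean = pulse_wave(amp=40.0, width=0.03)  # brisk systolic upstroke
        noisy = clean + rng.normal(0.0, 0.1, clean.size)
        f_clean = detect_foot(SignalTrace(clean, DT))
        f_noisy = detect_foot(SignalTrace(noisy, DT), smooth=15)
        assert abs(f_noisy - f_clean) <= 2 * DT

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_foot(SignalTrace(np.full(100, 80.0), DT))


class TestPWV:
    def test_pure_delay(self):
        p = SignalTrace(pulse_wave(amp=40.0), DT)
        pd = p.shifted(0.1)
        assert pulse_wave_velocity(p, pd, 0.55) == pytest.approx(5.5, rel=1e-6)

    @pytest.mark.parametrize("delay_samples", [10, 25, 60, 120])
    def test_recovers_imposed_speed_within_one_percent(self, delay_samples):
        p = SignalTrace(pulse_wave(amp=40.0), DT)
        tau = delay_samples * DT
        path = 6.0 * tau  # impose 6 m/s
        pwv = pulse_wave_velocity(p, p.shifted(tau), path)
        assert pwv == pytest.approx(6.0, rel=0.01)

    def test_wraparound_delay(self):
        """Feet falling on opposite sides of the cycle boundary still give
        a positive transit time."""
        p = SignalTrace(pulse_wave(t0=0.8), DT)
        pd = p.shifted(0.1)  # foot wraps past t=0
        assert pulse_wave_velocity(p, pd, 0.6) == pytest.approx(6.0, rel=0.02)


class TestWaveIntensity:
    def _forward_pair(self, c=6.0):
        p = SignalTrace(pulse_wave(amp=10 * MMHG, t0=0.25), DT, "Pa")
        U = SignalTrace((p.samples - p.samples.min()) / (RHO * c), DT, "m/s")
        return p, U, c

    def test_pure_forward_wave_has_no_backward_intensity(self):
        p, U, c = self._forward_pair()
        res = wave_intensity(p, U, RHO, c)
        assert np.allclose(res.dI_minus.samples, 0.0, atol=1e-12)
        assert res.dI_plus.samples.max() > 0

    def test_pure_backward_wave_has_no_forward_intensity(self):
        p, U, c = self._forward_pair()
        U_back = SignalTrace(-U.samples, DT, "m/s")
        res = wave_intensity(p, U_back, RHO, c)
        assert np.allclose(res.dI_plus.samples, 0.0, atol=1e-12)
        assert res.dI_minus.samples.min() < 0

    def test_net_is_sum_of_components(self):
        rng = np.random.default_rng(7)
        p = SignalTrace(rng.normal(100 * MMHG, MMHG, 400), DT, "Pa")
        U = SignalTrace(rng.normal(0.2, 0.05, 400), DT, "m/s")
        res = wave_intensity(p, U, RHO, 6.0)
        assert np.allclose(res.dI_net.samples,
                           res.dI_plus.samples + res.dI_minus.samples,
                           rtol=1e-12, atol=1e-9)

    def test_signs(self):
        rng = np.random.default_rng(8)
        p = SignalTrace(rng.normal(100 * MMHG, MMHG, 400), DT, "Pa")
        U = SignalTrace(rng.normal(0.2, 0.05, 400), DT, "m/s")
        res = wave_intensity(p, U, RHO, 6.0)
        assert np.all(res.dI_plus.samples >= 0)
        assert np.all(res.dI_minus.samples <= 0)

    def test_nonpositive_wave_speed_rejected(self):
        p, U, _ = self._forward_pair()
        with pytest.raises(ValueError):
            wave_intensity(p, U, RHO, 0.0)


class TestWIAFeatures:
    def test_synthetic_lobe_recovery(self):
        t = np.arange(850) * DT
        fcw = 1e6 * np.exp(-0.5 * ((t - 0.22) / 0.015) ** 2)
        few = 4e5 * np.exp(-0.5 * ((t - 0.48) / 0.02) ** 2)
        bcw = -3e5 * np.exp(-0.5 * ((t - 0.30) / 0.02) ** 2)
        res_plus = SignalTrace(fcw + few, DT)
        res_minus = SignalTrace(bcw, DT)
        from circwave.analysis import WIAResult
        res = WIAResult(res_plus, res_minus,
                        SignalTrace(fcw + few + bcw, DT))
        feats = wia_features(res, ejection_onset=0.2)
        assert feats["peak_bcw"] == pytest.approx(3e5, rel=1e-3)
        assert feats["peak_fcw"] == pytest.approx(1e6, rel=1e-3)
        assert feats["peak_few"] == pytest.approx(4e5, rel=1e-3)
        # onset: 1% threshold of a Gaussian lobe sits ~3 sigma early
        assert feats["bcw_delay_s"] == pytest.approx(0.30 - 3.03 * 0.02 - 0.2,
                                                     abs=0.005)

    def test_no_backward_lobe_raises(self):
        from circwave.analysis import WIAResult
        z = SignalTrace(np.zeros(100), DT)
        pos = SignalTrace(np.ones(100), DT)
        with pytest.raises(ValueError):
            wia_features(WIAResult(pos, z, pos), 0.01)


class TestIndices:
    def test_constant_trace(self):
        ind = haemodynamic_indices(SignalTrace(np.full(100, 100.0 * MMHG), DT, "Pa"))
        assert (ind.p_sys, ind.p_dia, ind.p_pulse) == (100.0, 100.0, 0.0)

    def test_pulse_pressure_identity(self):
        ind = haemodynamic_indices(SignalTrace(pulse_wave() * MMHG, DT, "Pa"))
        assert ind.p_pulse == pytest.approx(ind.p_sys - ind.p_dia)
        assert ind.p_sys >= ind.p_dia
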