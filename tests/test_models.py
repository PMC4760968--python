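"""Biophysical model components: channel activation, currents, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cabayes.models import (BurstQGIFParams, CalciumParams, FHNParams,
                            NeuronModelSpec, QGIFParams, boltzmann_activation,
                            calcium_current, calcium_derivative,
                            fhn_derivatives, logistic, qgif_derivative,
                            resting_state)
from cabayes.simulate import StimulusProtocol, burst_sizes, simulate
from cabayes.observation import ObservationParams


class TestBoltzmannActivation:
    def test_midpoint_is_half(self):
        assert boltzmann_activation(-25.0, -25.0, 5.0) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert boltzmann_activation(1e4, -25.0, 5.0) == pytest.approx(1.0)
        assert boltzmann_activation(-1e4, -25.0, 5.0) == pytest.approx(0.0)

    def test_scalar_value(self):
        # 1/(1+e^4) at 20 mV below half-activation with 5 mV slope
        assert boltzmann_activation(-45.0, -25.0, 5.0) == pytest.approx(
            1.0 / (1.0 + np.exp(4.0)), rel=1e-12)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            boltzmann_activation(0.0, -25.0, 0.0)

    @given(st.floats(-200, 200), st.floats(-200, 200))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, v1, v2):
        lo, hi = sorted((v1, v2))
        a, b = boltzmann_activation(lo, -25.0, 5.0), boltzmann_activation(hi, -25.0, 5.0)
        assert 0.0 <= a <= b <= 1.0


class TestCalciumCurrent:
    def test_zero_at_reversal(self):
        p = CalciumParams()
        assert calcium_current(p.E_Ca, p) == pytest.approx(0.0)

    def test_half_activation(self):
        p = CalciumParams()
        expected = p.g_Ca * 0.5 * (p.V_half - p.E_Ca)
        assert calcium_current(p.V_half, p) == pytest.approx(expected)

    def test_scalar_value(self):
        p = CalciumParams(g_Ca=5.0, V_half=-25.0, rho=5.0, E_Ca=120.0)
        s = 1.0 / (1.0 + np.exp(-25.0 / 5.0))
        assert calcium_current(0.0, p) == pytest.approx(5.0 * s * (0.0 - 120.0))
        assert calcium_current(0.0, p) == pytest.approx(-595.98, abs=0.01)

    def test_inward_below_reversal(self):
        p = CalciumParams()
        V = np.linspace(-80, 100, 50)
        assert np.all(calcium_current(V, p) <= 0)


class TestCalciumKinetics:
    def test_fixed_point(self):
        p = CalciumParams()
        assert calcium_derivative(p.Ca_base, 0.0, p) == pytest.approx(0.0)

    def test_unit_decay(self):
        p = CalciumParams()
        assert calcium_derivative(p.Ca_base + p.tau_Ca, 0.0, p) == pytest.approx(-1.0)

    def test_influx_conversion(self):
        p = CalciumParams(kappa_Ca=0.002)
        assert calcium_derivative(p.Ca_base, -500.0, p) == pytest.approx(1.0)


class TestFHN:
    def test_cubic_origin(self):
        p = FHNParams()
        dV, dW = fhn_derivatives(0.0, 0.0, 0.0, p)
        assert dV == pytest.approx(0.0)
        assert dW == pytest.approx(p.lam * p.psi1)

    def test_resting_state_is_fixed_point(self):
        m = NeuronModelSpec("fhn", FHNParams(), CalciumParams(), dt=0.2)
        x = resting_state(m)
        dV, dW = fhn_derivatives(x[0], x[1], 0.0, m.neuron)
        assert abs(dV) < 1e-8 and abs(dW) < 1e-8

    def test_spike_peak_scaling(self):
        # a full spike peaks near +2, which the affine scaling maps to 20 mV
        p = FHNParams()
        assert p.iota1 * 2.0 - p.iota2 == pytest.approx(20.0)


class TestQGIF:
    def test_quadratic_vanishes_at_threshold(self):
        p = QGIFParams()
        # at V_th the net current is I - I_th (repolarization off far from peak)
        d = qgif_derivative(p.V_th, 0.0, p, 0.2)
        assert d == pytest.approx(-p.I_th / p.C)

    def test_repolarization_off_far_from_peak(self):
        from cabayes.models import _f_rep
        p = QGIFParams()
        assert _f_rep(-60.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_repolarization_full_at_peak(self):
        from cabayes.models import _f_rep
        p = QGIFParams()
        assert _f_rep(p.V_peak, p) == pytest.approx(p.I_rep_bar)

    def test_resting_state(self):
        m = NeuronModelSpec("qgif", QGIFParams(), CalciumParams(), dt=0.05)
        x = resting_state(m)
        expected = m.neuron.V_th - np.sqrt(
            2 * m.neuron.Delta_th * m.neuron.I_th / m.neuron.g_L)
        assert x[0] == pytest.approx(expected)

    def test_sustained_drive_spikes_periodically(self):
        # a 0.2 uA/cm^2 sustained depolarization produces repetitive firing
        # with peaks inside the repolarization gate, just below V_peak
        m = NeuronModelSpec("qgif", QGIFParams(), CalciumParams(), dt=0.05)
        r = simulate(m, StimulusProtocol.square_pulses([0.0], [3000.0], [0.2]),
                     T=3000.0, dt=0.05, dt_frame=1.0,
                     obs=ObservationParams())
        assert len(r.spike_times) >= 15
        isis = np.diff(r.spike_times)
        assert isis.std() / isis.mean() < 0.05  # periodic
        peaks = r.states[(r.states[:, 0] > 0), 0]
        assert np.all(np.abs(peaks.max() - m.neuron.V_peak) < 6.0)

    def test_rest_is_stable_without_input(self):
        m = NeuronModelSpec("qgif", QGIFParams(), CalciumParams(), dt=0.05)
        r = simulate(m, StimulusProtocol.zero(), T=2000.0, dt=0.05, dt_frame=1.0,
                     obs=ObservationParams())
        x0 = resting_state(m)
        assert np.max(np.abs(r.states[:, 0] - x0[0])) < 1e-6
        assert np.max(np.abs(r.states[:, 1] - x0[1])) < 1e-6


class TestBurstingQGIF:
    def test_gate_stays_in_unit_interval(self):
        # strictly inside (0, 1) wherever float64 can represent it, and never
        # outside [0, 1] even at saturation
        z_aux = np.linspace(-30, 30, 101)
        z = logistic(z_aux)
        assert np.all((z > 0) & (z < 1))
        z_ext = logistic(np.array([-1e6, 1e6]))
        assert np.all((z_ext >= 0) & (z_ext <= 1))

    def test_reduces_to_qgif_without_extra_currents(self):
        # with g_NaP = g_M = 0 the voltage path equals the plain QGIF's
        q = QGIFParams(I_rep_bar=87.0)
        b = BurstQGIFParams(I_rep_bar=87.0, g_M=0.0, g_NaP=0.0)
        mq = NeuronModelSpec("qgif", q, CalciumParams(), dt=0.05)
        mb = NeuronModelSpec("bursting_qgif", b, CalciumParams(), dt=0.05)
        prot = StimulusProtocol.square_pulses([50.0], [30.0], [1.0])
        rq = simulate(mq, prot, T=500.0, dt=0.05, dt_frame=1.0)
        rb = simulate(mb, prot, T=500.0, dt=0.05, dt_frame=1.0)
        # roundoff (1e-16) amplifies chaotically through the near-step
        # repolarization gate during spikes, so exact bit equality is not
        # attainable; the trajectories agree physically and spike identically
        np.testing.assert_allclose(rq.states[:, 0], rb.states[:, 0],
                                   rtol=0, atol=1e-3)
        np.testing.assert_allclose(rq.spike_times, rb.spike_times, atol=0.05)

    def test_persistent_sodium_increases_burstiness(self):
        sizes = {}
        for gnap in (0.3, 0.5):
            b = BurstQGIFParams(I_rep_bar=80.0, g_NaP=gnap)
            m = NeuronModelSpec("bursting_qgif", b, CalciumParams(tau_Ca=800.0),
                                dt=0.05)
            r = simulate(m, StimulusProtocol.square_pulses([50.0], [2000.0], [1.0]),
                         T=2100.0, dt=0.05, dt_frame=1.0)
            sizes[gnap] = np.mean(burst_sizes(r.spike_times, gap_ms=50.0))
        assert sizes[0.5] > sizes[0.3]

    def test_blocking_m_current_prolongs_burst(self):
        # a brief pulse elicits a short burst normally, but a long-lasting
        # discharge when the slow K+ current is removed
        dur = {}
        for gm in (1.0, 0.0):
            b = BurstQGIFParams(I_rep_bar=80.0, g_M=gm)
            m = NeuronModelSpec("bursting_qgif", b, CalciumParams(tau_Ca=800.0),
                                dt=0.05)
            r = simulate(m, StimulusProtocol.square_pulses([50.0], [30.0], [0.6]),
                         T=2500.0, dt=0.05, dt_frame=1.0)
            st_ = r.spike_times
            dur[gm] = (st_[-1] - st_[0]) if len(st_) > 1 else 0.0
        assert dur[0.0] > dur[1.0] + 100.0

    def test_resting_state_is_fixed_point(self):
        m = NeuronModelSpec("bursting_qgif", BurstQGIFParams(),
                            CalciumParams(tau_Ca=800.0), dt=0.05)
        x = resting_state(m)
        step = m.step(x, 0.0)
        assert np.max(np.abs(step - x)) < 1e-6


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        {"rho": -1.0}, {"tau_Ca": 0.0},
    ])
    def test_calcium_params_validated(self, kwargs):
        with pytest.raises(ValueError):
            CalciumParams(**kwargs)

    def test_unknown_model_name(self):
        with pytest.raises(ValueError):
            NeuronModelSpec("hodgkin_huxley", QGIFParams())
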