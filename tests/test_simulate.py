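"""Forward simulator: reproducibility, ground truth, noise, rise stretching."""

import numpy as np
import pytest

from cabayes.models import CalciumParams, NeuronModelSpec, QGIFParams
from cabayes.observation import ObservationParams, estimate_snr
from cabayes.simulate import (StimulusProtocol, add_noise, burst_sizes,
                              make_fixture, simulate, stretch_rise)


@pytest.fixture(scope="module")
def qgif_sim():
    m = NeuronModelSpec("qgif", QGIFParams(), CalciumParams(), dt=0.05)
    prot = StimulusProtocol.square_pulses([500.0, 2500.0, 4500.0],
                                          [10.0, 10.0, 10.0], [1.2, 1.2, 1.2])
    return simulate(m, prot, T=6000.0, dt=0.05, dt_frame=30.0,
                    obs=ObservationParams())


class TestSimulate:
    def test_bit_reproducible(self, qgif_sim):
        m = NeuronModelSpec("qgif", QGIFParams(), CalciumParams(), dt=0.05)
        prot = StimulusProtocol.square_pulses([500.0, 2500.0, 4500.0],
                                              [10.0, 10.0, 10.0], [1.2, 1.2, 1.2])
        again = simulate(m, prot, T=6000.0, dt=0.05, dt_frame=30.0,
                         obs=ObservationParams())
        np.testing.assert_array_equal(qgif_sim.states, again.states)
        np.testing.assert_array_equal(qgif_sim.trace.values, again.trace.values)

    def test_one_spike_per_pulse(self, qgif_sim):
        assert len(qgif_sim.spike_times) == 3

    def test_spike_times_match_voltage_maxima(self, qgif_sim):
        V = qgif_sim.states[:, 0]
        idx = (qgif_sim.spike_times / qgif_sim.dt).astype(int)
        assert np.all(V[idx] > 0)
        assert np.all(V[idx] >= V[idx - 1])

    def test_frame_grid_subsamples_fine_grid(self, qgif_sim):
        stride = round(30.0 / 0.05)
        from cabayes.observation import hill_observation
        expected = hill_observation(qgif_sim.states[::stride, -1],
                                    qgif_sim.obs)
        np.testing.assert_allclose(qgif_sim.trace.values, expected, rtol=0, atol=0)

    def test_zero_protocol_is_flat(self):
        m = NeuronModelSpec("qgif", QGIFParams(), CalciumParams(), dt=0.05)
        r = simulate(m, StimulusProtocol.zero(), T=3000.0, dt=0.05, dt_frame=30.0,
                     obs=ObservationParams())
        assert len(r.spike_times) == 0
        assert np.ptp(r.trace.values) < 1e-9

    def test_incommensurate_steps_rejected(self):
        m = NeuronModelSpec("qgif", QGIFParams(), CalciumParams(), dt=0.05)
        with pytest.raises(ValueError):
            simulate(m, StimulusProtocol.zero(), T=100.0, dt=0.05, dt_frame=30.03)

    def test_fast_integrator_matches_generic_step(self):
        # the plain-float inner loop must agree with the vectorized stepper
        for name in ("qgif", "fhn", "bursting_qgif"):
            from cabayes.defaults import default_parameters
            ps = default_parameters(name, "SIM")
            m = ps.model_spec()
            prot = StimulusProtocol.square_pulses([20.0], [10.0], [0.8])
            r = simulate(m, prot, T=60.0, dt=m.dt, dt_frame=m.dt, obs=ps.obs)
            x = __import__("cabayes.models", fromlist=["resting_state"]).resting_state(m)
            I = prot.current(np.arange(len(r.states)) * m.dt)
            for t in range(len(r.states)):
                x = m.step(x, I[t])
                np.testing.assert_allclose(x, r.states[t], rtol=1e-10, atol=1e-10)


class TestAddNoise:
    def test_same_seed_same_noise(self, qgif_sim):
        a = add_noise(qgif_sim.trace, 20.0, 5, qgif_sim.spike_times)
        b = add_noise(qgif_sim.trace, 20.0, 5, qgif_sim.spike_times)
        np.testing.assert_array_equal(a.values, b.values)

    def test_infinite_snr_is_identity(self, qgif_sim):
        out = add_noise(qgif_sim.trace, np.inf, 5, qgif_sim.spike_times)
        np.testing.assert_array_equal(out.values, qgif_sim.trace.values)

    def test_nonpositive_snr_rejected(self, qgif_sim):
        with pytest.raises(ValueError):
            add_noise(qgif_sim.trace, 0.0, 5, qgif_sim.spike_times)

    def test_target_snr_calibration(self):
        # measured SNR within the sampling band around the request (t1 scale)
        vals = [estimate_snr(make_fixture("qgif_fast_rise", s)["noisy"])
                for s in range(1, 21)]
        assert 24.0 <= np.mean(vals) <= 36.0


class TestStretchRise:
    def test_peaks_preserved(self, qgif_sim):
        out = stretch_rise(qgif_sim.trace, 400.0, qgif_sim.spike_times)
        for t_ev in qgif_sim.spike_times:
            i0 = int(t_ev / 30.0)
            orig = qgif_sim.trace.values[i0:i0 + 40].max()
            new = out.values[i0:i0 + 40].max()
            assert new == pytest.approx(orig, rel=0.01)

    def test_rise_duration_applied(self, qgif_sim):
        out = stretch_rise(qgif_sim.trace, 400.0, qgif_sim.spike_times)
        for t_ev in qgif_sim.spike_times:
            i0 = int(t_ev / 30.0)
            seg = out.values[i0:i0 + 40]
            t_peak = np.argmax(seg) * 30.0
            assert t_peak == pytest.approx(400.0, abs=35.0)

    def test_overlap_rejected(self, qgif_sim):
        with pytest.raises(ValueError):
            stretch_rise(qgif_sim.trace, 2500.0, qgif_sim.spike_times)


class TestFixtures:
    def test_named_fixture_spike_counts(self):
        assert len(make_fixture("qgif_fast_rise", 1)["sim"].spike_times) == 12
        assert len(make_fixture("fhn_low_snr", 1)["sim"].spike_times) == 13

    def test_burst_fixture_composition(self):
        fx = make_fixture("burst_700hz", 1)
        sizes = burst_sizes(fx["sim"].spike_times)
        assert sum(sizes) >= 10
        assert 2 in sizes and 3 in sizes and 1 in sizes

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            make_fixture("nonexistent", 1)

    def test_fixture_deterministic(self):
        a = make_fixture("qgif_fast_rise", 3)["noisy"].values
        b = make_fixture("qgif_fast_rise", 3)["noisy"].values
        np.testing.assert_array_equal(a, b)
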