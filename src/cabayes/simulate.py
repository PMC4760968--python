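"""Synthetic fluorescence-trace generation.

A forward simulation Euler-integrates one of the assembled generative models
at a fine time step, with zero state noise, under a stimulation protocol
(square current pulses or a sinusoid), passes the [Ca2+] trajectory through
the Hill observation mapping, and subsamples at the imaging frame rate.
Ground-truth spike times are recorded as local voltage maxima above a
model-appropriate threshold.  Gaussian background noise is added afterwards,
scaled to reach a requested SNR (minimum transient amplitude over baseline
standard deviation).  Transient rise times can be stretched by interpolation
to emulate the slow rise kinetics of immature neurons.

The per-model integrators below use plain-float inner loops (hundreds of
thousands of Euler steps are routine); they are cross-checked against
``NeuronModelSpec.step`` in the test suite.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .models import (
    BurstQGIFParams,
    CalciumParams,
    FHNParams,
    NeuronModelSpec,
    QGIFParams,
    resting_state,
)
from .observation import ObservationParams, Trace, hill_observation

__all__ = [
    "StimulusProtocol",
    "SimulationResult",
    "simulate",
    "add_noise",
    "stretch_rise",
    "FIXTURES",
    "make_fixture",
    "burst_sizes",
    "transient_amplitudes",
    "true_spike_times",
]

_V_GUARD = 500.0  # mV; |V| beyond this is treated as numerical blow-up


@dataclass
class StimulusProtocol:
    """Applied-current protocol u(t).

    ``square_pulses``: non-overlapping depolarizing pulses given by onsets,
    widths (ms) and amplitudes (uA/cm^2).  ``sinusoid``: amplitude * sin(w*t).
    """

    kind: str = "square_pulses"
    onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    widths: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitude: float = 0.0       # sinusoid amplitude
    angular_freq: float = 0.0    # rad/ms

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.kind == "square_pulses":
            order = np.argsort(self.onsets)
            self.onsets = self.onsets[order]
            self.widths = self.widths[order]
            self.amplitudes = self.amplitudes[order]
            ends = self.onsets + self.widths
            if np.any(self.onsets[1:] < ends[:-1]):
                raise ValueError("overlapping stimulus pulses")
        if not (np.all(np.isfinite(self.amplitudes)) and math.isfinite(self.amplitude)):
            raise ValueError("non-finite stimulus amplitude")

    @classmethod
    def square_pulses(cls, onsets, widths, amplitudes) -> "StimulusProtocol":
        return cls("square_pulses", onsets, widths, amplitudes)

    @classmethod
    def sinusoid(cls, amplitude: float, angular_freq: float) -> "StimulusProtocol":
        return cls("sinusoid", amplitude=amplitude, angular_freq=angular_freq)

    @classmethod
    def zero(cls) -> "StimulusProtocol":
        return cls("square_pulses")

    def current(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(self.angular_freq * times)
        I = np.zeros_like(times)
        for o, w, a in zip(self.onsets, self.widths, self.amplitudes):
            I[(times >= o) & (times < o + w)] += a
        return I


@dataclass
class SimulationResult:
    model: NeuronModelSpec
    obs: ObservationParams
    protocol: StimulusProtocol
    dt: float                 # fine step, ms
    states: np.ndarray        # (n_steps, n_states) fine-grid trajectory
    trace: Trace              # noise-free frame-grid fluorescence
    spike_times: np.ndarray   # ms, fine-grid ground truth
    seed: int | None = None

    @property
    def fine_times(self) -> np.ndarray:
        return np.arange(self.states.shape[0]) * self.dt


def _safe_exp(x: float) -> float:
    return math.exp(min(max(x, -700.0), 700.0))


def _frep(V: float, p: QGIFParams) -> float:
    G = p.a_rep / (p.sigma_peak * math.sqrt(math.pi)) * _safe_exp(
        -((V - p.V_peak) / p.sigma_peak) ** 2
    )
    return p.I_rep_bar / (1.0 + _safe_exp(-p.b_rep * (G - p.c_rep)))


def _integrate(model: NeuronModelSpec, I: np.ndarray, dt: float, x0: np.ndarray) -> np.ndarray:
    """Forward-Euler integration with zero state noise; raises on blow-up."""
    n = len(I)
    c = model.calcium
    out = np.empty((n, model.n_states))
    if model.name == "fhn":
        p: FHNParams = model.neuron
        V, W, Ca = map(float, x0)
        for t in range(n):
            Vs = p.iota1 * V - p.iota2
            s = 1.0 / (1.0 + _safe_exp(-(Vs - c.V_half) / c.rho))
            ICa = c.g_Ca * s * (Vs - c.E_Ca)
            dV = V - V ** 3 / 3.0 - W + I[t]
            dW = p.lam * (V + p.psi1 - p.psi2 * W)
            Ca += dt * (-c.kappa_Ca * ICa - (Ca - c.Ca_base) / c.tau_Ca)
            V += dt * dV
            W += dt * dW
            out[t, 0], out[t, 1], out[t, 2] = V, W, Ca
    elif model.name == "qgif":
        p = model.neuron
        V, Ca = map(float, x0)
        a_quad = p.g_L / (2.0 * p.Delta_th)
        for t in range(n):
            s = 1.0 / (1.0 + _safe_exp(-(V - c.V_half) / c.rho))
            ICa = c.g_Ca * s * (V - c.E_Ca)
            Ca += dt * (-c.kappa_Ca * ICa - (Ca - c.Ca_base) / c.tau_Ca)
            V += dt * ((I[t] + a_quad * (V - p.V_th) ** 2 - p.I_th) / p.C) - _frep(V, p)
            if abs(V) > _V_GUARD:
                raise RuntimeError(f"integration blow-up (|V| > {_V_GUARD} mV) at t = {t * dt:.2f} ms")
            out[t, 0], out[t, 1] = V, Ca
    else:
        p: BurstQGIFParams = model.neuron
        V, z_aux, Ca = map(float, x0)
        a_quad = p.g_L / (2.0 * p.Delta_th)
        for t in range(n):
            s = 1.0 / (1.0 + _safe_exp(-(V - c.V_half) / c.rho))
            ICa = c.g_Ca * s * (V - c.E_Ca)
            z = 1.0 / (1.0 + _safe_exp(-z_aux))
            r_inf = 1.0 / (1.0 + _safe_exp(-(V - p.r_half) / p.r_slope))
            z_inf = 1.0 / (1.0 + _safe_exp(-(V - p.z_half) / p.z_slope))
            I_NaP = p.g_NaP * r_inf * (V - p.E_Na)
            I_M = p.g_M * z * (V - p.E_K)
            Ca += dt * (-c.kappa_Ca * ICa - (Ca - c.Ca_base) / c.tau_Ca)
            V_new = V + dt * ((I[t] + a_quad * (V - p.V_th) ** 2 - p.I_th - I_NaP - I_M) / p.C) - _frep(V, p)
            z_aux += dt / p.tau_z * (z_inf - z) / max(z - z * z + p.O, 1e-9)
            V = V_new
            if abs(V) > _V_GUARD:
                raise RuntimeError(f"integration blow-up (|V| > {_V_GUARD} mV) at t = {t * dt:.2f} ms")
            out[t, 0], out[t, 1], out[t, 2] = V, z_aux, Ca
    return out


def true_spike_times(V: np.ndarray, dt: float, threshold: float) -> np.ndarray:
    """Local maxima of the fine-grid voltage above threshold, in ms."""
    idx = np.flatnonzero((V[1:-1] > threshold) & (V[1:-1] >= V[:-2]) & (V[1:-1] > V[2:])) + 1
    return idx * dt


def simulate(model: NeuronModelSpec, protocol: StimulusProtocol, T: float,
             dt: float | None = None, dt_frame: float = 30.03,
             obs: ObservationParams | None = None, seed: int | None = None) -> SimulationResult:
    """Generate a noise-free fluorescence trace plus ground truth.

    ``T`` is the duration in ms, ``dt`` the fine integration step and
    ``dt_frame`` the imaging frame interval; ``dt`` must divide ``dt_frame``
    within rounding tolerance.  Initial conditions are the model's resting
    state.  The simulation is deterministic; ``seed`` is recorded for the
    downstream noise stage.
    """
    dt = model.dt if dt is None else dt
    stride = dt_frame / dt
    if abs(stride - round(stride)) > 1e-6:
        raise ValueError(f"fine step {dt} must divide frame interval {dt_frame}")
    stride = int(round(stride))
    obs = obs or ObservationParams()
    n = int(round(T / dt))
    times = np.arange(n) * dt
    I = protocol.current(times)
    x0 = resting_state(model)
    states = _integrate(model, I, dt, x0)
    thr = 1.0 if model.name == "fhn" else 0.0
    spikes = true_spike_times(states[:, 0], dt, thr)
    frame_idx = np.arange(0, n, stride)
    F = hill_observation(states[frame_idx, -1], obs)
    trace = Trace(F, dt_frame, meta={"model": model.name, "seed": seed, "clean": True})
    return SimulationResult(model, obs, protocol, dt, states, trace, spikes, seed)


def _event_groups(spike_times: np.ndarray, gap_ms: float = 300.0) -> list[np.ndarray]:
    """Group spikes separated by less than ``gap_ms`` into one transient-evoking event."""
    if len(spike_times) == 0:
        return []
    splits = np.flatnonzero(np.diff(spike_times) > gap_ms) + 1
    return np.split(np.asarray(spike_times, dtype=float), splits)


def transient_amplitudes(trace: Trace, event_times: np.ndarray,
                         gap_ms: float = 300.0) -> np.ndarray:
    """Per-event transient amplitude: peak minus the pre-onset level.

    ``event_times`` are ground-truth spike times (ms); spikes closer than
    ``gap_ms`` count as a single (burst) event.
    """
    groups = _event_groups(np.asarray(event_times, dtype=float), gap_ms)
    if not groups:
        raise ValueError("trace has no events; transient amplitude undefined")
    onsets = [g[0] for g in groups]
    bounds = onsets[1:] + [len(trace.values) * trace.dt_frame]
    amps = []
    for onset, end in zip(onsets, bounds):
        i0 = int(onset / trace.dt_frame)
        i1 = max(i0 + 2, int(min(end, onset + 1500.0) / trace.dt_frame))
        pre = trace.values[max(i0 - 1, 0)]
        amps.append(float(np.max(trace.values[i0:i1 + 1]) - pre))
    return np.asarray(amps)


def add_noise(t: Trace, target_snr: float, seed: int | None,
              event_times: np.ndarray | None = None) -> Trace:
    """Add zero-mean Gaussian background noise scaled to a target SNR.

    The noise standard deviation is (minimum transient amplitude)/target_snr,
    so the measured SNR (min amplitude over baseline std) approximates the
    request.  ``target_snr = inf`` returns the trace unchanged.  Deterministic
    given ``seed``.
    """
    if not target_snr > 0:
        raise ValueError("target_snr must be > 0")
    if math.isinf(target_snr):
        return replace(t, values=t.values.copy())
    if event_times is not None and len(event_times) > 0:
        amps = transient_amplitudes(t, event_times)
    else:
        rng_vals = t.values - np.median(t.values[t.baseline_slice()])
        m = float(np.max(rng_vals))
        if m <= 0:
            raise ValueError("trace has no transient; cannot target an SNR")
        amps = np.array([m])
    sd = float(np.min(amps)) / target_snr
    rng = np.random.default_rng(seed)
    noisy = t.values + rng.normal(0.0, sd, size=len(t.values))
    return replace(t, values=noisy,
                   meta={**t.meta, "target_snr": target_snr, "noise_sd": sd, "clean": False})


def stretch_rise(t: Trace, rise_duration, event_times: np.ndarray,
                 gap_ms: float = 300.0) -> Trace:
    """Stretch each transient's rising phase to ``rise_duration`` ms.

    The original rising segment (event onset to transient peak) is replaced by
    a time-rescaled interpolation of itself lasting ``rise_duration``; the
    peak value and the decay segment are preserved (the decay is shifted to
    start at the new peak time and truncated at the next event onset).
    ``rise_duration`` may be a scalar or one value per event.  Raises if a
    stretched rise would overlap the next event.
    """
    groups = _event_groups(np.asarray(event_times, dtype=float), gap_ms)
    if not groups:
        raise ValueError("no events to stretch")
    onsets = np.array([g[0] for g in groups])
    durs = np.broadcast_to(np.asarray(rise_duration, dtype=float), (len(onsets),))
    vals = t.values.copy()
    n = len(vals)
    bounds = list(onsets[1:] / t.dt_frame) + [n]
    for onset, dur, bound in zip(onsets, durs, bounds):
        i0 = int(onset / t.dt_frame)
        i_end = int(bound)
        if dur >= (i_end - i0) * t.dt_frame:
            raise ValueError(
                f"rise duration {dur} ms overlaps the next event after onset {onset:.0f} ms"
            )
        seg = t.values[i0:i_end]
        ip = i0 + int(np.argmax(seg))
        new_ip = i0 + max(1, int(round(dur / t.dt_frame)))
        if new_ip >= i_end:
            raise ValueError("stretched rise exceeds inter-event interval")
        # time-rescaled interpolation of the original rise, forced monotone
        orig_t = np.linspace(0.0, 1.0, max(ip - i0 + 1, 2))
        orig_v = np.maximum.accumulate(t.values[i0:max(ip, i0 + 1) + 1])
        new_t = np.linspace(0.0, 1.0, new_ip - i0 + 1)
        vals[i0:new_ip + 1] = np.interp(new_t, orig_t, orig_v)
        # decay segment shifted to follow the new peak
        decay = t.values[ip:i_end]
        keep = min(len(decay), i_end - new_ip)
        vals[new_ip:new_ip + keep] = decay[:keep]
        if new_ip + keep < i_end:
            vals[new_ip + keep:i_end] = decay[-1] if keep else t.values[ip]
    return replace(t, values=vals, meta={**t.meta, "stretched_rise": True})


# ---------------------------------------------------------------------------
# Named fixtures: the study conditions used throughout the test suite and the
# reproduction script.  Each returns the simulation result plus the noisy
# trace; everything is deterministic given the seed.
# ---------------------------------------------------------------------------

FIXTURES = (
    "qgif_fast_rise",
    "fhn_fast_rise",
    "fhn_low_snr",
    "qgif_slow_rise",
    "burst_700hz",
    "tau_change_control",
    "tau_change_treated",
    "gm_change_high",
    "gm_change_low",
)

#: pulse shapes (amplitude uA/cm^2, width ms) producing a given number of
#: spikes in the bursting model under its simulation defaults
_BURST_SHAPES = {1: (0.6, 40.0), 2: (0.8, 40.0), 3: (0.68, 80.0), 5: (1.0, 40.0)}


def _spaced_pulses(rng, n, start, spacing, jitter, amp_range, width_range):
    onsets = start + np.arange(n) * spacing + rng.uniform(-jitter, jitter, n)
    amps = rng.uniform(*amp_range, n)
    widths = rng.uniform(*width_range, n)
    return StimulusProtocol.square_pulses(onsets, widths, amps)


def make_fixture(name: str, seed: int = 1) -> dict:
    """Build one named synthetic dataset.

    Returns a dict with the noise-free :class:`SimulationResult` (``sim``),
    the noisy frame-grid trace (``noisy``), the target SNR, and the SIM/INV
    parameter sets used to generate and to invert it.
    """
    from .defaults import default_parameters

    rng = np.random.default_rng(seed)
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")

    if name in ("qgif_fast_rise", "qgif_slow_rise"):
        ps = default_parameters("qgif", "SIM")
        prot = _spaced_pulses(rng, 12, 3500.0, 2150.0, 150.0, (1.0, 1.8), (8.0, 15.0))
        sim = simulate(ps.model_spec(), prot, T=30000.0, dt=ps.dt_sim,
                       dt_frame=30.0, obs=ps.obs, seed=seed)
        snr = 30.0
        clean = sim.trace
        if name == "qgif_slow_rise":
            rises = rng.uniform(200.0, 450.0, 12)
            clean = stretch_rise(clean, rises, sim.spike_times)
            sim = SimulationResult(sim.model, sim.obs, sim.protocol, sim.dt,
                                   sim.states, clean, sim.spike_times, seed)
            snr = 25.0
        noisy = add_noise(clean, snr, seed, sim.spike_times)
        inv = default_parameters("qgif", "INV")

    elif name in ("fhn_fast_rise", "fhn_low_snr"):
        ps = default_parameters("fhn", "SIM")
        prot = _spaced_pulses(rng, 13, 3300.0, 2050.0, 150.0, (0.4, 0.7), (8.0, 15.0))
        sim = simulate(ps.model_spec(), prot, T=30000.0, dt=ps.dt_sim,
                       dt_frame=30.0, obs=ps.obs, seed=seed)
        snr = 20.0 if name == "fhn_fast_rise" else 2.5
        noisy = add_noise(sim.trace, snr, seed, sim.spike_times)
        inv = default_parameters("fhn", "INV")

    elif name == "burst_700hz":
        ps = default_parameters("bursting_qgif", "SIM")
        counts = [1, 2, 3, 5, 1, 2, 1]
        onsets = [600.0, 1300.0, 2000.0, 2700.0, 3500.0, 4100.0, 4600.0]
        amps = [_BURST_SHAPES[c][0] for c in counts]
        widths = [_BURST_SHAPES[c][1] for c in counts]
        prot = StimulusProtocol.square_pulses(onsets, widths, amps)
        sim = simulate(ps.model_spec(), prot, T=5000.0, dt=ps.dt_sim,
                       dt_frame=1.4, obs=ps.obs, seed=seed)
        snr = 3.0
        noisy = add_noise(sim.trace, snr, seed, sim.spike_times)
        inv = default_parameters("bursting_qgif", "INV")

    elif name.startswith("tau_change"):
        ps = default_parameters("fhn", "SIM")
        tau = 600.0 if name.endswith("control") else 6000.0
        ps.calcium = replace(ps.calcium, tau_Ca=tau)
        prot = _spaced_pulses(rng, 5, 5000.0, 8600.0, 300.0, (0.45, 0.6), (8.0, 12.0))
        sim = simulate(ps.model_spec(), prot, T=45000.0, dt=ps.dt_sim,
                       dt_frame=30.0, obs=ps.obs, seed=seed)
        snr = 20.0
        noisy = add_noise(sim.trace, snr, seed, sim.spike_times)
        inv = default_parameters("fhn", "INV")
        inv.tau_Ca_real = 1000.0 if name.endswith("control") else 9000.0
        inv.Ups_y = 5.0

    else:  # gm_change_high / gm_change_low
        ps = default_parameters("bursting_qgif", "SIM")
        g_M = 0.8 if name.endswith("high") else 0.45
        ps.neuron = replace(ps.neuron, g_M=g_M, g_NaP=0.18, g_L=0.01)
        ps.calcium = replace(ps.calcium, tau_Ca=500.0)
        ps.obs = replace(ps.obs, kappa_F=1.0, K_d=150.0)
        ps.tau_Ca_real = 500.0
        prot = StimulusProtocol.sinusoid(0.74, 0.003)
        sim = simulate(ps.model_spec(), prot, T=3200.0, dt=ps.dt_sim,
                       dt_frame=0.5, obs=ps.obs, seed=seed)
        snr = 20.0
        noisy = add_noise(sim.trace, snr, seed, sim.spike_times)
        # inversion uses the true (simulation) parameterization with only g_M
        # and the initial conditions free
        inv = copy.deepcopy(ps)
        inv.role = "INV"
        inv.free = ["g_M"]

    return {"name": name, "sim": sim, "noisy": noisy, "target_snr": snr,
            "sim_set": ps, "inv_set": inv, "seed": seed}


def burst_sizes(spike_times, gap_ms: float = 300.0) -> list:
    """Spikes per burst: spike times clustered by inter-spike gaps."""
    groups = _event_groups(np.asarray(spike_times, dtype=float), gap_ms)
    return [len(g) for g in groups]
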