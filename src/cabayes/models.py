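"""Biophysical generative models: spiking dynamics, HVA calcium channel, [Ca2+] kinetics.

Three differentiable single-compartment spiking models are provided:

* ``fhn`` -- FitzHugh-Nagumo, a 2D reduction of Hodgkin-Huxley with a cubic
  voltage nullcline and a linear recovery variable.  Voltage is dimensionless;
  a full spike peaks near +2 and undershoots near -2.
* ``qgif`` -- quadratic-Gaussian integrate-and-fire: a quadratic spike-generating
  current plus a smooth, Gaussian-gated repolarization current, so spikes are
  produced without any discontinuous reset.
* ``bursting_qgif`` -- the QGIF extended with a persistent Na+ current (burst
  promotion) and a slow M-type K+ current (burst termination), with the M-gate
  propagated through a logistic transform so its activation stays in (0, 1).

Voltage feeds a high-voltage-activated (L-type) calcium channel with Boltzmann
activation; the resulting current drives first-order [Ca2+] kinetics that decay
back to a basal concentration.  All step/derivative functions broadcast over
numpy arrays so that whole trajectories of linearization points can be pushed
through at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FHNParams",
    "QGIFParams",
    "BurstQGIFParams",
    "CalciumParams",
    "NeuronModelSpec",
    "boltzmann_activation",
    "calcium_current",
    "calcium_derivative",
    "fhn_derivatives",
    "qgif_derivative",
    "qgif_step",
    "bursting_qgif_step",
    "resting_state",
    "logistic",
]

_EXP_CLIP = 700.0  # exp() overflow guard


def logistic(x):
    """Numerically safe logistic 1/(1+exp(-x)); maps all finite x into (0, 1)."""
    return 1.0 / (1.0 + np.exp(np.clip(-np.asarray(x, dtype=float), -_EXP_CLIP, _EXP_CLIP)))


@dataclass
class FHNParams:
    """FitzHugh-Nagumo constants (dimensionless) and the affine voltage scaling
    ``iota1*V - iota2`` used only where voltage feeds the calcium channel."""

    psi1: float = 0.7
    psi2: float = 0.8
    lam: float = 0.08
    iota1: float = 30.0  # mV per voltage unit
    iota2: float = 40.0  # mV

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("FHN rate constant lam must be > 0")
        if self.iota1 <= 0:
            raise ValueError("voltage scale iota1 must be > 0")


@dataclass
class QGIFParams:
    """Quadratic-Gaussian integrate-and-fire parameters.

    The repolarization current ``f_rep`` is a steep sigmoid of a delta-like
    Gaussian bump centred on the spike peak; per Euler step it pulls the
    membrane potential down by ``I_rep_bar`` millivolts, which places the
    after-spike potential below rest (the hyperpolarization phase).
    ``E_L`` only shifts the leak current, which cancels against the leak term
    inside the quadratic spike current, so the resting potential is
    ``V_th - sqrt(2*Delta_th*I_th/g_L)`` independent of ``E_L``.
    """

    C: float = 1.0          # uF/cm^2
    g_L: float = 0.1        # mS/cm^2
    E_L: float = -65.0      # mV (kept for completeness; cancels analytically)
    V_th: float = -59.9     # mV
    I_th: float = 0.16      # uA/cm^2
    Delta_th: float = 3.48  # mV
    V_peak: float = 30.0    # mV
    sigma_peak: float = 1.0  # mV
    a_rep: float = 1e12     # mV
    b_rep: float = 1e4
    c_rep: float = 0.1
    I_rep_bar: float = 120.0  # repolarization size (mV per step)

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("capacitance C must be > 0")
        if self.g_L < 0:
            raise ValueError("leak conductance g_L must be >= 0")
        if self.Delta_th <= 0:
            raise ValueError("slope factor Delta_th must be > 0")
        if self.sigma_peak <= 0:
            raise ValueError("sigma_peak must be > 0")


@dataclass
class BurstQGIFParams(QGIFParams):
    """QGIF plus M-type K+ and persistent Na+ currents.

    The gating steady states are Boltzmann functions with configurable
    half-activation and slope; ``tau_z`` is the (fixed) M-gate time constant.
    ``O`` is a numerical-stability constant added to the ``z - z^2``
    denominator of the logistic-transformed gate update.
    """

    I_rep_bar: float = 87.0
    g_M: float = 1.0       # mS/cm^2
    g_NaP: float = 0.41    # mS/cm^2
    E_K: float = -90.0     # mV
    E_Na: float = 55.0     # mV
    tau_z: float = 75.0    # ms
    O: float = 0.0
    r_half: float = -41.0  # mV, persistent-Na activation midpoint
    r_slope: float = 3.0   # mV
    z_half: float = -39.0  # mV, M-gate activation midpoint
    z_slope: float = 5.0   # mV

    def __post_init__(self):
        super().__post_init__()
        if self.g_M < 0 or self.g_NaP < 0:
            raise ValueError("conductances g_M, g_NaP must be >= 0")
        if self.tau_z <= 0:
            raise ValueError("gating time constant tau_z must be > 0")


@dataclass
class CalciumParams:
    """HVA calcium channel and first-order [Ca2+] kinetics."""

    g_Ca: float = 5.0       # mS/cm^2
    E_Ca: float = 120.0     # mV
    V_half: float = -25.0   # mV
    rho: float = 5.0        # mV
    kappa_Ca: float = 0.002  # current-to-concentration conversion
    tau_Ca: float = 2000.0  # ms
    Ca_base: float = 0.0    # nM

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("Boltzmann slope factor rho must be > 0")
        if self.tau_Ca <= 0:
            raise ValueError("decay time constant tau_Ca must be > 0")


def boltzmann_activation(V, V_half, rho):
    """Steady-state channel activation 1/(1+exp(-(V - V_half)/rho)), in (0, 1)."""
    if rho <= 0:
        raise ValueError("Boltzmann slope factor rho must be > 0")
    return logistic((np.asarray(V, dtype=float) - V_half) / rho)


def calcium_current(V, p: CalciumParams, *, kwargs: Mapping | None = None):
    """HVA calcium current I_Ca = g_Ca * s_inf(V) * (V - E_Ca) in uA/cm^2.

    Negative (inward) for V < E_Ca.
    """
    s = boltzmann_activation(V, p.V_half, p.rho)
    return p.g_Ca * s * (np.asarray(V, dtype=float) - p.E_Ca)


def calcium_derivative(Ca, I_Ca, p: CalciumParams, *, tau_Ca=None, kappa_Ca=None, Ca_base=None):
    """d[Ca2+]/dt = -kappa_Ca*I_Ca - (Ca - Ca_base)/tau_Ca  (nM/ms).

    Keyword overrides let the inversion inject free-parameter values (e.g. a
    frame-rescaled tau_Ca) without mutating the parameter set.
    """
    tau = p.tau_Ca if tau_Ca is None else tau_Ca
    kap = p.kappa_Ca if kappa_Ca is None else kappa_Ca
    base = p.Ca_base if Ca_base is None else Ca_base
    return -kap * np.asarray(I_Ca, dtype=float) - (np.asarray(Ca, dtype=float) - base) / tau


def fhn_derivatives(V, W, I, p: FHNParams):
    """FitzHugh-Nagumo right-hand sides (dV/dt, dW/dt)."""
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    dV = V - V ** 3 / 3.0 - W + I
    dW = p.lam * (V + p.psi1 - p.psi2 * W)
    return dV, dW


def _f_sp(V, p: QGIFParams):
    """Quadratic spike-generating current minus threshold current, net of leak.

    Returns f_sp(V) - I_L = g_L/(2*Delta_th)*(V - V_th)^2 - I_th; the leak
    current inside f_sp cancels the explicit leak term of the balance equation.
    """
    return p.g_L / (2.0 * p.Delta_th) * (V - p.V_th) ** 2 - p.I_th


def _f_rep(V, p: QGIFParams):
    """Repolarization current: steep sigmoid of a delta-like Gaussian at V_peak.

    Approximately I_rep_bar within ~5 sigma_peak of the peak and 0 elsewhere.
    """
    G = p.a_rep / (p.sigma_peak * np.sqrt(np.pi)) * np.exp(
        -(((np.asarray(V, dtype=float) - p.V_peak) / p.sigma_peak) ** 2)
    )
    return p.I_rep_bar * logistic(p.b_rep * (G - p.c_rep))


def qgif_derivative(V, I, p: QGIFParams, dt: float, *, Delta_th=None):
    """QGIF dV/dt in mV/ms for an Euler step of size dt.

    The repolarization term is scaled by gamma = C/dt so that one Euler step
    near the spike peak drops the potential by I_rep_bar millivolts regardless
    of the step size.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    V = np.asarray(V, dtype=float)
    if Delta_th is None:
        quad = _f_sp(V, p)
    else:
        quad = p.g_L / (2.0 * Delta_th) * (V - p.V_th) ** 2 - p.I_th
    return (I + quad) / p.C - _f_rep(V, p) / dt


def qgif_step(V, I, p: QGIFParams, dt: float, *, Delta_th=None):
    """Forward-Euler step of the QGIF voltage."""
    return np.asarray(V, dtype=float) + dt * qgif_derivative(V, I, p, dt, Delta_th=Delta_th)


def bursting_qgif_step(V, z_aux, I, p: BurstQGIFParams, dt: float, *,
                       Delta_th=None, g_NaP=None, g_M=None):
    """One Euler step of the bursting-QGIF (V, z_aux) pair.

    The M-gate activation z = logistic(z_aux) stays in (0, 1) for all finite
    z_aux.  The z_aux update divides by z - z^2 + O (the chain-rule factor of
    the logit transform); the denominator is clamped at 1e-9 below so the
    update remains finite when z saturates and O = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    V = np.asarray(V, dtype=float)
    z_aux = np.asarray(z_aux, dtype=float)
    gnap = p.g_NaP if g_NaP is None else g_NaP
    gm = p.g_M if g_M is None else g_M
    z = logistic(z_aux)
    r_inf = boltzmann_activation(V, p.r_half, p.r_slope)
    z_inf = boltzmann_activation(V, p.z_half, p.z_slope)
    I_NaP = gnap * r_inf * (V - p.E_Na)
    I_M = gm * z * (V - p.E_K)
    if Delta_th is None:
        quad = _f_sp(V, p)
    else:
        quad = p.g_L / (2.0 * Delta_th) * (V - p.V_th) ** 2 - p.I_th
    V_next = V + dt * ((I + quad - I_NaP - I_M) / p.C) - _f_rep(V, p)
    denom = np.maximum(z - z * z + p.O, 1e-9)
    z_aux_next = z_aux + dt / p.tau_z * (z_inf - z) / denom
    return V_next, z_aux_next


@dataclass
class NeuronModelSpec:
    """A fully assembled generative model: spiking dynamics + calcium channel
    + [Ca2+] kinetics (+ fluorescence observation handled separately).

    ``state_names`` orders the hidden state vector; the membrane potential is
    always first and [Ca2+] last.
    """

    name: str
    neuron: FHNParams | QGIFParams | BurstQGIFParams
    calcium: CalciumParams = field(default_factory=CalciumParams)
    dt: float = 0.2  # ms, fine integration step

    def __post_init__(self):
        if self.name not in ("fhn", "qgif", "bursting_qgif"):
            raise ValueError(f"unknown model name: {self.name!r}")

    @property
    def state_names(self) -> tuple[str, ...]:
        return {
            "fhn": ("V", "W", "Ca"),
            "qgif": ("V", "Ca"),
            "bursting_qgif": ("V", "z_aux", "Ca"),
        }[self.name]

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def scaled_voltage(self, V):
        """Voltage as seen by the calcium channel (mV); affine-scaled for FHN."""
        if self.name == "fhn":
            return self.neuron.iota1 * np.asarray(V, dtype=float) - self.neuron.iota2
        return np.asarray(V, dtype=float)

    def step(self, x, I, dt: float | None = None, overrides: Mapping | None = None):
        """One Euler step of the full state vector.

        ``x`` has the state components along the last axis and broadcasts over
        any leading axes.  ``overrides`` maps free-parameter names (tau_Ca,
        kappa_Ca, Ca_base, Delta_th, g_NaP, g_M) to values used in place of
        the stored defaults; this is how the inversion injects its current
        parameter estimates.
        """
        dt = self.dt if dt is None else dt
        ov = dict(overrides or {})
        x = np.asarray(x, dtype=float)
        V = x[..., 0]
        Ca = x[..., -1]
        if self.name == "fhn":
            W = x[..., 1]
            dV, dW = fhn_derivatives(V, W, I, self.neuron)
            V_next = V + dt * dV
            W_next = W + dt * dW
            rest = (W_next,)
        elif self.name == "qgif":
            V_next = qgif_step(V, I, self.neuron, dt, Delta_th=ov.get("Delta_th"))
            rest = ()
        else:
            V_next, z_next = bursting_qgif_step(
                V, x[..., 1], I, self.neuron, dt,
                Delta_th=ov.get("Delta_th"), g_NaP=ov.get("g_NaP"), g_M=ov.get("g_M"),
            )
            rest = (z_next,)
        I_Ca = calcium_current(self.scaled_voltage(V), self.calcium)
        Ca_next = Ca + dt * calcium_derivative(
            Ca, I_Ca, self.calcium,
            tau_Ca=ov.get("tau_Ca"), kappa_Ca=ov.get("kappa_Ca"), Ca_base=ov.get("Ca_base"),
        )
        return np.stack((V_next, *rest, Ca_next), axis=-1)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "dt": self.dt,
            "neuron": asdict(self.neuron),
            "calcium": asdict(self.calcium),
        }


def _qgif_rest_voltage(p: QGIFParams) -> float:
    return p.V_th - np.sqrt(2.0 * p.Delta_th * p.I_th / p.g_L)


def resting_state(model: NeuronModelSpec, tol: float = 1e-8) -> np.ndarray:
    """Steady state of the assembled model at zero input current.

    Used as the prior mean for initial conditions.  The returned state,
    plugged back into the derivative functions, has residuals below ``tol``.
    Raises ``RuntimeError`` with diagnostics if no stable fixed point exists.
    """
    p = model.neuron
    if model.name == "fhn":
        def h(V):
            W = (V + p.psi1) / p.psi2
            return V - V ** 3 / 3.0 - W
        V0 = brentq(h, -3.0, 0.0, xtol=1e-14)
        W0 = (V0 + p.psi1) / p.psi2
        rest = (W0,)
    elif model.name == "qgif":
        V0 = _qgif_rest_voltage(p)
        rest = ()
    else:
        def h(V):
            z = boltzmann_activation(V, p.z_half, p.z_slope)
            r = boltzmann_activation(V, p.r_half, p.r_slope)
            return (_f_sp(V, p) - p.g_NaP * r * (V - p.E_Na) - p.g_M * z * (V - p.E_K))
        lo, hi = -120.0, p.V_th
        if h(lo) * h(hi) > 0:
            raise RuntimeError(
                f"no resting state in [{lo}, {hi}]: f({lo})={h(lo):.3g}, f({hi})={h(hi):.3g}"
            )
        V0 = brentq(h, lo, hi, xtol=1e-14)
        z0 = boltzmann_activation(V0, p.z_half, p.z_slope)
        z0 = min(max(z0, 1e-12), 1 - 1e-12)
        rest = (np.log(z0 / (1.0 - z0)),)
    c = model.calcium
    I_Ca = calcium_current(model.scaled_voltage(V0), c)
    Ca0 = c.Ca_base - c.kappa_Ca * c.tau_Ca * I_Ca
    x = np.array([V0, *rest, Ca0], dtype=float)
    # verify: one Euler step moves nothing beyond tol
    resid = (model.step(x, 0.0) - x) / model.dt
    # the z_aux residual is amplified by the logit chain factor; check z itself
    if model.name == "bursting_qgif":
        resid = resid.copy()
        resid[1] *= logistic(x[1]) * (1 - logistic(x[1]))
    if np.max(np.abs(resid)) > max(tol, 1e-8):
        raise RuntimeError(f"resting state residual too large: {resid}")
    return x
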