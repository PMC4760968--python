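"""Named default parameter sets and prior sets.

Two roles are shipped for every model:

* ``SIM`` -- the generative parameterization used to simulate data (effectively
  noise-free dynamics: precisions fixed at 1e12), with the calcium channel
  half-activation at -25 mV and the simulation-grade decay constants;
* ``INV`` -- the inversion parameterization (lag, inverse-covariance weights,
  prior base values) used when fitting traces, with the half-activation at
  -45 mV and deliberately loose priors on the free parameters.

The free (inferred) parameters are the calcium kinetics (tau_Ca, kappa_Ca,
basal [Ca2+]), the observation scale/offset (kappa_F, d_F), the noise
precisions, the initial conditions, and -- for the bursting model --
Delta_th, g_NaP and g_M.  Positivity-constrained parameters carry Gaussian
priors on their log-scale modal coordinate (theta = theta0 * exp(chi)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .inference import ParamPrior, PriorSet, tau_frame
from .models import (
    BurstQGIFParams,
    CalciumParams,
    FHNParams,
    NeuronModelSpec,
    QGIFParams,
    resting_state,
)
from .observation import ObservationParams, Trace

__all__ = ["NamedParameterSet", "default_parameters", "default_priors", "MODELS"]

MODELS = ("fhn", "qgif", "bursting_qgif")

#: free ([U]-flagged) parameters per model, beyond initial conditions/precisions
_FREE = {
    "fhn": ["tau_Ca", "kappa_Ca", "Ca_base", "kappa_F", "d_F"],
    "qgif": ["tau_Ca", "kappa_Ca", "Ca_base", "kappa_F", "d_F"],
    "bursting_qgif": ["tau_Ca", "kappa_Ca", "Ca_base", "kappa_F", "d_F",
                      "Delta_th", "g_NaP", "g_M"],
}

_SIM_PRECISION = 1e12  # "infinite" precision used when simulating


@dataclass
class NamedParameterSet:
    """One assembled model parameterization with its role tag."""

    model: str
    role: str                     # "SIM" | "INV"
    neuron: object
    calcium: CalciumParams
    obs: ObservationParams
    dt: float                     # inversion micro-step / table integration step (ms)
    dt_sim: float                 # fine simulation step (ms)
    lag: int
    Ups_x: dict                   # per-state inverse-covariance weights
    Ups_y: float
    tau_Ca_real: float            # real-time decay constant (ms)
    free: list = field(default_factory=list)

    def model_spec(self) -> NeuronModelSpec:
        dt = self.dt_sim if self.role == "SIM" else self.dt
        return NeuronModelSpec(self.model, self.neuron, self.calcium, dt=dt)

    def ups_vector(self) -> np.ndarray:
        spec = self.model_spec()
        return np.array([self.Ups_x[s] for s in spec.state_names], dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["neuron_class"] = type(self.neuron).__name__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NamedParameterSet":
        d = dict(d)
        ncls = {"FHNParams": FHNParams, "QGIFParams": QGIFParams,
                "BurstQGIFParams": BurstQGIFParams}[d.pop("neuron_class")]
        d["neuron"] = ncls(**d["neuron"])
        d["calcium"] = CalciumParams(**d["calcium"])
        d["obs"] = ObservationParams(**d["obs"])
        return cls(**d)


def default_parameters(model: str, role: str = "SIM") -> NamedParameterSet:
    """The shipped default parameter values for one model and role."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if role not in ("SIM", "INV"):
        raise ValueError(f"role must be 'SIM' or 'INV', got {role!r}")
    sim = role == "SIM"
    calcium = CalciumParams(
        g_Ca=5.0, E_Ca=120.0, rho=5.0,
        V_half=-25.0 if sim else -45.0,
        kappa_Ca=0.002, Ca_base=0.0,
        tau_Ca={"fhn": (2000.0, 7500.0), "qgif": (2000.0, 7500.0),
                "bursting_qgif": (800.0, 850.0)}[model][0 if sim else 1],
    )
    if model == "fhn":
        neuron = FHNParams()
        obs = ObservationParams(kappa_F=5.0, d_F=0.0, K_d=200.0)
        return NamedParameterSet(model, role, neuron, calcium, obs,
                                 dt=0.2, dt_sim=0.2, lag=3,
                                 Ups_x={"V": 2.0, "W": 30.0, "Ca": 10.0}, Ups_y=3.0,
                                 tau_Ca_real=calcium.tau_Ca, free=list(_FREE[model]))
    if model == "qgif":
        neuron = QGIFParams(I_rep_bar=120.0, Delta_th=3.48)
        obs = ObservationParams(kappa_F=10.0, d_F=0.0, K_d=200.0)
        # the table step (0.2 ms) under-resolves the repolarization gate when
        # forward-simulating, so simulations use a finer step
        return NamedParameterSet(model, role, neuron, calcium, obs,
                                 dt=0.2, dt_sim=0.05, lag=3,
                                 Ups_x={"V": 0.005, "Ca": 10.0}, Ups_y=3.0,
                                 tau_Ca_real=calcium.tau_Ca, free=list(_FREE[model]))
    neuron = BurstQGIFParams(I_rep_bar=87.0 if sim else 80.0,
                             g_M=1.0, g_NaP=0.41, Delta_th=3.48,
                             E_K=-90.0, E_Na=55.0, O=0.0)
    obs = ObservationParams(kappa_F=5.0, d_F=0.0, K_d=200.0)
    return NamedParameterSet(model, role, neuron, calcium, obs,
                             dt=0.05, dt_sim=0.05, lag=8,
                             Ups_x={"V": 0.005, "z_aux": 20.0, "Ca": 10.0}, Ups_y=6.0,
                             tau_Ca_real=calcium.tau_Ca, free=list(_FREE[model]))


def default_priors(pset: NamedParameterSet, dt_frame: float,
                   trace: Trace | None = None,
                   micro_steps: int = 1,
                   free: list | None = None,
                   fix_precisions: bool = False) -> PriorSet:
    """The shipped prior set for an inversion parameterization.

    ``trace`` supplies the data-dependent prior mean of the fluorescence
    offset, d_F ~ N(0.5*min(F), 0.25).  ``free`` restricts the free-parameter
    list (e.g. only ``g_M`` in a conductance-change experiment); parameters in
    the model's default free list that are excluded here are shipped with zero
    prior variance, which pins them.
    """
    spec = NeuronModelSpec(pset.model, pset.neuron, pset.calcium, dt=pset.dt)
    freelist = list(pset.free) if free is None else list(free)
    dt_total = pset.dt * micro_steps
    tau0_frame = tau_frame(pset.tau_Ca_real, dt_total, dt_frame)

    def var_of(name, v):
        return v if name in freelist else 0.0

    params = [
        ParamPrior("tau_Ca", base=tau0_frame, transform="exp",
                   var=var_of("tau_Ca", 5.0), report_base=pset.tau_Ca_real),
        ParamPrior("kappa_Ca", base=pset.calcium.kappa_Ca, transform="exp",
                   var=var_of("kappa_Ca", 5.0)),
        ParamPrior("Ca_base", transform="linear", mean=pset.calcium.Ca_base,
                   var=var_of("Ca_base", 100.0)),
        ParamPrior("kappa_F", base=pset.obs.kappa_F, transform="exp",
                   var=var_of("kappa_F", 1.0), target="observation"),
        ParamPrior("d_F", transform="linear",
                   mean=0.5 * float(np.min(trace.values)) if trace is not None else pset.obs.d_F,
                   var=var_of("d_F", 0.25), target="observation"),
    ]
    if pset.model == "bursting_qgif":
        params += [
            ParamPrior("Delta_th", base=pset.neuron.Delta_th, transform="exp",
                       var=var_of("Delta_th", 1.0)),
            ParamPrior("g_NaP", base=pset.neuron.g_NaP, transform="exp",
                       var=var_of("g_NaP", 1.0)),
            ParamPrior("g_M", base=pset.neuron.g_M, transform="exp",
                       var=var_of("g_M", 1.0)),
        ]

    # initial conditions: prior means at the resting state of the frame-grid
    # model (the [Ca2+] steady state uses the frame-rescaled decay constant)
    x0 = resting_state(spec)
    from .models import calcium_current
    I_rest = calcium_current(spec.scaled_voltage(x0[0]), pset.calcium)
    x0[-1] = pset.calcium.Ca_base - pset.calcium.kappa_Ca * tau0_frame * I_rest
    x0_var = {"fhn": {"V": 4.0, "W": 1.0, "Ca": 25.0},
              "qgif": {"V": 100.0, "Ca": 25.0},
              "bursting_qgif": {"V": 100.0, "z_aux": 1.0, "Ca": 25.0}}[pset.model]
    x0v = np.array([x0_var[s] for s in spec.state_names], dtype=float)

    kwargs = {}
    if fix_precisions:
        kwargs = {"alpha_fixed": _SIM_PRECISION, "sigma_fixed": _SIM_PRECISION}
    return PriorSet(params=params, x0_mean=x0, x0_var=x0v,
                    alpha=(1.0, 1.0), sigma=(1.0, 1.0), **kwargs)
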