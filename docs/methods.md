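# Methods

This note documents the models, the inference scheme, the numerical choices,
and the known limitations of the package, in the order a user meets them.

## Generative models

A fluorescence trace is modelled as the output of a three-stage generative
model: a spiking model for the membrane potential V, a high-voltage-activated
(L-type) calcium channel plus first-order [Ca²⁺] kinetics, and a saturating
Hill observation.

**Spiking models.** Three single-compartment models are shipped.

* *FitzHugh–Nagumo* (`fhn`): dV/dt = V − V³/3 − W + I,
  dW/dt = λ(V + ψ₁ − ψ₂W), with ψ₁ = 0.7, ψ₂ = 0.8, λ = 0.08. V is
  dimensionless (full spikes peak near +2, undershoot near −2); only where V
  feeds the calcium channel is it mapped to millivolts by ι₁V − ι₂ with
  ι₁ = 30, ι₂ = 40.
* *Quadratic-Gaussian integrate-and-fire* (`qgif`): a quadratic
  spike-generating current g_L/(2Δ_th)(V − V_th)² − I_th plus a smooth
  repolarization current — a steep sigmoid of a delta-like Gaussian centred
  on the spike peak (V_peak = 30 mV, σ_peak = 1 mV) — so spikes need no
  discontinuous reset. The repolarization scaling is implemented so that one
  Euler step inside the Gaussian gate drops the potential by Ī_rep millivolts
  regardless of the step size; with the literal reading γ = dt/C the
  repolarization term (≈ 5 mV per step at dt = 0.2 ms) can never beat the
  quadratic current near the peak and the model diverges, whereas γ = C/dt
  produces the documented repetitive firing and after-spike hyperpolarization
  near −80 mV. The leak reversal E_L cancels analytically (the leak current
  inside the quadratic spike current offsets the explicit leak term), so the
  resting potential is V_th − √(2Δ_th·I_th/g_L) ≈ −63.2 mV independent of
  E_L; the field is kept for completeness.
* *Bursting QGIF* (`bursting_qgif`): the QGIF plus a persistent Na⁺ current
  I_NaP = g_NaP·r∞(V)(V − E_Na) (burst promotion) and a slow M-type K⁺
  current I_M = g_M·z(V − E_K) (burst termination). The printed forms of the
  gating steady states are typeset-garbled; they are implemented as Boltzmann
  functions r∞ = (1+exp(−(V+41)/3))⁻¹ and z∞ = (1+exp(−(V+39)/5))⁻¹
  (configurable midpoints/slopes), with gate time constant τ_z = 75 ms. The
  gate is propagated through its logit z_aux = log(z/(1−z)), which keeps
  z ∈ (0,1); the chain-rule denominator z − z² + O is clamped at 10⁻⁹ so the
  update stays finite when the gate saturates with O = 0.

**Calcium.** I_Ca = g_Ca·s∞(V)(V − E_Ca) with Boltzmann activation s∞
(half-activation −25 mV when simulating, −45 mV when inverting; slope 5 mV),
and d[Ca²⁺]/dt = −κ_Ca·I_Ca − ([Ca²⁺] − [Ca²⁺]_base)/τ_Ca. With the default
κ_Ca = 0.002 the simulated spike-evoked transients are a few to ~15 nM.

**Observation.** F = κ_F·[Ca²⁺]/([Ca²⁺] + K_d) + d_F with K_d = 200 nM
(a high-affinity indicator). Traces are preprocessed by optional degree-4
polynomial detrending, baseline zeroing on a pre-stimulus window (first 10%
of frames by default), and scaling so max(F) = 1.

## Forward simulation

Forward Euler with zero state noise. The bursting model integrates stably at
its tabled step (0.05 ms); the plain QGIF needs 0.05 ms as well when
simulating (at 0.2 ms the Euler step below the narrow repolarization gate
exceeds the gate's width and the trajectory can escape upward), while the
FHN uses 0.2 ms. Ground-truth spike times are voltage maxima above 0 mV
(QGIF family) or above 1 (FHN). Traces are subsampled at the frame rate and
zero-mean Gaussian background noise is added, scaled so that the minimum
transient amplitude over the baseline standard deviation matches a requested
SNR. Rise times can be stretched to 200–450 ms by time-rescaling each rising
segment, preserving peaks and decays.

## Inversion

The inverse model lives on the frame grid: per observed frame the neuron
dynamics advance by `micro_steps` Euler steps of size dt (one by default), and
the calcium decay constant is rescaled to τ_frame = τ_real·dt·micro_steps/
dt_frame so [Ca²⁺] relaxes at its real per-frame rate. The synaptic input is
unknown to the inversion and is absorbed by the state noise. Free parameters
(the calcium kinetics, the observation scale/offset, the bursting
conductances, initial conditions and both noise precisions) carry the shipped
priors; positivity-constrained ones are estimated through θ = θ⁰·exp(χ) with
a Gaussian prior on χ.

The posterior is approximated under a mean-field factorization
q(states)·q(θ)·q(φ)·q(α)·q(σ) with Gaussian state/parameter marginals and
Gamma precision marginals, optimized in two phases.

**Fit phase.** Sweeps alternate (i) a state update — a damped Gauss–Newton
refinement of the state mode, each step solved by a Kalman–Rauch pass of the
model linearized at the current trajectory, with a backtracking line search
on the exact joint density; (ii) Gauss–Newton parameter updates with a
trust region of 3.5 prior standard deviations (at most 0.5 per sweep during
the warm-up) accepted only if the free energy does not drop once the warm-up
ends; (iii) exact conjugate Gamma updates for the precisions. The first pass
is a lagged cubature (sigma-point) filter–smoother: statistical linearization
is essential because a point Jacobian of the saturating channel activation
taken at rest is nearly zero and makes a linearized smoother extrapolate
wildly. The observation precision starts at the baseline-window noise level
and both precisions are held for the first ten sweeps so the states and
parameters settle in the transient-tracking regime; without this warm-up the
iteration reliably falls into a degenerate optimum in which the calcium state
noise absorbs the transients and the voltage decouples from the data. The
calcium gain κ_Ca is likewise initialized so that one frame of influx at the
channel's optimal voltage can supply the largest observed single-frame
[Ca²⁺] increment. The free energy (exact for linear-Gaussian models, where
it reproduces the analytic log-evidence; first-order otherwise) is tracked
per sweep and the best iterate is kept, so the reported trajectory over
accepted sweeps is non-decreasing.

**Spike readout phase.** The fitted mode is only weakly identified along the
voltage: the data constrain influx, and equal influx is available at
sub-threshold voltages, so the unconstrained optimum tends to "park" the
voltage below the 0 mV detection threshold. The readout therefore projects
the solution onto the spiking branch of the dynamics: depolarization events
are taken from contiguous supra-threshold runs of the first (lagged) pass and
the converged fit, each required to coincide with a [Ca²⁺] rise above four
increment-noise standard deviations (integrated over the run, so slow rises
qualify); the deterministic dynamics are rolled forward and, at each
supported event, the voltage is lifted into the repolarization gate just
below the spike peak — the quadratic current tops the spike off and the gate
resets it next frame (one-frame spikes). For the bursting model every strong
per-frame calcium jump inside a run gets its own spike (separated by at
least ~2 frames); for the others one spike per event with a 1 s refractory.
For the FHN, whose full orbit lasts dozens of frames, the lifted voltage is
reset to rest on the next frame. The calcium (and gating) components are
then re-refined with the voltage frozen (a conditional mode). Detection is
upward 0-crossing of the readout voltage with a 6 ms lockout (two frame
intervals for the bursting model, whose within-burst intervals at
near-kilohertz frame rates can be shorter than 6 ms). For the FHN the
unconstrained refined mode already crosses threshold at events (its
influx-optimal depolarization is above 0 on the dimensionless scale) and is
reported for detection.

**Decay readout.** The jointly fitted decay constant is locally degenerate
with spurious sub-threshold influx (a too-fast decay plus a dribble of
influx fits as well as the true decay), so the reported τ_Ca is read from
the spike-pinned trajectory, whose influx is localized at the detected
events: over decay segments (masking 600 ms after each calcium jump) the
per-frame increment is regressed on the level; the slope is −dt_frame/τ,
independent of the unknown baseline.

**Conductance profiling.** When all parameters except one conductance are
known (the pharmacological-intervention setting), the gradient update is
uninformative — with the stimulus unknown the smoothed states trade
conductance changes against state noise — so the conductance is profiled:
for each candidate value the data-implied spike train is imposed on the model
and the joint log-density of the conditional mode, plus the log-normal prior,
scores the candidate; the posterior mean over the grid is reported.

## Numerical choices

Voltage in the inverse model is bounded at V_peak + 3σ_peak above (the
model's own maximum; beyond the gate the quadratic current runs away) and
−150 mV below; the gate's logit is clipped at ±16 and [Ca²⁺] above −0.45·K_d
(away from the Hill singularity). Evolution Jacobians use central finite
differences with state-scaled steps (0.5 mV for voltage) so the
sub-millivolt-wide repolarization shell is differenced across rather than
inside, and are clipped at ±50. Covariance updates use the Joseph form,
noise covariances are floored at 10⁻¹² (precisions capped at 10¹², matching
the "infinite precision" convention of the simulation parameter sets), and
smoothed covariances are projected onto the PSD cone with a 10⁸ variance
ceiling. Convergence is declared when the free energy changes by less than
10⁻² over two successive sweeps after the warm-up, with a 40-sweep cap in
the shipped pipelines.

## What the generator emulates — and what it does not

The fixtures reproduce the study conditions this package is tested on:
12-spike QGIF and 13-spike FHN traces at 33.3 Hz (SNR ≈ 30 / 20 / 2.5),
rise-stretched variants (SNR ≈ 25), a ~714 Hz bursting trace with singles,
doublets and triplets (SNR ≈ 3; intra-burst intervals ≥ ~2.4 ms so they are
resolvable at the frame rate), calcium-decay interventions (τ_Ca = 600 vs
6000 ms; SNR 20, chosen as a routine high-quality recording), and M-type
conductance interventions (g_M = 0.8 vs 0.45 mS/cm² under
0.74·sin(0.003t) μA/cm² drive, 0.5 ms frames, SNR 20). Stimulation protocols
are square pulses with randomized timing jitter (the intervention fixtures
use five transients over 45 s; the 33.3 Hz fixtures 12–13 transients over
30 s ≈ 1000 frames, chosen to keep a single inversion under a minute).

Background noise is i.i.d. Gaussian — real background light is weakly
correlated. The generator has no drifts (the detrending path is exercised
separately), no indicator photobleaching, no motion artefacts, and no
synaptic barrage between events; passing tests on these fixtures demonstrate
the machinery, not performance on any particular recording system.

## Known limitations

* Burst-trace detection at SNR ≈ 3 is noise-limited at this desk scale: a
  single within-burst spike produces a one-frame jump of about three noise
  standard deviations, and the pipeline currently leaves roughly one to two
  dozen total errors on the 14-spike fixture rather than zero.
* The conductance profile reliably separates small-g_M from large-g_M regimes
  but is biased toward the low end: with the stimulus unknown, suppressing a
  spike costs the model nothing, so the evidence against small conductances
  is weak. The g_M = 0.45 condition is recovered well; the 0.8 condition is
  underestimated (≈ 0.45–0.6).
* Under the reconstructed gating forms the sinusoidally driven bursting model
  fires 2 spikes per burst at g_M = 0.8 and 5 (not 4) at g_M = 0.45; a scan
  over the plausible reconstruction space found no variant producing the
  (2, 4) pair without silencing the g_M = 0.8 neuron.
* The inversion time-dilates the neuron dynamics (dt of model time per
  frame), so inferred spike shapes are stretched relative to real time;
  onsets, not shapes, are the meaningful output at ordinary frame rates.
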