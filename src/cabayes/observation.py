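"""Fluorescence observation model and trace preprocessing.

The mapping from intracellular [Ca2+] to relative fluorescence (dF/F0) is a
saturating Hill function with dissociation constant ``K_d`` (indicator
affinity), scale ``kappa_F`` and offset ``d_F``.  Preprocessing follows common
practice for somatic dF/F traces: degree-4 polynomial detrending against slow
drifts (photobleaching, mechanical movement), baseline re-zeroing on a
pre-stimulus window, and scaling so the trace maximum equals a fixed value.

SNR is defined as the minimum fluorescence-transient amplitude divided by the
standard deviation of the baseline fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ObservationParams",
    "Trace",
    "hill_observation",
    "estimate_snr",
    "detrend_poly",
    "normalize_trace",
]


@dataclass
class ObservationParams:
    kappa_F: float = 10.0  # fluorescence scale
    d_F: float = 0.0       # fluorescence offset
    K_d: float = 200.0     # nM, dissociation constant

    def __post_init__(self):
        if self.K_d <= 0:
            raise ValueError("dissociation constant K_d must be > 0")
        if self.kappa_F <= 0:
            raise ValueError("fluorescence scale kappa_F must be > 0")


@dataclass
class Trace:
    """A single-neuron dF/F0 time series.

    ``baseline_window`` is an index range ``(start, stop)`` treated as the
    pre-stimulus baseline; when None the first 10% of frames are used.
    """

    values: np.ndarray
    dt_frame: float  # ms
    baseline_window: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt_frame <= 0:
            raise ValueError("frame interval dt_frame must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    def __len__(self):
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Frame times in ms."""
        return np.arange(len(self.values)) * self.dt_frame

    def baseline_slice(self) -> slice:
        if self.baseline_window is not None:
            lo, hi = self.baseline_window
        else:
            lo, hi = 0, max(2, len(self.values) // 10)
        return slice(lo, hi)


def hill_observation(Ca, p: ObservationParams):
    """Saturating Hill mapping F = kappa_F * Ca / (Ca + K_d) + d_F.

    Strictly increasing and concave for Ca >= 0, bounded above by
    kappa_F + d_F.  Raises on the singular input Ca = -K_d.
    """
    Ca = np.asarray(Ca, dtype=float)
    if np.any(np.isclose(Ca, -p.K_d)):
        raise ValueError("singular input: Ca = -K_d")
    return p.kappa_F * Ca / (Ca + p.K_d) + p.d_F


def _transient_amplitudes(values: np.ndarray, dt_frame: float, baseline: slice,
                          height: float, min_separation_ms: float = 1000.0):
    """Peak amplitudes (relative to the baseline median) of candidate transients."""
    base = np.median(values[baseline])
    distance = max(1, int(round(min_separation_ms / dt_frame)))
    # require prominence as well as height so that noise bumps riding on
    # slowly decaying tails do not qualify as transients
    peaks, _ = find_peaks(values - base, height=height, distance=distance,
                          prominence=height)
    # amplitude: peak above the pre-transient level (minimum over the
    # preceding second), matching how noise injection targets the SNR
    amps = np.array([
        values[p] - np.min(values[max(0, p - distance):p + 1]) for p in peaks
    ])
    return amps, peaks


def estimate_snr(t: Trace, *, threshold_mult: float = 5.0) -> float:
    """Minimum transient amplitude divided by baseline standard deviation.

    Transients are peaks above ``threshold_mult`` baseline standard deviations
    separated by at least one second.  Raises if the baseline is noise-free
    (undefined SNR) or no transient exceeds the threshold.
    """
    base = t.baseline_slice()
    sd = float(np.std(t.values[base]))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("undefined SNR: baseline standard deviation is zero")
    amps, _ = _transient_amplitudes(t.values, t.dt_frame, base, threshold_mult * sd)
    if len(amps) == 0:
        raise ValueError("no fluorescence transient detected above threshold")
    return float(np.min(amps) / sd)


def detrend_poly(t: Trace, degree: int = 4) -> Trace:
    """Remove a least-squares polynomial trend of the given degree.

    After subtraction the trace is re-zeroed on the baseline-window median.
    """
    n = len(t.values)
    if n <= degree + 1:
        raise ValueError(f"trace length {n} too short for degree-{degree} detrending")
    x = np.linspace(-1.0, 1.0, n)  # scaled abscissa keeps the fit well conditioned
    coef = np.polynomial.polynomial.polyfit(x, t.values, degree)
    resid = t.values - np.polynomial.polynomial.polyval(x, coef)
    resid = resid - np.median(resid[t.baseline_slice()])
    return replace(t, values=resid, meta={**t.meta, "detrended": degree})


def normalize_trace(t: Trace, scale: float = 1.0) -> Trace:
    """Zero the baseline then scale so that max(F) equals ``scale``.

    Idempotent: applying it to its own output returns the same trace.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    vals = t.values - np.median(t.values[t.baseline_slice()])
    m = float(np.max(vals))
    if m <= 0:
        raise ValueError("nonpositive trace maximum after baseline zeroing")
    return replace(t, values=vals * (scale / m), meta={**t.meta, "scale": scale})
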