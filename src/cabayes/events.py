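"""Spike/event readout from inferred membrane potentials, and scoring.

Spikes are read out as upward threshold crossings of the (inferred or
simulated) membrane potential; after each detection, further upward crossings
are discounted for a lockout period (default 6 ms) to suppress double counts
from high-frequency fluctuations.  Detected events are scored against ground
truth by greedy nearest-neighbour one-to-one matching inside a window,
yielding missed (M) and falsely detected (FD) counts plus per-match timing
errors.  For population recordings of synchronized network events, per-neuron
onset latencies are pooled after centering each event on its median onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["EventSet", "MatchReport", "detect_spikes", "match_events", "gdp_latencies"]


@dataclass
class EventSet:
    """Sorted event onset times in ms."""

    times: np.ndarray
    source: str = "inferred"   # "true" | "inferred"

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, dtype=float))

    def __len__(self):
        return len(self.times)


@dataclass
class MatchReport:
    n_true: int
    missed: int                     # true events with no matched detection
    falsely_detected: int           # detections with no matched true event
    timing_errors: np.ndarray       # inferred - true, per matched pair
    unit: str = "ms"

    @property
    def total_errors(self) -> int:
        return self.missed + self.falsely_detected

    def summary(self) -> dict:
        te = np.asarray(self.timing_errors, dtype=float)
        return {
            "n_true": self.n_true,
            "missed": self.missed,
            "falsely_detected": self.falsely_detected,
            "timing_error_mean": float(np.mean(te)) if len(te) else None,
            "timing_error_std": float(np.std(te)) if len(te) else None,
            "unit": self.unit,
        }


def detect_spikes(V: np.ndarray, dt: float, threshold: float = 0.0,
                  lockout: float = 6.0) -> EventSet:
    """Upward threshold crossings of a voltage series with a lockout.

    ``dt`` is the sample interval in ms.  A crossing within ``lockout`` ms of
    the previous detection is discounted.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage series contains non-finite values")
    idx = np.flatnonzero((V[:-1] <= threshold) & (V[1:] > threshold)) + 1
    kept = []
    last = -np.inf
    for i in idx:
        t = i * dt
        if t - last >= lockout:
            kept.append(t)
            last = t
    return EventSet(np.asarray(kept), source="inferred")


def match_events(inferred: EventSet, truth: EventSet, window: float,
                 dt_frame: float | None = None) -> MatchReport:
    """Greedy nearest-neighbour one-to-one matching within ``window`` ms.

    Unmatched true events count as missed; unmatched detections as falsely
    detected.  Timing errors are inferred minus true onset, in frames when
    ``dt_frame`` is given, otherwise in ms.
    """
    if window <= 0:
        raise ValueError("matching window must be > 0")
    ti = np.asarray(inferred.times, dtype=float)
    tt = np.asarray(truth.times, dtype=float)
    pairs = [(abs(a - b), i, j) for i, a in enumerate(ti) for j, b in enumerate(tt)
             if abs(a - b) <= window]
    pairs.sort()
    used_i, used_j, errors = set(), set(), []
    for d, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        errors.append(ti[i] - tt[j])
    errors = np.asarray(errors, dtype=float)
    unit = "ms"
    if dt_frame:
        errors = errors / dt_frame
        unit = "frames"
    return MatchReport(n_true=len(tt), missed=len(tt) - len(used_j),
                       falsely_detected=len(ti) - len(used_i),
                       timing_errors=errors, unit=unit)


def gdp_latencies(onsets: list, fit: bool = True):
    """Pooled cellular-activation latencies across synchronized network events.

    ``onsets`` is a list with one array of per-neuron onset times (ms) per
    event.  Each event's latencies are taken relative to the event's median
    onset; events with fewer than two neurons are skipped with a warning.
    Returns ``(latencies, (mean, std))``; the Gaussian fit is ``None`` when
    ``fit`` is False.
    """
    pooled = []
    for k, ev in enumerate(onsets):
        ev = np.asarray(ev, dtype=float)
        ev = ev[np.isfinite(ev)]
        if len(ev) < 2:
            warnings.warn(f"event {k} has fewer than two neurons; skipped")
            continue
        pooled.append(ev - np.median(ev))
    if not pooled:
        return np.array([]), None
    lat = np.concatenate(pooled)
    return lat, (tuple(norm.fit(lat)) if fit else None)
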