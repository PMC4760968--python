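"""File formats: traces (CSV/HDF5), event sets (JSON), posteriors (HDF5),
parameter sets and run configuration (YAML).

All formats are plain and documented in ``docs/formats.md``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .defaults import NamedParameterSet
from .events import EventSet, MatchReport
from .inference import Posterior
from .observation import Trace

__all__ = [
    "trace_to_csv", "trace_from_csv", "trace_to_hdf5", "trace_from_hdf5",
    "events_to_json", "events_from_json", "match_report_to_json",
    "posterior_to_hdf5", "parameter_set_to_yaml", "parameter_set_from_yaml",
    "load_config",
]


def trace_to_csv(trace: Trace, path) -> None:
    """Two-column CSV: time_ms, dff."""
    pd.DataFrame({"time_ms": trace.times, "dff": trace.values}).to_csv(path, index=False)


def trace_from_csv(path, baseline_window=None) -> Trace:
    df = pd.read_csv(path)
    if not {"time_ms", "dff"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_ms, dff")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: trace needs at least two samples")
    dt = float(np.median(np.diff(t)))
    return Trace(df["dff"].to_numpy(dtype=float), dt, baseline_window=baseline_window)


def trace_to_hdf5(trace: Trace, path, dataset: str = "dff") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=trace.values)
        d.attrs["dt_frame"] = trace.dt_frame
        if trace.baseline_window is not None:
            d.attrs["baseline_window"] = list(trace.baseline_window)


def trace_from_hdf5(path, dataset: str = "dff") -> Trace:
    with h5py.File(path, "r") as f:
        d = f[dataset]
        bw = d.attrs.get("baseline_window")
        return Trace(d[()], float(d.attrs["dt_frame"]),
                     baseline_window=tuple(int(v) for v in bw) if bw is not None else None)


def events_to_json(events: EventSet, path, extra: dict | None = None) -> None:
    payload = {"onset_times_ms": [float(t) for t in events.times],
               "source": events.source, **(extra or {})}
    Path(path).write_text(json.dumps(payload, indent=2))


def events_from_json(path) -> EventSet:
    payload = json.loads(Path(path).read_text())
    return EventSet(np.asarray(payload["onset_times_ms"], dtype=float),
                    payload.get("source", "inferred"))


def match_report_to_json(report: MatchReport, path) -> None:
    payload = report.summary()
    payload["timing_errors"] = [float(e) for e in report.timing_errors]
    Path(path).write_text(json.dumps(payload, indent=2))


def posterior_to_hdf5(post: Posterior, path) -> None:
    """State marginals, parameter marginals, precision posteriors and the
    free-energy trajectory."""
    with h5py.File(path, "w") as f:
        f.create_dataset("state_means", data=post.state_means)
        f.create_dataset("state_covs", data=post.state_covs)
        f.create_dataset("free_energy", data=np.asarray(post.free_energy))
        f.attrs["state_names"] = list(post.state_names)
        f.attrs["dt_frame"] = post.dt_frame
        f.attrs["model"] = post.meta.get("model", "")
        f.attrs["converged"] = post.converged
        f.attrs["alpha_shape"], f.attrs["alpha_rate"] = post.alpha
        f.attrs["sigma_shape"], f.attrs["sigma_rate"] = post.sigma
        for tag, marg in (("theta", post.theta), ("phi", post.phi)):
            g = f.create_group(tag)
            g.attrs["names"] = list(marg.names)
            g.create_dataset("mean", data=marg.mean)
            g.create_dataset("cov", data=marg.cov)
        nat = f.create_group("natural")
        for name in list(post.theta.names) + list(post.phi.names):
            nat.attrs[name] = post.param_natural(name)


def parameter_set_to_yaml(pset: NamedParameterSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(pset.to_dict(), sort_keys=False))


def parameter_set_from_yaml(path) -> NamedParameterSet:
    return NamedParameterSet.from_dict(yaml.safe_load(Path(path).read_text()))


def load_config(path) -> dict:
    """YAML run configuration for the command-line interface."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
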