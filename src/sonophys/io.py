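"""File formats: delimited-text and HDF5 trace containers, event tables,
rate-series tables, pressure-map grids.

Text traces are two-column ``time_s,value`` CSV with a ``# key = value``
metadata header; values are written with 17 significant digits so a
write/read round trip is lossless.  The HDF5 layout is ``/trace/samples``
(dataset) with metadata as attributes on ``/trace/meta``, and optionally
``/truth/events`` plus truth attributes.  The declared units must match the
clamp mode (pA for voltage clamp, mV for current clamp); a mismatch raises
:class:`~sonophys.core.UnitMismatchError`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .core import (
    ClampMode,
    EventKind,
    EventList,
    EventSource,
    GroundTruth,
    InvalidParameterError,
    Trace,
    UNITS,
    UnitMismatchError,
)
from .dosimetry import PressureMap
from .rates import RateSeries

__all__ = [
    "save_trace_text", "load_trace_text",
    "save_trace_h5", "load_trace_h5",
    "load_trace", "save_trace",
    "save_events", "load_events",
    "save_rate_series", "load_rate_series",
    "save_pressure_map", "load_pressure_map",
]

_FLOAT_FMT = "%.17g"


def _check_units(units: str, clamp_mode: ClampMode) -> None:
    expected = UNITS[clamp_mode]
    if units != expected:
        raise UnitMismatchError(
            f"units {units!r} inconsistent with clamp mode {clamp_mode.value!r} "
            f"(expected {expected!r})"
        )


# ---------------------------------------------------------------------------
# Text trace container
# ---------------------------------------------------------------------------

def save_trace_text(trace: Trace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz = {trace.sampling_rate!r}\n")
        fh.write(f"# clamp_mode = {trace.clamp_mode.value}\n")
        fh.write(f"# units = {trace.units}\n")
        fh.write(f"# start_time_s = {trace.start_time!r}\n")
        fh.write(f"# channel_meta = {json.dumps(trace.channel_meta, sort_keys=True)}\n")
        fh.write("time_s,value\n")
        t = trace.times
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{_FLOAT_FMT % ti},{_FLOAT_FMT % vi}\n")


def _parse_header(path: Path) -> Tuple[dict, int]:
    meta, n_header = {}, 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            if "=" not in line:
                raise InvalidParameterError(f"malformed header line: {line.strip()!r}")
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
    for required in ("sampling_rate_hz", "clamp_mode", "units"):
        if required not in meta:
            raise InvalidParameterError(f"trace header missing field {required!r}")
    return meta, n_header


def load_trace_text(path) -> Trace:
    path = Path(path)
    meta, n_header = _parse_header(path)
    clamp_mode = ClampMode(meta["clamp_mode"])
    _check_units(meta["units"], clamp_mode)
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    return Trace(
        samples=df["value"].to_numpy(),
        sampling_rate=float(meta["sampling_rate_hz"]),
        clamp_mode=clamp_mode,
        start_time=float(meta.get("start_time_s", 0.0)),
        channel_meta=json.loads(meta.get("channel_meta", "{}")),
    )


# ---------------------------------------------------------------------------
# HDF5 trace container
# ---------------------------------------------------------------------------

def save_trace_h5(trace: Trace, path, truth: Optional[GroundTruth] = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trace")
        g.create_dataset("samples", data=trace.samples)
        m = g.create_group("meta")
        m.attrs["sampling_rate_hz"] = trace.sampling_rate
        m.attrs["clamp_mode"] = trace.clamp_mode.value
        m.attrs["units"] = trace.units
        m.attrs["start_time_s"] = trace.start_time
        m.attrs["channel_meta_json"] = json.dumps(trace.channel_meta, sort_keys=True)
        if truth is not None:
            tg = f.create_group("truth")
            eg = tg.create_group("events")
            eg.create_dataset("times_s", data=truth.events.times)
            if truth.events.amplitudes is not None:
                eg.create_dataset("amplitudes_pa", data=truth.events.amplitudes)
            eg.attrs["kind"] = truth.events.kind.value
            eg.attrs["source"] = truth.events.source.value
            tg.attrs["tonic_step_pa"] = truth.tonic_step_pa
            tg.attrs["tonic_step_time_s"] = (
                np.nan if truth.tonic_step_time is None else truth.tonic_step_time)
            tg.attrs["suppression_ratio"] = truth.suppression_ratio
            tg.attrs["suppression_onset_s"] = (
                np.nan if truth.suppression_onset is None else truth.suppression_onset)


def load_trace_h5(path) -> Tuple[Trace, Optional[GroundTruth]]:
    with h5py.File(path, "r") as f:
        m = f["trace/meta"].attrs
        clamp_mode = ClampMode(m["clamp_mode"])
        _check_units(str(m["units"]), clamp_mode)
        trace = Trace(
            samples=f["trace/samples"][...],
            sampling_rate=float(m["sampling_rate_hz"]),
            clamp_mode=clamp_mode,
            start_time=float(m["start_time_s"]),
            channel_meta=json.loads(m["channel_meta_json"]),
        )
        truth = None
        if "truth" in f:
            tg = f["truth"]
            eg = tg["events"]
            amps = eg["amplitudes_pa"][...] if "amplitudes_pa" in eg else None
            events = EventList(EventKind(eg.attrs["kind"]), eg["times_s"][...],
                               amps, EventSource(eg.attrs["source"]))
            step_t = float(tg.attrs["tonic_step_time_s"])
            onset = float(tg.attrs["suppression_onset_s"])
            truth = GroundTruth(
                events=events,
                tonic_step_pa=float(tg.attrs["tonic_step_pa"]),
                tonic_step_time=None if np.isnan(step_t) else step_t,
                suppression_ratio=float(tg.attrs["suppression_ratio"]),
                suppression_onset=None if np.isnan(onset) else onset,
            )
    return trace, truth


def load_trace(path, fmt: Optional[str] = None) -> Trace:
    """Load a trace from a recognized container (``'text'`` or ``'h5'``)."""
    path = Path(path)
    if fmt is None:
        fmt = "h5" if path.suffix in (".h5", ".hdf5") else "text"
    if fmt == "h5":
        return load_trace_h5(path)[0]
    if fmt == "text":
        return load_trace_text(path)
    raise InvalidParameterError(f"unrecognized trace format {fmt!r}")


def save_trace(trace: Trace, path, fmt: Optional[str] = None,
               truth: Optional[GroundTruth] = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "h5" if path.suffix in (".h5", ".hdf5") else "text"
    if fmt == "h5":
        save_trace_h5(trace, path, truth)
    elif fmt == "text":
        save_trace_text(trace, path)
    else:
        raise InvalidParameterError(f"unrecognized trace format {fmt!r}")


# ---------------------------------------------------------------------------
# Event, rate and map tables
# ---------------------------------------------------------------------------

def save_events(events: EventList, path) -> None:
    amps = (events.amplitudes if events.amplitudes is not None
            else np.full(len(events), np.nan))
    df = pd.DataFrame({
        "kind": [events.kind.value] * len(events),
        "time_s": events.times,
        "amplitude_pA": amps,
        "source": [events.source.value] * len(events),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_events(path) -> EventList:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("kind", "time_s", "amplitude_pA", "source"):
        if col not in df.columns:
            raise InvalidParameterError(f"event table missing column {col!r}")
    if len(df) == 0:
        return EventList(EventKind.SPIKE, np.empty(0), None, EventSource.DETECTED)
    kind = EventKind(df["kind"].iloc[0])
    source = EventSource(df["source"].iloc[0])
    amps = df["amplitude_pA"].to_numpy()
    return EventList(kind, df["time_s"].to_numpy(),
                     None if np.all(np.isnan(amps)) else amps, source)


def save_rate_series(series: RateSeries, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# kernel_width_s = {series.kernel_width!r}\n")
        fh.write(f"# normalized = {series.normalized}\n")
        if series.baseline_window is not None:
            fh.write(f"# baseline_window_s = {series.baseline_window[0]!r} {series.baseline_window[1]!r}\n")
        fh.write("time_s,rate\n")
        for ti, vi in zip(series.times, series.values):
            fh.write(f"{_FLOAT_FMT % ti},{_FLOAT_FMT % vi}\n")


def load_rate_series(path) -> RateSeries:
    path = Path(path)
    meta, n_header = {}, 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    bw = None
    if "baseline_window_s" in meta:
        a, b = meta["baseline_window_s"].split()
        bw = (float(a), float(b))
    return RateSeries(df["time_s"].to_numpy(), df["rate"].to_numpy(),
                      float(meta["kernel_width_s"]),
                      normalized=meta.get("normalized", "False") == "True",
                      baseline_window=bw)


def save_pressure_map(pmap: PressureMap, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# plane = {pmap.plane}\n")
        fh.write("# axis1_mm = " + " ".join(_FLOAT_FMT % v for v in pmap.axis1_mm) + "\n")
        fh.write("# axis2_mm = " + " ".join(_FLOAT_FMT % v for v in pmap.axis2_mm) + "\n")
        for row in pmap.values_kpa:
            fh.write(",".join(_FLOAT_FMT % v for v in row) + "\n")


def load_pressure_map(path) -> PressureMap:
    path = Path(path)
    meta, n_header = {}, 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
    values = np.loadtxt(path, delimiter=",", skiprows=n_header, ndmin=2)
    ax1 = np.array([float(v) for v in meta["axis1_mm"].split()])
    ax2 = np.array([float(v) for v in meta["axis2_mm"].split()])
    return PressureMap(ax1, ax2, values, plane=meta.get("plane", "XY"))
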