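"""Plain-text readers and writers for traces, spike trains and recording sets.

Everything is CSV/JSON/text: files stay small at desk scale and diff-able.
Traces round-trip at full float precision; the sampling step is recovered
from the time column and validated uniform.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import SpikeTrain
from .model import SimulationTrace, TwoCompartmentModel
from .protocol import ProtocolConfig, RecordingSet

__all__ = [
    "write_trace", "read_trace",
    "write_spikes", "read_spikes",
    "write_recording_set", "read_recording_set",
]

_TRACE_COLUMNS = ["t_ms", "I_s_pA", "I_d_pA", "V_s_mV", "V_d_mV", "V_T_mV",
                  "m", "x"]


def _FMT(v):
    """Shortest decimal that round-trips the float64 exactly."""
    return repr(float(v))


def write_trace(path, trace: SimulationTrace) -> None:
    n = trace.v_s.size
    zero = np.zeros(n)
    df = pd.DataFrame({
        "t_ms": trace.t,
        "I_s_pA": zero if trace.i_s is None else trace.i_s,
        "I_d_pA": zero if trace.i_d is None else trace.i_d,
        "V_s_mV": trace.v_s,
        "V_d_mV": trace.v_d,
        "V_T_mV": trace.v_t,
        "m": trace.m,
        "x": trace.x,
    })
    df.to_csv(path, index=False, float_format=_FMT)


def read_trace(path, spike_times=None) -> SimulationTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} missing column(s): {missing}")
    t = df["t_ms"].to_numpy()
    if t.size < 2:
        raise ValueError("trace must contain at least two samples")
    steps = np.diff(t)
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(np.abs(steps - dt) > 1e-6 * dt + 1e-9)) + 1
        raise ValueError(f"non-uniform time grid near row {bad}")
    return SimulationTrace(
        dt=float(dt),
        v_s=df["V_s_mV"].to_numpy(), v_d=df["V_d_mV"].to_numpy(),
        v_t=df["V_T_mV"].to_numpy(), m=df["m"].to_numpy(),
        x=df["x"].to_numpy(),
        spike_times=np.empty(0) if spike_times is None else np.asarray(spike_times),
        i_s=df["I_s_pA"].to_numpy(), i_d=df["I_d_pA"].to_numpy(),
    )


def write_spikes(path, train: SpikeTrain) -> None:
    """One spike time (ms) per line, duration in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={float(train.duration)!r}\n")
        for t in train.times:
            fh.write(f"{float(t)!r}\n")


def read_spikes(path) -> SpikeTrain:
    duration = None
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "duration_ms=" in line:
                    duration = float(line.split("duration_ms=")[1])
                continue
            times.append(float(line))
    if duration is None:
        raise ValueError(f"{path}: missing '# duration_ms=' header")
    times = np.asarray(times)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: spike times not strictly increasing")
    if times.size and times[0] < 0:
        raise ValueError(f"{path}: negative spike time")
    return SpikeTrain(times, duration)


def write_recording_set(directory, rec: RecordingSet) -> None:
    """Persist a RecordingSet as protocol.csv + per-repetition files + meta."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.i_s.size) * rec.dt
    pd.DataFrame({"t_ms": t, "I_s_pA": rec.i_s, "I_d_pA": rec.i_d}).to_csv(
        directory / "protocol.csv", index=False, float_format=_FMT)
    for r in range(rec.n_repetitions):
        pd.DataFrame({"t_ms": t, "V_s_mV": rec.v_s[r], "V_d_mV": rec.v_d[r]}
                     ).to_csv(directory / f"rep{r:02d}_trace.csv", index=False,
                              float_format=_FMT)
        write_spikes(directory / f"rep{r:02d}_spikes.txt",
                     SpikeTrain(rec.spike_times[r], rec.duration_ms))
    meta = {
        "dt": rec.dt,
        "split_ms": rec.split_ms,
        "n_repetitions": rec.n_repetitions,
        "config": None if rec.config is None else rec.config.__dict__,
        "ground_truth": None if rec.ground_truth is None
        else rec.ground_truth.to_dict(),
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_recording_set(directory) -> RecordingSet:
    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    proto = pd.read_csv(directory / "protocol.csv",
                        float_precision="round_trip")
    v_s, v_d, spikes = [], [], []
    for r in range(meta["n_repetitions"]):
        df = pd.read_csv(directory / f"rep{r:02d}_trace.csv",
                         float_precision="round_trip")
        v_s.append(df["V_s_mV"].to_numpy())
        v_d.append(df["V_d_mV"].to_numpy())
        spikes.append(read_spikes(directory / f"rep{r:02d}_spikes.txt").times)
    config = (ProtocolConfig(**meta["config"])
              if meta.get("config") else None)
    gt = (TwoCompartmentModel.from_dict(meta["ground_truth"])
          if meta.get("ground_truth") else None)
    return RecordingSet(meta["dt"], proto["I_s_pA"].to_numpy(),
                        proto["I_d_pA"].to_numpy(), v_s, v_d, spikes,
                        split_ms=meta["split_ms"], ground_truth=gt,
                        config=config)
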