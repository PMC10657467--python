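"""Data model, on-disk format, and signal conditioning for patch-clamp traces.

Canonical units are fixed package-wide: time in ms (wall-clock offsets in s),
current in pA, voltage in mV, pressure in mmHg, concentrations in molar,
temperature in °C.  With conductance expressed in nS, Ohm's law
``I[pA] = G[nS] * V[mV]`` holds without conversion factors.

The on-disk dialect is a plain-text pair: a CSV sample table with header
``sweep_index,time_ms,current_pA,voltage_mV[,pressure_mmHg]`` sorted by
(sweep_index, time_ms), plus a JSON sidecar carrying the protocol, solution,
pressure events and provenance.  Sample indexing is 0-based and epoch time
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, ParameterError, TraceValidationError

__all__ = [
    "SolutionPair",
    "Epoch",
    "VoltageProtocol",
    "PressureStimulus",
    "Sweep",
    "Recording",
    "read_recording",
    "write_recording",
    "condition_sweep",
    "condition_recording",
]

_EPOCH_KINDS = ("hold", "step", "ramp")

# Accepted unit strings in sidecars, with multipliers to canonical units.
_UNIT_SCALES = {
    "time": {"ms": 1.0, "s": 1000.0},
    "current": {"pA": 1.0, "nA": 1000.0, "A": 1e12},
    "voltage": {"mV": 1.0, "V": 1000.0},
    "pressure": {"mmHg": 1.0},
}

# Float formatting for trace files. 12 significant digits keeps the
# write->read round trip numerically transparent at double precision.
_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class SolutionPair:
    """Intracellular/extracellular recording solutions for one experiment.

    ``delta_pH`` follows the proton-channel convention pH_o − pH_i; a positive
    gradient favors outward proton current at positive voltages.
    """

    pH_i: float
    pH_o: float
    metal_conc_i: float = 0.0
    metal_conc_o: float = 0.0
    metal_species: str = "none"
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pH_i < 14.0 and 0.0 < self.pH_o < 14.0):
            raise TraceValidationError(f"pH values must lie in (0, 14): {self.pH_i}, {self.pH_o}")
        if self.metal_conc_i < 0 or self.metal_conc_o < 0:
            raise TraceValidationError("metal concentrations must be >= 0")
        if self.metal_species not in ("K+", "Na+", "none"):
            raise TraceValidationError(f"unknown metal species {self.metal_species!r}")
        if self.metal_species == "none" and (self.metal_conc_i != 0 or self.metal_conc_o != 0):
            raise TraceValidationError("metal_species 'none' requires zero metal concentrations")

    @property
    def delta_pH(self) -> float:
        return self.pH_o - self.pH_i


@dataclass(frozen=True)
class Epoch:
    """One segment of a command-voltage protocol (piecewise linear)."""

    kind: str
    duration_ms: float
    V_start_mV: float
    V_end_mV: float

    def __post_init__(self) -> None:
        if self.kind not in _EPOCH_KINDS:
            raise TraceValidationError(f"epoch kind must be one of {_EPOCH_KINDS}, got {self.kind!r}")
        if not self.duration_ms > 0:
            raise TraceValidationError("epoch duration must be > 0")
        if self.kind in ("hold", "step") and self.V_start_mV != self.V_end_mV:
            raise TraceValidationError(f"{self.kind} epoch must have V_start == V_end")
        if self.kind == "ramp" and self.V_start_mV == self.V_end_mV:
            raise TraceValidationError("ramp epoch must have V_start != V_end")


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered epochs plus per-sweep stepping rules.

    ``incremented_epochs`` lists the indices of step epochs whose voltage is
    offset by ``sweep_index * sweep_increment_mV`` (a step family).
    """

    epochs: tuple[Epoch, ...]
    holding_mV: float
    sweep_increment_mV: float = 0.0
    incremented_epochs: tuple[int, ...] = ()
    n_sweeps: int = 1
    inter_sweep_interval_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        object.__setattr__(self, "incremented_epochs", tuple(self.incremented_epochs))
        if self.n_sweeps < 1:
            raise TraceValidationError("n_sweeps must be >= 1")
        for i in self.incremented_epochs:
            if not (0 <= i < len(self.epochs)):
                raise TraceValidationError(f"incremented epoch index {i} out of range")
            if self.epochs[i].kind != "step":
                raise TraceValidationError("only step epochs may carry a sweep increment")

    @property
    def total_duration_ms(self) -> float:
        return float(sum(e.duration_ms for e in self.epochs))

    def epoch_bounds_ms(self) -> list[tuple[float, float]]:
        bounds, t = [], 0.0
        for e in self.epochs:
            bounds.append((t, t + e.duration_ms))
            t += e.duration_ms
        return bounds

    def n_samples(self, sample_interval_ms: float) -> int:
        return int(math.ceil(self.total_duration_ms / sample_interval_ms - 1e-9))

    def epoch_slice(self, epoch_index: int, sample_interval_ms: float) -> slice:
        """Sample-index slice of an epoch; intervals are half-open [start, end)."""
        start, end = self.epoch_bounds_ms()[epoch_index]
        i0 = int(math.ceil(start / sample_interval_ms - 1e-9))
        i1 = int(math.ceil(end / sample_interval_ms - 1e-9))
        return slice(i0, i1)

    def epoch_voltage(self, epoch_index: int, sweep_index: int) -> tuple[float, float]:
        """(V_start, V_end) of an epoch after applying the sweep increment."""
        e = self.epochs[epoch_index]
        offset = (
            sweep_index * self.sweep_increment_mV
            if epoch_index in self.incremented_epochs
            else 0.0
        )
        return e.V_start_mV + offset, e.V_end_mV + offset

    def command(self, sweep_index: int, sample_interval_ms: float) -> np.ndarray:
        """Per-sample command voltage for one sweep (mV)."""
        n = self.n_samples(sample_interval_ms)
        out = np.empty(n, dtype=float)
        for i, (start, end) in enumerate(self.epoch_bounds_ms()):
            sl = self.epoch_slice(i, sample_interval_ms)
            vs, ve = self.epoch_voltage(i, sweep_index)
            t = np.arange(sl.start, sl.stop) * sample_interval_ms - start
            dur = end - start
            out[sl] = vs + (ve - vs) * (t / dur)
        return out


@dataclass(frozen=True)
class PressureStimulus:
    """A pipette-pressure step; negative magnitude means suction."""

    onset_s: float
    duration_s: float
    magnitude_mmHg: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise TraceValidationError("pressure stimulus duration must be > 0")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Sweep:
    """Uniformly sampled current/command (and optional pressure) traces."""

    sample_interval_ms: float
    current_pA: np.ndarray
    command_mV: np.ndarray
    pressure_mmHg: Optional[np.ndarray] = None
    sweep_index: int = 0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.command_mV = np.asarray(self.command_mV, dtype=float)
        if self.pressure_mmHg is not None:
            self.pressure_mmHg = np.asarray(self.pressure_mmHg, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.sample_interval_ms > 0:
            raise TraceValidationError("sample_interval_ms must be > 0")
        n = self.current_pA.size
        if n < 2:
            raise TraceValidationError("a sweep needs at least 2 samples")
        if self.command_mV.size != n:
            raise TraceValidationError("current and command lengths differ")
        if self.pressure_mmHg is not None and self.pressure_mmHg.size != n:
            raise TraceValidationError("pressure length differs from current")

    @property
    def n_samples(self) -> int:
        return int(self.current_pA.size)

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_ms


@dataclass
class Recording:
    """A set of sweeps plus protocol, solutions and pressure metadata.

    The unit every analysis consumes.  ``provenance`` carries generator
    parameters for synthetic data and correction factors added by analysis
    steps (leak conductance, rundown scale factors).
    """

    sweeps: list[Sweep]
    protocol: VoltageProtocol
    solution: SolutionPair
    pressure_events: list[PressureStimulus] = field(default_factory=list)
    labels: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, check_command: bool = True, atol_mV: float = 1e-6) -> None:
        if len(self.sweeps) == 0:
            raise TraceValidationError("recording has no sweeps")
        idx = [s.sweep_index for s in self.sweeps]
        if len(set(idx)) != len(idx):
            raise TraceValidationError("sweep_index values must be unique")
        starts = [s.start_time_s for s in self.sweeps]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise TraceValidationError("sweeps must be ordered by start_time_s")
        if check_command:
            for s in self.sweeps:
                expected_n = self.protocol.n_samples(s.sample_interval_ms)
                if s.n_samples != expected_n:
                    raise TraceValidationError(
                        f"sweep {s.sweep_index}: {s.n_samples} samples, protocol implies {expected_n}"
                    )
                expected = self.protocol.command(s.sweep_index, s.sample_interval_ms)
                err = np.max(np.abs(expected - s.command_mV))
                if err > atol_mV:
                    raise TraceValidationError(
                        f"sweep {s.sweep_index}: command deviates from protocol by {err:.3g} mV"
                    )

    @property
    def sample_interval_ms(self) -> float:
        return self.sweeps[0].sample_interval_ms

    def map_sweeps(self, fn) -> "Recording":
        """New Recording with ``fn(sweep) -> sweep`` applied to every sweep."""
        rec = dataclasses.replace(self, sweeps=[fn(s) for s in self.sweeps])
        return rec


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------


def _paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".csv":
        base = p.with_suffix("")
    elif p.suffix == ".json":
        base = p.with_suffix("")
    else:
        base = p
    return base.with_suffix(".csv"), base.with_suffix(".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_recording(rec: Recording, path) -> Path:
    """Write a Recording as a CSV trace table plus JSON sidecar.

    Output is byte-deterministic for identical input: fixed column order,
    fixed float formatting, fixed JSON key order.
    Returns the CSV path; the sidecar sits next to it with a .json suffix.
    """
    rec.validate()
    csv_path, json_path = _paths(path)

    has_pressure = any(s.pressure_mmHg is not None for s in rec.sweeps)
    frames = []
    for s in rec.sweeps:
        cols = {
            "sweep_index": np.full(s.n_samples, s.sweep_index, dtype=int),
            "time_ms": s.times_ms(),
            "current_pA": s.current_pA,
            "voltage_mV": s.command_mV,
        }
        if has_pressure:
            pr = s.pressure_mmHg if s.pressure_mmHg is not None else np.zeros(s.n_samples)
            cols["pressure_mmHg"] = pr
        frames.append(pd.DataFrame(cols))
    table = pd.concat(frames, ignore_index=True)
    try:
        table.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    except OSError as exc:  # pragma: no cover - passthrough
        raise exc

    sidecar = {
        "sample_interval_ms": rec.sample_interval_ms,
        "n_sweeps": len(rec.sweeps),
        "holding_mV": rec.protocol.holding_mV,
        "sweep_increment_mV": rec.protocol.sweep_increment_mV,
        "incremented_epochs": list(rec.protocol.incremented_epochs),
        "inter_sweep_interval_s": rec.protocol.inter_sweep_interval_s,
        "epochs": [dataclasses.asdict(e) for e in rec.protocol.epochs],
        "sweep_start_times_s": [s.start_time_s for s in rec.sweeps],
        "sweep_indices": [s.sweep_index for s in rec.sweeps],
        "pH_i": rec.solution.pH_i,
        "pH_o": rec.solution.pH_o,
        "metal_species": rec.solution.metal_species,
        "metal_conc_i_M": rec.solution.metal_conc_i,
        "metal_conc_o_M": rec.solution.metal_conc_o,
        "temperature_C": rec.solution.temperature_C,
        "pressure_events": [dataclasses.asdict(e) for e in rec.pressure_events],
        "units": {"time": "ms", "current": "pA", "voltage": "mV", "pressure": "mmHg"},
        "labels": _jsonable(rec.labels),
        "provenance": _jsonable(rec.provenance),
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")
    return csv_path


def _unit_scale(units: dict, key: str) -> float:
    name = units.get(key, {"time": "ms", "current": "pA", "voltage": "mV", "pressure": "mmHg"}[key])
    table = _UNIT_SCALES[key]
    if name not in table:
        raise TraceValidationError(f"unknown {key} unit {name!r} in sidecar")
    return table[name]


def read_recording(path) -> Recording:
    """Read a CSV+JSON trace pair and return a validated Recording.

    Units are taken from the sidecar's ``units`` block (defaults: canonical)
    and converted to ms / pA / mV / mmHg on load.
    """
    csv_path, json_path = _paths(path)
    if not json_path.exists():
        raise FormatError(f"missing JSON sidecar {json_path}")
    if not csv_path.exists():
        raise FormatError(f"missing trace CSV {csv_path}")
    with open(json_path) as fh:
        side = json.load(fh)

    units = side.get("units", {})
    t_scale = _unit_scale(units, "time")
    i_scale = _unit_scale(units, "current")
    v_scale = _unit_scale(units, "voltage")
    p_scale = _unit_scale(units, "pressure")

    table = pd.read_csv(csv_path)
    for col in ("sweep_index", "time_ms", "current_pA", "voltage_mV"):
        if col not in table.columns:
            raise TraceValidationError(f"trace CSV lacks required column {col!r}")
    has_pressure = "pressure_mmHg" in table.columns

    dt = float(side["sample_interval_ms"]) * t_scale
    epochs = tuple(
        Epoch(
            kind=e["kind"],
            duration_ms=float(e["duration_ms"]) * t_scale,
            V_start_mV=float(e["V_start_mV"]) * v_scale,
            V_end_mV=float(e["V_end_mV"]) * v_scale,
        )
        for e in side["epochs"]
    )
    protocol = VoltageProtocol(
        epochs=epochs,
        holding_mV=float(side["holding_mV"]) * v_scale,
        sweep_increment_mV=float(side.get("sweep_increment_mV", 0.0)) * v_scale,
        incremented_epochs=tuple(side.get("incremented_epochs", ())),
        n_sweeps=int(side["n_sweeps"]),
        inter_sweep_interval_s=float(side.get("inter_sweep_interval_s", 0.0)),
    )
    solution = SolutionPair(
        pH_i=float(side["pH_i"]),
        pH_o=float(side["pH_o"]),
        metal_conc_i=float(side.get("metal_conc_i_M", 0.0)),
        metal_conc_o=float(side.get("metal_conc_o_M", 0.0)),
        metal_species=side.get("metal_species", "none"),
        temperature_C=float(side.get("temperature_C", 22.0)),
    )
    events = [
        PressureStimulus(
            onset_s=float(e["onset_s"]),
            duration_s=float(e["duration_s"]),
            magnitude_mmHg=float(e["magnitude_mmHg"]) * p_scale,
        )
        for e in side.get("pressure_events", [])
    ]

    start_times = side.get("sweep_start_times_s")
    indices = side.get("sweep_indices")
    sweeps = []
    grouped = table.groupby("sweep_index", sort=True)
    n_sweeps = int(side["n_sweeps"])
    if grouped.ngroups != n_sweeps:
        raise TraceValidationError(
            f"CSV holds {grouped.ngroups} sweeps but sidecar declares {n_sweeps}"
        )
    for pos, (idx, grp) in enumerate(grouped):
        grp = grp.sort_values("time_ms")
        cur = grp["current_pA"].to_numpy(dtype=float) * i_scale
        cmd = grp["voltage_mV"].to_numpy(dtype=float) * v_scale
        pr = grp["pressure_mmHg"].to_numpy(dtype=float) * p_scale if has_pressure else None
        if cur.size != cmd.size:
            raise TraceValidationError("column length mismatch inside a sweep")
        start = float(start_times[pos]) if start_times else pos * protocol.inter_sweep_interval_s
        sw_idx = int(indices[pos]) if indices else int(idx)
        sweeps.append(
            Sweep(
                sample_interval_ms=dt,
                current_pA=cur,
                command_mV=cmd,
                pressure_mmHg=pr,
                sweep_index=sw_idx,
                start_time_s=start,
            )
        )
    return Recording(
        sweeps=sweeps,
        protocol=protocol,
        solution=solution,
        pressure_events=events,
        labels=side.get("labels", {}),
        provenance=side.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------


def condition_sweep(
    sweep: Sweep,
    cutoff_Hz: float,
    baseline_window_ms: tuple[float, float],
) -> Sweep:
    """Low-pass filter the current and zero its baseline.

    The offline filter is a zero-phase digital approximation of a 4-pole
    low-pass Bessel: a 2nd-order Bessel section (magnitude-normalized so the
    gain is -3 dB at ``cutoff_Hz``) applied forward and backward with
    ``sosfiltfilt``, giving a monotone 4-pole magnitude response and no phase
    delay — isochronal time points are not shifted.  The mean current over
    ``baseline_window_ms`` (half-open, relative to sweep start) is then
    subtracted.  Command and pressure channels are returned unchanged.
    """
    fs = 1000.0 / sweep.sample_interval_ms
    if not (0.0 < cutoff_Hz < fs / 2.0):
        raise ParameterError(f"cutoff {cutoff_Hz} Hz outside (0, Nyquist={fs / 2:.6g} Hz)")
    t0, t1 = baseline_window_ms
    dur = sweep.n_samples * sweep.sample_interval_ms
    if not (0.0 <= t0 < t1 <= dur + 1e-9):
        raise ParameterError(f"baseline window ({t0}, {t1}) ms outside sweep [0, {dur:.6g}) ms")

    sos = signal.bessel(2, cutoff_Hz, btype="low", fs=fs, output="sos", norm="mag")
    filtered = signal.sosfiltfilt(sos, sweep.current_pA)

    dt = sweep.sample_interval_ms
    i0 = int(math.ceil(t0 / dt - 1e-9))
    i1 = max(i0 + 1, int(math.ceil(t1 / dt - 1e-9)))
    baseline = float(np.mean(filtered[i0:i1]))
    return replace(sweep, current_pA=filtered - baseline)


def default_baseline_window(protocol: VoltageProtocol, max_ms: float = 50.0) -> tuple[float, float]:
    """Last ``max_ms`` (or the whole epoch if shorter) of the holding period
    preceding the first non-holding epoch."""
    bounds = protocol.epoch_bounds_ms()
    first = protocol.epochs[0]
    if first.kind != "hold":
        raise ParameterError("protocol does not start with a holding epoch")
    start, end = bounds[0]
    return (max(start, end - max_ms), end)


def condition_recording(
    rec: Recording,
    cutoff_Hz: float,
    baseline_window_ms: Optional[tuple[float, float]] = None,
) -> Recording:
    """Apply :func:`condition_sweep` to every sweep of a recording.

    When no baseline window is given, the default is the last 50 ms of the
    initial holding epoch.
    """
    win = baseline_window_ms or default_baseline_window(rec.protocol)
    return rec.map_sweeps(lambda s: condition_sweep(s, cutoff_Hz, win))
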