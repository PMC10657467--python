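"""Generative model of inside-out-patch Hv-channel currents.

The simulator produces recordings with exactly the statistical structure the
analysis pipeline assumes:

* a Boltzmann-gated proton conductance ``G_max / (1 + exp((V_half - V)/s))``
  whose midpoint shifts linearly with the transmembrane pH gradient
  (ΔpH = pH_o − pH_i) and with intracellular pH,
* a Nernstian reversal potential (Goldman–Hodgkin–Katz when a metal ion is
  given a nonzero relative permeability),
* single-exponential activation/deactivation kinetics (one first-order gate),
* ohmic leak reversing at 0 mV,
* slow multiplicative rundown of the maximal conductance in wall-clock time,
* a latching silent→primed availability switch triggered by sustained
  pipette suction (mechanical priming), and
* optional Hill-type inhibition plus additive i.i.d. Gaussian noise.

Voltages are mV, currents pA, conductances nS, times ms (wall clock s).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .trace_model_io import (
    Epoch,
    PressureStimulus,
    Recording,
    SolutionPair,
    Sweep,
    VoltageProtocol,
)

__all__ = [
    "ChannelParams",
    "preset",
    "make_protocol",
    "default_priming_stimulus",
    "steady_state_current",
    "simulate_recording",
    "priming_latch_time",
    "boltzmann_open_fraction",
    "midpoint_mV",
    "reversal_mV",
]

# Reference condition at which V_half_ref_mV is defined.
REF_DELTA_PH = 0.0
REF_PH_I = 6.0

_GAS_R = 8.314462618  # J / (mol K)
_FARADAY = 96485.33212  # C / mol


def _rtf_mV(temperature_C: float) -> float:
    return 1000.0 * _GAS_R * (temperature_C + 273.15) / _FARADAY


@dataclass(frozen=True)
class ChannelParams:
    """Full parameterization of the simulated Hv channel.

    ``S_dpH_mV`` and ``S_pHi_mV`` are positive magnitudes: the activation
    midpoint is ``V_half_ref − S_dpH·ΔpH − S_pHi·(6.0 − pH_i)``, so a larger
    ΔpH or a lower pH_i moves activation to more negative voltages, as
    observed for proton channels.  ``silent_availability`` is the fraction of
    the conductance available before mechanical priming; priming latches
    permanently once suction of at least ``priming_threshold_mmHg`` is held
    for ``priming_min_duration_s``.
    """

    G_max_nS: float = 1.0
    V_half_ref_mV: float = 44.8
    slope_mV: float = 14.3
    S_dpH_mV: float = 60.0
    S_pHi_mV: float = 35.0
    tau_act_ms: float = 100.0
    tau_deact_ms: float = 50.0
    g_leak_nS: float = 0.0
    rundown_tau_s: Optional[float] = None
    silent_availability: float = 1.0
    priming_threshold_mmHg: float = 8.0
    priming_min_duration_s: float = 2.0
    inhibitor_IC50_uM: Optional[float] = None
    inhibitor_h: Optional[float] = None
    inhibitor_conc_uM: float = 0.0
    noise_sd_pA: float = 0.0
    metal_perm_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.G_max_nS < 0:
            raise ParameterError("G_max_nS must be >= 0")
        if self.slope_mV <= 0:
            raise ParameterError("slope_mV must be > 0")
        if not (0.0 <= self.silent_availability <= 1.0):
            raise ParameterError("silent_availability must lie in [0, 1]")
        if self.tau_act_ms <= 0 or self.tau_deact_ms <= 0:
            raise ParameterError("time constants must be > 0")
        if self.noise_sd_pA < 0:
            raise ParameterError("noise_sd_pA must be >= 0")
        if self.metal_perm_ratio < 0:
            raise ParameterError("metal_perm_ratio must be >= 0")
        if self.rundown_tau_s is not None and self.rundown_tau_s <= 0:
            raise ParameterError("rundown_tau_s must be > 0 (or None to disable)")
        if self.inhibitor_conc_uM < 0:
            raise ParameterError("inhibitor_conc_uM must be >= 0")
        if self.inhibitor_conc_uM > 0 and (
            self.inhibitor_IC50_uM is None or self.inhibitor_h is None
        ):
            raise ParameterError("inhibitor concentration given without IC50/h")


_PRESETS = {
    # Sitka-spruce-like channel: constitutively active, mildly mechanosensitive.
    # Midpoint and slope follow the tail-current G-V of the spruce channel
    # (V_half 44.8 mV, slope 14.3 mV at pH_i = pH_o = 6.0); the pre-priming
    # availability of 1/1.5 reproduces its two-pulse ratio of ~1.5.
    "PsHv1_like": ChannelParams(
        G_max_nS=1.0,
        V_half_ref_mV=44.8,
        slope_mV=14.3,
        S_dpH_mV=60.0,
        S_pHi_mV=35.0,
        tau_act_ms=100.0,
        tau_deact_ms=50.0,
        g_leak_nS=0.1,
        silent_availability=1.0 / 1.5,
        inhibitor_IC50_uM=372.0,
        inhibitor_h=1.42,
        noise_sd_pA=1.0,
    ),
    # Arabidopsis-like channel: electrically silent until mechanically primed.
    # silent_availability 1/17 is a tuning choice that makes the simulated
    # two-pulse ratio ~17; it is not a measured constant.
    "AtHv1_like": ChannelParams(
        G_max_nS=1.0,
        V_half_ref_mV=60.0,
        slope_mV=16.0,
        S_dpH_mV=47.0,
        S_pHi_mV=38.0,
        tau_act_ms=100.0,
        tau_deact_ms=50.0,
        g_leak_nS=0.1,
        silent_availability=1.0 / 17.0,
        noise_sd_pA=1.0,
    ),
    # Pure leak membrane (uninjected-oocyte-style negative control).
    "leak_only": ChannelParams(
        G_max_nS=0.0,
        g_leak_nS=1.0,
        silent_availability=1.0,
        noise_sd_pA=1.0,
    ),
}


def preset(name: str) -> ChannelParams:
    """Documented parameter sets: ``PsHv1_like``, ``AtHv1_like``, ``leak_only``."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Biophysics
# ---------------------------------------------------------------------------


def midpoint_mV(params: ChannelParams, solution: SolutionPair) -> float:
    """Activation midpoint under the given solution pair."""
    return (
        params.V_half_ref_mV
        - params.S_dpH_mV * (solution.delta_pH - REF_DELTA_PH)
        - params.S_pHi_mV * (REF_PH_I - solution.pH_i)
    )


def reversal_mV(params: ChannelParams, solution: SolutionPair) -> float:
    """Reversal potential: Nernst for protons, or GHK with one metal ion."""
    rtf = _rtf_mV(solution.temperature_C)
    h_i = 10.0 ** (-solution.pH_i)
    h_o = 10.0 ** (-solution.pH_o)
    if params.metal_perm_ratio > 0.0:
        num = params.metal_perm_ratio * solution.metal_conc_o + h_o
        den = params.metal_perm_ratio * solution.metal_conc_i + h_i
        return rtf * math.log(num / den)
    return rtf * math.log(h_o / h_i)


def boltzmann_open_fraction(V_mV, V_half_mV: float, slope_mV: float):
    """Steady-state open fraction 1 / (1 + exp((V_half − V)/s))."""
    x = np.clip((V_half_mV - np.asarray(V_mV, dtype=float)) / slope_mV, -700, 700)
    return 1.0 / (1.0 + np.exp(x))


def _inhibition_factor(params: ChannelParams) -> float:
    if params.inhibitor_conc_uM <= 0 or params.inhibitor_IC50_uM is None:
        return 1.0
    c, ic50, h = params.inhibitor_conc_uM, params.inhibitor_IC50_uM, params.inhibitor_h
    pct = 100.0 * c**h / (ic50**h + c**h)
    return 1.0 - pct / 100.0


def _rundown_factor(params: ChannelParams, wallclock_s) -> np.ndarray | float:
    if params.rundown_tau_s is None or not np.isfinite(params.rundown_tau_s):
        return 1.0
    return np.exp(-np.asarray(wallclock_s, dtype=float) / params.rundown_tau_s)


def steady_state_current(
    params: ChannelParams,
    V_mV: float,
    solution: SolutionPair,
    primed: bool = True,
    wallclock_s: float = 0.0,
) -> float:
    """Deterministic steady-state current (pA) at a command voltage.

    ``A·G_max·rundown·inhibition·P_open(V)·(V − V_rev) + g_leak·V`` where
    A = 1 if primed else ``silent_availability``.
    """
    avail = 1.0 if primed else params.silent_availability
    vh = midpoint_mV(params, solution)
    vrev = reversal_mV(params, solution)
    popen = float(boltzmann_open_fraction(V_mV, vh, params.slope_mV))
    gated = (
        avail
        * params.G_max_nS
        * float(_rundown_factor(params, wallclock_s))
        * _inhibition_factor(params)
        * popen
        * (V_mV - vrev)
    )
    return gated + params.g_leak_nS * V_mV


# ---------------------------------------------------------------------------
# Protocol builders
# ---------------------------------------------------------------------------

_PROTOCOL_KINDS = (
    "step_family",
    "tail_family",
    "slow_ramp",
    "vrev_ramp",
    "two_pulse_priming",
    "inhibition_series",
)


def _sweep_count(V_first: float, V_last: float, increment: float) -> int:
    n_float = (V_last - V_first) / increment + 1.0
    n = round(n_float)
    if n < 1 or abs(n_float - n) > 1e-9:
        raise ParameterError(
            f"voltage range {V_first}..{V_last} mV is not an integer number of "
            f"{increment} mV increments"
        )
    return int(n)


def make_protocol(kind: str, **settings) -> VoltageProtocol:
    """Build one of the standard experimental designs.

    Defaults reproduce the designs used throughout the analyses: the tail
    family includes a fixed +120 mV pre-pulse before each variable test step
    (for rundown correction), the slow ramp runs at 3.5 mV/s, the
    reversal-potential ramp at 1 mV/ms after a +120 mV step, and the
    two-pulse priming protocol has two identical depolarizations separated by
    a holding interval long enough for a 3 s suction stimulus.
    """
    if kind not in _PROTOCOL_KINDS:
        raise ParameterError(f"unknown protocol kind {kind!r}; choose from {_PROTOCOL_KINDS}")
    s = dict(settings)
    holding = float(s.pop("holding_mV", -60.0))

    def hold(ms):
        return Epoch("hold", ms, holding, holding)

    if kind == "step_family":
        v0 = float(s.pop("V_first_mV", -40.0))
        v1 = float(s.pop("V_last_mV", 120.0))
        inc = float(s.pop("increment_mV", 20.0))
        hold_ms = float(s.pop("hold_ms", 200.0))
        step_ms = float(s.pop("step_ms", 500.0))
        post_ms = float(s.pop("post_ms", 300.0))
        n = _sweep_count(v0, v1, inc)
        epochs = (hold(hold_ms), Epoch("step", step_ms, v0, v0), hold(post_ms))
        proto = VoltageProtocol(epochs, holding, inc, (1,), n, float(s.pop("inter_sweep_interval_s", 2.0)))
    elif kind == "tail_family":
        v0 = float(s.pop("V_first_mV", -40.0))
        v1 = float(s.pop("V_last_mV", 120.0))
        inc = float(s.pop("increment_mV", 20.0))
        pre_mV = float(s.pop("prepulse_mV", 120.0))
        pre_ms = float(s.pop("prepulse_ms", 300.0))
        gap_ms = float(s.pop("gap_ms", 300.0))
        step_ms = float(s.pop("step_ms", 500.0))
        tail_mV = float(s.pop("tail_mV", -60.0))
        tail_ms = float(s.pop("tail_ms", 300.0))
        n = _sweep_count(v0, v1, inc)
        epochs = (
            hold(200.0),
            Epoch("step", pre_ms, pre_mV, pre_mV),  # rundown-correction pre-pulse
            hold(gap_ms),
            Epoch("step", step_ms, v0, v0),  # variable test step (epoch 3)
            Epoch("step", tail_ms, tail_mV, tail_mV),  # fixed tail (epoch 4)
            hold(100.0),
        )
        proto = VoltageProtocol(epochs, holding, inc, (3,), n, float(s.pop("inter_sweep_interval_s", 3.0)))
    elif kind == "slow_ramp":
        v0 = float(s.pop("V_from_mV", -60.0))
        v1 = float(s.pop("V_to_mV", 120.0))
        rate = float(s.pop("rate_mV_per_s", 3.5))
        if rate <= 0:
            raise ParameterError("ramp rate must be > 0")
        dur = abs(v1 - v0) / rate * 1000.0
        epochs = (hold(200.0), Epoch("ramp", dur, v0, v1), hold(100.0))
        proto = VoltageProtocol(epochs, holding, 0.0, (), 1, float(s.pop("inter_sweep_interval_s", 0.0)))
    elif kind == "vrev_ramp":
        step_mV = float(s.pop("step_mV", 120.0))
        step_ms = float(s.pop("step_ms", 300.0))
        v1 = float(s.pop("V_to_mV", -60.0))
        rate = float(s.pop("rate_mV_per_ms", 1.0))
        if rate <= 0:
            raise ParameterError("ramp rate must be > 0")
        dur = abs(v1 - step_mV) / rate
        epochs = (
            hold(200.0),
            Epoch("step", step_ms, step_mV, step_mV),
            Epoch("ramp", dur, step_mV, v1),
            hold(100.0),
        )
        proto = VoltageProtocol(epochs, holding, 0.0, (), 1, float(s.pop("inter_sweep_interval_s", 0.0)))
    elif kind == "two_pulse_priming":
        test_mV = float(s.pop("test_mV", 120.0))
        pulse_ms = float(s.pop("pulse_ms", 300.0))
        inter_ms = float(s.pop("inter_ms", 4000.0))
        epochs = (
            hold(500.0),
            Epoch("step", pulse_ms, test_mV, test_mV),  # pulse A
            hold(inter_ms),  # suction applied here
            Epoch("step", pulse_ms, test_mV, test_mV),  # pulse B
            hold(300.0),
        )
        proto = VoltageProtocol(epochs, holding, 0.0, (), 1, float(s.pop("inter_sweep_interval_s", 0.0)))
    else:  # inhibition_series
        step_mV = float(s.pop("step_mV", 120.0))
        step_ms = float(s.pop("step_ms", 500.0))
        n = int(s.pop("n_sweeps", 1))
        epochs = (hold(200.0), Epoch("step", step_ms, step_mV, step_mV), hold(300.0))
        proto = VoltageProtocol(epochs, holding, 0.0, (), n, float(s.pop("inter_sweep_interval_s", 5.0)))
    if s:
        raise ParameterError(f"unknown settings for {kind}: {sorted(s)}")
    return proto


def default_priming_stimulus(
    protocol: VoltageProtocol,
    magnitude_mmHg: float = -10.0,
    duration_s: float = 3.0,
) -> PressureStimulus:
    """Suction step centered in the inter-pulse holding epoch of a two-pulse
    protocol (−10 mmHg for 3 s by default)."""
    bounds = protocol.epoch_bounds_ms()
    # the inter-pulse hold is the epoch between the two matching steps
    steps = [i for i, e in enumerate(protocol.epochs) if e.kind == "step"]
    if len(steps) < 2:
        raise ParameterError("protocol has no two depolarizing pulses")
    inter = range(steps[0] + 1, steps[1])
    holds = [i for i in inter if protocol.epochs[i].kind == "hold"]
    if not holds:
        raise ParameterError("no holding epoch between the two pulses")
    start_ms, end_ms = bounds[holds[0]][0], bounds[holds[-1]][1]
    span_s = (end_ms - start_ms) / 1000.0
    if span_s < duration_s:
        raise ParameterError("inter-pulse interval shorter than the stimulus")
    onset = start_ms / 1000.0 + (span_s - duration_s) / 2.0
    return PressureStimulus(onset_s=onset, duration_s=duration_s, magnitude_mmHg=magnitude_mmHg)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def priming_latch_time(
    pressure_events: Sequence[PressureStimulus], params: ChannelParams
) -> Optional[float]:
    """Wall-clock time (s) at which the channel latches into the primed state,
    or None if no stimulus qualifies.

    A stimulus qualifies when its suction reaches ``priming_threshold_mmHg``
    and lasts at least ``priming_min_duration_s``; the latch engages after the
    minimum duration has elapsed and never reverts.
    """
    times = [
        ev.onset_s + params.priming_min_duration_s
        for ev in pressure_events
        if ev.magnitude_mmHg <= -params.priming_threshold_mmHg
        and ev.duration_s >= params.priming_min_duration_s
    ]
    return min(times) if times else None


def _gate_trajectory(
    params: ChannelParams,
    protocol: VoltageProtocol,
    sweep_index: int,
    dt_ms: float,
    vh: float,
) -> np.ndarray:
    """Open fraction at each sample time for one sweep.

    Constant-voltage epochs are integrated analytically; ramps use an
    exponential-Euler step per sample.  The gate starts at steady state for
    the first epoch's initial voltage.
    """
    n = protocol.n_samples(dt_ms)
    p = np.empty(n, dtype=float)
    v0, _ = protocol.epoch_voltage(0, sweep_index)
    state = float(boltzmann_open_fraction(v0, vh, params.slope_mV))
    for i, (start, end) in enumerate(protocol.epoch_bounds_ms()):
        sl = protocol.epoch_slice(i, dt_ms)
        vs, ve = protocol.epoch_voltage(i, sweep_index)
        epoch = protocol.epochs[i]
        if epoch.kind in ("hold", "step"):
            p_inf = float(boltzmann_open_fraction(vs, vh, params.slope_mV))
            tau = params.tau_act_ms if p_inf > state else params.tau_deact_ms
            t = np.arange(sl.start, sl.stop) * dt_ms - start
            p[sl] = p_inf + (state - p_inf) * np.exp(-t / tau)
            state = p_inf + (state - p_inf) * math.exp(-(end - start) / tau)
        else:  # ramp: voltage changes every sample
            dur = end - start
            ks = np.arange(sl.start, sl.stop)
            vgrid = vs + (ve - vs) * (ks * dt_ms - start) / dur
            pinf = boltzmann_open_fraction(vgrid, vh, params.slope_mV)
            out = np.empty(ks.size, dtype=float)
            fa = 1.0 - math.exp(-dt_ms / params.tau_act_ms)
            fd = 1.0 - math.exp(-dt_ms / params.tau_deact_ms)
            st = state
            for j in range(ks.size):
                out[j] = st
                target = pinf[j]
                st = st + (target - st) * (fa if target > st else fd)
            p[sl] = out
            state = st
    return p


def simulate_recording(
    params: ChannelParams,
    protocol: VoltageProtocol,
    solution: SolutionPair,
    pressure_events: Sequence[PressureStimulus] = (),
    seed: Optional[int] = None,
    sample_interval_ms: float = 0.2,
    labels: Optional[dict] = None,
) -> Recording:
    """Integrate the generative model over a protocol and return a Recording.

    Identical ``(params, protocol, solution, pressure_events, seed)`` give a
    bit-identical Recording.  A seed is mandatory whenever ``noise_sd_pA > 0``.
    """
    if params.noise_sd_pA > 0 and seed is None:
        raise ParameterError("a seed is required when noise_sd_pA > 0")
    rng = np.random.default_rng(seed) if seed is not None else None

    vh = midpoint_mV(params, solution)
    vrev = reversal_mV(params, solution)
    inhib = _inhibition_factor(params)
    latch = priming_latch_time(pressure_events, params)
    events = list(pressure_events)

    dt = sample_interval_ms
    interval = protocol.inter_sweep_interval_s
    if protocol.n_sweeps > 1 and interval <= 0:
        interval = protocol.total_duration_ms / 1000.0 + 1.0

    sweeps = []
    for k in range(protocol.n_sweeps):
        start_s = k * interval
        cmd = protocol.command(k, dt)
        t_wall = start_s + np.arange(cmd.size) * dt / 1000.0
        popen = _gate_trajectory(params, protocol, k, dt, vh)
        if latch is None:
            avail = params.silent_availability
        else:
            avail = np.where(t_wall >= latch, 1.0, params.silent_availability)
        gated = (
            avail
            * params.G_max_nS
            * _rundown_factor(params, t_wall)
            * inhib
            * popen
            * (cmd - vrev)
        )
        current = gated + params.g_leak_nS * cmd
        if params.noise_sd_pA > 0:
            current = current + rng.normal(0.0, params.noise_sd_pA, size=current.size)
        pressure = None
        if events:
            pressure = np.zeros(cmd.size)
            for ev in events:
                mask = (t_wall >= ev.onset_s) & (t_wall < ev.end_s)
                pressure[mask] = ev.magnitude_mmHg
        sweeps.append(
            Sweep(
                sample_interval_ms=dt,
                current_pA=current,
                command_mV=cmd,
                pressure_mmHg=pressure,
                sweep_index=k,
                start_time_s=start_s,
            )
        )

    prov = {
        "generator": "hvprime.synthetic_data.simulate_recording",
        "seed": seed,
        "params": dataclasses.asdict(params),
        "primed_at_s": latch,
    }
    proto = protocol
    if protocol.n_sweeps > 1 and protocol.inter_sweep_interval_s <= 0:
        proto = dataclasses.replace(protocol, inter_sweep_interval_s=interval)
    return Recording(
        sweeps=sweeps,
        protocol=proto,
        solution=solution,
        pressure_events=events,
        labels=labels or {},
        provenance=prov,
    )
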