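"""Conductance–voltage analysis for voltage-gated proton channels.

Implements the standard workflow of an inside-out-patch gating study:

* ohmic leak subtraction from a subthreshold voltage window,
* rundown correction by scaling each sweep to a fixed +120 mV pre-pulse,
* G–V extraction from tail currents, ``G(V_test) = (I_test − I_tail) /
  (V_test − V_tail)``, or from ramp I–V curves, ``G(V) = I(V)/(V − V_rev)``,
* Boltzmann fitting ``G(V) = G_max / (1 + exp((V_half − V)/s))``,
* the activation-threshold metric V_T, estimated either as the V-intercept of
  the steepest linear segment of the I–V curve or in closed form from the
  Boltzmann parameters, ``V_T = (a·V_half + V_rev)/(a + 1)`` with
  ``a = (V_half − V_rev)/(2s)`` (the tangent to the I–V at V_half), and
* the ΔpH-shift analysis with the symmetric-pH correction that isolates the
  dependence on the transmembrane gradient from the dependence on pH_i.

V_T is independent of the expression level of the channel: scaling every
current by a constant leaves both estimators unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateInputError,
    FitFailureError,
    MethodInapplicableError,
    ParameterError,
    UnreliableCorrectionError,
)
from .trace_model_io import Recording, SolutionPair, Sweep

__all__ = [
    "IVCurve",
    "GVCurve",
    "BoltzmannFit",
    "ThresholdResult",
    "ShiftResult",
    "iv_from_ramp",
    "subtract_leak",
    "correct_rundown",
    "tail_gv",
    "ramp_gv",
    "fit_boltzmann",
    "normalize_gv",
    "average_gvs",
    "vt_intercept",
    "vt_from_fit",
    "dpH_shift_analysis",
]


@dataclass
class IVCurve:
    """Current–voltage relationship (V strictly increasing, >= 4 points)."""

    V_mV: np.ndarray
    I_pA: np.ndarray
    source: str = "ramp"  # "ramp" | "step_isochronal"
    solution: Optional[SolutionPair] = None

    def __post_init__(self) -> None:
        self.V_mV = np.asarray(self.V_mV, dtype=float)
        self.I_pA = np.asarray(self.I_pA, dtype=float)
        if self.V_mV.size != self.I_pA.size:
            raise ParameterError("V and I lengths differ")
        if self.V_mV.size < 4:
            raise ParameterError("an IVCurve needs at least 4 points")
        if not np.all(np.diff(self.V_mV) > 0):
            raise ParameterError("IVCurve voltages must be strictly increasing")


@dataclass
class GVCurve:
    """Conductance–voltage relationship; small negative noise excursions
    (>= −5% of the maximum) are tolerated."""

    V_mV: np.ndarray
    G_nS: np.ndarray
    normalized: bool = False
    solution: Optional[SolutionPair] = None

    def __post_init__(self) -> None:
        self.V_mV = np.asarray(self.V_mV, dtype=float)
        self.G_nS = np.asarray(self.G_nS, dtype=float)
        if self.V_mV.size != self.G_nS.size:
            raise ParameterError("V and G lengths differ")
        if not np.all(np.diff(self.V_mV) > 0):
            raise ParameterError("GVCurve voltages must be strictly increasing")
        gmax = float(np.max(self.G_nS))
        if self.normalized and abs(gmax - 1.0) > 1e-9:
            raise ParameterError("normalized GVCurve must have max G = 1")
        if gmax > 0 and float(np.min(self.G_nS)) < -0.05 * gmax:
            raise ParameterError("conductance more negative than -5% of max")


@dataclass
class BoltzmannFit:
    """Least-squares Boltzmann parameters with standard errors.

    ``amplitude`` is the fitted G_max in the units of the input curve;
    ``G_max_nS`` is None when the fit was performed on normalized data.
    """

    amplitude: float
    V_half_mV: float
    slope_mV: float
    stderr_amplitude: float
    stderr_V_half_mV: float
    stderr_slope_mV: float
    rss: float
    normalized: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def G_max_nS(self) -> Optional[float]:
        return None if self.normalized else self.amplitude

    def predict(self, V_mV) -> np.ndarray:
        x = np.clip((self.V_half_mV - np.asarray(V_mV, float)) / self.slope_mV, -700, 700)
        return self.amplitude / (1.0 + np.exp(x))


@dataclass
class ThresholdResult:
    """Activation threshold V_T and how it was obtained."""

    V_T_mV: float
    method: str  # "intercept" | "closed_form"
    a_dimensionless: Optional[float] = None  # closed_form only
    window_mV: Optional[tuple[float, float]] = None  # intercept only
    r2: Optional[float] = None  # intercept only


@dataclass
class ShiftResult:
    """ΔpH-shift analysis output (all slopes in mV per pH unit)."""

    shift_per_ddpH_mV: float
    S_pHi_mV: float
    corrected_per_dpH_mV: float
    per_unit_shifts_mV: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I-V extraction and preprocessing
# ---------------------------------------------------------------------------


def iv_from_ramp(
    rec: Recording,
    ramp_epoch: Optional[int] = None,
    sweep_index: int = 0,
) -> IVCurve:
    """I–V curve from the samples of a ramp epoch, sorted by voltage.

    Samples falling on identical voltages are averaged so the result is
    strictly increasing in V.
    """
    proto = rec.protocol
    if ramp_epoch is None:
        ramps = [i for i, e in enumerate(proto.epochs) if e.kind == "ramp"]
        if not ramps:
            raise ParameterError("protocol contains no ramp epoch")
        ramp_epoch = ramps[-1]
    sweep = next(s for s in rec.sweeps if s.sweep_index == sweep_index)
    sl = proto.epoch_slice(ramp_epoch, sweep.sample_interval_ms)
    V = sweep.command_mV[sl]
    I = sweep.current_pA[sl]
    order = np.argsort(V, kind="stable")
    V, I = V[order], I[order]
    uniq, inverse, counts = np.unique(V, return_inverse=True, return_counts=True)
    I_mean = np.bincount(inverse, weights=I) / counts
    return IVCurve(V_mV=uniq, I_pA=I_mean, source="ramp", solution=rec.solution)


def _estimate_noise_sd(sweep: Sweep, rec: Recording) -> float:
    """High-frequency noise SD from the first holding epoch (difference-based,
    insensitive to slow drift)."""
    sl = rec.protocol.epoch_slice(0, sweep.sample_interval_ms)
    seg = sweep.current_pA[sl]
    if seg.size < 3:
        seg = sweep.current_pA[: max(3, sweep.n_samples // 20)]
    return float(np.std(np.diff(seg)) / math.sqrt(2.0))


def _steady_mask(rec: Recording, sweep: Sweep) -> np.ndarray:
    """Mask of samples past the settling portion of constant-voltage epochs.

    The first 75% of every hold/step epoch — and in any case the first
    150 ms, several deactivation time constants — is excluded so that
    capacitive and gating relaxation transients (e.g. deactivation tails
    right after a depolarizing pre-pulse) do not contaminate quasi-steady
    measurements; epochs shorter than the settling time contribute nothing.
    Ramp samples are all kept.
    """
    settle_ms = 150.0
    dt = sweep.sample_interval_ms
    mask = np.zeros(sweep.n_samples, dtype=bool)
    for i, epoch in enumerate(rec.protocol.epochs):
        sl = rec.protocol.epoch_slice(i, dt)
        if epoch.kind == "ramp":
            mask[sl] = True
        else:
            n = sl.stop - sl.start
            start = sl.start + max((3 * n) // 4, int(math.ceil(settle_ms / dt)))
            mask[start : sl.stop] = True
    return mask


def subtract_leak(rec: Recording, leak_window: tuple[float, float]) -> Recording:
    """Fit an ohmic leak (reversal 0 mV) over a subthreshold voltage window
    and subtract ``g_leak·V(t)`` from every sample.

    The fit is ``I = g_leak·V + c``: the conductance is ohmic through 0 mV
    while the free offset ``c`` absorbs any baseline reference (recordings
    whose baseline was zeroed at the holding potential would otherwise bias a
    through-origin fit).  Both terms are subtracted.  Only quasi-steady
    samples enter the fit (see :func:`_steady_mask`).  The fitted ``g_leak``
    (nS) lands in ``provenance['g_leak_nS']``.  If the conductance estimated
    from the lower- and upper-voltage halves of the window disagrees (gated
    current contaminating the window), the output is flagged via
    ``provenance['leak_window_warning']`` rather than rejected.
    """
    lo, hi = leak_window
    if not lo < hi:
        raise ParameterError("leak window must satisfy lo < hi")
    Vs, Is = [], []
    for s in rec.sweeps:
        m = (s.command_mV >= lo) & (s.command_mV <= hi) & _steady_mask(rec, s)
        Vs.append(s.command_mV[m])
        Is.append(s.current_pA[m])
    V = np.concatenate(Vs)
    I = np.concatenate(Is)
    if V.size == 0:
        raise ParameterError("no samples fall inside the leak window")

    def _fit(v, i):
        if v.size < 2 or float(np.ptp(v)) == 0.0:
            return None
        g_, c_ = np.polyfit(v, i, 1)
        return float(g_), float(c_)

    fitted = _fit(V, I)
    if fitted is None:
        # single-voltage window: no offset identifiable, fall back to ohmic
        denom = float(np.sum(V * V))
        if denom == 0.0:
            raise ParameterError("leak window contains only 0 mV samples")
        g, c = float(np.sum(I * V) / denom), 0.0
    else:
        g, c = fitted

    # Residual trend check: compare per-half conductances across the window.
    warning = False
    med = np.median(V)
    lo_m, hi_m = V <= med, V > med
    f_lo, f_hi = _fit(V[lo_m], I[lo_m]), _fit(V[hi_m], I[hi_m])
    if f_lo is not None and f_hi is not None:
        noise = _estimate_noise_sd(rec.sweeps[0], rec)
        tol = 0.1 * max(abs(g), 0.01) + 3.0 * noise / max(abs(med), 1.0) / math.sqrt(max(V.size, 1))
        if abs(f_hi[0] - f_lo[0]) > tol:
            warning = True

    out = rec.map_sweeps(
        lambda s: dataclasses.replace(s, current_pA=s.current_pA - g * s.command_mV - c)
    )
    out.provenance = dict(out.provenance)
    out.provenance["g_leak_nS"] = g
    out.provenance["leak_offset_pA"] = c
    out.provenance["leak_window_mV"] = [lo, hi]
    out.provenance["leak_window_warning"] = warning
    return out


def correct_rundown(
    rec: Recording,
    prepulse_epoch: int,
    window_ms: Optional[tuple[float, float]] = None,
    min_amplitude_pA: float = 0.5,
) -> Recording:
    """Scale each sweep so its pre-pulse amplitude matches the first sweep's.

    ``window_ms`` is relative to the pre-pulse epoch start (default: its final
    20%).  Refuses to correct when any pre-pulse amplitude is within 5× the
    baseline noise SD (with an absolute floor of ``min_amplitude_pA``), since
    dividing by noise would corrupt the data.  Scale factors are stored in
    ``provenance['rundown_scale_factors']``.
    """
    proto = rec.protocol
    if not (0 <= prepulse_epoch < len(proto.epochs)):
        raise ParameterError("prepulse_epoch out of range")
    epoch = proto.epochs[prepulse_epoch]
    if prepulse_epoch in proto.incremented_epochs:
        raise ParameterError("pre-pulse must be a fixed-voltage epoch common to all sweeps")
    dur = epoch.duration_ms
    if window_ms is None:
        window_ms = (0.8 * dur, dur)
    w0, w1 = window_ms
    if not (0 <= w0 < w1 <= dur + 1e-9):
        raise ParameterError("window_ms outside the pre-pulse epoch")

    amps = []
    for s in rec.sweeps:
        sl = proto.epoch_slice(prepulse_epoch, s.sample_interval_ms)
        dt = s.sample_interval_ms
        i0 = sl.start + int(math.ceil(w0 / dt - 1e-9))
        i1 = max(i0 + 1, sl.start + int(math.ceil(w1 / dt - 1e-9)))
        amps.append(float(np.mean(s.current_pA[i0:i1])))
        noise = _estimate_noise_sd(s, rec)
        if abs(amps[-1]) <= max(5.0 * noise, min_amplitude_pA):
            raise UnreliableCorrectionError(
                f"sweep {s.sweep_index}: pre-pulse amplitude {amps[-1]:.3g} pA is "
                "too close to the noise floor for rundown correction"
            )
    scales = [amps[0] / a for a in amps]
    sweeps = [
        dataclasses.replace(s, current_pA=s.current_pA * sc)
        for s, sc in zip(rec.sweeps, scales)
    ]
    out = dataclasses.replace(rec, sweeps=sweeps)
    out.provenance = dict(out.provenance)
    out.provenance["rundown_scale_factors"] = scales
    out.provenance["prepulse_amplitudes_pA"] = amps
    return out


# ---------------------------------------------------------------------------
# Conductance extraction
# ---------------------------------------------------------------------------


def _isochronal_mean(current: np.ndarray, frac: float = 0.05, min_samples: int = 10) -> float:
    """Mean over the final ``frac`` of an epoch (at least ``min_samples``)."""
    n = current.size
    k = min(n, max(min_samples, int(math.ceil(frac * n))))
    return float(np.mean(current[n - k :]))


def _tail_amplitude(
    current: np.ndarray,
    dt_ms: float,
    blank_ms: float,
    extrap_window_ms: float = 20.0,
) -> float:
    """Tail-current amplitude at the instant of repolarization.

    The first ``blank_ms`` after the voltage change are blanked (capacitive
    settling).  The deactivating tail is back-extrapolated to the epoch onset:
    on clean single-exponential segments by a linear fit of log|I|, otherwise
    by a nonlinear exponential fit; a smoothed peak is the last resort.
    Extrapolation (rather than the raw post-blanking peak) matters because the
    tail decays during the blanking interval, and raw peak-picking on a
    noise-dominated tail is extreme-value biased.
    """
    k0 = int(math.ceil(blank_ms / dt_ms - 1e-9))
    if k0 >= current.size:
        raise ParameterError("blanking interval longer than the tail epoch")
    seg = current[k0:]
    kw = max(5, int(math.ceil(extrap_window_ms / dt_ms)))
    seg = seg[:kw]
    t = (k0 + np.arange(seg.size)) * dt_ms
    peak = float(seg[np.argmax(np.abs(seg))])
    sign = math.copysign(1.0, peak) if peak != 0 else 1.0
    if seg.size >= 5 and np.all(sign * seg > 0):
        y = np.log(sign * seg)
        b, a = np.polyfit(t, y, 1)
        pred = a + b * t
        if float(np.max(np.abs(y - pred))) < 0.05:  # clean exponential
            return sign * math.exp(a)
    if seg.size >= 5:
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(seg, kernel, mode="valid")
        amp0 = float(smooth[np.argmax(np.abs(smooth))])
        try:
            # tau floor: decay faster than the blanking interval cannot be
            # resolved, and letting tau collapse would explode the
            # back-extrapolated amplitude on noise-dominated segments
            tau_min = max(2.0 * dt_ms, 0.5 * blank_ms)
            popt, pcov = curve_fit(
                lambda tt, amp, tau: amp * np.exp(-tt / tau),
                t - t[0] + blank_ms,
                seg,
                p0=(amp0, max(10.0 * dt_ms, 2.0 * tau_min)),
                bounds=([-np.inf, tau_min], [np.inf, 1e4]),
                maxfev=5000,
            )
            se_amp = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else 0.0
            if se_amp > 0 and abs(popt[0]) < 2.0 * se_amp:
                # no resolvable decay: the segment is noise around a flat
                # level and its mean is the unbiased amplitude estimate
                return float(np.mean(seg))
            return float(popt[0])
        except (RuntimeError, ValueError):
            return amp0
    return peak


def tail_gv(
    rec: Recording,
    test_epoch: int,
    tail_epoch: int,
    blank_ms: float = 2.0,
    isochronal_frac: float = 0.05,
) -> GVCurve:
    """Tail-current conductance, ``G = (I_test − I_tail)/(V_test − V_tail)``.

    Expects a leak-subtracted, rundown-corrected step family followed by a
    fixed tail voltage.  ``I_test`` is the isochronal mean over the final 5%
    of the test epoch; ``I_tail`` is the tail amplitude at the tail-epoch
    onset (see :func:`_tail_amplitude`).
    """
    proto = rec.protocol
    Vs, Gs = [], []
    for s in rec.sweeps:
        dt = s.sample_interval_ms
        sl_test = proto.epoch_slice(test_epoch, dt)
        sl_tail = proto.epoch_slice(tail_epoch, dt)
        v_test = proto.epoch_voltage(test_epoch, s.sweep_index)[1]
        v_tail = proto.epoch_voltage(tail_epoch, s.sweep_index)[0]
        if v_test == v_tail:
            raise DegenerateInputError(
                f"sweep {s.sweep_index}: V_test == V_tail == {v_test} mV, conductance undefined"
            )
        i_test = _isochronal_mean(s.current_pA[sl_test], isochronal_frac)
        i_tail = _tail_amplitude(s.current_pA[sl_tail], dt, blank_ms)
        Vs.append(v_test)
        Gs.append((i_test - i_tail) / (v_test - v_tail))
    order = np.argsort(Vs)
    return GVCurve(
        V_mV=np.asarray(Vs)[order], G_nS=np.asarray(Gs)[order], solution=rec.solution
    )


def ramp_gv(iv: IVCurve, V_rev_mV: float, exclusion_mV: float = 10.0) -> GVCurve:
    """Chord conductance from a leak-subtracted ramp I–V.

    Points with ``|V − V_rev| < exclusion_mV`` are dropped: near the reversal
    potential the quotient I/(V − V_rev) amplifies noise without bounds.
    """
    keep = np.abs(iv.V_mV - V_rev_mV) >= exclusion_mV
    if np.count_nonzero(keep) < 4:
        raise ParameterError("fewer than 4 points remain outside the exclusion zone")
    G = iv.I_pA[keep] / (iv.V_mV[keep] - V_rev_mV)
    return GVCurve(V_mV=iv.V_mV[keep], G_nS=G, solution=iv.solution)


def normalize_gv(gv: GVCurve) -> GVCurve:
    """Divide by the maximum conductance (max G becomes exactly 1)."""
    gmax = float(np.max(gv.G_nS))
    if gmax <= 0:
        raise ParameterError("cannot normalize a non-positive G-V curve")
    return GVCurve(V_mV=gv.V_mV, G_nS=gv.G_nS / gmax, normalized=True, solution=gv.solution)


def average_gvs(gvs: Sequence[GVCurve]) -> GVCurve:
    """Point-wise mean of normalized G–V curves sharing a voltage grid."""
    if not gvs:
        raise ParameterError("no curves to average")
    V0 = gvs[0].V_mV
    for gv in gvs[1:]:
        if gv.V_mV.size != V0.size or np.max(np.abs(gv.V_mV - V0)) > 1e-9:
            raise ParameterError("G-V curves must share the same voltage grid")
    mean = np.mean([normalize_gv(gv).G_nS for gv in gvs], axis=0)
    mean = mean / np.max(mean)
    return GVCurve(V_mV=V0, G_nS=mean, normalized=True, solution=gvs[0].solution)


# ---------------------------------------------------------------------------
# Boltzmann fitting
# ---------------------------------------------------------------------------

# Fixed restart multipliers (amplitude, midpoint, slope); no RNG involved.
_JITTER_TABLE = (
    (1.0, 1.0, 1.0),
    (1.2, 0.9, 1.3),
    (0.8, 1.1, 0.7),
    (1.1, 1.05, 1.5),
)


def _boltz_model(V, gmax, vhalf, s):
    x = np.clip((vhalf - V) / s, -700, 700)
    return gmax / (1.0 + np.exp(x))


def _v_at_level(V: np.ndarray, G: np.ndarray, level: float) -> float:
    return float(V[int(np.argmin(np.abs(G - level)))])


def fit_boltzmann(gv: GVCurve) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G–V curve.

    Deterministic: the initial guess is G_max ← 1.05·max(G), V_half ← voltage
    nearest half of that, s ← (V at 75% − V at 25%)/2.2, followed by up to
    four restarts from a fixed jitter table before declaring failure.
    """
    V, G = gv.V_mV, gv.G_nS
    if V.size < 5:
        raise ParameterError("Boltzmann fit needs at least 5 points")
    gmax0 = 1.05 * float(np.max(G))
    if gmax0 <= 0:
        raise FitFailureError("all conductances are non-positive")
    v0 = _v_at_level(V, G, gmax0 / 2.0)
    s0 = (_v_at_level(V, G, 0.75 * gmax0) - _v_at_level(V, G, 0.25 * gmax0)) / 2.2
    if not s0 > 0:
        s0 = float(V[-1] - V[0]) / 4.0

    flags: list[str] = []
    half = gmax0 / 2.0
    if float(np.max(G)) < half or float(np.min(G)) > half:
        flags.append("data_do_not_span_half_max")

    last_err = None
    for ja, jv, js in _JITTER_TABLE:
        p0 = (gmax0 * ja, v0 * jv if v0 != 0 else 5.0 * (jv - 1.0), s0 * js)
        try:
            popt, pcov = curve_fit(
                _boltz_model,
                V,
                G,
                p0=p0,
                bounds=([1e-12, -500.0, 1e-3], [np.inf, 500.0, 500.0]),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        resid = G - _boltz_model(V, *popt)
        rss = float(np.sum(resid**2))
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        se = np.where(np.isfinite(se), se, 0.0)
        return BoltzmannFit(
            amplitude=float(popt[0]),
            V_half_mV=float(popt[1]),
            slope_mV=float(popt[2]),
            stderr_amplitude=float(se[0]),
            stderr_V_half_mV=float(se[1]),
            stderr_slope_mV=float(se[2]),
            rss=rss,
            normalized=gv.normalized,
            flags=flags,
        )
    raise FitFailureError(
        "Boltzmann fit failed to converge after bounded restarts",
        diagnostics={"initial_guess": (gmax0, v0, s0), "last_error": repr(last_err)},
    )


# ---------------------------------------------------------------------------
# Activation threshold V_T
# ---------------------------------------------------------------------------


def vt_intercept(
    iv: IVCurve,
    window_points: Optional[int] = None,
    r2_min: float = 0.98,
) -> ThresholdResult:
    """V_T as the V-intercept of the steepest linear segment of the I–V.

    A window of W consecutive points (default max(5, 10% of the curve))
    slides over the rising phase; among windows with positive slope and
    r² ≥ ``r2_min`` the steepest wins (ties go to the smaller-voltage
    window).  Fails with :class:`MethodInapplicableError` when no window
    qualifies — e.g. an entirely subthreshold I–V — in which case the
    closed-form estimate :func:`vt_from_fit` should be used instead.
    """
    V, I = iv.V_mV, iv.I_pA
    n = V.size
    W = window_points if window_points is not None else max(5, int(math.ceil(0.1 * n)))
    if W < 3:
        raise ParameterError("window must span at least 3 points")
    if n < W:
        raise MethodInapplicableError("I-V curve shorter than the fitting window")

    best = None  # (slope, intercept, r2, i)
    for i in range(n - W + 1):
        x = V[i : i + W]
        y = I[i : i + W]
        xm, ym = x.mean(), y.mean()
        sxx = float(np.sum((x - xm) ** 2))
        sxy = float(np.sum((x - xm) * (y - ym)))
        slope = sxy / sxx
        if slope <= 0:
            continue
        icpt = ym - slope * xm
        ss_tot = float(np.sum((y - ym) ** 2))
        ss_res = float(np.sum((y - slope * x - icpt) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if r2 < r2_min:
            continue
        if best is None or slope > best[0]:  # strict ">" keeps the smaller-V tie
            best = (slope, icpt, r2, i)
    if best is None:
        raise MethodInapplicableError(
            "no window with positive slope reaches the r^2 gate; "
            "use vt_from_fit on the G-V instead"
        )
    slope, icpt, r2, i = best
    return ThresholdResult(
        V_T_mV=-icpt / slope,
        method="intercept",
        window_mV=(float(V[i]), float(V[i + W - 1])),
        r2=r2,
    )


def vt_from_fit(fit: BoltzmannFit, V_rev_mV: float) -> ThresholdResult:
    """Closed-form V_T from Boltzmann parameters.

    ``V_T = (a·V_half + V_rev)/(a + 1)`` with ``a = (V_half − V_rev)/(2s)`` —
    the V-intercept of the tangent to the I–V curve at the midpoint.  Requires
    enough separation between activation and reversal (V_half > V_rev).
    """
    if fit.slope_mV <= 0:
        raise ParameterError("slope must be positive")
    if not fit.V_half_mV > V_rev_mV:
        raise ParameterError(
            f"V_half ({fit.V_half_mV} mV) must exceed V_rev ({V_rev_mV} mV) "
            "for the threshold to be defined"
        )
    a = (fit.V_half_mV - V_rev_mV) / (2.0 * fit.slope_mV)
    vt = (a * fit.V_half_mV + V_rev_mV) / (a + 1.0)
    return ThresholdResult(V_T_mV=vt, method="closed_form", a_dimensionless=a)


# ---------------------------------------------------------------------------
# ΔpH-shift analysis
# ---------------------------------------------------------------------------


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x.mean(), y.mean()
    return float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))


def dpH_shift_analysis(
    vts: Sequence[tuple[ThresholdResult, SolutionPair]],
    symmetric_vts: Sequence[tuple[ThresholdResult, SolutionPair]],
) -> ShiftResult:
    """Quantify the ΔpH dependence of V_T, correcting for the pH_i dependence.

    ``vts`` holds thresholds at different transmembrane gradients (changed via
    pH_i); ``symmetric_vts`` holds thresholds at ΔpH = 0 and different pH.
    The raw per-unit shifts are measured against the condition nearest
    ΔpH = 0; the corrected gradient-only shift subtracts the magnitude of the
    symmetric-pH slope: ``corrected = mean(|shift per ΔΔpH|) − |S_pHi|``.
    """
    if len(vts) < 2:
        raise ParameterError("need at least 2 gradient conditions")
    if len(symmetric_vts) < 2:
        raise ParameterError("need at least 2 symmetric-pH conditions")
    dphs = np.array([sol.delta_pH for _, sol in vts])
    if np.unique(np.round(dphs, 9)).size < 2:
        raise ParameterError("gradient conditions must differ in delta_pH")
    for _, sol in symmetric_vts:
        if abs(sol.delta_pH) > 1e-9:
            raise ParameterError("symmetric conditions must have delta_pH = 0")
    phs = np.array([sol.pH_i for _, sol in symmetric_vts])
    if np.unique(np.round(phs, 9)).size < 2:
        raise ParameterError("symmetric conditions must differ in pH")

    warnings = []
    methods = {t.method for t, _ in vts} | {t.method for t, _ in symmetric_vts}
    if len(methods) > 1:
        warnings.append("threshold methods are mixed across conditions")

    vt_vals = np.array([t.V_T_mV for t, _ in vts])
    shift_slope = _slope(dphs, vt_vals)
    s_phi = _slope(phs, np.array([t.V_T_mV for t, _ in symmetric_vts]))

    ref = int(np.argmin(np.abs(dphs)))
    per_unit = [
        (vt_vals[i] - vt_vals[ref]) / (dphs[i] - dphs[ref])
        for i in range(len(vts))
        if i != ref and abs(dphs[i] - dphs[ref]) > 1e-9
    ]
    corrected = float(np.mean(np.abs(per_unit))) - abs(s_phi)
    return ShiftResult(
        shift_per_ddpH_mV=shift_slope,
        S_pHi_mV=s_phi,
        corrected_per_dpH_mV=corrected,
        per_unit_shifts_mV=[float(v) for v in per_unit],
        warnings=warnings,
    )
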