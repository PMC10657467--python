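"""Proton selectivity and pharmacology analysis.

Reversal-potential estimation by zero-crossing interpolation, the Nernst
relation for protons, Goldman–Hodgkin–Katz (GHK) permeability-ratio analysis
for a single monovalent metal ion M+ under the assumption of negligible Cl−
permeability,

    ΔV_rev = (RT/F) · ln((P_M·[M]_o + P_H·[H]_o) / (P_M·[M]_i + P_H·[H]_i)),

and Hill concentration–inhibition fitting,

    %_i = %_i,max · [L]^h / (IC50^h + [L]^h),   with %_i,max fixed at 100.

Temperature enters only through RT/F (default 22 °C).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .errors import (
    InversionError,
    OutOfRangeError,
    ParameterError,
    FitFailureError,
)
from .trace_model_io import Recording, SolutionPair
from .gating_analysis import IVCurve, iv_from_ramp

__all__ = [
    "VrevMeasurement",
    "VrevSlopeFit",
    "PermeabilityResult",
    "InhibitionPoint",
    "HillFit",
    "nernst_eh",
    "estimate_vrev",
    "fit_vrev_slope",
    "ghk_delta_vrev",
    "infer_permeability_ratio",
    "inhibition_percent",
    "fit_hill",
    "GHK_DEFAULTS",
]

_GAS_R = 8.314462618  # J / (mol K)
_FARADAY = 96485.33212  # C / mol

# Default ionic conditions for the metal-permeability assay:
# symmetric pH 6.0 and a 10-fold inward metal gradient.
GHK_DEFAULTS = {"H_i_M": 1e-6, "H_o_M": 1e-6, "M_i_M": 1e-2, "M_o_M": 1e-3}


def _rtf_mV(temperature_C: float) -> float:
    return 1000.0 * _GAS_R * (temperature_C + 273.15) / _FARADAY


@dataclass
class VrevMeasurement:
    """A reversal potential with the bracketing (V, I) points used."""

    V_rev_mV: float
    solution: Optional[SolutionPair] = None
    bracket: Optional[tuple[tuple[float, float], tuple[float, float]]] = None


@dataclass
class VrevSlopeFit:
    """OLS slope of V_rev versus ΔpH (mV per pH unit)."""

    slope_mV_per_pH: float
    stderr_mV_per_pH: float
    intercept_mV: float
    n: int


@dataclass
class PermeabilityResult:
    """Relative metal-ion permeability inferred from a ΔV_rev measurement."""

    delta_Vrev_mV: float
    ratio: float  # P_M+ / P_H+
    is_upper_bound: bool


@dataclass(frozen=True)
class InhibitionPoint:
    conc_uM: float
    percent_inhibition: float

    def __post_init__(self) -> None:
        if self.conc_uM <= 0:
            raise ParameterError("concentration must be > 0")
        if not (-1e-9 <= self.percent_inhibition <= 100.0 + 1e-9):
            raise ParameterError("percent inhibition must lie in [0, 100]")


@dataclass
class HillFit:
    """Hill-equation parameters with standard errors (%_i,max fixed at 100)."""

    IC50_uM: float
    h: float
    stderr_IC50_uM: float
    stderr_h: float
    rss: float
    max_percent: float = 100.0

    def predict(self, conc_uM) -> np.ndarray:
        c = np.asarray(conc_uM, dtype=float)
        return self.max_percent * c**self.h / (self.IC50_uM**self.h + c**self.h)


# ---------------------------------------------------------------------------
# Nernst / reversal potentials
# ---------------------------------------------------------------------------


def nernst_eh(solution: SolutionPair) -> float:
    """Nernst equilibrium potential for protons, in mV.

    ``E_H = (RT/F)·ln([H]_o/[H]_i) = −(RT/F)·ln(10)·ΔpH`` at the solution's
    temperature; ≈ −58.6 mV per ΔpH unit at 22 °C.
    """
    return -_rtf_mV(solution.temperature_C) * math.log(10.0) * solution.delta_pH


def estimate_vrev(
    trace_or_iv: Union[Recording, IVCurve],
    ramp_epoch: Optional[int] = None,
    sweep_index: int = 0,
) -> VrevMeasurement:
    """Reversal potential by linear interpolation of the zero crossing.

    Accepts a leak-subtracted post-depolarization ramp Recording (the I–V is
    extracted from the ramp epoch) or an IVCurve directly.  Among the
    sign-change brackets the one with the smallest current magnitudes is used
    — points far from the crossing are model-dependent because the tail
    current decays along the ramp.
    """
    if isinstance(trace_or_iv, Recording):
        iv = iv_from_ramp(trace_or_iv, ramp_epoch=ramp_epoch, sweep_index=sweep_index)
    else:
        iv = trace_or_iv
    V, I = iv.V_mV, iv.I_pA

    best = None  # (|I_k| + |I_k+1|, k)
    for k in range(V.size - 1):
        if I[k] == 0.0 and I[k + 1] == 0.0:
            continue
        if I[k] * I[k + 1] <= 0.0:
            score = abs(I[k]) + abs(I[k + 1])
            if best is None or score < best[0]:
                best = (score, k)
    if best is None:
        raise OutOfRangeError("current does not change sign within the data range")
    k = best[1]
    v0, v1 = float(V[k]), float(V[k + 1])
    i0, i1 = float(I[k]), float(I[k + 1])
    vrev = v0 if i0 == i1 else v0 - i0 * (v1 - v0) / (i1 - i0)
    return VrevMeasurement(
        V_rev_mV=vrev, solution=iv.solution, bracket=((v0, i0), (v1, i1))
    )


def fit_vrev_slope(measurements: Sequence[VrevMeasurement]) -> VrevSlopeFit:
    """OLS slope of reversal potential versus ΔpH with its standard error.

    Requires measurements at >= 3 distinct ΔpH values (replicates at each
    gradient enter as individual points).
    """
    if any(m.solution is None for m in measurements):
        raise ParameterError("every measurement needs a SolutionPair for its delta_pH")
    x = np.array([m.solution.delta_pH for m in measurements])
    y = np.array([m.V_rev_mV for m in measurements])
    if np.unique(np.round(x, 9)).size < 3:
        raise ParameterError("need V_rev at >= 3 distinct delta_pH values")
    res = stats.linregress(x, y)
    return VrevSlopeFit(
        slope_mV_per_pH=float(res.slope),
        stderr_mV_per_pH=float(res.stderr),
        intercept_mV=float(res.intercept),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# GHK permeability analysis
# ---------------------------------------------------------------------------


def ghk_delta_vrev(
    perm_ratio: float,
    H_i_M: float = GHK_DEFAULTS["H_i_M"],
    H_o_M: float = GHK_DEFAULTS["H_o_M"],
    M_i_M: float = GHK_DEFAULTS["M_i_M"],
    M_o_M: float = GHK_DEFAULTS["M_o_M"],
    temperature_C: float = 22.0,
) -> float:
    """Reversal-potential change (mV) predicted by the GHK voltage equation
    for a given relative permeability ``P_M+/P_H+``.

    With the default concentrations (symmetric pH 6, metal 10 mM inside /
    1 mM outside) a perfectly proton-selective channel gives 0 mV.
    """
    if perm_ratio < 0:
        raise ParameterError("perm_ratio must be >= 0")
    if H_i_M <= 0 or H_o_M <= 0:
        raise ParameterError("proton concentrations must be > 0")
    if M_i_M < 0 or M_o_M < 0:
        raise ParameterError("metal concentrations must be >= 0")
    num = perm_ratio * M_o_M + H_o_M
    den = perm_ratio * M_i_M + H_i_M
    return _rtf_mV(temperature_C) * math.log(num / den)


def infer_permeability_ratio(
    delta_Vrev_mV: float,
    resolution_mV: float = 0.0,
    H_i_M: float = GHK_DEFAULTS["H_i_M"],
    H_o_M: float = GHK_DEFAULTS["H_o_M"],
    M_i_M: float = GHK_DEFAULTS["M_i_M"],
    M_o_M: float = GHK_DEFAULTS["M_o_M"],
    temperature_C: float = 22.0,
) -> PermeabilityResult:
    """Invert the GHK relation for the permeability ratio by bisection.

    When the measured shift is within the stated measurement resolution the
    data only bound the ratio from above: the ratio at a shift equal to the
    resolution (in the achievable direction) is returned with
    ``is_upper_bound = True``.
    """
    if resolution_mV < 0:
        raise ParameterError("resolution must be >= 0")

    def f(r):
        return ghk_delta_vrev(r, H_i_M, H_o_M, M_i_M, M_o_M, temperature_C)

    direction = math.copysign(1.0, f(1.0) - f(0.0)) if f(1.0) != f(0.0) else 0.0
    if direction == 0.0:
        raise InversionError("GHK shift does not depend on the permeability ratio")

    is_bound = abs(delta_Vrev_mV) <= resolution_mV
    target = direction * resolution_mV if is_bound else delta_Vrev_mV
    offset = f(0.0)
    if target == offset:
        return PermeabilityResult(delta_Vrev_mV, 0.0, is_bound)
    # achievable range is between f(0) and the ratio->inf limit
    limit = _rtf_mV(temperature_C) * math.log(M_o_M / M_i_M) if M_i_M > 0 and M_o_M > 0 else direction * math.inf
    lo_v, hi_v = sorted((offset, limit))
    if not (lo_v < target < hi_v):
        raise InversionError(
            f"shift {target:.4g} mV outside the achievable GHK range ({lo_v:.4g}, {hi_v:.4g}) mV"
        )
    hi = 1.0
    while (f(hi) - target) * direction < 0:
        hi *= 10.0
        if hi > 1e12:
            raise InversionError("failed to bracket the permeability ratio")
    ratio = optimize.brentq(lambda r: f(r) - target, 0.0, hi, xtol=1e-300, rtol=1e-12)
    return PermeabilityResult(delta_Vrev_mV, float(ratio), is_bound)


# ---------------------------------------------------------------------------
# Inhibition / Hill analysis
# ---------------------------------------------------------------------------


def inhibition_percent(I_control_pA: float, I_drug_pA: float) -> float:
    """Percent inhibition from isochronal currents, ``100·(1 − I_drug/I_ctrl)``,
    clipped to [0, 100].  Clipping (noise pushing the drug current slightly
    negative, or above control) raises a warning but still returns a value."""
    if not I_control_pA > 0:
        raise ParameterError("control current must be positive (outward, leak-subtracted)")
    pct = 100.0 * (1.0 - I_drug_pA / I_control_pA)
    if pct < 0.0 or pct > 100.0:
        _warnings.warn(
            f"inhibition {pct:.3g}% outside [0, 100]; clipping", stacklevel=2
        )
        pct = min(max(pct, 0.0), 100.0)
    return pct


def _hill_logc_model(logc, log_ic50, h):
    # %i = 100 / (1 + exp(-h (ln[L] - ln IC50))): logistic in log-concentration
    z = np.clip(h * (logc - log_ic50), -700, 700)
    return 100.0 / (1.0 + np.exp(-z))


def fit_hill(points: Sequence[InhibitionPoint]) -> HillFit:
    """Least-squares Hill fit with maximal inhibition fixed at 100%.

    Fitting runs in log-concentration space, where the Hill equation is a
    two-parameter logistic, with equal weights; requires >= 4 distinct
    concentrations spanning at least one decade.
    """
    concs = np.array([p.conc_uM for p in points], dtype=float)
    pct = np.array([p.percent_inhibition for p in points], dtype=float)
    distinct = np.unique(concs)
    if distinct.size < 4:
        raise ParameterError("need >= 4 distinct concentrations")
    if distinct.max() / distinct.min() < 10.0:
        raise ParameterError("concentrations must span at least one decade")
    logc = np.log(concs)

    order = np.argsort(concs)
    ic50_guess = float(np.interp(50.0, pct[order], concs[order])) if (
        pct.min() < 50.0 < pct.max()
    ) else float(np.exp(np.mean(logc)))
    p0 = (math.log(ic50_guess), 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _hill_logc_model,
            logc,
            pct,
            p0=p0,
            bounds=([math.log(1e-6), 1e-3], [math.log(1e9), 50.0]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "Hill fit failed to converge", diagnostics={"p0": p0, "error": repr(exc)}
        ) from exc
    log_ic50, h = popt
    ic50 = math.exp(log_ic50)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    se = np.where(np.isfinite(se), se, 0.0)
    resid = pct - _hill_logc_model(logc, *popt)
    return HillFit(
        IC50_uM=ic50,
        h=float(h),
        stderr_IC50_uM=ic50 * float(se[0]),  # delta method from log-scale SE
        stderr_h=float(se[1]),
        rss=float(np.sum(resid**2)),
    )
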