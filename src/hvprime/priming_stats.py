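"""Mechanical-priming quantification and heteroscedastic group comparisons.

A two-pulse pressure experiment brackets a suction stimulus with two
identical depolarizing pulses; the isochronal currents at their ends, I_A
(before) and I_B (after), give the priming ratio I_B/I_A.  A ratio near 1
means the stimulus did nothing; an electrically silent channel rescued by
membrane stretch produces ratios far above 1.  The ratio is a quotient of
currents from the same patch, so it is invariant under uniform current
scaling (expression level, seal quality).

Group comparisons follow the heteroscedasticity-robust route used for such
ratios: Welch's one-way ANOVA (weights n_i/s_i², Welch–Satterthwaite
denominator degrees of freedom) for the omnibus test, and Dunnett's T3
procedure against a designated reference group — Welch-type t statistics
with per-comparison Satterthwaite df, adjusted family-wise through the
studentized maximum modulus (SMM) distribution.  SMM quantiles have no
closed form; they are evaluated here by numerical integration over the
chi-distributed denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, special, stats

from .errors import DegenerateInputError, ParameterError, ProtocolError
from .trace_model_io import PressureStimulus, Recording

__all__ = [
    "PrimingResult",
    "PairwiseComparison",
    "GroupComparison",
    "priming_ratio",
    "welch_anova",
    "dunnett_t3",
    "compare_groups",
    "smm_cdf",
]


@dataclass
class PrimingResult:
    """Per-patch outcome of a two-pulse priming experiment."""

    I_A_pA: float
    I_B_pA: float
    ratio: float
    stimulus: Optional[PressureStimulus] = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PairwiseComparison:
    group_index: int
    reference_index: int
    t_statistic: float
    df: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class GroupComparison:
    """Welch ANOVA omnibus result plus optional pairwise T3 comparisons."""

    F_statistic: float
    df_numerator: float
    df_denominator: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Priming ratio
# ---------------------------------------------------------------------------


def _isochronal_mean(current: np.ndarray, frac: float = 0.05, min_samples: int = 10) -> float:
    n = current.size
    k = min(n, max(min_samples, int(math.ceil(frac * n))))
    return float(np.mean(current[n - k :]))


def priming_ratio(rec: Recording, isochronal_frac: float = 0.05) -> PrimingResult:
    """I_B/I_A from a leak-subtracted two-pulse priming recording.

    The recording must contain two depolarizing step epochs at the same test
    voltage with a pressure stimulus applied between them.  I_A and I_B are
    isochronal means over the final 5% of each pulse.  A ``low_signal`` flag
    marks patches whose pre-priming current sits below 3× the baseline noise
    SD (silent channels can start from currents of only 1–2 pA); such
    results are flagged, never dropped.
    """
    proto = rec.protocol
    sweep = rec.sweeps[0]
    dt = sweep.sample_interval_ms
    steps = [
        i
        for i, e in enumerate(proto.epochs)
        if e.kind == "step" and e.V_start_mV != proto.holding_mV
    ]
    if len(steps) < 2:
        raise ProtocolError("protocol lacks two depolarizing pulses")
    a_idx, b_idx = steps[0], steps[1]
    va = proto.epoch_voltage(a_idx, sweep.sweep_index)[0]
    vb = proto.epoch_voltage(b_idx, sweep.sweep_index)[0]
    if va != vb:
        raise ProtocolError(f"pulse voltages differ ({va} vs {vb} mV); pulses must match")

    bounds = proto.epoch_bounds_ms()
    a_end_s = sweep.start_time_s + bounds[a_idx][1] / 1000.0
    b_start_s = sweep.start_time_s + bounds[b_idx][0] / 1000.0
    between = [
        ev
        for ev in rec.pressure_events
        if ev.onset_s >= a_end_s and ev.end_s <= b_start_s
    ]
    if not between:
        raise ProtocolError("no pressure stimulus between the two pulses")

    i_a = _isochronal_mean(sweep.current_pA[proto.epoch_slice(a_idx, dt)], isochronal_frac)
    i_b = _isochronal_mean(sweep.current_pA[proto.epoch_slice(b_idx, dt)], isochronal_frac)
    if i_a == 0.0:
        raise DegenerateInputError("I_A is exactly zero; the priming ratio is undefined")

    flags = []
    hold_seg = sweep.current_pA[proto.epoch_slice(0, dt)]
    noise_sd = float(np.std(np.diff(hold_seg)) / math.sqrt(2.0)) if hold_seg.size > 2 else 0.0
    if noise_sd > 0 and abs(i_a) < 3.0 * noise_sd:
        flags.append("low_signal")

    return PrimingResult(
        I_A_pA=i_a,
        I_B_pA=i_b,
        ratio=i_b / i_a,
        stimulus=between[0],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Welch ANOVA
# ---------------------------------------------------------------------------


def _group_stats(groups: Sequence[Sequence[float]]):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ParameterError("need at least 2 groups")
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise ParameterError(f"group {i} has fewer than 2 observations")
        if np.var(a, ddof=1) == 0.0:
            raise DegenerateInputError(f"group {i} has zero variance")
    n = np.array([a.size for a in arrs], dtype=float)
    mean = np.array([a.mean() for a in arrs])
    var = np.array([a.var(ddof=1) for a in arrs])
    return n, mean, var


def welch_anova(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Welch's heteroscedastic one-way ANOVA.

    Group weights are n_i/s_i²; the denominator degrees of freedom follow the
    Welch–Satterthwaite approximation.  Identical group means give F = 0,
    p = 1.
    """
    n, mean, var = _group_stats(groups)
    k = n.size
    w = n / var
    W = w.sum()
    grand = float((w * mean).sum() / W)
    A = float((w * (mean - grand) ** 2).sum() / (k - 1))
    lam = 3.0 * float((((1.0 - w / W) ** 2) / (n - 1.0)).sum()) / (k**2 - 1.0)
    F = A / (1.0 + 2.0 * lam * (k - 2.0) / 3.0)
    df1 = float(k - 1)
    df2 = 1.0 / lam
    p = float(stats.f.sf(F, df1, df2))
    return GroupComparison(F_statistic=F, df_numerator=df1, df_denominator=df2, p_value=p)


# ---------------------------------------------------------------------------
# Dunnett's T3
# ---------------------------------------------------------------------------


def smm_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized maximum modulus: P(max_i |Z_i| / S <= q) for k
    independent standard normals Z_i and S = sqrt(chi2_df / df).

    Evaluated by quadrature over the chi-distributed denominator; absolute
    tolerance well below 1e-4.  ``k = 1`` reduces to the folded-t CDF.
    """
    if q <= 0:
        return 0.0
    sqrt_df = math.sqrt(df)

    def integrand(u):
        # P(|Z| <= q u)^k weighted by the density of S
        return special.erf(q * u / math.sqrt(2.0)) ** k * stats.chi.pdf(u * sqrt_df, df) * sqrt_df

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-10, epsrel=1e-10, limit=200)
    return min(max(val, 0.0), 1.0)


def _smm_sf(q: float, k: int, df: float) -> float:
    """1 − smm_cdf, computed from the complement integrand to keep precision
    in the far tail (adjusted p-values can be ≪ 1e-8)."""
    if q <= 0:
        return 1.0
    sqrt_df = math.sqrt(df)

    def integrand(u):
        return (1.0 - special.erf(q * u / math.sqrt(2.0)) ** k) * stats.chi.pdf(
            u * sqrt_df, df
        ) * sqrt_df

    val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-14, epsrel=1e-10, limit=200)
    return min(max(val, 0.0), 1.0)


def dunnett_t3(
    groups: Sequence[Sequence[float]], reference_index: int
) -> list[PairwiseComparison]:
    """Dunnett's T3 pairwise comparisons against a reference group.

    Each non-reference group gets a Welch-type t statistic with its own
    Welch–Satterthwaite df; the family-wise adjusted p-value is the SMM
    survival probability at |t| over the k comparisons.  Adjusted p-values
    are monotone in |t| and never smaller than the unadjusted Welch p.
    """
    n, mean, var = _group_stats(groups)
    k_groups = n.size
    if not (0 <= reference_index < k_groups):
        raise ParameterError("reference_index out of range")
    k = k_groups - 1  # number of comparisons
    nr, mr, vr = n[reference_index], mean[reference_index], var[reference_index]

    out = []
    for i in range(k_groups):
        if i == reference_index:
            continue
        se2 = var[i] / n[i] + vr / nr
        t = float((mean[i] - mr) / math.sqrt(se2))
        df = se2**2 / (
            (var[i] / n[i]) ** 2 / (n[i] - 1) + (vr / nr) ** 2 / (nr - 1)
        )
        p_un = float(2.0 * stats.t.sf(abs(t), df))
        p_adj = float(_smm_sf(abs(t), k, df))
        out.append(
            PairwiseComparison(
                group_index=i,
                reference_index=reference_index,
                t_statistic=t,
                df=float(df),
                p_unadjusted=p_un,
                p_adjusted=p_adj,
            )
        )
    return out


def compare_groups(
    groups: Sequence[Sequence[float]], reference_index: int = 0
) -> GroupComparison:
    """Welch omnibus ANOVA plus Dunnett-T3 comparisons against a reference."""
    omnibus = welch_anova(groups)
    omnibus.pairwise = dunnett_t3(groups, reference_index)
    return omnibus
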