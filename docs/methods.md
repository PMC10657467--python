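# Methods

This note documents the models, estimators and numerical choices behind
hvprime, and what the synthetic-data tests do and do not demonstrate about
real recordings.

## Units and data model

Canonical units are fixed package-wide: time in ms (wall-clock offsets in
s), current in pA, voltage in mV, pressure in mmHg, concentrations in molar,
temperature in °C.  Conductance in nS then satisfies I[pA] = G[nS]·V[mV]
with no conversion factors.  Sample indexing is 0-based and epoch intervals
are half-open [start, end).  Trace files are a CSV sample table plus a JSON
sidecar; floats are written with 12 significant digits so that a
write→read round trip is numerically transparent (absolute error below
1e−9 for every quantity the pipeline handles), while files remain
byte-deterministic for identical input.

## Signal conditioning

Acquisition-style traces are low-pass filtered offline with a zero-phase
digital approximation of a 4-pole Bessel filter: a 2nd-order
magnitude-normalized Bessel section run forward and backward
(`sosfiltfilt`), giving a monotone 4-pole magnitude response with no phase
delay, so isochronal time points are not shifted.  Baseline correction
subtracts the mean current over a holding-epoch window (default: the last
50 ms before the first non-holding epoch; no standard window exists, this
is a package choice).  Note that zero-phase filtering smears voltage-step
boundaries in both directions over roughly two cutoff periods; analyses
that read values near a step (tail currents) must blank at least that long
(the CLI uses `blank = max(2, 2000/cutoff_Hz)` ms).

## The generative model

The simulator is the simplest process consistent with the assumptions of
the analyses:

* **Gating.** A single first-order gate with steady state
  `p_inf(V) = 1/(1 + exp((V_half − V)/s))` relaxing with τ_act when
  activating and τ_deact when deactivating.  Constant-voltage epochs are
  integrated analytically; ramps use an exponential-Euler step per sample.
  No multi-state Markov kinetics: the analyses consume only isochronal or
  steady-state values.
* **ΔpH dependence.** `V_half = V_half_ref − S_dpH·ΔpH − S_pHi·(6 − pH_i)`
  with the reference condition fixed at ΔpH = 0, pH_i = 6.0.  Both
  sensitivities are positive magnitudes; larger gradients and more acidic
  interiors shift activation negative.
* **Reversal.** Nernst for protons; Goldman–Hodgkin–Katz with a single
  monovalent metal ion when `metal_perm_ratio > 0`.  Chloride permeability
  is taken as negligible throughout.
* **Leak and rundown.** Ohmic leak reversing at 0 mV.  Rundown multiplies
  G_max by exp(−t/τ_rundown) in wall-clock time; the phenomenon is only
  qualitative in excised patches, an exponential is the minimal monotone
  model.
* **Mechanical priming.** A deterministic, latching availability switch:
  the conductance fraction `silent_availability` is available until pipette
  suction of at least the threshold magnitude persists for the minimum
  duration, after which availability is 1 permanently.  Reversion to the
  silent state is not modeled (it is too slow to follow within one
  recording).
* **Inhibition and noise.** A Hill-type inhibition factor applied to
  G_max, and i.i.d. Gaussian current noise added after gating; a seed is
  mandatory whenever noise is nonzero, and identical inputs give
  bit-identical recordings.

Defaults that matter: `PsHv1_like` uses V_half_ref 44.8 mV, slope 14.3 mV
(tail-current gating of the spruce channel at symmetric pH 6), ΔpH
sensitivity 60 mV/pH, symmetric-pH sensitivity 35 mV/pH, pre-priming
availability 1/1.5; `AtHv1_like` uses availability 1/17, which is a tuning
choice reproducing the observed two-pulse ratio of the silent Arabidopsis
channel, not a measured constant.  τ_act 100 ms, τ_deact 50 ms, leak
0.1 nS and noise 1 pA SD are field-realistic round numbers (no kinetic or
noise figures are published for these channels); the priming stimulus is
−10 mmHg for 3 s, with an 8 mmHg / 2 s latching requirement so the standard
stimulus primes with margin.

What the generator does **not** emulate: capacitive transients, stochastic
single-channel gating, series-resistance and space-clamp errors,
temperature dependence of kinetics, drifting baselines, or the unexplained
pressure-coincident inward current seen in some patches.  Passing
round-trip tests therefore demonstrates estimator correctness under the
model's assumptions, not robustness to every artifact of real data.

## Corrections

**Leak subtraction** fits `I = g_leak·V + c` to quasi-steady samples whose
command voltage lies in a caller-chosen subthreshold window and subtracts
both terms.  The conductance is ohmic through 0 mV; the free offset c
absorbs the baseline reference (a through-origin fit would be biased on
recordings whose baseline was zeroed at the holding potential).
Quasi-steady means: within constant-voltage epochs, only samples past 75%
of the epoch and at least 150 ms after the last voltage change — several
deactivation time constants — so post-depolarization tail currents cannot
masquerade as leak.  If the conductances fitted to the lower- and
upper-voltage halves of the window disagree beyond 10% plus a noise
allowance, the result carries a warning flag (gated current in the window)
rather than being rejected.

**Rundown correction** scales every sweep so its fixed pre-pulse amplitude
(mean over the final 20% of the pre-pulse by default) matches the first
sweep's.  Correction is refused when any pre-pulse amplitude is within 5×
the baseline noise SD, with an absolute floor of 0.5 pA for noiseless data
— dividing by noise would corrupt the record.

## Conductance extraction and fitting

**Tail G–V.**  `G(V_test) = (I_test − I_tail)/(V_test − V_tail)`.  I_test
is the isochronal mean over the final 5% of the test step (≥ 10 samples).
I_tail is the tail amplitude *at the instant of repolarization*: after a
blanking interval (default 2 ms, for capacitive settling), the decaying
tail is back-extrapolated to the epoch onset — by a log-linear fit when the
segment is cleanly exponential, otherwise by a nonlinear exponential fit
with the time constant bounded below (decay faster than the blank is
unresolvable, and an unbounded τ would explode the extrapolation on
noise-dominated segments).  When the fitted amplitude is statistically
indistinguishable from zero, the segment mean is used instead: raw
peak-picking on a flat noisy segment is extreme-value biased.
Back-extrapolation matters because the tail decays during the blanking
interval by a factor exp(−blank/τ_deact) that varies with nothing — but
its effect on G varies with V_test, distorting the fitted slope.

**Ramp G–V.**  `G = I/(V − V_rev)` with points inside ±10 mV of the
reversal potential dropped (0/0 noise amplification).

**Boltzmann fit.**  Nonlinear least squares with a deterministic
initialization — G_max ← 1.05·max(G); V_half ← voltage nearest half of
that; s ← (V at 75% − V at 25%)/2.2 — and up to four restarts from a fixed
jitter table (no RNG) before declaring failure.  Standard errors come from
the covariance of the fit.  Curves not spanning half-maximum are flagged,
not rejected.  Normalized curves (max G = 1) report no G_max.

## Activation threshold V_T

Two estimators:

1. **Steepest-segment intercept** — a window of W consecutive points
   (default max(5, 10% of the curve)) slides over the I–V; among windows
   with positive slope and r² ≥ 0.98 the steepest wins, ties going to the
   smaller-voltage window; V_T is that line's V-intercept.  The window
   size, r² gate and tie-break are package operationalizations: "steepest
   segment" has no standard definition.
2. **Closed form** — `V_T = (a·V_half + V_rev)/(a+1)`, `a = (V_half −
   V_rev)/(2s)`, which is algebraically the V-intercept of the tangent to
   the I–V curve at V_half.  It requires V_half > V_rev, and the intercept
   method itself is only meaningful with enough activation/reversal
   separation (codified as V_half − V_rev ≥ 2s; below that the quasi-linear
   region above the curve collapses onto the rising phase).

A systematic caveat, quantified by the test suite: on an ideal Boltzmann
I–V the steepest window straddles the curve's *inflection* V\* > V_half,
and the tangent intercept g(V) = V − I/I′ is maximized exactly there
(g′ = I·I″/I′²).  The two estimators therefore differ by s·δ(a) with
δ(1) ≈ 0.37, δ(2) ≈ 0.21, δ(4) ≈ 0.08 — up to several mV near the a = 1
applicability boundary, shrinking below the fit's typical standard error
once a ≳ 3.  Both estimators are invariant under uniform current scaling
(channel expression level).

**ΔpH-shift analysis.**  The raw shift is the least-squares slope of V_T
against ΔpH; per-unit shifts are also computed against the condition
nearest ΔpH = 0.  The symmetric-pH dependence S_pHi is the slope of V_T
against pH at ΔpH = 0, and the gradient-only shift is
mean(|per-unit shifts|) − |S_pHi|.  Mixing threshold methods across
compared conditions triggers a warning.

## Selectivity and pharmacology

Reversal potentials are estimated by linear interpolation of the zero
crossing between the bracketing points closest to zero current — not a
global fit, because the tail current decays along the post-step ramp and
distant points are model-dependent.  The V_rev-vs-ΔpH slope is ordinary
least squares with its standard error.  GHK permeability inversion uses
Brent root finding to relative tolerance 1e−12 on the monotone
shift-vs-ratio relation; shifts within the stated measurement resolution
return the ratio at the resolution as an upper bound.  Default assay
concentrations: symmetric pH 6 ([H]=1e−6 M) with a 10-fold inward metal
gradient (10 mM in / 1 mM out).  Hill fits run in log-concentration space
(where the model is a two-parameter logistic) with equal weights and the
maximal inhibition fixed at 100%; the IC50 standard error is delta-method
transformed from the log scale.  Temperature enters all electrochemical
formulas only through RT/F with T = temperature_C + 273.15 (default 22 °C).

## Priming statistics

I_B/I_A is computed per patch (isochronal means over the final 5% of each
pulse) and then averaged across patches — the mean of ratios, matching how
such cohorts are reported.  Low-signal patches (I_A below 3× baseline
noise SD; silent channels start from 1–2 pA) are flagged, never dropped.
Group comparisons use Welch's one-way ANOVA (weights n_i/s_i²,
Welch–Satterthwaite denominator df) and Dunnett's T3 against a designated
reference: Welch-type t statistics with per-comparison Satterthwaite df,
family-wise adjusted through the studentized-maximum-modulus distribution.
SMM probabilities have no closed form; they are computed by adaptive
quadrature over the chi-distributed denominator (absolute error well below
1e−4), using the complement integrand in the far tail so that very small
adjusted p-values retain precision.  For one comparison the SMM reduces
exactly to the folded t distribution, so the adjusted p equals the Welch
t-test p; adjusted p-values are monotone in |t| and never smaller than
unadjusted ones.

## Problem sizes and determinism

Simulations default to 5 kHz sampling; the test suite and acceptance
script use 1–5 kHz and protocols of a few seconds so every stage runs in
seconds while keeping ≥ 10 samples in each isochronal window.  Monte-Carlo
recovery studies use 200 fixed seeds; cohort studies use 10 patches per
group with 10% patch-to-patch variability in availability and conductance.
Every stochastic path takes an explicit seed, and the acceptance script
derives all of its randomness from the `--seed` argument.

## Known limitations

* The steepest-segment/closed-form V_T discrepancy near the a = 1
  applicability boundary (quantified above).
* Leak and rundown corrections assume ohmic leak and a common rundown
  factor per sweep; P/n-style subtraction and within-sweep rundown are not
  modeled.
* GHK analysis handles one metal species at a time and no surface-potential
  corrections.
* The simulator's priming switch is binary and permanent; graded or
  reversible priming cannot be represented.
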