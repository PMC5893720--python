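# Methods

This note documents the models, conventions and numerical choices behind
ephyskit, and what the synthetic fixtures do and do not establish about
real recordings.

## Containers and conventions

All times are milliseconds; sample `i` of a trace sits at `t_start + i·dt`
(0-based) and analysis windows are closed intervals `[xbgn, xend]` on
sample times. Currents are pA, voltages mV, conductances nS; dividing a
pA trace by a mV trace yields nS (×1000), but no general unit algebra is
attempted. Every transform returns a new trace and appends exactly one
provenance note (timestamp, operation, parameter string), so a processed
trace carries its own history; the CLI additionally appends one entry per
invocation to a JSON-lines command log. Sweep sets carry named boolean
set memberships; the special set `SetX` is excluded from every selection.
Group assignment defaults to a repeating cycle (sweep index mod
n_groups), matching protocols acquired in repeating sequences.

Filter edges use reflection padding, which avoids endpoint bias in
baseline windows. The low-pass filter is a zero-phase Gaussian FIR with
its −3 dB (amplitude 1/√2) point at the requested corner frequency,
i.e. time-domain σ = √(ln 2)/(2π f_c). `normalize` ((x−min)/(max−min))
and `differentiate` (central differences) are conventions of this
package, not prescriptions of any particular acquisition system.

## Synaptic waveform and fitting

The synaptic waveform family is
`Y(t) = [1 − e^−(t−t0)/τr]^n (a_d1 e^−(t−t0)/τd1 + a_d2 e^−(t−t0)/τd2)`
with `Y ≡ 0` for `t < t0`; the function is undefined before onset and
zero is the physical convention. The default parameter set
(τr = 0.116 ms, n = 1, a_d1 = 86.72, τd1 = 0.36 ms, a_d2 = 13.28,
τd2 = 2.034 ms) is a fast AMPA-receptor miniature-EPSC time course.
Unit-peak normalization rescales both decay amplitudes by a common factor
so max|Y| = 1, with the peak located by bounded golden-section search to
10⁻⁶ ms.

All models (SynExp, variance–mean, Gaussian, double exponential) share
one fitting engine: trust-region-reflective least squares with parameter
bounds enforcing validity (τ > 0, n ≥ 1, N > 0, SD > 0), Jacobian
scaling, and relative tolerance 10⁻⁸ by default. Bounds rather than
penalty guards matter here: a hard invalidity cliff (e.g. at n = 1)
stalls a trust-region step, while a bound lets the optimizer ride the
constraint. Held parameters are fixed exactly, excluded from the
Jacobian, and reported with standard error 0. Standard errors of free
parameters come from (JᵀJ)⁻¹ of the whitened Jacobian when per-point
errors are supplied (absolute-σ convention), otherwise scaled by
RSS/dof. SynExp initial values are heuristic — onset at the last 20%
crossing before the peak, decay from a log-linear tail fit — and the
double-exponential initializer splits a single-exponential peel 70/30.

With the CVs held, the variance–mean relation is linear in
(Q_p, 1/N), so the weighted fit has a closed-form solution
(`VarianceMeanModel.closed_form`); the iterative fit starts there and the
test suite uses the closed form as an independent oracle. Per-point
errors are floored at 10⁻³ of the median error before weighting: a
degenerate zero-variance condition (P = 1 with no quantal variability)
would otherwise receive unbounded weight and collapse the fit.

## Windowed statistics and MPFA summaries

Window measures (avg/min/max) are baseline-relative, with the baseline
the mean over a separate window. Fractional rise times interpolate the
last crossings of baseline + p·(peak − baseline) before the peak; the
rise-time slope is (y_high − y_low)/(t_high − t_low), which scales with
amplitude while the rise time does not — the basis of the fast/slow
classification pair. The peak-measurement helper centers a 0.1-ms window
on the extremum of the set average.

Stability selection scans start indices upward and returns the first
(longest) suffix window whose Spearman rank correlation with sweep index
has two-sided p ≥ α (default 0.05, minimum 10 sweeps). The scan is
suffix-anchored by design — stability is wanted at the *end* of a
recording — so a series that drifts at its end has no stable region even
though its reversal does; the tests pin exactly this asymmetry.

MPFA condition summaries report I_p = mean(peaks),
σ² = var(peaks) − var(backgrounds) (unbiased variances; background
subtraction is standard practice and switchable), and the variance error
from h-statistics: the unbiased estimate of Var(s²),
`(1/n)·(m̂₄ − ŝ⁴·(n−3)/(n−1))`, where m̂₄ and ŝ⁴ are the unbiased
fourth-central-moment and σ⁴ estimators (Kendall–Stuart polykays). The
estimator is validated in the tests against a 10⁴-resample bootstrap on
Gaussian and binomial fixtures (agreement within 15%) and against the
Gaussian closed form 2σ⁴/(n−1). Negative corrected variances are floored
at zero with a warning. Spillover correction is a generic subtraction
hook taking externally supplied mean/variance estimates.

## Event detection

Threshold search: the sliding baseline at test time t is the mean over
[t − Δt_f − b, t − Δt_f] (width b, forward offset Δt_f); a crossing
occurs when the sample deviates from it beyond the level, given in
absolute units or as a multiple of the same window's rolling SD. After a
crossing, a provisional peak is the polarity extremum in the peak window;
the onset is the latest pre-crossing sample within 10% of the event
amplitude of baseline (the onset criterion is a documented convention —
configurable via `onset_fraction`). Events failing required onset/peak
detection are returned rejected with a reason rather than dropped. The
scan resumes one minimum-separation after the peak, so events closer than
the separation merge into the earlier one. An optional detection-time
low-pass (typically 1 kHz) suppresses false threshold crossings in wide-
band noise.

Template matching follows the scaled-template scheme: at each offset the
data segment is fitted as s·w + c in closed form, and the criterion is
DC = s/σ_res with σ_res = √(SSE/(K−1)) (K−1 denominator; an ε = 10⁻¹²
guard prevents division by zero on perfect matches). Sliding sums are
computed by FFT correlation, so a 100-s record at 50 kHz scans in well
under a second. Events are local extrema of DC beyond the criterion
level respecting polarity and minimum separation. The template is
normalized to baseline 0 and peak +1 (dividing by the signed peak), so
negative-going events produce negative DC and the conventional level is
−3 to −4.

## Simulators

**Quantal release.** Site amplitudes are drawn as whole sets from
Gaussian(Q_p, |Q_p|·CV_QII) until the set's sample mean and CV match the
targets within the requested precision (1% default); sign-flipped draws
are resampled, and whole-set resampling (rather than member adjustment)
is the documented choice. Per trial and site, release is a uniform draw
against P; a success contributes site amplitude × (1 + N(0, CV_QS)),
latency-shifted by N(0, σ_QL), on the unit-peak waveform; successes sum
per trial, with optional additive Gaussian noise. The ground-truth
release table (trial, site, amplitude, latency) is returned alongside the
sweeps. Spillover is out of scope for the default protocol (disabled).

**Simulated MPFA protocol.** One site-amplitude set is shared across all
P-conditions; each condition gets a fresh child seed from a seed
sequence. Per-trial peaks are the mean current in a 0.1-ms window
centered on the peak of the grand average pooled over conditions (one
shared measurement window, as MPFA requires); the background window has
the same width and sits before the stimulus. The latency jitter
attenuates the measured quantal peak through this window (E ≈ 0.89 for
the default kinetics, i.e. an effective quantal peak near −17.8 pA for
Q_p = −20) and induces an amplitude CV of ≈ 0.18–0.2; the fit therefore
holds CV_QI = √(CV_QS² + 0.2²) = 0.36 by default, while the simulator's
ground-truth table lets callers measure the actually induced CV rather
than assume it. At the protocol's published scale (150 trials per
condition) the fitted N scatters roughly ±0.5 around its expectation and
Q_p by ±1 pA across seeds; large-trial runs converge to N ≈ 5.1 and
Q_p ≈ −17.6, confirming the estimator is essentially unbiased under the
measurement convention.

**R·P plasticity.** Event-driven and exact: the pre-update (R, P, R·P)
is recorded at each event, then R → R − R·P and P → P + Δ(1 − P), with
closed-form exponential relaxation between events. For a regular train
with Δ = 0 the steady state has the closed form
R* = (1 − e^−T/τR)/(1 − (1 − P_inf)e^−T/τR), used as a 10⁻¹⁰-level oracle.
Conductance trains sum R·P-scaled waveforms over inputs and over direct/
spillover components, each component holding independent state per input
train. Poisson input trains use a shifted-exponential interval
(dead time + Exp) with the rate corrected so the asymptotic mean rate
equals the requested one — plain rejection of short intervals would bias
the rate low.

**Integrate-and-fire.** Exponential Euler per step, with each step
represented by its endpoint-average conductance and drive; this keeps the
update exact for piecewise-constant inputs while making it second-order
accurate for smooth conductance trains, which is what lets spike times
converge under step refinement (dt vs dt/10 agree to < dt on the
conductance-train protocol in the tests). Threshold crossings are
linearly interpolated within the step for sub-sample spike times; the
spike sample is drawn at V_peak purely cosmetically and excluded from any
voltage statistic; the membrane then holds at V_reset for the refractory
period. Spike detection on recorded/simulated voltage uses upward level
crossings with interpolation; requiring the previous sample below the
level is exactly the fall-below re-arm rule, so one action potential
yields one spike.

## Synthetic fixtures: scope and limits

The generators are pure functions of (parameters, seed). The standard
event fixture embeds 20 unit-waveform EPSCs of −20 pA in white Gaussian
noise of SD 2 pA (SNR 10) with ≥ 50 ms spacing — event times drawn as
uniform order statistics with the minimum gap re-inserted, so high
densities remain feasible. White noise is a deliberate simplification:
real recordings have colored noise and drifting baselines, so detector
recall/precision measured here bounds performance under the configured
absolute thresholds but does not certify behavior on real colored noise
(a one-pole-filtered noise option exists for that). The action-potential
fixture inserts a stylized ~2-ms spike shape; it validates crossing
logic and extraction alignment, not biophysics. The direct binomial
variance–mean sampler bypasses waveform kinetics entirely for fast fit
tests.

Problem sizes in the test suite (10⁴-trial variance checks, 100-s
false-positive runs, 10⁴-resample bootstraps, 150-trial × 5-condition
protocol runs) were chosen so statistical tolerances are comfortably
resolved while the whole suite stays around half a minute on one core.

## Known limitations

- No acquisition hardware support; conductance trains can be generated
  for dynamic clamp, but the closed loop itself is external.
- ABF import requires the optional pyabf dependency; HEKA/Igor/MATLAB
  formats and NWB are not supported.
- The quantal simulator's spillover component and the empirical
  spillover-correction relations are not modeled; only a generic
  subtraction hook is provided.
- Single-compartment integrate-and-fire only; no Hodgkin–Huxley gating,
  no voltage-dependent NMDA block, no multi-compartment models.
- The onset criterion in threshold detection and the suffix-anchored
  stability scan are documented conventions; other implementations may
  differ in detail.
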