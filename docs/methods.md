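# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `singlechan`.  It is written for a reader who wants to
judge what the pipeline's validation does and does not establish.

## Gating simulator

The generator (`singlechan.gating_sim`) emulates chart-recorder-era
single-channel recordings from peptide channels in planar bilayers:

- **Arrivals.** Opening events are a homogeneous Poisson process with
  intensity `opening_rate` (events/min).  The recordings this emulates
  show no closed-state structure beyond apparent randomness, and no
  closed-time kinetics are published for this system, so Poisson arrivals
  are a modelling decision, not an inference.
- **Open durations** are drawn i.i.d. from a one- or two-component
  exponential mixture `(w, τ1, τ2)` — the generative counterpart of the
  survival model `N(t) = A1·e^(−t/τ1) + A2·e^(−t/τ2)` with
  `w ≈ A1/(A1+A2)`.  Invariants: `τ1 ≤ τ2`; `w = 1` or `τ2 = None`
  collapses to a single exponential.
- **Amplitudes.** Each event draws a conductance from a Gaussian
  `(mean, sd)` in nS, held constant for the event (square events, the
  observed phenomenology); the current step is `g·V` pA.  Events may
  overlap up to `max_stack` simultaneous levels; an arrival that would
  exceed the stack is discarded (the membrane carries a finite number of
  conducting assemblies).  Default `max_stack = 1` because the analysis
  modules are simplest to validate without stacking; the study drivers use
  3, matching the multi-level openings seen with choline.
- **Bursts.** Optional "paroxystic" episodes multiply the opening rate by
  `burst.intensity` inside Poisson-arriving windows of fixed length.
  Windows are recorded in metadata and events inside them are flagged, so
  analysis stages can exclude them — during real paroxysms individual
  events cannot be counted, and the flagged windows model exactly that.
- **Noise and rasterization.** Traces add white Gaussian baseline noise
  per sample.  Real recordings have 1/f drift, filter ringing, and
  capacitance transients that this generator does not produce; passing the
  round-trip tests therefore shows the idealizer is correct under ideal
  stationary noise, not that it is robust to instrument drift.
- **Determinism.** All draws derive from `numpy` generators seeded from
  the caller's integer; identical inputs give bit-identical outputs.
  `simulate_event_table` and `simulate_trace` share the event stream, so
  the table is the exact ground truth for the trace.

## Idealization

`idealize_trace` implements half-amplitude threshold detection, the
standard criterion when the original analysts' manual rule is unknown:

- Baseline: trace median by default (valid while open probability < 50%),
  or a fixed value for heavy-activity recordings — the study driver fixes
  it at the empty-membrane level, as measured before peptide
  incorporation in a real experiment.
- Unit amplitude: supplied, or estimated from the amplitude histogram of
  above-noise samples.  The noise scale comes from the median absolute
  first difference (insensitive to open-state occupancy); the estimator
  takes the first prominent histogram mode and averages the samples
  within [0.75, 1.5)× of it, so per-event conductance scatter does not
  split one conductance level into several apparent modes.
- A level-k event spans samples with occupancy ≥ k, where occupancy
  counts crossings of baseline + (k − ½)·unit.  Closures shorter than the
  dead time (default 10 ms, the worst-case chart-recorder resolution) do
  not terminate an event; events shorter than the dead time are dropped.
- Amplitude is reported as the event's own conductance step — plateau
  mean minus baseline minus the (k−1) unit levels underneath — which
  keeps conductance histograms single-peaked under stacking.  An event
  whose step does not reach its own detection threshold is discarded as a
  noise artifact (brief blips fused by dead-time gap closure).
- Validation: on simulated control-condition recordings (7.73 events/min,
  0.161 nS at 60 mV, noise 0.1× amplitude), ≥ 95% of uncensored
  ground-truth events lasting ≥ 5 dead times are recovered with duration
  error < 2 dead times, with no spurious detections.  Events still open
  at the end of the recording are right-censored and excluded from this
  comparison.
- Limitation: at open probabilities near 50% and above, occupancy-run
  durations are unions/fragments of overlapping individual openings, so
  the per-level durations are not per-channel dwell times.  The study
  driver therefore runs lifetime fits on event tables (what a chart
  analyst reads off as individual channels); frequencies and conductance
  steps remain valid because every arrival opens exactly one level-k run.

## Conductance statistics

Per-event conductance is |amplitude/voltage| (pA/mV = nS), reported as a
magnitude; the voltage's sign convention (it labels the trans-side
potential) lives in metadata.  Burst-flagged events are excluded by
default.

The histogram uses Freedman–Diaconis binning unless explicit edges are
given, is normalized to probabilities, and is fitted with a 3-parameter
Gaussian by nonlinear least squares, weighted by the multinomial bin
uncertainty √(p(1−p)/n) with `absolute_sigma`, so the covariance-derived
SE of the center reflects true sampling variability (simulated z-spread
1.09, 92% nominal-2SE coverage at n ≈ 500–900).  This follows the
histogram-fit workflow of the original Prism analysis rather than maximum
likelihood on raw values; a Gaussian MLE is provided as a cross-check and
agrees within 2 SE on unimodal data.  Below 30 events no fit is
attempted — the honest summary there is the raw mean ± SD.  Whether the
published "± SE" on central conductances is a fit-parameter SE or a raw
SEM is not stated anywhere; this package uses the fit-parameter SE.

Condition comparison is a Welch-style t on the two fitted centers with
their SEs and Welch–Satterthwaite degrees of freedom from the event
counts.  Two degenerate zero-SE fits with equal centers compare as
(t, P) = (0, 1).

## Lifetime analysis and model selection

`survival_curve` counts, exactly, the events with duration ≥ t at the
sorted unique durations (so N at the smallest duration equals the event
count).  `fit_lifetime` does positivity-bounded nonlinear least squares of
the one- or two-component survival model, initialized at the 25th/75th
duration percentiles with up to 5 seeded random restarts; two-component
results are canonically sorted τ1 < τ2.  `select_lifetime_model` applies
the extra sum-of-squares F-test with P from F(df1−df2, df2); a tie at
exactly α keeps the simpler model, and SS2 > SS1 clips F at 0.

**Fitting grid.** Least squares on cumulative survival counts has heavily
correlated residuals.  Evaluated at one threshold per event, that
correlation inflates the F-test's false-positive rate to ~50% at α = 0.05
(simulated, n = 300 single-exponential events) — the nominal F reference
distribution is simply wrong there.  `analyze_lifetimes` therefore fits on
a fixed 10-point grid: t = 0 plus quantiles 0.1…0.98 of the durations
(falling back to unique durations for tiny samples).  Quantile spacing
puts equal event mass in each interval; with it the simulated
false-positive rate is 5.6% (500 replicates, n = 300), two-component
detection power at the study's mixture (τ = 1.53/8.34 s, fast weight 0.8,
n = 2000) is 100%, and median recovered time constants are 1.52 s and
7.95 s.  A dwell-time maximum-likelihood mixture fit is provided as an
independent cross-check of the LS estimates.

The fast-component weight 0.8 used for the two-component study condition
is a reconstruction — the original analysis reports time constants only,
never amplitudes.  Cases with 0.05 ≤ P < 0.15 are reported by the study
driver as "indeterminate" rather than forced into either model order.
No missed-event (dead-time) correction is applied to τ estimates.

## GHK selectivity

Constants: R = 8.314462618 J mol⁻¹ K⁻¹, F = 96485.33212 C mol⁻¹; the bath
temperature 23 °C gives RT/F = 25.52 mV.  Concentrations (not activities)
enter the GHK relation, with KCl fully dissociated.  The closed-form
inversion r = ([Cl]c − x·[Cl]t)/(x·[K]c − [K]t), x = e^(VF/RT), is exact:
the forward/inverse round trip holds to 1e−12 relative error over four
decades of r, and r = 0 / r = ∞ reproduce the Cl⁻ and K⁺ Nernst limits.

Against the six published reversal-potential→ratio pairs under 100/50 mM
KCl, five invert to the printed two-decimal value exactly; 6.42 mV inverts
to 0.454, which rounds to 0.45 against the printed 0.46 — a one-digit
rounding discrepancy in the original report, within the ±0.01 band used
here.  The published no-choline POPC:Ch pair (8.99 mV → 0.32) inverts to
0.31 at the stated temperature and is documented as inconsistent rather
than asserted.

Reversal potentials are estimated two ways, matching the two experimental
routes: ordinary least squares on I–V points (I = g(V − V_rev), slope =
chord conductance in nS, V_rev SE by the delta method) and linear
interpolation of the zero crossing in a ±4 mV stepped-potential sweep.

## Tracer flux

The permeability coefficient uses the initial-flux two-compartment
formula P = (N_trans/Δt)/(A·C_cis): receiver-side sampled counts are
scaled to the chamber volume (default 4000 µL, sampled 10 µL), divided by
the elapsed time (default 30 min) and by membrane area (default the
300 µm aperture, A ≈ 7.07×10⁻⁴ cm²) times donor concentration.  The
original report names no formula; this is the standard choice for a
single-timepoint design in which receiver accumulation stays far below
donor content.  P is invariant to the tracer's specific activity, and the
forward model in `simulate_flux_counts` closes an exact round trip in
tests.  The published coefficients (≈ 47×10⁻⁶ cm/s) cannot be recomputed
from printed inputs (raw counts were never published) and are used only
as the scale for the forward/inverse consistency demonstration.  No
isotope-decay or unstirred-layer corrections are applied.

## Study orchestration and problem sizes

`run_study` runs simulate → idealize → conductance → frequency → lifetime
for every condition × voltage cell, with per-cell seeds derived from the
study seed via `SeedSequence` (byte-identical reruns), per-cell error
capture, and one structured log line per stage (input hash, parameters,
outcome).  Configuration is a flat YAML document.

Problem sizes used by the validation suite and the acceptance script —
2000 dwell times × 20 seeds for mixture recovery, 500 replicates of n=300
for the F-test null, 505/898 events for conductance fits, 200 one-hour
Poisson recordings for frequency, 40 one-minute noisy traces for the
idealization round trip — were chosen to estimate each quantity's
sampling variability well below the tolerance being checked while keeping
the whole suite in tens of seconds.  The analysis drivers use one-hour
recordings at 1 kHz so each condition yields several hundred events, the
scale at which the published lifetime tables operate.

## Known limitations

- The simulator's stationary white noise and constant baseline idealize
  real recordings; drift robustness is untested by construction.
- Threshold idealization undercounts and mis-measures durations at open
  probabilities approaching 50% (see above); hidden-Markov idealization
  would be the next step and is out of scope.
- LS-on-survival-counts remains less efficient than dwell-time MLE even
  on the coarse grid; it is kept because it mirrors the workflow being
  reproduced, with the MLE as a cross-check.
- Closed-time kinetics, missed-event corrections, multi-ion GHK, and
  surface-potential corrections are out of scope.
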