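# Methods

Units everywhere: mV, pA, ms, nS, pF. With these units nS = pA/mV,
pF = fC/mV and GΩ·pF = ms, so no conversion constants appear in formulas.
Default sampling interval is 0.05 ms (20 kHz).

## Recording model and protocols

A `Trace` is one sampled channel; a `Recording` is a list of
(command, response) sweep pairs with a `StepProtocol` (or gap-free marker)
and free-form metadata. The built-in protocols mirror standard cultured-
neuron acquisition:

- current clamp: 35 steps of 3 pA, 400 ms, starting 12 pA below the holding
  current, APs counted over the first 17 steps;
- voltage clamp: 400 ms steps spanning −90…+80 mV from a −60 mV hold
  (10 mV spacing by default; the spacing is read from the command channel
  when one is present);
- gap-free EPSC recordings at −60 mV command (−70 mV after liquid-junction
  correction; the ~10 mV correction is carried as metadata and applied to
  reported potentials only when `apply_junction_correction` is set, since
  figures conventionally show commanded values).

Command potentials/currents, QC dispositions and every analysis constant
used are logged per run; the run manifest lists the config hash, seeds,
inputs and outputs, and re-running with the same manifest inputs reproduces
all outputs byte-for-byte.

## Spontaneous EPSC analysis

EPSCs are inward current transients. The detector:

1. tracks the slow baseline with a running median (200 ms window, evaluated
   on a window/4 grid and linearly interpolated — equivalent to a dense
   running median for drifts much slower than the window);
2. low-passes the baseline-subtracted current with a 4-pole Bessel at
   1 kHz (zero-phase, forward-backward);
3. estimates the noise SD robustly (1.4826·MAD) on the filtered signal and
   thresholds negative peaks at max(5 pA, 4·σ̂) with ≥1 ms peak separation
   and prominence ≥ half the threshold;
4. takes the onset at the preceding 10 %-of-peak crossing and the amplitude
   peak-to-local-baseline from the *unfiltered* signal near the peak (the
   low-pass attenuates sharp peaks).

Overlapping events separated by a repolarizing interval are split into
distinct detections; closer pairs merge into one detection by design — the
ground-truth inventory still lists them individually, which is why detector
scoring uses one-to-one matching with a ±2 ms window rather than exactness.

Decay constants come from a per-event least-squares fit of A·e^(−t/τ) from
the peak over ≤20 ms, truncated at the next event's onset; if a *larger*
event begins inside the window the decay is contaminated and τ is reported
missing, as are fits with R² < 0.5. Fits use the unfiltered
baseline-subtracted signal so the filter cannot bias τ.

A neuron *has synaptic activity* if it exceeds 20 events per 60 s. Exactly
20 is classified inactive: the defining clauses cover "more than 20" and
"fewer than 20" only, and the boundary is resolved conservatively (and
logged). For durations ≠ 60 s the rule is applied to the 60 s-scaled count
with a provenance note.

## Evoked action potentials

Detection requires a dV/dt upstroke crossing 10 mV/ms within 5 ms before a
voltage peak exceeding −20 mV; peaks closer than 2 ms merge (earliest
kept). The derivative is taken on a Savitzky–Golay-smoothed copy (0.5 ms,
order 3); peak times are refined on the raw trace. Counting covers the step
epoch only (no rebound spikes) over the first `count_steps` sweeps.
All constants are config keys (`spike.*`).

Neurons whose holding current exceeds 50 pA in magnitude fail QC and are
excluded from group statistics (strict inequality: exactly 50 pA passes).
Holding current comes from metadata or the pre-step command baseline; if
unavailable the QC result is *indeterminate* (excluded by default,
configurable).

## Spike shape

Measured on the first evoked AP — the lowest-current sweep containing a
spike:

- **Threshold**: the first maximum of d²V/dt² before the peak. The second
  derivative is estimated with a Savitzky–Golay derivative filter; the
  "first maximum" is the earliest local maximum whose prominence clears
  both 10 % of the window maximum and 4× the robust noise SD of d²V itself
  (pure height floors select smoothing ripple riding on the depolarizing
  ramp). The sample is then refined on the raw second difference when the
  raw corner stands ≥6 robust SDs clear of noise (noiseless data:
  sample-exact), else by parabolic sub-sample interpolation of the
  smoothed derivative. Ties go to the earliest candidate.
- **Amplitude**: peak V − threshold.
- **FWHM**: between the half-amplitude crossings bracketing the peak,
  linearly interpolated between samples (sub-sample width).
- **Fast AHP**: V(t_recross + 5 ms) − threshold, where t_recross is where
  the downstroke re-crosses threshold; missing if the sweep ends first.

On noiseless template cohorts all four fields are sample-exact; with 0.5 mV
sample noise the threshold voltage carries a few-mV uncertainty because it
is read off a ~30 mV/ms ramp.

## Passive properties

- **Input conductance**: (I(−50) − I(−70)) / 20 mV from steady-state means
  (final 25 % of each epoch, configurable). In practice the two currents
  come from the matching steps of the voltage-clamp family. The measure is
  operational: at −50 mV small voltage-gated tails contribute, exactly as
  they do in a real recording.
- **Capacitance**: from the averaged membrane-test sweep. ΔV and the step
  onset are read from the command channel; the Ohmic plateau is the final
  25 % of the step epoch; the transient charge above the plateau gives
  C = Q/ΔV. A mono-exponential fit of the transient provides the
  cross-check C = τ/R with R = ΔV/I_plateau; both estimates and their
  relative discrepancy are reported. Charge integration is primary because
  it is insensitive to series-resistance distortion of τ. A step reaching
  its plateau within ~2 samples (or ΔV = 0) is an estimation error, not a
  zero.

## Ionic current families

Per voltage step, after subtracting the pre-step baseline: Na peak = the
early-window minimum (window 0.5–10 ms after onset; the first 0.5 ms is
blanked against the capacitive artifact), clipped at ≤0 by convention;
fast K = the early-window maximum; slow K = the mean over the final 50 ms
of the step. All three are divided by the cell capacitance (pA/pF);
without a capacitance the values are returned in raw pA with an explicit
`unnormalized` flag. Window bounds are `vc.*` config keys. When the inward
transient overlaps the potassium rise, the "fast K" value is the net
outward peak — the operational definition, not an ionic decomposition.
Voltage lookups (`density_at_voltage`) are nearest-grid within half the
step spacing, never interpolated.

## Group statistics

The default two-group comparison is a two-tailed Welch t-test
(unequal-variance reading of "two-sample t-test"; pooled Student's t sits
behind a flag for sensitivity probes). The active fraction is compared by
Fisher's exact test on the 2×2 active/inactive table (chi-square behind a
flag). Current-density families are compared by one-way ANOVA on each
neuron's extreme density (most negative Na across steps; largest K); since
the original ANOVA structure is ambiguous, a two-way additive
group × voltage layout is provided as an alternative and neither is
asserted as canonical. Amplitude distributions are compared by two-sample
KS with a median-shift direction flag. Only QC-passed neurons enter group
statistics; missing values are excluded and reflected in the reported n.
No multiple-testing correction is applied; reports annotate the number of
tests performed. Pooling of patient lines into one group is a config
option, not a default.

## Synthetic data generator

The generator's role is oracle testing: every recording comes with the
exact inventory needed to score the pipeline.

- **EPSC traces**: homogeneous Poisson event times, lognormal amplitude
  magnitudes (mean/CV parameterization; the amplitude family of real EPSCs
  is not established, so lognormal is a modeling choice), instantaneous
  rise + mono-exponential decay kernels (a finite-rise biexponential is a
  config option, default off), linear summation of overlaps, additive white
  Gaussian noise on a zero baseline. Events drawn past the recording end
  are excluded from trace *and* inventory. Defaults — 1 event/s, 20 pA,
  CV 0.3, τ 2.3 ms, 2 pA noise, 60 s — are the desk-scale study
  conditions; the "PD-like" demo group scales the mean rate by 0.2 and
  sets τ = 1.5 ms.
- **Current-clamp families**: deterministic spike counts from a
  thresholded-linear F–I rule ⌊gain·(I − rheobase)⌋ (0 below rheobase;
  default gain 0.15 spikes/pA, rheobase 6 pA relative to holding), spikes
  evenly spaced in the step. Templates are piecewise linear (rise, fall,
  AHP plateau, recovery) so threshold, amplitude, FWHM and fast AHP have
  closed forms; the pre-threshold depolarizing foot is cubic in time with
  an end slope fixed at 40 % of the upstroke slope, so the slope *increases*
  at threshold — the property the second-derivative criterion measures.
  The subthreshold step response is a linear depolarization clipped 10 mV
  below threshold. Conductance-based (HH) simulation is deliberately out of
  scope; templates are what make feature recovery exactly checkable.
- **Voltage-clamp families**: closed-form step currents — linear leak
  referenced to the hold, a Boltzmann-gated transient inward component
  (V½ = −30 mV, slope 6; activation τ 0.4 ms, inactivation τ 2 ms,
  E = +60 mV), an early-peaking partially-inactivating outward component
  and a slowly activating sustained outward component (E = −90 mV).
  Ground-truth densities evaluate the noiseless model on the sample grid
  under the same window definitions the extraction applies. Default scales
  (Na 10 nS, fast K 3 nS, slow K 2 nS, leak 0.5–1 nS, C ≈ 20–25 pF) put
  peak Na densities in the 10–20 pA/pF range typical of these cultures.
- **Membrane test**: ideal RC response I(t) = (ΔV/R)(1 + e^(−t/RC)) — the
  simplest trace with transient τ = RC and transient charge exactly
  Q = C·ΔV. Default 250 ms sweeps leave ≥10 τ of relaxation for the
  charge integral.
- **Cohorts**: per-neuron parameters drawn from per-group distributions —
  lognormal rates (CV 0.8), truncated-normal conductance scales and
  capacitance (CV 0.2–0.3), normal spike-threshold jitter (SD 2 mV).
  One root `SeedSequence` per cohort is spawned per neuron and per
  recording, so cohorts are exactly reproducible and any neuron can be
  regenerated in isolation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: series-resistance and space-clamp errors,
electrode drift and seal instability, non-stationary event rates and
correlated (burst) release, dendritic filtering of EPSC kinetics, channel
noise, and spike-frequency adaptation. The oracle tests validate the
*estimators*; detector settings for real recordings still need the usual
per-dataset sanity checks, and the original deposited recordings can be
analyzed by pointing `extract` at them once converted to the interchange
format.

## Numerical choices and degenerate inputs

- Decay fits and the capacitance cross-check use bounded trust-region
  least squares with positivity bounds on τ and A.
- FWHM and event onsets interpolate linearly between samples.
- Exact-20-events classification: inactive (above).
- Welch t on near-identical groups returns t ≈ 0, p ≈ 1 (scipy may warn
  about precision on degenerate variance; harmless).
- Empty event lists summarize to rate 0, inactive, with amplitude/τ stats
  missing (never 0).
- Feature CSVs write missing metrics as empty fields and use 10
  significant digits so round-trips preserve at least 6.

## Problem sizes in the test suite

The oracle suite runs at desk scale: 100 × 60 s recordings for detector
scoring, 30 neurons per group for the τ contrast, 130 step families for
spike counting, 500 replicates for test calibration, and a 3 + 3-neuron
demo cohort for the byte-identity determinism check — sizes chosen so the
whole suite stays in the minutes range on one CPU while keeping Monte-Carlo
standard errors well inside the asserted tolerances.
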