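# synaptoprobe

Whole-cell patch-clamp analysis for cultured neuron cohorts — built for the
kind of study that compares iPSC-derived dopaminergic neurons from
Parkinson's-disease patients against healthy controls, where the headline
readout is a *reduction in spontaneous synaptic activity* alongside
unchanged or subtly altered intrinsic excitability.

The package covers the full analysis chain:

- **Spontaneous EPSCs** (gap-free voltage clamp at −60 mV under
  bicuculline): median-baseline tracking → low-pass filtering → robust
  thresholding at max(5 pA, 4·σ̂), per-event amplitude, mono-exponential
  decay-τ fits, event rate, and the *synaptically active* classification
  (> 20 events per 60 s).
- **Evoked excitability** (35 current steps of 3 pA, 400 ms, starting 12 pA
  below holding): spike detection with a dV/dt criterion and total
  AP count over the first 17 steps; neurons needing more than 50 pA of
  holding current are excluded by QC.
- **Spike shape** on the first evoked AP: threshold as the first maximum of
  d²V/dt², amplitude = peak − threshold, sub-sample FWHM, and the fast AHP
  5 ms after threshold re-crossing.
- **Passive properties**: input conductance G = ΔI/20 mV between −70 and
  −50 mV; capacitance from the membrane-test transient by charge
  integration C = Q/ΔV, cross-checked by C = τ/R.
- **Ionic currents** (−90…+80 mV steps from −60 mV): Na peak (early-window
  minimum), fast K (early-window maximum), slow K (late-window mean), all
  baseline-subtracted and normalized to pA/pF by the cell capacitance.
- **Group statistics**: two-tailed Welch t per feature, Fisher's exact test
  on the active fraction, one-way ANOVA across current-density families,
  KS comparison of amplitude ECDFs, per-group mean ± SEM tables.
- **A synthetic-data generator with exact ground truth** — Poisson EPSC
  trains with lognormal amplitudes on Gaussian noise, piecewise-linear
  spike templates with closed-form shape metrics, Boltzmann-gated
  inward/outward current families, ideal-RC membrane tests, and multi-group
  cohorts — so every stage of the pipeline is testable without recordings.

Everything is plain Python on numpy/scipy/pandas; recordings live in a
small documented HDF5 interchange format (ABF and NWB readers are available
as optional extras `synaptoprobe[abf]` / `synaptoprobe[nwb]`).

## Worked example

```python
import numpy as np
import synaptoprobe as sp

rec, truth = sp.gen_epsc_trace(rate=1.0, amp_mean=20.0, amp_cv=0.3, tau=2.3,
                               noise_sd=2.0, duration=60.0, seed=42)
events = sp.detect_epscs(rec.sweeps[0][1])
summary = sp.summarize_events(events, duration=60.0)
print(summary.n_events, round(summary.rate, 2), summary.active)
```

prints `67 1.12 True`: the detector found all 67 inserted events, the rate
is 1.12 events/s, and the neuron is classified synaptically active because
it exceeds 20 events per 60 s. Running
`python examples/04_cohort_comparison.py` takes this to the cohort level
(10 control vs 10 "PD" synthetic neurons, PD with a 5× lower mean rate and
faster decay):

```
EPSC rate: control 0.87 ± 0.14 vs PD 0.29 ± 0.09 events/s (Welch t, p = 0.00314)
decay tau: control 2.25 vs PD 1.47 ms (p = 4.89e-14)
active fraction: 90% vs 20% (Fisher exact, p = 0.00548)
Na density ANOVA: F = 0.17, p = 0.689 (groups share one Na-conductance distribution, so no effect expected)
```

The generated decay constants were 2.3 vs 1.5 ms; the pipeline recovers
2.25 vs 1.47 ms and flags the contrast, while correctly finding no effect
in the sodium densities, which were drawn identically for both groups.

Each script in `examples/` is a short narrative of one capability:
EPSC detection, excitability + spike shape, passive properties + I–V
curves, and the cohort comparison. The same pipeline is scriptable from
the shell:

```bash
synaptoprobe simulate --seed 1 --out rec/
synaptoprobe extract --in rec/ --out features.csv
synaptoprobe compare --in rec/ --groups control,PD --out stats.json
synaptoprobe all --seed 1 --out run/       # simulate→extract→compare, with manifest
```

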