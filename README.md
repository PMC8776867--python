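# mauthner

Stochastic Mauthner-cell model of audiovisual escape decisions in goldfish.

Goldfish escape looming threats with an all-or-none C-start driven by a
single spike of the Mauthner cell, a command neuron that sums auditory and
visual input at its soma.  When a brief auditory pip is added near the end
of a visual loom, escape probability rises beyond what independent
processing would predict — most strongly for weak cues (inverse
effectiveness) — and escapes lock to the pip.  This package is for
computational and behavioral neuroscientists who want to simulate,
quantify and test that computation:

* a leaky integrate-and-fire Mauthner cell (`tau dV/dt = -(V - V_rest) +
  R_in I_syn`, threshold -65 mV, rest -80 mV, tau 0.5 ms) driven by a ramped
  "visual" current `v(t) = e v_max (s - t) / (s e^{(s-t)/s})` (slope `s`
  redrawn per trial from Gamma(mean 200 ms, sd 150 ms)) and a 20 ms square
  "auditory" pulse, with per-trial amplitude multipliers R1, R2 ~ U(0, 1];
* the multisensory statistics: Expected Response Probability
  `ERP = P(V) + P(A) - P(V)P(A)`, Integration Coefficient
  `IC = (ORP - ERP)/(ORP + ERP)`, MSI/LP/UV response-time windows and
  inverse-effectiveness regressions;
* calibration of the six auditory and six visual input intensities to
  behavioral unisensory response probabilities;
* looming-stimulus geometry (subtended angle, L/V, Michelson contrast);
* a synthetic behavioral-trial generator with the statistical structure of
  the study (freezing prior state, intensity-dependent C-starts,
  habituation, modality-specific response-time distributions) plus a
  parameter-recovery harness.

## Worked example

```python
import numpy as np
from mauthner import (AuditoryInputSpec, MauthnerParams, TrialConfig,
                      VisualInputSpec, run_condition,
                      expected_response_probability, integration_coefficient)

params = MauthnerParams()
cfg = TrialConfig()  # 1300 ms trial, loom ends at 1000 ms, pip at 840 ms

weak_v = VisualInputSpec(v_max=95.0)    # nA
weak_a = AuditoryInputSpec(a_max=90.0)  # nA
p_v = run_condition(weak_v, None, cfg, params, n_trials=2000, seed=1).p
p_a = run_condition(None, weak_a, cfg, params, n_trials=2000, seed=2).p
both = run_condition(weak_v, weak_a, cfg, params, n_trials=2000, seed=3)
erp = expected_response_probability(p_v, p_a)
ic = integration_coefficient(both.p, erp)
print(f"P(V) = {p_v:.3f}   P(A) = {p_a:.3f}")
print(f"ERP  = {erp:.3f}   ORP  = {both.p:.3f}   IC = {ic:.2f}")
locked = np.mean((both.valid_spike_times >= -160) & (both.valid_spike_times < -120))
print(f"responses within 40 ms of the pip: {100 * locked:.1f}%")
```

prints

```
P(V) = 0.204   P(A) = 0.164
ERP  = 0.335   ORP  = 0.554   IC = 0.25
responses within 40 ms of the pip: 81.9%
```

Each weak cue alone fires the cell on ~20% of trials, so independent
processing predicts 33.5%; the paired stimulus fires on 55.4% of trials —
a positive Integration Coefficient of 0.25 — and most of those spikes fall
inside the 40 ms multisensory-integration window after the pip: the
subthreshold loom depolarization and the pulse sum at the soma.

The same logic at the extremes: two 10% cues give ERP 0.19, and an observed
50% yields IC 0.45, whereas 70%/80% cues give ERP 0.94, so even a saturated
100% response yields only IC 0.03 — enhancement fades as cue salience grows.

## Command line

```bash
mauthner describe-stimulus            # loom geometry: L/V 0.1935, 2.06 -> 100.79 deg
mauthner calibrate --out intensities.yaml
mauthner simulate --config config.yaml --out results/
mauthner analyze --trials trials.csv --unisensory uni.csv --out results/
mauthner generate --config behavior.yaml --out trials.csv
mauthner report --out results/      # full pipeline + JSON summary
```

`mauthner report` calibrates the six per-modality intensities to the
behavioral unisensory ranges (visual 10-71%, auditory 0-76%), runs all 36
audiovisual combinations at 200 trials each with a 160 ms audio lead plus
the delay sweep (-40 to -460 ms), and emits the IC matrices per response
window, inverse-effectiveness fits, window occupancies and the
low-probability-gap lengths per delay.

## Layout

```
src/mauthner/
  lif.py          LIF Mauthner cell, input waveforms, trial/condition runners
  geometry.py     loom geometry and Michelson contrast
  calibration.py  intensity fitting against behavioral probabilities
  msi.py          ERP/IC, response windows, IC matrices, OLS fits
  behavior.py     synthetic behavioral tables and parameter recovery
  config.py       YAML experiment configuration
  pipeline.py     calibrate -> simulate -> analyze -> report driver
  cli.py          click command line
docs/methods.md   model description, numerical choices, limitations
```
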