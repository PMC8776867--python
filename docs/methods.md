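# Methods

This note documents the model, the statistics, the synthetic-data generator
and the numerical choices behind the `mauthner` package, in the spirit of a
model-description appendix.

## The scientific problem

Goldfish escape imminent threats with an explosive C-start, an all-or-none
maneuver triggered by a single action potential of the Mauthner cell, a
bilateral reticulospinal command neuron that integrates auditory input (via
its lateral dendrite) and visual input (via its ventral dendrite) at the
soma.  When a looming visual stimulus (an expanding dark disk) is paired with
a brief auditory pip, escape probability exceeds what independent processing
of the two channels would predict, the enhancement is strongest for weak
cues (inverse effectiveness), and response times collapse onto the moment of
the pip.  The package reproduces this audiovisual decision computation with a
single-cell model and quantifies it with the Integration Coefficient
framework.

## The Mauthner-cell model (`mauthner.lif`)

A single-compartment leaky integrate-and-fire unit:

    tau_m dV/dt = -(V - V_rest) + R_in * I_syn(t)

with `V_rest = -80 mV`, threshold `-65 mV` (threshold gap dV = 15 mV), reset
`-80 mV`, `tau_m = 0.5 ms`.  A trial ends at the first threshold crossing
(single-spike semantics): one crossing, one C-start.

Note the sign of the leak: the source equation for this model class is often
written with `+(V - V_rest)`, which is unstable; the standard stable form
above is what any integrate-and-fire simulator actually integrates, and is
what we implement.

**Inputs.** Two current waveforms are injected directly into the membrane
equation with unit weight:

* *Visual ramp*: `v(t) = e * v_max * (s - t')/(s * exp((s - t')/s))` with
  `t'` measured from the ramp peak, equivalently `v = v_max * u * e^(1-u)`
  with `u = 1 + (t_peak - t)/s`.  It rises monotonically to `v_max` at the
  end of loom expansion and decays afterwards.  The slope constant `s` is
  drawn once per trial from a Gamma distribution with mean 200 ms and s.d.
  150 ms (shape 16/9, scale 112.5 ms), mimicking trial-to-trial variability
  of looming-evoked depolarization.  Past `t_peak + s` the printed form turns
  negative and, for small `s`, diverges; we truncate the ramp at zero there
  (the drive is excitatory by construction), which leaves the ramp on and
  before the peak exactly as written.
* *Auditory pulse*: a 20 ms square current pulse of amplitude `a_max`,
  half-open in time (`[onset, onset + 20)`).

Per trial, both amplitudes are scaled by independent multipliers
`R1, R2 ~ Uniform(0, 1]` (sampled as `1 - U[0,1)` so that zero is excluded),
representing variability in stimulus efficacy across fish and trials.  These
multipliers and `s` are the model's only stochastic elements.

**Timing.** Trials last 1300 ms; the visual ramp peaks at 1000 ms (300 ms
before trial end); the auditory onset precedes the ramp peak by the
audiovisual delay (default 160 ms).  Response times are reported relative to
the end of visual expansion (negative = before the end).

**Input pathway.**  The input waveforms are specified as currents, so they
are injected directly rather than filtered through an exponential synapse;
with `tau_m = 0.5 ms` the membrane already low-pass-filters on a faster
timescale than any feature of the inputs, and no synaptic time constant is
part of the model specification.

**Circuit variants.**  `inhibition_mode="feedforward"` adds the negative of
each excitatory input delayed by 7 ms, the latency of auditory feedforward
inhibition onto the Mauthner cell; since the membrane equilibrates within
~3 ms, this barely affects the fast pulse but strongly attenuates the slow
ramp, so it raises effective sensory thresholds while leaving the response
topology unchanged.  `inhibition_mode="freezing"` adds a constant negative
current; the default (-23 nA) is the analytically smallest constant current
that halves a mid-intensity auditory response probability
(`calibration.freezing_current_for_halving`), since no magnitude is part of
the model specification.  Both variants shift thresholds without reshaping
the response-time distribution, matching their intended interpretation.

**Integration.**  Exact exponential update per step
(`V <- V_inf + (V - V_inf) * exp(-dt/tau)`, `dt = 0.1 ms`), with the current
held constant over each step (left-edge sampling).  The trajectory therefore
equals the closed-form solution at every step boundary to machine precision
(tested).  Threshold is detected at step boundaries; the spike time is the
first boundary with `V >= threshold`.  The per-trial recursion is evaluated
with a linear filter over the whole time grid, vectorized across trials in
chunks of 256 (a few tens of MB of workspace), which makes the full
experiment grid run in seconds.

**Analytic oracle.**  Because the pulse outlasts `tau_m` by a factor 40, the
auditory-only response probability has a closed form,
`P = max(0, 1 - dV/(R_in * a_max))`, used to seed calibration and to
cross-check the simulator (agreement within 3 binomial SE is enforced in the
tests).

## Current-to-voltage scale and calibration (`mauthner.calibration`)

The model is scale-free in the product (current x resistance): the published
parameters include a specific capacitance (2500 pF/cm^2) but no membrane
area, so `R_in` cannot be pinned down and is exposed as a parameter rather
than guessed.  The default `R_in = 0.2 MOhm` anchors the printed auditory
range (75-250 nA) to the threshold gap: 75 nA x 0.2 MOhm = 15 mV exactly, so
the weakest pulse never fires — matching the observation that the lowest
auditory intensity yielded no responses.  Calibration treats intensities,
never `R_in`, as free, avoiding unidentifiability.

The six per-modality intensities are fitted so that simulated unisensory
response probabilities match behavioral targets (defaults: visual 0.10 to
0.71 and auditory 0 to 0.76, linearly interpolated across the six levels —
the behavioral per-level values themselves were not published).  The fit is
bisection on intensity, exploiting monotonicity, with 2000 Monte-Carlo
trials per evaluation and a stopping tolerance of 0.02 (25 iterations max).
All evaluations inside one fit reuse a single frozen set of per-trial draws
(common random numbers), which makes the estimated probability exactly
monotone in intensity and the whole procedure deterministic given the seed.

Within the printed intensity bounds and with the anchored `R_in`, the
achievable probability ranges are about 0-0.70 (auditory) and 0.17-0.66
(visual) — slightly short of the behavioral endpoints.  Unreachable targets
return the nearest bound flagged `clipped` in the diagnostics; all derived
quantities (window concentration, IC signs, slopes) are insensitive to this
few-percent shortfall at the range ends.

## Loom geometry (`mauthner.geometry`)

The on-screen disk grows exponentially from 0.27 cm to 18.15 cm in 5.3 s
(subtending 2.06 degrees to 100.84 degrees).  Two idealizations are
implemented side by side and deliberately not forced to coincide: the
exponential screen stimulus (`loom_diameter`, `loom_angle`) and the
constant-velocity approach summary `L/V = 2*duration /
(cot(theta0/2) - cot(theta1/2))`, which evaluates to 0.192 s for this
stimulus.  The viewing distance implied by the initial angle (~7.51 cm)
differs from the final-angle solution by under 1%, a consequence of rounding
in the published angles; we anchor on the initial angle and tolerate 0.1
degrees on the final one.  Contrast is the Michelson index
`(I_disk - I_bg)/(I_disk + I_bg)`; dark-on-light looms are labelled by |MI|.
The six MI values (0.03-0.49) and six amplitudes (133.5-166.1 dB re 1 uPa)
are configuration labels carried through to outputs; mapping pixel values or
dB to physical units is projector/speaker-specific and out of scope.

## Integration statistics (`mauthner.msi`)

* `ERP = P(V) + P(A) - P(V)P(A)` (addition rule for independent events);
  `IC = (ORP - ERP)/(ORP + ERP)` in [-1, 1].  ICs with `ORP + ERP = 0` are
  reported missing, never imputed.
* **Windows.**  PRE (before auditory onset), MSI (40 ms after onset), LP and
  UV.  The LP/UV boundary is empirical: the 5%/95% quantiles of the pooled
  post-MSI response times delimit the UV window; times beyond the 95%
  quantile remain labelled UV, the quantile pair being a window *boundary*
  estimate, not a filter.  Boundaries are fitted on times pooled per
  condition set (per delay condition in the sweep), not per combination,
  where 200 trials would make quantiles too noisy.
* **Window ICs.**  The window ORP counts trials responding in that window
  over *all* trials of the combination: a fish that escaped during MSI
  cannot respond again later, which is what makes late (UV) coefficients
  negative.  The unisensory probabilities entering the window ERP are
  restricted to the same window (`window_erp=True`, the default): the
  comparison is then like-for-like (e.g. the UV-window ERP is essentially
  the probability of a late visual-only response, and the MSI-window ERP is
  dominated by the auditory probability, whose unisensory latencies fall
  inside the window entirely).  Comparing a windowed ORP against whole-trial
  ERPs (available via `window_erp=False`) conflates the window restriction
  with integration: combinations with salient looms fire before the pip and
  mechanically depress the windowed ORP far below the whole-trial ERP,
  flipping the sign of the mean MSI coefficient for reasons unrelated to
  integration.
* **Mean IC.**  Reported with a delta-method standard error propagating the
  binomial noise of each cell's ORP (independent across cells) and of each
  unisensory level probability (shared across that row/column of the grid).
* **Inverse effectiveness.**  OLS of IC on auditory amplitude and on visual
  contrast (values in nA, or level ranks), with 95% CIs — the model-data
  analogue of the behavioral regression; full GLM machinery is reserved for
  the behavioral generator's recovery harness.

## Synthetic behavior (`mauthner.behavior`)

The generator emulates the study design: ~180 animals, 9-13 trials each with
at least one visual-only and one auditory-only trial (remainder
multisensory), freezing prior state with probability 0.367, C-start
probability logistic in intensity level per modality (non-freezing defaults
0.10-0.71 visual, 0.02-0.76 auditory — an exact 0 lies outside the logistic
family, so the auditory floor is 0.02), multiplied by 1/3 when freezing,
multiplied by a per-trial habituation decay (default 1.94%/trial, i.e. ~21%
cumulative by trial 13), and an intensity-independent alarm probability
(0.17 non-freezing, 0.01 freezing) for trials without a C-start — alarm and
C-start are mutually exclusive outcomes, with the C-start drawn first.

Multisensory C-start probability is the ERP plus a configurable
super-additive term `enhancement * (1-ERP) * (1-pV) * (1-pA)` whose shape
builds in inverse effectiveness; `enhancement=0` gives exact independence.

Response times: visual-only draws are a time-mirrored shifted log-normal
with mode near the end of expansion, left-shifted multiplicatively with
contrast, truncated to [-960, +100] ms; auditory-only draws are a scaled
Beta on [4, 17] ms plus a distance-to-speaker latency (+4 ms per 30 cm),
clipped to the observed 4-21 ms support; multisensory C-starts are locked
into the MSI window with weight 0.85, otherwise drawn from the visual
distribution excluding a 45 ms LP gap.  Positions follow the observed
thigmotaxis (distance-to-center ~ Normal(29.4, 4.8) cm); the optional
distance-to-loom covariate on response probability is off by default.

`recover_parameters` fits binomial GLMs of C-start on level and prior state
per modality, returning model-based per-level probabilities with standard
errors, slope CIs, a freezing probability ratio, empirical per-level
proportions, and a separation flag.  Because the configured freezing effect
is multiplicative in probability (not a logit shift), the unbiased estimate
of it is the empirical pooled rate ratio, which is also returned.  Recovery
validation uses a configuration with habituation off and no freezing, so the
per-level truth is exactly the configured logistic curve; note that the
logistic MLE carries a small rare-event bias at the lowest-probability level
(fractions of a standard error at the default sizes).

**What passing tests do and do not show.**  The generator reproduces the
study's marginal and conditional response *statistics*, not fish: there is
no animal identity beyond an exchangeable label, no within-animal
correlation other than the shared trial-index decay, no kinematics, and the
response-time families are smooth idealizations of the published densities.
Tests passing on these tables demonstrate that the analysis stack is
correct and well-calibrated, not that real data would satisfy its
assumptions.

## Pipeline, problem sizes and determinism (`mauthner.pipeline`)

The driver runs calibration (2000 evaluations per bisection step), the six
plus six unisensory conditions and the 36-combination grid at 200 trials per
condition, fits windows and IC matrices, and sweeps the six audiovisual
delays (-40 to -460 ms) at 100 trials per delay using the midpoint of the
calibrated level-3/4 intensities as the mid-salience condition (the
published sweep used MI 0.16 and 149 dB, both between the printed levels 3
and 4).  These are the study's own problem sizes; the full pipeline takes
well under a minute on one CPU.  All stage seeds are spawned from a single
`SeedSequence`, so identical configurations give byte-identical CSVs, and
every output row carries the configuration hash and seed.

## Known limitations

* Single compartment, one cell: no dendritic filtering, no left/right
  Mauthner pair, no spinal circuitry, no non-Mauthner escape pathways.
* The quasi-static visual response (membrane tracks the ramp) concentrates
  visual-only spikes at or before the ramp peak; behavioral UV responses
  extending ~80 ms past the end of expansion have no model counterpart to
  the right of the peak.
* Absolute currents are meaningful only relative to `R_in`; only the
  products (nA x MOhm) are constrained.
* The printed intensity bounds cannot quite reach the extreme behavioral
  probabilities under the anchored scale (see calibration above).
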