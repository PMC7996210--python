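# Methods

## Model and assumptions

The simulator couples three components: a memristive synapse model, a leaky
integrate-and-fire (LIF) output layer with winner-take-all (WTA) lateral
inhibition, and a simplified spike-timing-dependent plasticity (STDP) rule
with homeostatic threshold adaptation.

### Device model

Each synapse stores a continuous normalized conductance in
`[g_min, g_max]`. Potentiation and depression follow exponential
pulse-response curves parameterised per branch by a non-linearity factor ν
(see README for the formulas); β scales the LTP exponent only, so in the
linear limit one LTP pulse moves the weight β times as far as one LTD
pulse. Design choices where the device literature leaves room:

- **State variable.** The internal state is the continuous conductance, not
  an integer pulse counter. A pulse inverts the branch curve at the current
  weight, advances the continuous index by one, and re-evaluates. This is
  the only representation that stays well-defined when LTP and LTD curves
  have different shapes and the weight alternates between them; the device
  resolution (256 states) enters as the step granularity, not as a
  quantisation of the stored weight.
- **LTD traversal direction.** The depression branch is parameterised with
  `p = P` at `g_max`, so depression decrements the index.
- **Linear limit.** α is 0/0 at ν = 0; for |ν| < 1e-6 the closed-form
  linear ramp is substituted. The exponential expression is written as an
  `expm1` ratio so the boundary identities (`w_LTP(0) = g_min`,
  `w_LTD(P) = g_max`, `w_LTD(0) = g_min`) hold exactly in floating point.
- **Saturation.** Curve values are clipped to the bounds and pulses applied
  at a bound return it unchanged; `apply_pulse` additionally enforces
  monotonicity against last-bit rounding.
- **Ratio profiling.** The single-pulse LTP/LTD magnitude ratio is only a
  property of the curves where neither pulse clips; `ratio_profile`
  therefore evaluates on the saturation-free band
  `[w_LTD(1), w_LTP(p_sat − 1)]`. On that band the ratio is exactly β for a
  linear device and constant in w for symmetric pairs (ν, −ν) — the
  constants for (10, −10) and (−10, 10) are
  `(1 − e^{−νβ/P})/(e^{ν/P} − 1) ≈ 3.631` and
  `(e^{νβ/P} − 1)/(1 − e^{−ν/P}) ≈ 4.415`; the weight dependence cancels
  algebraically, and both are "close to β = 4", which is why symmetric
  devices keep the network balanced.
- `fit_nonlinearity` estimates ν from measured (pulse, weight) staircases
  by scalar least squares (grid scan + bounded refinement); on noiseless
  model-generated data it recovers ν to ~1e-9 relative error, so measured
  devices can be placed on the sweep map.

Not modeled: device-to-device and cycle-to-cycle variability, conductance
drift/retention, compliance-current physics.

### Neuron and inhibition

Membrane potentials decay with the exact per-bin factor `exp(−dt/τ)`
(unconditionally stable; identical to the ODE solution between spikes)
rather than forward Euler. Refractory and inhibited neurons ignore input
entirely. The inhibitory partner neurons are modeled as instantaneous
relays: when a neuron fires, every other output is reset to rest and held
there for `t_inhibit` (the self-inhibition path is absent, i.e. the
effective inhibition matrix has zero diagonal). If several neurons cross
threshold in one bin, the largest supra-threshold margin wins, ties to the
lowest index — at most one winner per 1-ms bin, deterministic.

The neuron constants are configuration decisions (the governing equations
fix only their roles): τ = 100 ms, t_ref = 5 ms, t_inhibit = 10 ms,
threshold_init = 24 (in units of summed normalized weight) at full scale.
These are biologically plausible orders of magnitude in line with
WTA-digit-classification networks of this family, and all are exposed in
the config.

### Plasticity and homeostasis

On each post-synaptic spike, afferents with a pre spike at most 45 ms
earlier (boundary inclusive) receive one LTP pulse; **all other afferents
receive one LTD pulse**. The no-recent-pre-spike depression is what carves
the black background into trained features; pre-spike timing is tracked
within the current sample only. Nothing happens on pre spikes alone. All
weight changes go through the device model, so bounds and saturation shape
learning directly.

Homeostasis adapts thresholds every `homeo_interval` presentations by
`Δthreshold = (f_actual − f_target)·threshold·γ`, with `f_actual` counted
per adjustment window. Thresholds are floored at `1e-6 · threshold_init`
to prevent sign flips under aggressive γ. Note the update is
multiplicative: a silent neuron's threshold decays by the factor
`(1 − f_target·γ)` per window, so `f_target·γ` must stay well below 1 for
the adaptation to be stable — this constraint drives the desk-scale
calibration below.

## Scales, defaults, and calibration

Full scale mirrors the standard MNIST setup: 28×28 images border-cropped
to 24×24 (576 inputs), 300 output neurons, 180,000 presentations
(3 shuffled epochs of the 60,000-sample training set), evaluation every
10,000 presentations with the final score the mean of the last 10
evaluations, homeostasis every 600 samples. These runs need the external
IDX files and hours of CPU.

The desk scale exercises every code path in minutes: 12×12 synthetic
stroke patterns (3 classes: bars and diagonals, pixel values 0/255, each
pixel flipped with probability 0.1), 30 output neurons, 3,000
presentations, evaluation every 300 (so the final score is again a mean of
10 evaluations over 100 labeled + 100 test samples). Scaled-down
constants: threshold_init = 10 (the input sum is ~4× smaller than at full
scale), homeostasis window 25 samples with f_target = 10, γ = 0.001.

The homeostasis rate was calibrated on the linear device so that the whole
0.5×–4× γ band used by the homeostasis sweep remains stable:
`f_target·γ ≤ 0.04` per window even at 4×. With a faster base rate the 4×
condition collapses silent neurons' thresholds (40% per window), producing
bursts that are an artifact of the discrete window update rather than a
property of the device under study.

### What the synthetic generator does and does not emulate

The generator produces class-balanced, near-orthogonal binary prototypes
with independent per-pixel flip noise. Like handwritten digits, classes
are linearly separable pixel patterns with background clutter; unlike
digits there is no within-class shape variability, no correlated noise,
and far fewer classes, so desk-scale accuracies are much higher than
digit-task accuracies at the same network size. Passing desk-scale checks
demonstrates that the learning dynamics (feature specialisation, weight
bimodality, edge-sticking, homeostasis response) behave correctly, not
that any particular digit-task accuracy would be reached.

## Experiment analyses

- **Weight histograms** report the distribution over `[g_min, g_max]` and
  the "edge mass" within 1% of each bound. A trained linear device shows
  the characteristic U-shape; a (−10,−10) device (weak LTP and LTD near
  the bounds) traps essentially all weights at the edges; a (10,10) device
  keeps weights mobile and mid-range.
- **Firing diagnostics** record the total spike count per presentation and
  a histogram of per-neuron firing counts within one presentation
  ("burst" sizes). The excessive-firing tail is summarised as the number
  of events with ≥16 spikes — roughly twice the typical winner count —
  and decreases as γ grows for the strong-LTP/weak-LTD device (10,−10).
- **Sweeps** train one independent network per cell from the identical
  seed stream, so cells differ only in the swept parameter. The default
  non-linearity grid is ν ∈ {−10, −8, …, 10} on both axes (121 cells);
  reduced grids are supported for desk-scale work.

## Determinism

All randomness derives from a single master seed through
`numpy.random.SeedSequence` spawning (initial weights, epoch shuffles,
per-presentation encodings, evaluation passes). Identical config + seed
reproduce bit-identical weights, logs, and artifacts; checkpoints are
written with fixed zip timestamps so files are byte-identical too.

## Known limitations

- The inhibitory layer is a functional relay; inhibitory membrane dynamics
  and inhibition strength are not modeled (suppression is reset-and-hold).
- Only the simplified fixed-Δw STDP rule is implemented; exponential
  biological kernels and triplet rules are out of scope.
- The Bernoulli-per-bin Poisson approximation slightly under-disperses at
  the highest rate (0.022 spikes/bin), a negligible effect at these rates.
- Desk-scale results are qualitative transfers of the full-scale
  phenomenology, not quantitative predictions for digit tasks.
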