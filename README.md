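# memsnn

Simulation of unsupervised spiking neural networks whose synapses are
memristive devices with non-linear, state-dependent conductance updates.

Emerging resistive-switching devices are attractive hardware synapses —
their conductance directly stores a weight and changes under voltage
pulses — but real devices update non-linearly: the weight change produced
by one pulse depends on the current weight. `memsnn` is for researchers in
neuromorphic engineering and computational neuroscience who want to ask,
*before* fabricating hardware: how much device non-linearity can an
unsupervised spiking network tolerate, and which network parameters
(LTP/LTD asymmetry, homeostasis rate) restore the balance when the device
is imperfect?

## Model

**Synapse (device model).** A normalized conductance `g ∈ [g_min, g_max]`
follows branch-specific pulse-response curves with non-linearity factors
ν and asymmetry β (pulse index `p ∈ [0, P]`, resolution `P = 256` states):

```
w_LTP(p) = α (1 − e^{−ν_LTP β p / P}) + g_min
w_LTD(p) = g_max − α (1 − e^{−ν_LTD (1 − p/P)})        α = (g_max − g_min)/(1 − e^{−ν})
```

ν = 0 is the linear limit (fixed Δw per pulse); ν > 0 updates fast then
saturates; ν < 0 starts slow. One programming pulse inverts the curve at
the current weight, advances the continuous pulse index by ±1, and
re-evaluates — so Δw is a function of the current weight, as measured on
real devices.

**Neuron.** Leaky integrate-and-fire:
`τ dU_j/dt = −U_j + Σ_i w_ji n_i(t)`, threshold crossing fires, resets to
rest, refractory `t_ref`. Each output neuron drives an inhibitory partner
projecting to all other outputs (winner-take-all lateral inhibition).

**Input.** Pixels become Poisson spike trains at
`f(Hz) = 1 / (A − B·pixel/255)` with `A = 41/20`, `B = 2.004545`
(≈0.49 Hz black, ≈22 Hz white), presented for 500 ms at a 1 ms clock.

**Learning.** Simplified STDP: when a neuron fires, afferents with a pre
spike in the last 45 ms get one LTP pulse, all others one LTD pulse.
Homeostasis adapts thresholds every `homeo_interval` samples:
`Δthreshold = (f_actual − f_target) · threshold · γ`.

**Readout.** Neurons are labeled by frozen-plasticity voting on labeled
samples; accuracy is the fraction of test samples whose winning neuron
carries the right label.

## Worked example

Train a small network on the built-in synthetic stroke patterns (3 classes
of noisy 12×12 bar/diagonal images, 30 output neurons, 3000 presentations):

```python
from memsnn import desk_scale_config, make_desk_datasets, train, weight_histogram

train_set, eval_set = make_desk_datasets(master_seed=1)
result = train(train_set, desk_scale_config(master_seed=1), eval_dataset=eval_set)
print(f"final accuracy: {result.final_accuracy:.1f}%")
hist = weight_histogram(result.network.weights)
print(f"edge mass: {hist.edge_frac_low:.2f} low / {hist.edge_frac_high:.2f} high")
```

```
final accuracy: 95.6%
edge mass: 0.53 low / 0.14 high
```

The unsupervised network reaches 95.6% on a 3-class task (chance 33.3%):
neurons specialise on the class prototypes. Two thirds of the trained
weights sit within 1% of a conductance bound — the characteristic U-shaped
(bimodal) weight distribution of a linear device, where pattern pixels
saturate high and background pixels saturate low.

The same study from the shell:

```
memsnn show-defaults
memsnn train --set train.n_exc=30 --set lif.threshold_init=10 --seed 1 --output runs/demo
memsnn sweep --nu "-10,0,10" --seed 1 --output runs/sweep
memsnn device-profile --nu-ltp 10 --nu-ltd -10 --out profile.csv
```

Device behaviour worth knowing, all computable with `ratio_profile`:
a linear device with β = 4 has an LTP/LTD step-ratio of exactly 4 at every
weight; symmetric pairs (ν, −ν) keep the ratio constant in w (≈3.63 for
(10,−10), ≈4.41 for (−10,10) — both close to β); same-signed pairs have a
ratio that varies by orders of magnitude across the weight range, which is
what destabilises learning.

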