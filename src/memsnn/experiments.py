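"""Training, label assignment, evaluation, and parameter sweeps.

The network learns without supervision: inputs are presented as Poisson
rasters, simplified STDP shapes the synaptic conductances on every output
spike, and homeostasis keeps firing spread over the population.  Because the
features are learned unlabeled, classification is scored in two passes:

1. *Label assignment* — with plasticity frozen, labeled samples are
   presented; each neuron is assigned the class it "wins" most often (the
   winner of a sample is the neuron with the most output spikes).
2. *Evaluation* — test samples are presented and the winner's assigned
   label is the prediction; samples with no winner (or an unassigned
   winner) count as errors.

Sweeps train an independent network per device-parameter cell — the
(nu_ltp, nu_ltd) non-linearity grid, or a range of homeostasis rates gamma —
with identical seed streams so cells differ only in the swept parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .device import DeviceParams, SynapseArray
from .encoding import EncoderParams, ImageSample, generate_synthetic_patterns, poisson_encode
from .errors import RangeError
from .network import LIFParams, NeuronState, Topology, run_sample
from .plasticity import PlasticityParams, homeostasis_update, stdp_on_post_spike

__all__ = [
    "UNASSIGNED",
    "TrainConfig",
    "TrainedNetwork",
    "TrainResult",
    "SweepResult",
    "GammaSweepResult",
    "WeightHistogram",
    "train",
    "assign_labels",
    "evaluate",
    "default_nu_grid",
    "sweep_grid",
    "sweep_nonlinearity",
    "sweep_gamma",
    "weight_histogram",
    "firing_tail",
    "burst_tail_events",
    "desk_scale_config",
    "make_desk_datasets",
]

#: Sentinel class label for neurons that never win a sample.
UNASSIGNED = -1

_SEED_MAX = 2**31  # children seeds stay below 2**31


@dataclass(frozen=True)
class TrainConfig:
    """Everything needed to train and evaluate one network."""

    device: DeviceParams
    lif: LIFParams
    plasticity: PlasticityParams
    encoder: EncoderParams
    topology: Topology
    n_train_presentations: int = 180_000
    eval_interval: int = 10_000
    label_set_size: int = 1000
    eval_set_size: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_presentations < 1:
            raise ValueError("n_train_presentations must be >= 1")
        if self.eval_interval < 1:
            raise ValueError("eval_interval must be >= 1")


@dataclass
class TrainedNetwork:
    """Frozen snapshot of a trained network, sufficient for inference."""

    weights: SynapseArray
    thresholds: np.ndarray
    lif: LIFParams
    encoder: EncoderParams


@dataclass
class TrainResult:
    network: TrainedNetwork
    state: NeuronState
    labels: np.ndarray
    accuracy_history: list[tuple[int, float]]
    final_accuracy: Optional[float]
    spikes_per_sample: np.ndarray
    #: firing_count_hist[k] = number of (neuron, sample) events in which one
    #: neuron fired exactly k times during one presentation (k capped at the
    #: array length); the histogram behind the excessive-firing diagnostics.
    firing_count_hist: np.ndarray
    homeo_log: pd.DataFrame


def _frozen_state(network: TrainedNetwork) -> NeuronState:
    st = NeuronState.initial(network.weights.n_outputs, network.lif)
    st.threshold[:] = network.thresholds
    return st


def train(
    dataset: Sequence[ImageSample],
    config: TrainConfig,
    eval_dataset: Optional[Sequence[ImageSample]] = None,
) -> TrainResult:
    """Run the unsupervised training loop.

    Initial conductances are uniform random over ``[g_min, g_max]``.  The
    dataset is presented in shuffled epochs until ``n_train_presentations``
    is reached; every output spike triggers one simplified-STDP update, and
    thresholds adapt every ``homeo_interval`` presentations.  When
    ``eval_dataset`` is given, a frozen label-assignment/evaluation pass
    runs every ``eval_interval`` presentations and the final score is the
    mean of the last (up to) 10 evaluations.  All randomness derives from
    ``config.master_seed``, so identical inputs reproduce bit-identical
    weights and logs.
    """
    samples = list(dataset)
    if not samples:
        raise ValueError("training dataset is empty")
    n_inputs = samples[0].pixels.size
    if n_inputs != config.topology.n_inputs:
        raise ValueError(
            f"samples have {n_inputs} pixels but topology expects {config.topology.n_inputs}"
        )
    ss = np.random.SeedSequence(config.master_seed)
    s_init, s_shuffle, s_encode, s_eval = ss.spawn(4)
    rng_init = np.random.default_rng(s_init)
    rng_shuffle = np.random.default_rng(s_shuffle)
    rng_encode = np.random.default_rng(s_encode)
    rng_eval = np.random.default_rng(s_eval)

    weights = SynapseArray.random_uniform(
        n_inputs, config.topology.n_exc, config.device, rng_init
    )
    state = NeuronState.initial(config.topology.n_exc, config.lif)
    W = weights.weights
    device, pp = config.device, config.plasticity

    def on_post(j: int, t_ms: float, last_pre: np.ndarray) -> None:
        W[:, j] = stdp_on_post_spike(t_ms, last_pre, W[:, j], device, pp)

    n_pres = config.n_train_presentations
    order: list[int] = []
    while len(order) < n_pres:
        order.extend(rng_shuffle.permutation(len(samples)).tolist())
    order = order[:n_pres]

    label_subset = samples[: config.label_set_size]
    eval_subset = list(eval_dataset)[: config.eval_set_size] if eval_dataset else None

    spikes_per_sample = np.zeros(n_pres, dtype=np.int64)
    firing_count_hist = np.zeros(201, dtype=np.int64)
    homeo_rows: list[dict] = []
    accuracy_history: list[tuple[int, float]] = []

    for i, idx in enumerate(order):
        raster = poisson_encode(
            samples[idx], config.encoder, int(rng_encode.integers(_SEED_MAX))
        )
        counts, _ = run_sample(raster, state, weights, config.lif, on_post_spike=on_post)
        spikes_per_sample[i] = counts.sum()
        fired = np.minimum(counts[counts > 0], firing_count_hist.size - 1)
        if fired.size:
            firing_count_hist += np.bincount(fired, minlength=firing_count_hist.size)
        if (i + 1) % pp.homeo_interval == 0:
            f_actual = state.fire_count_window.copy()
            before = state.threshold.copy()
            homeostasis_update(state, pp)
            for n in range(state.n_exc):
                homeo_rows.append(
                    {
                        "presentation": i + 1,
                        "neuron": n,
                        "f_actual": int(f_actual[n]),
                        "threshold_before": before[n],
                        "threshold_after": state.threshold[n],
                    }
                )
        if eval_subset is not None and (i + 1) % config.eval_interval == 0:
            net = TrainedNetwork(
                weights=weights,
                thresholds=state.threshold.copy(),
                lif=config.lif,
                encoder=config.encoder,
            )
            labels = assign_labels(net, label_subset, seed=int(rng_eval.integers(_SEED_MAX)))
            acc = evaluate(net, labels, eval_subset, seed=int(rng_eval.integers(_SEED_MAX)))
            accuracy_history.append((i + 1, acc))

    network = TrainedNetwork(
        weights=weights,
        thresholds=state.threshold.copy(),
        lif=config.lif,
        encoder=config.encoder,
    )
    labels = assign_labels(network, label_subset, seed=int(rng_eval.integers(_SEED_MAX)))
    final_accuracy = (
        float(np.mean([a for _, a in accuracy_history[-10:]])) if accuracy_history else None
    )
    return TrainResult(
        network=network,
        state=state,
        labels=labels,
        accuracy_history=accuracy_history,
        final_accuracy=final_accuracy,
        spikes_per_sample=spikes_per_sample,
        firing_count_hist=firing_count_hist,
        homeo_log=pd.DataFrame(homeo_rows),
    )


def _winner(counts: np.ndarray) -> Optional[int]:
    """Neuron with the most spikes for a sample; None if nothing fired.

    Ties go to the lowest index (argmax convention).
    """
    if counts.max() <= 0:
        return None
    return int(np.argmax(counts))


def assign_labels(
    network: TrainedNetwork, labeled_samples: Sequence[ImageSample], seed: int = 0
) -> np.ndarray:
    """Assign a class label to every output neuron by frozen-plasticity voting.

    Each labeled sample is presented without learning; the winning neuron
    accumulates a vote for the sample's class.  A neuron's label is its
    most-voted class (ties to the lowest class id); neurons that never win
    get :data:`UNASSIGNED`.
    """
    samples = list(labeled_samples)
    if any(s.label is None for s in samples):
        raise ValueError("all samples must be labeled for assignment")
    n_classes = max(s.label for s in samples) + 1
    wins = np.zeros((network.weights.n_outputs, n_classes), dtype=np.int64)
    rng = np.random.default_rng(seed)
    state = _frozen_state(network)
    for s in samples:
        raster = poisson_encode(s, network.encoder, int(rng.integers(_SEED_MAX)))
        counts, _ = run_sample(raster, state, network.weights, network.lif)
        w = _winner(counts)
        if w is not None:
            wins[w, s.label] += 1
    labels = np.full(network.weights.n_outputs, UNASSIGNED, dtype=np.int64)
    won = wins.sum(axis=1) > 0
    labels[won] = np.argmax(wins[won], axis=1)
    return labels


def evaluate(
    network: TrainedNetwork,
    neuron_labels: np.ndarray,
    test_samples: Sequence[ImageSample],
    seed: int = 0,
) -> float:
    """Classification accuracy (%) of the frozen network on labeled samples.

    A sample is correct when its winning neuron carries the sample's label;
    samples that elicit no spikes, or whose winner is unassigned, count as
    errors.
    """
    samples = list(test_samples)
    if not samples:
        raise ValueError("test set is empty")
    rng = np.random.default_rng(seed)
    state = _frozen_state(network)
    correct = 0
    for s in samples:
        raster = poisson_encode(s, network.encoder, int(rng.integers(_SEED_MAX)))
        counts, _ = run_sample(raster, state, network.weights, network.lif)
        w = _winner(counts)
        if w is not None and neuron_labels[w] != UNASSIGNED and neuron_labels[w] == s.label:
            correct += 1
    return 100.0 * correct / len(samples)


def default_nu_grid() -> np.ndarray:
    """The standard non-linearity sweep values: -10 to 10 in steps of 2."""
    return np.arange(-10.0, 10.0 + 1e-9, 2.0)


def sweep_grid(nu_values: Optional[Sequence[float]] = None) -> list[tuple[float, float]]:
    """All (nu_ltp, nu_ltd) cells of a sweep; 11 x 11 = 121 cells by default."""
    vals = default_nu_grid() if nu_values is None else np.asarray(nu_values, dtype=float)
    if vals.size == 0:
        raise ValueError("nu grid is empty")
    return [(float(l), float(d)) for l in vals for d in vals]


@dataclass
class CellDiagnostics:
    spikes_per_sample: np.ndarray
    histogram: "WeightHistogram"
    final_thresholds: np.ndarray


@dataclass
class SweepResult:
    """Accuracy grid over (nu_ltp, nu_ltd) plus per-cell diagnostics."""

    table: pd.DataFrame  # columns: nu_ltp, nu_ltd, accuracy
    diagnostics: dict[tuple[float, float], CellDiagnostics]


def sweep_nonlinearity(
    base_config: TrainConfig,
    train_set: Sequence[ImageSample],
    eval_set: Sequence[ImageSample],
    nu_values: Optional[Sequence[float]] = None,
) -> SweepResult:
    """Train one independent network per (nu_ltp, nu_ltd) cell.

    Every cell uses ``base_config`` with only the device non-linearity
    factors replaced, and the identical master seed, so differences between
    cells are attributable to the device alone.
    """
    rows = []
    diagnostics: dict[tuple[float, float], CellDiagnostics] = {}
    for nu_ltp, nu_ltd in sweep_grid(nu_values):
        cfg = replace(
            base_config,
            device=replace(base_config.device, nu_ltp=nu_ltp, nu_ltd=nu_ltd),
        )
        res = train(train_set, cfg, eval_dataset=eval_set)
        rows.append({"nu_ltp": nu_ltp, "nu_ltd": nu_ltd, "accuracy": res.final_accuracy})
        diagnostics[(nu_ltp, nu_ltd)] = CellDiagnostics(
            spikes_per_sample=res.spikes_per_sample,
            histogram=weight_histogram(res.network.weights),
            final_thresholds=res.network.thresholds.copy(),
        )
    return SweepResult(table=pd.DataFrame(rows), diagnostics=diagnostics)


@dataclass
class GammaSweepResult:
    """Accuracy and firing statistics across homeostasis rates."""

    # columns: multiplier, gamma, accuracy, firing_tail, burst_events
    table: pd.DataFrame
    spikes_per_sample: dict[float, np.ndarray]
    firing_count_hist: dict[float, np.ndarray]
    final_thresholds: dict[float, np.ndarray]


def firing_tail(spikes_per_sample: np.ndarray, quantile: float = 0.9) -> float:
    """Mean per-sample firing count over the upper tail (default top decile).

    Summarises the excessive-firing behaviour: bursting networks have a few
    samples with very high total spike counts, which inflate this statistic.
    """
    s = np.sort(np.asarray(spikes_per_sample, dtype=float))
    k = max(1, int(round((1.0 - quantile) * s.size)))
    return float(s[-k:].mean())


def burst_tail_events(firing_count_hist: np.ndarray, min_spikes: int = 16) -> int:
    """Number of excessive-firing events in a per-sample firing-count histogram.

    An event is one neuron's spike count within one presentation; events
    with at least ``min_spikes`` spikes (well above the typical winner
    count) form the excessive-firing tail that homeostasis is meant to
    suppress.
    """
    return int(np.asarray(firing_count_hist)[min_spikes:].sum())


def sweep_gamma(
    base_config: TrainConfig,
    train_set: Sequence[ImageSample],
    eval_set: Sequence[ImageSample],
    gamma_multipliers: Sequence[float],
    device_nu: tuple[float, float] = (10.0, -10.0),
) -> GammaSweepResult:
    """Train per homeostasis rate for a strong-LTP/weak-LTD device.

    ``device_nu`` defaults to (10, -10) — the symmetric pair whose strong
    potentiation and weak depression provoke excessive firing, the regime
    where the homeostasis rate matters most.
    """
    if any(m <= 0 for m in gamma_multipliers):
        raise ValueError("gamma multipliers must be positive")
    base_gamma = base_config.plasticity.homeo_gamma
    rows = []
    spikes: dict[float, np.ndarray] = {}
    hists: dict[float, np.ndarray] = {}
    thresholds: dict[float, np.ndarray] = {}
    for m in gamma_multipliers:
        cfg = replace(
            base_config,
            device=replace(
                base_config.device, nu_ltp=device_nu[0], nu_ltd=device_nu[1]
            ),
            plasticity=replace(base_config.plasticity, homeo_gamma=base_gamma * m),
        )
        res = train(train_set, cfg, eval_dataset=eval_set)
        rows.append(
            {
                "multiplier": m,
                "gamma": base_gamma * m,
                "accuracy": res.final_accuracy,
                "firing_tail": firing_tail(res.spikes_per_sample),
                "burst_events": burst_tail_events(res.firing_count_hist),
            }
        )
        spikes[m] = res.spikes_per_sample
        hists[m] = res.firing_count_hist
        thresholds[m] = res.network.thresholds.copy()
    return GammaSweepResult(
        table=pd.DataFrame(rows),
        spikes_per_sample=spikes,
        firing_count_hist=hists,
        final_thresholds=thresholds,
    )


@dataclass
class WeightHistogram:
    """Weight distribution summary over the conductance range."""

    counts: np.ndarray
    bin_edges: np.ndarray
    edge_frac_low: float  # fraction of weights within 1% of g_min
    edge_frac_high: float  # fraction of weights within 1% of g_max

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def weight_histogram(weights: SynapseArray, n_bins: int = 50) -> WeightHistogram:
    """Histogram of synaptic conductances over ``[g_min, g_max]``.

    ``edge_frac_low``/``edge_frac_high`` report the fraction of weights
    within 1% of each bound — the "stuck at the edge" mass that
    distinguishes weak-plasticity devices from strong ones.
    """
    dev = weights.device
    flat = weights.weights.ravel()
    if np.any(flat < dev.g_min) or np.any(flat > dev.g_max):
        raise RangeError("weights outside device bounds")
    counts, edges = np.histogram(flat, bins=n_bins, range=(dev.g_min, dev.g_max))
    margin = 0.01 * dev.g_range
    return WeightHistogram(
        counts=counts,
        bin_edges=edges,
        edge_frac_low=float(np.mean(flat <= dev.g_min + margin)),
        edge_frac_high=float(np.mean(flat >= dev.g_max - margin)),
    )


def desk_scale_config(
    master_seed: int = 0,
    n_classes: int = 3,
    grid_size: int = 12,
    n_exc: int = 30,
    n_train_presentations: int = 3000,
    eval_interval: int = 300,
    nu_ltp: float = 0.0,
    nu_ltd: float = 0.0,
) -> TrainConfig:
    """Small-scale preset exercising every code path in minutes.

    Uses 12x12 synthetic stroke patterns (144 inputs), 30 output neurons and
    a few thousand presentations.  The initial threshold and homeostasis
    constants are scaled with the input count and run length (threshold 10
    instead of 24, adjustment every 25 samples instead of 600, gamma 0.001)
    so the firing regime matches the full-scale setup and the whole
    0.5x-4x gamma band remains stable: the per-window threshold decay for a
    silent neuron, homeo_target * gamma, stays well below 1 even at 4x.
    """
    return TrainConfig(
        device=DeviceParams(nu_ltp=nu_ltp, nu_ltd=nu_ltd),
        lif=LIFParams(threshold_init=10.0),
        plasticity=PlasticityParams(homeo_interval=25, homeo_target=10.0, homeo_gamma=0.001),
        encoder=EncoderParams(),
        topology=Topology(n_inputs=grid_size * grid_size, n_exc=n_exc),
        n_train_presentations=n_train_presentations,
        eval_interval=eval_interval,
        label_set_size=100,
        eval_set_size=100,
        master_seed=master_seed,
    )


def make_desk_datasets(
    master_seed: int = 0,
    n_classes: int = 3,
    grid_size: int = 12,
    n_train: int = 900,
    n_eval: int = 150,
    flip_noise: float = 0.1,
) -> tuple[list[ImageSample], list[ImageSample]]:
    """Synthetic train/eval splits matching :func:`desk_scale_config`."""
    s_train, s_eval = np.random.SeedSequence(master_seed).spawn(2)
    train_set = generate_synthetic_patterns(n_classes, grid_size, n_train, flip_noise, s_train)
    eval_set = generate_synthetic_patterns(n_classes, grid_size, n_eval, flip_noise, s_eval)
    return train_set, eval_set
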