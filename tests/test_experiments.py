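"""Training loop, labeling, evaluation, sweeps and histograms (tiny scale)."""

from dataclasses import replace

import numpy as np
import pytest

from memsnn import (
    UNASSIGNED,
    DeviceParams,
    EncoderParams,
    LIFParams,
    PlasticityParams,
    SynapseArray,
    Topology,
    TrainConfig,
    TrainedNetwork,
    assign_labels,
    default_nu_grid,
    desk_scale_config,
    evaluate,
    firing_tail,
    make_desk_datasets,
    sweep_grid,
    sweep_nonlinearity,
    train,
    weight_histogram,
)
from memsnn.encoding import prototype_images


@pytest.fixture(scope="module")
def tiny_data():
    return make_desk_datasets(master_seed=3, n_train=90, n_eval=30)


def tiny_config(seed=3, **kw):
    defaults = dict(n_train_presentations=120, eval_interval=60)
    defaults.update(kw)
    cfg = desk_scale_config(master_seed=seed, **defaults)
    return replace(cfg, label_set_size=30, eval_set_size=30)


@pytest.fixture(scope="module")
def tiny_run(tiny_data):
    train_set, eval_set = tiny_data
    return train(train_set, tiny_config(), eval_dataset=eval_set)


class TestTrain:
    def test_logs_and_shapes(self, tiny_run):
        assert len(tiny_run.accuracy_history) == 2
        assert all(0 <= a <= 100 for _, a in tiny_run.accuracy_history)
        assert tiny_run.spikes_per_sample.shape == (120,)
        assert tiny_run.network.weights.weights.shape == (144, 30)
        assert tiny_run.firing_count_hist.sum() > 0

    def test_weights_stay_in_bounds(self, tiny_run):
        w = tiny_run.network.weights.weights
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_deterministic_given_seed(self, tiny_data):
        train_set, eval_set = tiny_data
        a = train(train_set, tiny_config(), eval_dataset=eval_set)
        b = train(train_set, tiny_config(), eval_dataset=eval_set)
        assert np.array_equal(a.network.weights.weights, b.network.weights.weights)
        assert a.accuracy_history == b.accuracy_history
        assert np.array_equal(a.spikes_per_sample, b.spikes_per_sample)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], tiny_config())

    def test_homeostasis_log_records_thresholds(self, tiny_run):
        log = tiny_run.homeo_log
        assert set(log.columns) >= {"presentation", "neuron", "f_actual",
                                    "threshold_before", "threshold_after"}
        assert (log.threshold_after > 0).all()


def hand_built_network():
    """Two neurons, each tuned to one 2-class prototype."""
    protos = prototype_images(2, 12)
    device = DeviceParams(0.0, 0.0)
    w = np.full((144, 2), 0.05)
    for j, p in enumerate(protos):
        w[p.pixels.reshape(-1) > 0, j] = 1.0
    return TrainedNetwork(
        weights=SynapseArray(w, device),
        thresholds=np.full(2, 10.0),
        lif=LIFParams(threshold_init=10.0),
        encoder=EncoderParams(),
    )


class TestLabelingAndEvaluation:
    def test_orthogonal_network_labels_match_classes(self):
        net = hand_built_network()
        samples = [s for s in prototype_images(2, 12) for _ in range(5)]
        labels = assign_labels(net, samples, seed=0)
        assert list(labels) == [0, 1]

    def test_orthogonal_network_classifies_noisy_samples(self):
        net = hand_built_network()
        from memsnn import generate_synthetic_patterns

        test = generate_synthetic_patterns(2, 12, 40, 0.05, seed=9)
        labels = assign_labels(net, test[:20], seed=1)
        acc = evaluate(net, labels, test[20:], seed=2)
        assert acc == 100.0

    def test_never_winning_neuron_unassigned(self):
        net = hand_built_network()
        net.thresholds = np.array([10.0, 1e9])  # neuron 1 can never fire
        samples = [s for s in prototype_images(2, 12) for _ in range(3)]
        labels = assign_labels(net, samples, seed=0)
        assert labels[1] == UNASSIGNED

    def test_permuted_labels_score_worse(self):
        net = hand_built_network()
        from memsnn import generate_synthetic_patterns

        test = generate_synthetic_patterns(2, 12, 30, 0.05, seed=4)
        labels = assign_labels(net, test, seed=0)
        acc = evaluate(net, labels, test, seed=5)
        acc_perm = evaluate(net, labels[::-1].copy(), test, seed=5)
        assert acc_perm < acc

    def test_unlabeled_samples_rejected(self):
        net = hand_built_network()
        from memsnn import ImageSample

        with pytest.raises(ValueError):
            assign_labels(net, [ImageSample(pixels=np.zeros((12, 12)))], seed=0)


class TestSweeps:
    def test_default_grid_has_121_cells(self):
        assert len(sweep_grid()) == 121
        assert len(default_nu_grid()) == 11

    def test_reduced_grid(self):
        cells = sweep_grid([-10.0, 0.0, 10.0])
        assert len(cells) == 9

    def test_zero_cell_matches_standalone_run(self, tiny_data):
        """The (0,0) sweep cell is bit-identical to a standalone linear run."""
        train_set, eval_set = tiny_data
        cfg = tiny_config()
        res = sweep_nonlinearity(cfg, train_set, eval_set, nu_values=[0.0])
        standalone = train(train_set, cfg, eval_dataset=eval_set)
        row = res.table.iloc[0]
        assert row.accuracy == standalone.final_accuracy
        cell = res.diagnostics[(0.0, 0.0)]
        assert np.array_equal(cell.spikes_per_sample, standalone.spikes_per_sample)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_grid([])

    def test_firing_tail_of_constant_counts(self):
        assert firing_tail(np.full(100, 7), 0.9) == 7.0


class TestWeightHistogram:
    def test_counts_conserved_and_uniform_flat(self, rng):
        device = DeviceParams(0.0, 0.0)
        arr = SynapseArray.random_uniform(100, 50, device, rng)
        hist = weight_histogram(arr, n_bins=20)
        assert hist.total == 5000
        # uniform init: every bin within 5 sigma of the expected count
        expect = 5000 / 20
        assert np.all(np.abs(hist.counts - expect) < 5 * np.sqrt(expect))
        assert hist.edge_frac_low < 0.05 and hist.edge_frac_high < 0.05

    def test_all_weights_at_gmax(self):
        device = DeviceParams(0.0, 0.0)
        arr = SynapseArray(np.ones((4, 4)), device)
        hist = weight_histogram(arr)
        assert hist.edge_frac_high == 1.0
        assert hist.edge_frac_low == 0.0


class TestConfigValidation:
    def test_bad_train_config_rejected(self):
        cfg = desk_scale_config()
        with pytest.raises(ValueError):
            replace(cfg, n_train_presentations=0)
        with pytest.raises(ValueError):
            replace(cfg, eval_interval=0)

    def test_topology_mismatch_rejected(self, tiny_data):
        train_set, _ = tiny_data
        cfg = replace(tiny_config(), topology=Topology(n_inputs=99, n_exc=30))
        with pytest.raises(ValueError):
            train(train_set, cfg)
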