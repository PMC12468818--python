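"""Training engine: splits, class weights, loss contract, early stopping."""

import numpy as np
import pandas as pd
import pytest

from painspeech.network import GRUMixerNet, ModelConfig
from painspeech.train import (
    ABLATION_NAMES,
    AdamOptimizer,
    EarlyStopper,
    TrainConfig,
    ablation_configs,
    class_weights,
    split_speaker_independent,
    train,
    weighted_cross_entropy,
)


def grid_corpus(n_speakers=10, clips_each=10):
    rows = []
    for s in range(n_speakers):
        for c in range(clips_each):
            rows.append(
                {
                    "clip_id": f"s{s}c{c}",
                    "speaker_id": f"s{s}",
                    "pain": "pain" if c % 2 else "non-pain",
                    "intensity": "mild" if c % 2 else "none",
                    "thermal": "cold" if c % 3 else "warm",
                    "duration": 2.0,
                    "path": f"{s}/{c}.wav",
                }
            )
    return pd.DataFrame(rows)


class TestSplit:
    def test_speakers_disjoint(self):
        corpus = grid_corpus()
        tr, te = split_speaker_independent(corpus, TrainConfig(seed=0))
        assert not set(corpus.iloc[tr]["speaker_id"]) & set(corpus.iloc[te]["speaker_id"])

    def test_exact_divisibility_case(self):
        corpus = grid_corpus(10, 10)
        tr, te = split_speaker_independent(corpus, TrainConfig(seed=0))
        assert len(tr) == 80 and len(te) == 20

    def test_deterministic(self):
        corpus = grid_corpus()
        a = split_speaker_independent(corpus, TrainConfig(seed=5))
        b = split_speaker_independent(corpus, TrainConfig(seed=5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_single_speaker_rejected(self):
        corpus = grid_corpus(1, 10)
        with pytest.raises(ValueError, match="2 speakers"):
            split_speaker_independent(corpus, TrainConfig(seed=0))

    def test_clip_stratified_sizes(self):
        corpus = grid_corpus(4, 10)
        cfg = TrainConfig(seed=0, split_mode="clip_stratified")
        tr, te = split_speaker_independent(corpus, cfg)
        assert len(tr) == 32 and len(te) == 8
        # stratification keeps the class balance on both sides
        assert (corpus.iloc[tr]["pain"] == "pain").sum() == 16


class TestClassWeights:
    def test_balanced_gives_ones(self):
        np.testing.assert_allclose(class_weights(np.array([0, 1, 0, 1]), 2), [1.0, 1.0])

    def test_inverse_frequency_formula(self):
        labels = np.array([0] * 300 + [1] * 100)
        np.testing.assert_allclose(class_weights(labels, 2), [2 / 3, 2.0])

    def test_weighted_counts_recover_total(self, rng):
        labels = rng.integers(0, 3, size=500)
        w = class_weights(labels, 3)
        counts = np.bincount(labels, minlength=3)
        assert w @ counts == pytest.approx(500.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no examples"):
            class_weights(np.array([0, 0, 0]), 2)


class TestWeightedCrossEntropy:
    def test_perfect_prediction(self):
        assert weighted_cross_entropy([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_binary(self):
        assert weighted_cross_entropy([0.5, 0.5], [0, 1]) == pytest.approx(np.log(2))

    def test_weight_linearity(self):
        base = weighted_cross_entropy([0.7, 0.3], [1, 0], [1.0, 1.0])
        double = weighted_cross_entropy([0.7, 0.3], [1, 0], [2.0, 1.0])
        assert double == pytest.approx(2 * base)

    def test_zero_probability_floored(self):
        loss = weighted_cross_entropy([0.0, 1.0], [1, 0])
        assert np.isfinite(loss)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            weighted_cross_entropy([0.9, 0.9], [1, 0])


class TestEarlyStopper:
    def test_plateau_sequence_stops_after_patience(self):
        """No-improvement plateau: 0.6, 0.7, 0.7, 0.7, 0.7 with patience 3
        stops at the fifth epoch, keeping the second epoch as best."""
        stopper = EarlyStopper(patience=3)
        outcomes = [stopper.update(i, v) for i, v in enumerate([0.6, 0.7, 0.7, 0.7, 0.7])]
        assert outcomes == [False, False, False, False, True]
        assert stopper.best_epoch == 1
        assert stopper.best == 0.7

    def test_disabled_never_stops(self):
        stopper = EarlyStopper(patience=1, enabled=False)
        assert not any(stopper.update(i, 0.5) for i in range(10))

    def test_equal_value_is_not_improvement(self):
        stopper = EarlyStopper(patience=2)
        stopper.update(0, 0.8)
        stopper.update(1, 0.8)
        assert stopper.stale == 1


def make_toy_problem(n=24, t=6, f=4, seed=0):
    """Linearly separable toy sequences: class shifts the mean level."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.standard_normal((n, t, f)) * 0.3 + y[:, None, None] * 1.5
    return X, y


class TestTrainLoop:
    def test_single_epoch_cap(self):
        X, y = make_toy_problem()
        cfg = ModelConfig(input_size=4, hidden_size=4, num_layers=1, n_classes=2, dropout_p=0.0)
        net = GRUMixerNet(cfg, seed=0)
        _, hist = train(net, X, y, X, y, TrainConfig(max_epochs=1, seed=0))
        assert len(hist.test_accuracy) == 1

    def test_returns_best_epoch_parameters(self):
        X, y = make_toy_problem()
        cfg = ModelConfig(input_size=4, hidden_size=4, num_layers=1, n_classes=2, dropout_p=0.0)
        net = GRUMixerNet(cfg, seed=0)
        net, hist = train(
            net, X, y, X, y,
            TrainConfig(max_epochs=8, learning_rate=1e-2, seed=0, use_early_stopping=False),
        )
        assert hist.best_test_accuracy == max(hist.test_accuracy)
        # restored parameters reproduce the best monitored accuracy
        logits = net.forward(X, training=False)
        acc = np.mean(np.argmax(logits, axis=1) == y)
        assert acc == pytest.approx(hist.best_test_accuracy)

    def test_deterministic_history(self):
        X, y = make_toy_problem()
        cfg = ModelConfig(input_size=4, hidden_size=4, num_layers=1, n_classes=2, dropout_p=0.5)
        h1 = train(GRUMixerNet(cfg, seed=0), X, y, X, y, TrainConfig(max_epochs=3, seed=0))[1]
        h2 = train(GRUMixerNet(cfg, seed=0), X, y, X, y, TrainConfig(max_epochs=3, seed=0))[1]
        assert h1.test_accuracy == h2.test_accuracy
        assert h1.train_loss == h2.train_loss

    def test_learns_separable_toy_problem(self):
        X, y = make_toy_problem(n=32)
        cfg = ModelConfig(input_size=4, hidden_size=8, num_layers=1, n_classes=2, dropout_p=0.0)
        net = GRUMixerNet(cfg, seed=0)
        _, hist = train(
            net, X, y, X, y,
            TrainConfig(max_epochs=15, learning_rate=1e-2, seed=0, use_early_stopping=False),
        )
        assert hist.best_test_accuracy >= 0.9

    def test_empty_sets_rejected(self):
        cfg = ModelConfig(input_size=4, hidden_size=4, num_layers=1, n_classes=2)
        with pytest.raises(ValueError):
            train(GRUMixerNet(cfg, 0), np.empty((0, 5, 4)), np.empty(0),
                  np.empty((0, 5, 4)), np.empty(0), TrainConfig())


class TestAdam:
    def test_minimizes_quadratic(self):
        p = [np.array([5.0])]
        opt = AdamOptimizer(p, learning_rate=0.1)
        for _ in range(500):
            opt.step([2 * p[0]])
        assert abs(p[0][0]) < 1e-3

    def test_coupled_weight_decay_shrinks_parameters(self):
        p = [np.array([1.0])]
        opt = AdamOptimizer(p, learning_rate=0.01, weight_decay=0.1)
        for _ in range(200):
            opt.step([np.zeros(1)])  # only decay acts
        assert 0 < p[0][0] < 1.0


class TestAblationConfigs:
    def test_six_named_configurations(self):
        configs = ablation_configs(TrainConfig(seed=3))
        assert [name for name, _ in configs] == list(ABLATION_NAMES)
        assert len(configs) == 6

    def test_flag_audit(self):
        configs = dict(ablation_configs(TrainConfig(seed=3)))
        full = configs["Full Model"]
        assert full.use_dropout and full.use_weight_decay and full.use_early_stopping
        no_es = configs["No Early Stopping"]
        # differs from the full model only in the stopping flag
        assert no_es.use_dropout and no_es.use_weight_decay and not no_es.use_early_stopping
        gru_only = configs["GRU Only"]
        assert not (gru_only.use_dropout or gru_only.use_weight_decay
                    or gru_only.use_early_stopping)

    def test_shared_protocol_constants(self):
        base = TrainConfig(seed=9, learning_rate=2e-4, batch_size=4)
        for _, cfg in ablation_configs(base):
            assert cfg.seed == 9
            assert cfg.learning_rate == 2e-4
            assert cfg.batch_size == 4
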