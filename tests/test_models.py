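"""Model contracts: shapes, ranges, determinism, gradient correctness,
training behaviour, prediction, and checkpoints."""

import numpy as np
import pytest

import eboxnet as eb
from eboxnet import _nn
from eboxnet.dataset import SequenceExample, build_dataset
from eboxnet.evaluation import roc_auc
from eboxnet.models import (
    ARCHITECTURES,
    HyperConfig,
    build_model,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)

TINY = dict(n_filters=3, filter_length=5, lstm_hidden=4, fc_hidden=4,
            lstm_pool=2, dropout_p=0.0, conv_warmup_steps=0)


def random_seqs(rng, n, length):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


def toy_motif_dataset(seed=0, n=20, length=101):
    rng = np.random.default_rng(seed)
    positives = []
    for i in range(n):
        s = list(random_seqs(rng, 1, length)[0])
        pos = rng.integers(0, length - 6)
        s[pos : pos + 6] = "CACGTG"
        positives.append(SequenceExample(sequence="".join(s), label=1,
                                         provenance=f"p{i}", name=f"p{i}"))
    data, _ = build_dataset(positives, seed=seed, split_fractions=(0.6, 0.2, 0.2))
    return data


class TestHyperConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            HyperConfig(architecture="transformer").validate()
        with pytest.raises(ValueError):
            HyperConfig(n_filters=0).validate()
        with pytest.raises(ValueError):
            HyperConfig(dropout_p=1.0).validate()
        with pytest.raises(ValueError):
            HyperConfig(architecture="cnn", pooling="none").validate()
        with pytest.raises(ValueError):
            HyperConfig(filter_length=400).validate(window_length=301)


class TestForwardContracts:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_outputs_are_probabilities(self, arch):
        cfg = HyperConfig(architecture=arch, seed=1, **TINY)
        net = build_model(cfg)
        rng = np.random.default_rng(0)
        X = net.encode(random_seqs(rng, 7, 40))
        p = _nn.sigmoid(net.logits(X))
        assert p.shape == (7,)
        assert ((p >= 0) & (p <= 1)).all()

    def test_filter_response_length_under_defaults(self):
        # 301-nt window, 24-nt filters: 278 response positions per filter
        cfg = HyperConfig(architecture="cnn_lstm", seed=0)
        net = build_model(cfg)
        rng = np.random.default_rng(1)
        X = net.encode(random_seqs(rng, 2, 301))
        assert net.conv_response(X).shape == (2, 301 - 24 + 1, 16)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_same_seed_same_initial_weights(self, arch):
        cfg = HyperConfig(architecture=arch, seed=11, **TINY)
        a, b = build_model(cfg), build_model(cfg)
        for k in a.params():
            assert np.array_equal(a.params()[k].value, b.params()[k].value)

    def test_conv_filters_shape(self):
        cfg = HyperConfig(architecture="cnn_lstm", seed=0)
        data = toy_motif_dataset()
        cfg = HyperConfig(architecture="cnn_lstm", max_epochs=1, patience=1,
                          seed=0, conv_warmup_steps=0)
        trained = train(build_model(cfg), data, cfg)
        assert trained.conv_filters.shape == (16, 4, 24)


class TestGradients:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_backward_matches_directional_finite_difference(self, arch):
        cfg = HyperConfig(architecture=arch, seed=2, **TINY)
        net = build_model(cfg)
        rng = np.random.default_rng(0)
        X = net.encode(random_seqs(rng, 6, 20))

        def loss():
            return float(net.logits(X).astype(np.float64).sum())

        net.logits(X, train=True, rng=None)
        net.backward(np.ones(6, dtype=np.float32))
        dir_rng = np.random.default_rng(5)
        for k, par in net.params().items():
            d = dir_rng.standard_normal(par.value.shape).astype(np.float32)
            analytic = float((par.grad * d).sum())
            eps = 1e-3
            par.value += eps * d
            lp = loss()
            par.value -= 2 * eps * d
            lm = loss()
            par.value += eps * d
            numeric = (lp - lm) / (2 * eps)
            # piecewise-linear nets: the difference quotient crosses
            # relu/max-pool kinks, so agreement is approximate
            assert analytic == pytest.approx(numeric, rel=0.05, abs=5e-3), k

    def test_single_step_decreases_batch_loss(self):
        cfg = HyperConfig(architecture="cnn", seed=3, learning_rate=1e-3, **TINY)
        net = build_model(cfg)
        rng = np.random.default_rng(1)
        X = net.encode(random_seqs(rng, 8, 30))
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=np.float32)

        def batch_loss():
            z = net.logits(X)
            return float(np.mean(np.logaddexp(0.0, z) - y * z))

        before = batch_loss()
        opt = _nn.Adam(net.params(), lr=1e-3)
        z = net.logits(X, train=True, rng=None)
        p = _nn.sigmoid(z)
        net.backward(((p - y) / len(y)).astype(np.float32))
        opt.step()
        assert batch_loss() < before


class TestTraining:
    def test_toy_planted_motif_reaches_training_auc_one(self):
        data = toy_motif_dataset(seed=0)
        cfg = HyperConfig(architecture="cnn", n_filters=8, filter_length=8,
                          fc_hidden=8, dropout_p=0.0, learning_rate=5e-3,
                          max_epochs=80, patience=80, batch_size=16, seed=1)
        trained = train(build_model(cfg), data, cfg)
        tr = data.split("train")
        assert roc_auc(predict(trained, tr), [e.label for e in tr]) == 1.0
        # perfect ranking: every positive outscores every negative
        scores = predict(trained, tr)
        labels = np.array([e.label for e in tr])
        assert scores[labels == 1].min() > scores[labels == 0].max()

    def test_history_is_deterministic(self):
        data = toy_motif_dataset(seed=2, n=10)
        cfg = HyperConfig(architecture="cnn", max_epochs=3, patience=3,
                          batch_size=8, seed=4, **{k: v for k, v in TINY.items()
                                                   if k != "dropout_p"},
                          dropout_p=0.3)
        a = train(build_model(cfg), data, cfg)
        b = train(build_model(cfg), data, cfg)
        assert a.history == b.history
        assert a.validation_auc == b.validation_auc

    def test_single_class_training_split_rejected(self):
        rng = np.random.default_rng(3)
        examples = [SequenceExample(sequence=s, label=1, provenance=f"p{i}",
                                    name=f"p{i}", split="train")
                    for i, s in enumerate(random_seqs(rng, 6, 30))]
        examples += [SequenceExample(sequence=s, label=1, provenance=f"v{i}",
                                     name=f"v{i}", split="validation")
                     for i, s in enumerate(random_seqs(rng, 2, 30))]
        cfg = HyperConfig(architecture="cnn", **TINY)
        with pytest.raises(ValueError, match="single class"):
            train(build_model(cfg), eb.Dataset(examples), cfg)

    def test_null_data_gives_chance_level_auc(self):
        # no planted motif anywhere: the classifier must not beat chance
        spec = eb.SyntheticSpec(chrom_sizes={"chr1": 300_000}, n_peaks=600,
                                plant_probability=0.0, seed=17)
        genome = eb.generate_genome(spec)
        peaks, _ = eb.plant_peaks(genome, spec)
        from eboxnet.dataset import extract_positive_examples

        positives = extract_positive_examples(genome, peaks)
        data, _ = build_dataset(positives, seed=17)
        cfg = HyperConfig(architecture="cnn", max_epochs=3, patience=3,
                          learning_rate=5e-3, seed=17)
        trained = train(build_model(cfg), data, cfg)
        te = data.split("test")
        auc = roc_auc(predict(trained, te), [e.label for e in te])
        assert 0.40 <= auc <= 0.60
        assert 0.40 <= trained.validation_auc <= 0.60


class TestPredict:
    def test_repeated_calls_identical_and_bounded(self, trained_small, small_dataset):
        data, _ = small_dataset
        seqs = data.sequences("test")[:10]
        a = predict(trained_small, seqs)
        b = predict(trained_small, seqs)
        assert np.array_equal(a, b)
        assert ((a >= 0) & (a <= 1)).all()

    def test_wrong_length_error_names_expected_and_actual(self, trained_small):
        with pytest.raises(ValueError, match="301.*7"):
            predict(trained_small, ["ACGTACG"])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, trained_small, small_dataset):
        data, _ = small_dataset
        path = tmp_path / "model.npz"
        save_checkpoint(trained_small, path)
        loaded = load_checkpoint(path)
        seqs = data.sequences("test")[:8]
        assert np.array_equal(predict(loaded, seqs), predict(trained_small, seqs))
        assert loaded.config == trained_small.config
        assert loaded.history == trained_small.history
        assert np.array_equal(loaded.conv_filters, trained_small.conv_filters)
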