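"""The binding-site classifiers and their training loop.

Three architectures:

* ``cnn`` — DeepBind-style: one convolutional layer over the one-hot
  sequence, a learnable-threshold rectifier, global pooling, and a small
  fully connected head ending in a single sigmoid output.
* ``cnn_lstm`` — the DeeperBind/ECLSTM hybrid: the same convolution and
  rectifier, no pooling, two stacked LSTM layers over the filter-response
  sequence, with the final hidden state feeding the head. The convolution
  extracts PWM-like sub-motifs; the recurrence captures their order and
  spacing.
* ``cnn_embed`` — the embedding-input variant: overlapping k-mers are mapped
  through a learned embedding (trained end-to-end) before the convolution.

Training minimises binary cross-entropy with Adam, records validation AUC
every epoch, early-stops on a patience window, and restores the best-epoch
weights. Everything is seeded and deterministic.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .alphabet import encode_indices
from .dataset import Dataset, kmer_index_encode
from .evaluation import UndefinedMetricError, precision_at_threshold, roc_auc

ARCHITECTURES = ("cnn", "cnn_embed", "cnn_lstm")

__all__ = [
    "HyperConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class HyperConfig:
    """One point in the architecture/training search space."""

    architecture: str = "cnn_lstm"
    n_filters: int = 16
    filter_length: int = 24
    pooling: str = "max"  # cnn / cnn_embed only
    lstm_pool: int = 4  # cnn_lstm: local max-pool width/stride between conv and LSTM
    lstm_hidden: int = 16
    fc_hidden: int = 32
    dropout_p: float = 0.2
    learning_rate: float = 2e-3
    weight_decay: float = 0.0
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    # cnn_lstm trains its convolution first under a short CNN objective
    # (global max pooling), then the full recurrent model — the staged
    # protocol of the DeeperBind lineage. The budget is ~this many optimizer
    # steps (rounded up to whole epochs) so it adapts to dataset size.
    # 0 disables the warm start.
    conv_warmup_steps: int = 250
    conv_warmup_lr: float = 5e-3
    conv_warmup_decay: float = 1e-4
    embed_dim: int = 8
    kmer_k: int = 3
    seed: int = 0

    def validate(self, window_length: int | None = None) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        for name in ("n_filters", "filter_length", "lstm_pool", "lstm_hidden", "fc_hidden",
                     "batch_size", "max_epochs", "patience", "embed_dim", "kmer_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p {self.dropout_p} outside [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.architecture in ("cnn", "cnn_embed") and self.pooling not in ("max", "max_and_avg"):
            raise ValueError(f"pooling {self.pooling!r} invalid for {self.architecture}")
        if window_length is not None and self.filter_length > window_length:
            raise ValueError(
                f"filter_length {self.filter_length} exceeds window length {window_length}"
            )


class _Net:
    """Shared encode/forward plumbing for the three architectures."""

    config: HyperConfig

    def params(self) -> dict[str, _nn.Param]:
        raise NotImplementedError

    def encode(self, sequences: list[str]) -> np.ndarray:
        return np.stack([encode_indices(s) for s in sequences])

    def logits(self, batch: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogit: np.ndarray) -> None:
        raise NotImplementedError

    def conv_response(self, batch: np.ndarray) -> np.ndarray:
        """Rectified first-layer activations (B, T, n_filters), eval mode."""
        raise NotImplementedError

    @property
    def receptive_field(self) -> int:
        return self.config.filter_length

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.params().items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for k, p in self.params().items():
            p.value[...] = snap[k]


class CNNNet(_Net):
    def __init__(self, config: HyperConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        self.conv = _nn.ConvOneHot(config.filter_length, config.n_filters, rng)
        self.thresh = _nn.ThresholdReLU(config.n_filters)
        self.pool = _nn.GlobalPool(config.pooling)
        d_pool = self.pool.out_features(config.n_filters)
        self.fc1 = _nn.Dense(d_pool, config.fc_hidden, rng)
        self.relu = _nn.ReLU()
        self.drop = _nn.Dropout(config.dropout_p)
        self.fc2 = _nn.Dense(config.fc_hidden, 1, rng)

    def params(self):
        return {
            "conv.W": self.conv.W, "thresh.b": self.thresh.b,
            "fc1.W": self.fc1.W, "fc1.b": self.fc1.b,
            "fc2.W": self.fc2.W, "fc2.b": self.fc2.b,
        }

    def logits(self, batch, train=False, rng=None):
        a = self.thresh.forward(self.conv.forward(batch, keep_cache=train), keep_cache=train)
        h = self.pool.forward(a)
        h = self.relu.forward(self.fc1.forward(h, keep_cache=train), keep_cache=train)
        h = self.drop.forward(h, train, rng)
        return self.fc2.forward(h, keep_cache=train)[:, 0]

    def backward(self, dlogit):
        d = self.fc2.backward(dlogit[:, None])
        d = self.drop.backward(d)
        d = self.fc1.backward(self.relu.backward(d))
        d = self.pool.backward(d)
        self.conv.backward(self.thresh.backward(d))

    def conv_response(self, batch):
        return self.thresh.forward(self.conv.forward(batch, keep_cache=False),
                                   keep_cache=False)


class CNNLSTMNet(_Net):
    def __init__(self, config: HyperConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        self.conv = _nn.ConvOneHot(config.filter_length, config.n_filters, rng)
        self.thresh = _nn.ThresholdReLU(config.n_filters)
        self.lpool = _nn.LocalMaxPool(config.lstm_pool)
        self.lstm1 = _nn.LSTM(config.n_filters, config.lstm_hidden, rng)
        self.lstm2 = _nn.LSTM(config.lstm_hidden, config.lstm_hidden, rng)
        self.fc1 = _nn.Dense(config.lstm_hidden, config.fc_hidden, rng)
        self.relu = _nn.ReLU()
        self.drop = _nn.Dropout(config.dropout_p)
        self.fc2 = _nn.Dense(config.fc_hidden, 1, rng)

    def params(self):
        return {
            "conv.W": self.conv.W, "thresh.b": self.thresh.b,
            "lstm1.Wx": self.lstm1.Wx, "lstm1.Wh": self.lstm1.Wh, "lstm1.b": self.lstm1.b,
            "lstm2.Wx": self.lstm2.Wx, "lstm2.Wh": self.lstm2.Wh, "lstm2.b": self.lstm2.b,
            "fc1.W": self.fc1.W, "fc1.b": self.fc1.b,
            "fc2.W": self.fc2.W, "fc2.b": self.fc2.b,
        }

    def logits(self, batch, train=False, rng=None):
        a = self.thresh.forward(self.conv.forward(batch, keep_cache=train), keep_cache=train)
        a = self.lpool.forward(a, keep_cache=train)
        h1 = self.lstm1.forward(a, keep_cache=train)
        h2 = self.lstm2.forward(h1, keep_cache=train)
        last = h2[:, -1, :]
        self._T = h2.shape[1]
        h = self.relu.forward(self.fc1.forward(last, keep_cache=train), keep_cache=train)
        h = self.drop.forward(h, train, rng)
        return self.fc2.forward(h, keep_cache=train)[:, 0]

    def backward(self, dlogit):
        d = self.fc2.backward(dlogit[:, None])
        d = self.drop.backward(d)
        d = self.fc1.backward(self.relu.backward(d))
        dh2 = np.zeros((d.shape[0], self._T, self.config.lstm_hidden), dtype=_nn.F32)
        dh2[:, -1, :] = d
        dh1 = self.lstm2.backward(dh2)
        da = self.lpool.backward(self.lstm1.backward(dh1))
        self.conv.backward(self.thresh.backward(da))

    def conv_response(self, batch):
        return self.thresh.forward(self.conv.forward(batch, keep_cache=False),
                                   keep_cache=False)


class CNNEmbedNet(_Net):
    def __init__(self, config: HyperConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        vocab = 4**config.kmer_k + 1  # +1 for the unknown (N-containing) k-mer
        self.embed = _nn.Embedding(vocab, config.embed_dim, rng)
        self.conv = _nn.ConvDense(config.filter_length, config.embed_dim,
                                  config.n_filters, rng)
        self.thresh = _nn.ThresholdReLU(config.n_filters)
        self.pool = _nn.GlobalPool(config.pooling)
        d_pool = self.pool.out_features(config.n_filters)
        self.fc1 = _nn.Dense(d_pool, config.fc_hidden, rng)
        self.relu = _nn.ReLU()
        self.drop = _nn.Dropout(config.dropout_p)
        self.fc2 = _nn.Dense(config.fc_hidden, 1, rng)

    def params(self):
        return {
            "embed.E": self.embed.E, "conv.W": self.conv.W, "thresh.b": self.thresh.b,
            "fc1.W": self.fc1.W, "fc1.b": self.fc1.b,
            "fc2.W": self.fc2.W, "fc2.b": self.fc2.b,
        }

    def encode(self, sequences):
        return np.stack([kmer_index_encode(s, k=self.config.kmer_k) for s in sequences])

    def logits(self, batch, train=False, rng=None):
        x = self.embed.forward(batch, keep_cache=train)
        a = self.thresh.forward(self.conv.forward(x, keep_cache=train), keep_cache=train)
        h = self.pool.forward(a)
        h = self.relu.forward(self.fc1.forward(h, keep_cache=train), keep_cache=train)
        h = self.drop.forward(h, train, rng)
        return self.fc2.forward(h, keep_cache=train)[:, 0]

    def backward(self, dlogit):
        d = self.fc2.backward(dlogit[:, None])
        d = self.drop.backward(d)
        d = self.fc1.backward(self.relu.backward(d))
        d = self.pool.backward(d)
        dx = self.conv.backward(self.thresh.backward(d))
        self.embed.backward(dx)

    def conv_response(self, batch):
        x = self.embed.forward(batch, keep_cache=False)
        return self.thresh.forward(self.conv.forward(x, keep_cache=False),
                                   keep_cache=False)

    @property
    def receptive_field(self) -> int:
        # a width-w convolution over overlapping k-mers spans w + k - 1 nt
        return self.config.filter_length + self.config.kmer_k - 1


_NET_CLASSES = {"cnn": CNNNet, "cnn_lstm": CNNLSTMNet, "cnn_embed": CNNEmbedNet}


def build_model(config: HyperConfig) -> _Net:
    """An untrained, seeded network for the requested architecture."""
    config.validate()
    return _NET_CLASSES[config.architecture](config)


@dataclass
class TrainedModel:
    config: HyperConfig
    net: _Net = field(repr=False)
    history: list[dict] = field(repr=False)
    validation_auc: float
    window_length: int
    manifest_hash: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.validation_auc <= 1.0:
            raise ValueError(f"validation_auc {self.validation_auc} outside [0, 1]")

    @property
    def conv_filters(self) -> np.ndarray:
        """First-layer filters; (n_filters, 4, filter_length) for one-hot
        architectures, (n_filters, embed_dim, filter_length) for cnn_embed."""
        if isinstance(self.net, CNNEmbedNet):
            w, d, f = self.config.filter_length, self.config.embed_dim, self.config.n_filters
            return self.net.conv.W.value.T.reshape(f, w, d).transpose(0, 2, 1)
        return self.net.conv.filters

    @property
    def receptive_field(self) -> int:
        return self.net.receptive_field

    def conv_activations(self, sequences: list[str]) -> np.ndarray:
        """Rectified filter responses (B, T, n_filters) in evaluation mode."""
        return self.net.conv_response(self.net.encode(list(sequences)))


def _batched_scores(net: _Net, encoded: np.ndarray, batch: int = 512) -> np.ndarray:
    out = []
    for i in range(0, encoded.shape[0], batch):
        out.append(_nn.sigmoid(net.logits(encoded[i : i + batch], train=False)))
    return np.concatenate(out).astype(float)


def train(model: _Net, dataset: Dataset, config: HyperConfig) -> TrainedModel:
    """Minimise binary cross-entropy on the train split; keep the weights of
    the epoch with the best validation AUC; stop early after ``patience``
    epochs without improvement."""
    train_ex = dataset.split("train")
    val_ex = dataset.split("validation")
    if not train_ex or not val_ex:
        raise ValueError("dataset needs nonempty train and validation splits")
    if (config.architecture == "cnn_lstm" and config.conv_warmup_steps > 0
            and isinstance(model, CNNLSTMNet)):
        steps_per_epoch = -(-len(train_ex) // config.batch_size)
        warm_epochs = min(15, max(1, -(-config.conv_warmup_steps // steps_per_epoch)))
        warm_cfg = HyperConfig(**{**asdict(config),
                                  "architecture": "cnn", "pooling": "max",
                                  "learning_rate": config.conv_warmup_lr,
                                  "weight_decay": config.conv_warmup_decay,
                                  "max_epochs": warm_epochs,
                                  "patience": warm_epochs,
                                  "conv_warmup_steps": 0})
        warm = train(build_model(warm_cfg), dataset, warm_cfg)
        model.conv.W.value[...] = warm.net.conv.W.value
        model.thresh.b.value[...] = warm.net.thresh.b.value
    y_train = np.array([e.label for e in train_ex], dtype=_nn.F32)
    if y_train.min() == y_train.max():
        raise ValueError("training split contains a single class; loss/AUC undefined")
    window = len(train_ex[0].sequence)
    config.validate(window_length=window)
    X_train = model.encode([e.sequence for e in train_ex])
    X_val = model.encode([e.sequence for e in val_ex])
    y_val = np.array([e.label for e in val_ex], dtype=int)

    ss = np.random.SeedSequence(config.seed).spawn(2)
    shuffle_rng = np.random.default_rng(ss[0])
    drop_rng = np.random.default_rng(ss[1])
    opt = _nn.Adam(model.params(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)

    history: list[dict] = []
    best_auc, best_epoch = -np.inf, -1
    best_snap = model.snapshot()
    n = X_train.shape[0]
    for epoch in range(config.max_epochs):
        perm = shuffle_rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            z = model.logits(xb, train=True, rng=drop_rng)
            p = _nn.sigmoid(z)
            # stable BCE from logits: softplus(z) - y*z
            loss = float(np.mean(np.logaddexp(0.0, z) - yb * z))
            losses.append(loss)
            model.backward(((p - yb) / len(yb)).astype(_nn.F32))
            opt.step()
            opt.zero_grad()
        val_scores = _batched_scores(model, X_val)
        val_auc = roc_auc(val_scores, y_val)
        try:
            val_prec = precision_at_threshold(val_scores, y_val)
        except UndefinedMetricError:
            val_prec = None
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_auc": val_auc,
            "val_precision": val_prec,
        })
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_snap = model.snapshot()
        elif epoch - best_epoch >= config.patience:
            break
    model.restore(best_snap)
    return TrainedModel(
        config=config, net=model, history=history,
        validation_auc=float(best_auc), window_length=window,
    )


def predict(trained: TrainedModel, sequences) -> np.ndarray:
    """One probability in [0, 1] per sequence, deterministic (dropout off)."""
    seqs = [getattr(s, "sequence", s) for s in sequences]
    for s in seqs:
        if len(s) != trained.window_length:
            raise ValueError(
                f"expected sequences of length {trained.window_length}, got {len(s)}"
            )
    return _batched_scores(trained.net, trained.net.encode(seqs))


def save_checkpoint(trained: TrainedModel, path) -> None:
    meta = {
        "config": asdict(trained.config),
        "history": trained.history,
        "validation_auc": trained.validation_auc,
        "window_length": trained.window_length,
        "manifest_hash": trained.manifest_hash,
    }
    arrays = {f"param/{k}": p.value for k, p in trained.net.params().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = HyperConfig(**meta["config"])
        net = build_model(config)
        for k, p in net.params().items():
            p.value[...] = data[f"param/{k}"]
    return TrainedModel(
        config=config, net=net, history=meta["history"],
        validation_auc=meta["validation_auc"], window_length=meta["window_length"],
        manifest_hash=meta.get("manifest_hash"),
    )
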