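"""Two-phase random-search calibration.

Phase one trains ``n_trials`` (default 40) models with randomly sampled
hyperparameters on a short epoch budget and ranks them by a validation
metric. Phase two retrains ``n_final`` (default 6) full-budget models with
the winning configuration under distinct seeds and keeps the best finalist.

The selection metric defaults to validation AUC for both phases; validation
precision at threshold 0.5 is recorded alongside and can be selected instead
(``selection_metric="precision"``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import Dataset
from .models import HyperConfig, TrainedModel, build_model, train

__all__ = ["SearchSpace", "CalibrationReport", "sample_config", "calibrate",
           "write_report", "read_report"]


@dataclass
class SearchSpace:
    """Ranges for each sampled hyperparameter. Discrete fields are choice
    tuples; dropout is uniform on an interval; learning rate is log-uniform."""

    architectures: tuple[str, ...] = ("cnn", "cnn_lstm")
    n_filters: tuple[int, ...] = (8, 16, 32)
    filter_length: tuple[int, ...] = (12, 16, 24)
    pooling: tuple[str, ...] = ("max", "max_and_avg")
    lstm_hidden: tuple[int, ...] = (16, 32)
    fc_hidden: tuple[int, ...] = (16, 32, 64)
    embed_dim: tuple[int, ...] = (4, 8)
    dropout_range: tuple[float, float] = (0.0, 0.5)
    learning_rate_range: tuple[float, float] = (1e-4, 1e-2)
    batch_size: tuple[int, ...] = (32, 64, 128)

    def validate(self) -> None:
        for name in ("architectures", "n_filters", "filter_length", "pooling",
                     "lstm_hidden", "fc_hidden", "embed_dim", "batch_size"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty search range for {name}")
        lo, hi = self.learning_rate_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad learning_rate_range {self.learning_rate_range}")
        lo, hi = self.dropout_range
        if not (0 <= lo <= hi < 1):
            raise ValueError(f"bad dropout_range {self.dropout_range}")


def sample_config(space: SearchSpace, rng: np.random.Generator,
                  base: HyperConfig | None = None) -> HyperConfig:
    """One configuration with each field sampled independently."""
    space.validate()
    base = base or HyperConfig()
    lr_lo, lr_hi = space.learning_rate_range
    cfg = HyperConfig(
        architecture=str(rng.choice(space.architectures)),
        n_filters=int(rng.choice(space.n_filters)),
        filter_length=int(rng.choice(space.filter_length)),
        pooling=str(rng.choice(space.pooling)),
        lstm_hidden=int(rng.choice(space.lstm_hidden)),
        fc_hidden=int(rng.choice(space.fc_hidden)),
        embed_dim=int(rng.choice(space.embed_dim)),
        dropout_p=float(rng.uniform(*space.dropout_range)),
        learning_rate=float(math.exp(rng.uniform(math.log(lr_lo), math.log(lr_hi)))),
        batch_size=int(rng.choice(space.batch_size)),
        max_epochs=base.max_epochs,
        patience=base.patience,
        kmer_k=base.kmer_k,
        seed=base.seed,
    )
    cfg.validate()
    return cfg


@dataclass
class CalibrationReport:
    trials: list[tuple[HyperConfig, float | None]]
    best_config: HyperConfig | None
    finalists: list[tuple[int, float | None]]  # (seed, metric)
    selected: TrainedModel | None
    selection_metric: str
    n_trials: int
    n_final: int

    def __post_init__(self) -> None:
        if len(self.trials) != self.n_trials:
            raise ValueError("trial count mismatch")
        if self.finalists and len(self.finalists) != self.n_final:
            raise ValueError("finalist count mismatch")


def _metric(trained: TrainedModel, which: str) -> float:
    if which == "auc":
        return trained.validation_auc
    if which == "precision":
        best = max(trained.history, key=lambda h: h["val_auc"])
        prec = best["val_precision"]
        return -math.inf if prec is None else prec  # undefined precision never wins
    raise ValueError(f"unknown selection metric {which!r}")


def calibrate(
    dataset: Dataset,
    space: SearchSpace | None = None,
    n_trials: int = 40,
    n_final: int = 6,
    seed: int = 0,
    selection_metric: str = "auc",
    trial_epochs: int = 5,
    final_max_epochs: int | None = None,
    dry_run: bool = False,
) -> CalibrationReport:
    """Run the two-phase protocol; with ``dry_run`` only sample and count
    (no training), for fast contract checks of the protocol itself."""
    if n_trials < 1 or n_final < 1:
        raise ValueError("n_trials and n_final must both be >= 1")
    space = space or SearchSpace()
    ss = np.random.SeedSequence(seed)
    sample_rng = np.random.default_rng(ss.spawn(1)[0])
    # seeds for trials and finalists, all derived from the one entropy source
    trial_seeds = [int(s) for s in
                   np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31, size=n_trials)]
    final_seeds = [int(s) for s in
                   np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31, size=n_final)]

    configs = [sample_config(space, sample_rng) for _ in range(n_trials)]
    if dry_run:
        return CalibrationReport(
            trials=[(c, None) for c in configs], best_config=None,
            finalists=[(s, None) for s in final_seeds], selected=None,
            selection_metric=selection_metric, n_trials=n_trials, n_final=n_final,
        )

    trials: list[tuple[HyperConfig, float]] = []
    for cfg, tseed in zip(configs, trial_seeds):
        cfg.max_epochs = trial_epochs
        cfg.seed = tseed
        trained = train(build_model(cfg), dataset, cfg)
        trials.append((cfg, _metric(trained, selection_metric)))
    best_config = max(trials, key=lambda t: t[1])[0]

    finalists: list[tuple[int, float]] = []
    selected: TrainedModel | None = None
    selected_metric = -math.inf
    for fseed in final_seeds:
        cfg = HyperConfig(**{**asdict(best_config),
                             "seed": fseed,
                             "max_epochs": final_max_epochs or HyperConfig().max_epochs})
        trained = train(build_model(cfg), dataset, cfg)
        m = _metric(trained, selection_metric)
        finalists.append((fseed, m))
        if m > selected_metric:
            selected, selected_metric = trained, m
    return CalibrationReport(
        trials=trials, best_config=best_config, finalists=finalists,
        selected=selected, selection_metric=selection_metric,
        n_trials=n_trials, n_final=n_final,
    )


def write_report(report: CalibrationReport, path) -> None:
    doc = {
        "selection_metric": report.selection_metric,
        "n_trials": report.n_trials,
        "n_final": report.n_final,
        "trials": [{"config": asdict(c), "metric": m} for c, m in report.trials],
        "best_config": None if report.best_config is None else asdict(report.best_config),
        "finalists": [{"seed": s, "metric": m} for s, m in report.finalists],
        "selected_validation_auc":
            None if report.selected is None else report.selected.validation_auc,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
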