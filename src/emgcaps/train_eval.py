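"""End-to-end training and evaluation of the fusion capsule classifier.

A run featurizes windows into fused inputs, minimizes the margin loss with
Adam over minibatches, and reports per-gesture and overall accuracy.
Experiment drivers repeat a scenario across independently seeded runs and
tabulate accuracies as mean +/- standard deviation; the squash-ablation
driver does so for every squash variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .capsnet import CapsNet, CapsNetConfig, MarginLossConfig, margin_loss
from .features import SpectralConfig
from .fusion import FusionConfig, build_fused_input
from .nn import Adam
from .synthgen import (
    GESTURE_NAMES,
    ExperimentConfig,
    SyntheticDataset,
    generate_experiment,
)
from .windowing import SignalWindow

__all__ = [
    "TrainConfig",
    "EvalReport",
    "featurize_windows",
    "train",
    "evaluate",
    "run_experiment",
    "ablate_squash",
]

logger = logging.getLogger("emgcaps")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Batch size 32 matches the displacement protocol, 16 the cross-subject
    protocol (pass explicitly or let ``run_experiment`` pick by scenario).
    ``repeats`` is the number of independently seeded runs behind each
    mean +/- std entry.
    """

    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 30
    repeats: int = 3
    squash_kind: str = "e_squash"
    width_profile: str = "test"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class EvalReport:
    """Accuracies in percent (mean +/- std over seeded runs) plus diagnostics."""

    per_gesture_mean: np.ndarray
    per_gesture_std: np.ndarray
    overall_mean: float
    overall_std: float
    confusion: np.ndarray  # counts, last run; rows = true class
    histories: list[dict] = field(default_factory=list)
    gesture_names: tuple[str, ...] = GESTURE_NAMES

    def to_table(self):
        """Tables 3/4-style layout: one row, per-gesture and overall columns."""
        import pandas as pd

        row = {
            name: f"{m:.2f} ± {s:.2f}"
            for name, m, s in zip(
                self.gesture_names, self.per_gesture_mean, self.per_gesture_std
            )
        }
        row["Overall accuracy (%)"] = f"{self.overall_mean:.2f} ± {self.overall_std:.2f}"
        return pd.DataFrame([row])


def featurize_windows(
    windows: Sequence[SignalWindow],
    spectral: Optional[SpectralConfig] = None,
    fusion: Optional[FusionConfig] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windows -> (feature maps (N,E,15,15), segment matrices (N,E,15,20), labels)."""
    spectral = spectral or SpectralConfig(fs=windows[0].fs)
    fusion = fusion or FusionConfig(n_electrodes=windows[0].n_channels)
    fmaps, smats, labels = [], [], []
    for win in windows:
        fused = build_fused_input(win, spectral, fusion)
        fmaps.append(fused.feature_maps)
        smats.append(fused.segment_matrices)
        labels.append(-1 if win.label is None else win.label)
    return np.stack(fmaps), np.stack(smats), np.array(labels)


def train(
    model: CapsNet,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
    test_data: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
    seed: int = 0,
    loss_config: MarginLossConfig = MarginLossConfig(),
) -> dict:
    """Fit ``model`` by minibatch Adam on the margin loss.

    Returns a history dict with per-epoch mean train loss and (when test
    data is given) test accuracy.  Shuffling is seeded; a non-finite loss
    aborts with a diagnostic.
    """
    fmaps, smats, labels = train_data
    n = fmaps.shape[0]
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=config.learning_rate)
    history: dict = {"train_loss": [], "test_accuracy": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            lengths, _ = model.forward(fmaps[idx], smats[idx])
            loss = margin_loss(lengths, labels[idx], loss_config)
            if not (np.isfinite(lengths.data).all() and np.isfinite(loss.data)):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting at {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        msg = f"epoch {epoch + 1}/{config.epochs} train_loss={history['train_loss'][-1]:.4f}"
        if test_data is not None:
            acc = evaluate(model, test_data).overall_mean
            history["test_accuracy"].append(acc)
            msg += f" test_acc={acc:.2f}%"
        logger.info(msg)
    return history


def _predict_in_batches(model: CapsNet, fmaps: np.ndarray, smats: np.ndarray,
                        batch: int = 64) -> np.ndarray:
    preds = []
    for start in range(0, fmaps.shape[0], batch):
        preds.append(model.predict_batch(fmaps[start : start + batch],
                                         smats[start : start + batch]))
    return np.concatenate(preds)


def accuracy_metrics(
    preds: np.ndarray, labels: np.ndarray, n_classes: int
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-class accuracy (%, NaN for empty classes), overall (%), confusion."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(labels, preds):
        confusion[t, p] += 1
    row_tot = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(
            row_tot > 0, 100.0 * np.diag(confusion) / np.maximum(row_tot, 1), np.nan
        )
    overall = 100.0 * float((preds == labels).sum()) / labels.size
    return per_class, overall, confusion


def evaluate(
    model: CapsNet, test_data: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> EvalReport:
    """Evaluate one trained model on one test set (std entries are 0)."""
    fmaps, smats, labels = test_data
    preds = _predict_in_batches(model, fmaps, smats)
    per_class, overall, confusion = accuracy_metrics(preds, labels, model.config.n_classes)
    return EvalReport(
        per_gesture_mean=per_class,
        per_gesture_std=np.zeros_like(per_class),
        overall_mean=overall,
        overall_std=0.0,
        confusion=confusion,
        gesture_names=GESTURE_NAMES[: model.config.n_classes],
    )


def run_experiment(
    scenario: str = "displacement",
    squash_kind: str = "e_squash",
    train_config: Optional[TrainConfig] = None,
    experiment_config: Optional[ExperimentConfig] = None,
    seed: int = 0,
    dataset: Optional[SyntheticDataset] = None,
) -> EvalReport:
    """Run one full scenario: generate, featurize, train, evaluate.

    Repeats ``train_config.repeats`` times with independently derived seeds
    (fresh dataset and fresh weights each time) and aggregates accuracies as
    mean +/- std; the confusion matrix comes from the last run.
    """
    experiment_config = experiment_config or ExperimentConfig(scenario=scenario)
    if train_config is None:
        train_config = TrainConfig(
            batch_size=32 if scenario == "displacement" else 16,
            squash_kind=squash_kind,
        )
    n_classes = experiment_config.n_gestures
    per_class_runs, overall_runs, histories = [], [], []
    confusion = None
    seeds = np.random.SeedSequence(seed).generate_state(train_config.repeats) % (2**31)
    for run_seed in seeds:
        run_seed = int(run_seed)
        ds = dataset if dataset is not None else generate_experiment(
            experiment_config, seed=run_seed
        )
        train_arrays = featurize_windows(ds.subset("train"))
        test_arrays = featurize_windows(ds.subset("test"))
        model = CapsNet(
            CapsNetConfig(
                n_classes=n_classes,
                squash_kind=train_config.squash_kind,
                width_profile=train_config.width_profile,
                n_electrodes=experiment_config.n_channels,
            ),
            seed=run_seed,
        )
        history = train(model, train_arrays, train_config, seed=run_seed)
        histories.append(history)
        preds = _predict_in_batches(model, test_arrays[0], test_arrays[1])
        per_class, overall, confusion = accuracy_metrics(
            preds, test_arrays[2], n_classes
        )
        per_class_runs.append(per_class)
        overall_runs.append(overall)
        logger.info(
            "run seed=%d scenario=%s squash=%s overall=%.2f%%",
            run_seed, experiment_config.scenario, train_config.squash_kind, overall,
        )
    per_class_runs = np.array(per_class_runs)
    return EvalReport(
        per_gesture_mean=np.nanmean(per_class_runs, axis=0),
        per_gesture_std=np.nanstd(per_class_runs, axis=0),
        overall_mean=float(np.mean(overall_runs)),
        overall_std=float(np.std(overall_runs)),
        confusion=confusion,
        histories=histories,
        gesture_names=GESTURE_NAMES[:n_classes],
    )


def ablate_squash(
    scenario: str = "displacement",
    kinds: Sequence[str] = ("squash", "hsquash", "strict_squash", "squash_4", "e_squash"),
    train_config: Optional[TrainConfig] = None,
    experiment_config: Optional[ExperimentConfig] = None,
    seed: int = 0,
):
    """Compare squash variants on one scenario; returns a DataFrame with one
    row per squash kind (overall accuracy, mean +/- std)."""
    import pandas as pd

    rows = []
    reports = {}
    for kind in kinds:
        cfg = train_config
        if cfg is not None:
            cfg = TrainConfig(
                batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                epochs=cfg.epochs, repeats=cfg.repeats, squash_kind=kind,
                width_profile=cfg.width_profile,
            )
        report = run_experiment(
            scenario=scenario, squash_kind=kind, train_config=cfg,
            experiment_config=experiment_config, seed=seed,
        )
        reports[kind] = report
        rows.append(
            {
                "squash": kind,
                "overall_mean": report.overall_mean,
                "overall_std": report.overall_std,
                "formatted": f"{report.overall_mean:.2f} ± {report.overall_std:.2f}",
            }
        )
    return pd.DataFrame(rows), reports
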