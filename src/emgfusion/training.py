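"""Training loop, learning-rate schedule, and trial-level evaluation.

Targets are per-window: the trial label is broadcast over the window axis
to match the per-window softmax head, and trial-level predictions are
recovered by averaging window probabilities.  The loss is the per-sample
mean cross-entropy (batch-size invariant; the summed variant differs only
by a constant factor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .features import FeatureConfig, build_feature_tensor
from .model import ModelGraph, ModelSpec, build_dual_stream
from .nn import Adam, Tensor, log_softmax
from .preprocessing import (
    NormalizerStats,
    Trial,
    WindowSpec,
    fit_normalizer,
    slide_windows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "TrialInputs",
    "cross_entropy_loss",
    "lr_schedule",
    "fit_trial_normalizer",
    "prepare_inputs",
    "train",
    "predict_trial",
    "aggregate_trial",
    "evaluate",
    "run_subject_wise",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    base_lr: float = 1e-4
    lr_drop_epoch: int = 70
    lr_drop_factor: float = 0.1
    repeated_drops: bool = False
    epochs: int = 500
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    patience: int | None = None

    def __post_init__(self):
        if not 0 < self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def paper_scale_config(**overrides) -> TrainConfig:
    """The published full-scale training settings (multi-hour on real data)."""
    defaults = dict(batch_size=64, base_lr=1e-4, lr_drop_epoch=70,
                    lr_drop_factor=0.1, epochs=500)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def desk_scale_config(**overrides) -> TrainConfig:
    """Settings that converge on synthetic data within minutes."""
    defaults = dict(batch_size=64, base_lr=1e-3, lr_drop_epoch=70,
                    lr_drop_factor=0.1, epochs=30)
    defaults.update(overrides)
    return TrainConfig(**defaults)


class TrialInputs(NamedTuple):
    """Model-ready arrays for one trial."""

    features: np.ndarray  # (n_windows, 5, channels)
    raw: np.ndarray       # (n_windows, window_samples, channels)
    label: int            # 1-based gesture label
    subject: int
    repetition: int


@dataclass
class EvalReport:
    """Trial-level classification report."""

    overall_accuracy: float            # percent
    per_class_accuracy: np.ndarray     # percent, nan for absent classes
    confusion: np.ndarray              # (n_classes, n_classes) true x predicted
    n_trials: int
    window_accuracy: float | None = None  # percent, diagnostic

    def as_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": [None if np.isnan(v) else float(v)
                                   for v in self.per_class_accuracy],
            "confusion": self.confusion.tolist(),
            "n_trials": self.n_trials,
            "window_accuracy": self.window_accuracy,
        }

    def confusion_to_csv(self, path) -> None:
        np.savetxt(path, self.confusion, fmt="%d", delimiter=",")

    def confusion_heatmap(self, path) -> None:
        """Render the confusion matrix as a PNG heat map."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        image = ax.imshow(self.confusion, cmap="viridis")
        ax.set_xlabel("predicted class")
        ax.set_ylabel("true class")
        ax.set_title(f"accuracy {self.overall_accuracy:.2f}% "
                     f"({self.n_trials} trials)")
        fig.colorbar(image, ax=ax)
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def cross_entropy_loss(predicted_probs: np.ndarray,
                       true_onehot: np.ndarray) -> float:
    """Mean per-sample cross-entropy with a 1e-12 probability floor."""
    p = np.asarray(predicted_probs, dtype=np.float64)
    y = np.asarray(true_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    per_sample = -(y * np.log(np.maximum(p, 1e-12))).sum(axis=-1)
    return float(per_sample.mean())


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Step decay: base rate until `lr_drop_epoch`, then scaled by the factor.

    Single-drop by default; with `repeated_drops` the factor is applied once
    per completed interval of `lr_drop_epoch` epochs.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch < config.lr_drop_epoch:
        return config.base_lr
    if config.repeated_drops:
        return config.base_lr * config.lr_drop_factor ** (epoch // config.lr_drop_epoch)
    return config.base_lr * config.lr_drop_factor


# ---------------------------------------------------------------------------
# Input preparation


def fit_trial_normalizer(trials: Sequence[Trial]) -> NormalizerStats:
    return fit_normalizer([t.data for t in trials])


def prepare_inputs(trials: Sequence[Trial], wspec: WindowSpec,
                   feature_config: FeatureConfig | None = None,
                   stats: NormalizerStats | None = None) -> list[TrialInputs]:
    """Z-score (optionally), window, and featurize a batch of trials."""
    if feature_config is None:
        feature_config = FeatureConfig()
    out: list[TrialInputs] = []
    for trial in trials:
        if stats is not None:
            trial = Trial(data=stats.transform(trial.data), label=trial.label,
                          repetition=trial.repetition, subject=trial.subject,
                          padded=trial.padded)
        windows = slide_windows(trial, wspec)
        feats = build_feature_tensor(windows, feature_config)
        out.append(TrialInputs(features=feats.data, raw=windows.data,
                               label=trial.label, subject=trial.subject,
                               repetition=trial.repetition))
    return out


def _stack(inputs: Sequence[TrialInputs]):
    features = np.stack([t.features for t in inputs])
    raw = np.stack([t.raw for t in inputs])
    labels = np.array([t.label - 1 for t in inputs], dtype=np.int64)
    return features, raw, labels


def _model_inputs(graph: ModelGraph, features: np.ndarray, raw: np.ndarray):
    arrays = {"features": features, "raw": raw}
    return tuple(Tensor(arrays[k]) for k in graph.model.input_kinds)


def _forward_logits(graph: ModelGraph, features, raw, training=False, rng=None):
    return graph.model.forward(*_model_inputs(graph, features, raw),
                               training=training, rng=rng)


def _window_loss(logits: Tensor, labels: np.ndarray, n_classes: int) -> Tensor:
    """Mean cross-entropy over batch x windows with broadcast trial labels."""
    batch, n_windows, _ = logits.shape
    onehot = np.zeros((batch, n_windows, n_classes))
    onehot[np.arange(batch)[:, None], np.arange(n_windows)[None, :],
           labels[:, None]] = 1.0
    logp = log_softmax(logits, axis=-1)
    return -(logp * onehot).sum(axis=-1).mean()


def _predict_probs(graph: ModelGraph, inputs: Sequence[TrialInputs],
                   batch_size: int = 64) -> np.ndarray:
    """Eval-mode window probabilities, (n_trials, n_windows, n_classes)."""
    chunks = []
    for lo in range(0, len(inputs), batch_size):
        features, raw, _ = _stack(inputs[lo:lo + batch_size])
        logits = _forward_logits(graph, features, raw, training=False)
        shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        chunks.append(e / e.sum(axis=-1, keepdims=True))
    return np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# Training


def train(graph: ModelGraph, train_trials: Sequence[TrialInputs],
          val_trials: Sequence[TrialInputs], config: TrainConfig,
          verbose: bool = False):
    """Train a model graph in place; returns (graph, history).

    History records per-epoch loss, window-level train accuracy, trial-level
    validation accuracy and the learning rate.  Seeded and deterministic.
    """
    if len(train_trials) == 0:
        raise ValueError("training set is empty")
    spec = graph.spec
    rng = np.random.default_rng(config.seed)
    features, raw, labels = _stack(train_trials)
    n = features.shape[0]
    params = graph.model.parameters()
    optimizer = Adam(params, lr=config.base_lr, beta1=config.beta1,
                     beta2=config.beta2, l2=spec.l2_coefficient,
                     l2_params=graph.model.regularization_params())
    history = {"epoch": [], "lr": [], "train_loss": [],
               "train_window_accuracy": [], "val_trial_accuracy": []}
    best_val, since_best = -np.inf, 0
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        optimizer.lr = lr
        order = rng.permutation(n)
        epoch_loss, epoch_correct, epoch_windows = 0.0, 0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            logits = _forward_logits(graph, features[idx], raw[idx],
                                     training=True, rng=rng)
            loss = _window_loss(logits, labels[idx], spec.n_classes)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // config.batch_size}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            pred = logits.data.argmax(axis=-1)
            epoch_correct += int((pred == labels[idx][:, None]).sum())
            epoch_windows += pred.size
            epoch_loss += float(loss.data) * len(idx)
        val_acc = np.nan
        if len(val_trials) > 0:
            val_acc = evaluate(graph, val_trials).overall_accuracy
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(epoch_loss / n)
        history["train_window_accuracy"].append(100.0 * epoch_correct / epoch_windows)
        history["val_trial_accuracy"].append(val_acc)
        if verbose:
            logger.info("epoch %d: loss=%.4f window_acc=%.2f%% val_acc=%s",
                        epoch, history["train_loss"][-1],
                        history["train_window_accuracy"][-1], val_acc)
        if config.patience is not None and len(val_trials) > 0:
            if val_acc > best_val + 1e-12:
                best_val, since_best = val_acc, 0
            else:
                since_best += 1
                if since_best > config.patience:
                    break
    return graph, history


def predict_trial(graph: ModelGraph, trial: TrialInputs) -> np.ndarray:
    """Per-window class probabilities, shape (n_windows, n_classes)."""
    return _predict_probs(graph, [trial])[0]


def aggregate_trial(window_probs: np.ndarray) -> int:
    """Trial label = argmax of the window-mean probability vector.

    Ties resolve to the lowest class index (0-based).
    """
    window_probs = np.asarray(window_probs, dtype=np.float64)
    if window_probs.ndim != 2 or window_probs.shape[0] < 1:
        raise ValueError("need at least one window of probabilities")
    return int(np.argmax(window_probs.mean(axis=0)))


def evaluate(graph: ModelGraph, trials: Sequence[TrialInputs]) -> EvalReport:
    """Trial-level accuracy, per-class accuracy and confusion matrix."""
    if len(trials) == 0:
        raise ValueError("cannot evaluate an empty trial set")
    k = graph.spec.n_classes
    probs = _predict_probs(graph, trials)
    true = np.array([t.label - 1 for t in trials])
    predicted = np.array([aggregate_trial(p) for p in probs])
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (true, predicted), 1)
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = 100.0 * np.diag(confusion) / row_sums
    per_class = np.where(row_sums > 0, per_class, np.nan)
    overall = 100.0 * np.trace(confusion) / len(trials)
    window_pred = probs.argmax(axis=-1)
    window_acc = 100.0 * float((window_pred == true[:, None]).mean())
    return EvalReport(overall_accuracy=float(overall),
                      per_class_accuracy=per_class,
                      confusion=confusion, n_trials=len(trials),
                      window_accuracy=window_acc)


def run_subject_wise(subject_datasets: dict[int, tuple[Sequence[Trial], Sequence[Trial]]],
                     spec: ModelSpec, wspec: WindowSpec, config: TrainConfig,
                     feature_config: FeatureConfig | None = None,
                     build=build_dual_stream):
    """Train and validate one model per subject; average the accuracies.

    Normalizer statistics are fit on each subject's training trials only.
    Subjects without validation trials are excluded with a warning.
    """
    reports: dict[int, EvalReport] = {}
    for subject, (train_trials, val_trials) in sorted(subject_datasets.items()):
        if len(val_trials) == 0:
            warnings.warn(f"subject {subject} has no validation trials; skipped")
            continue
        stats = fit_trial_normalizer(train_trials)
        train_inputs = prepare_inputs(train_trials, wspec, feature_config, stats)
        val_inputs = prepare_inputs(val_trials, wspec, feature_config, stats)
        graph = build(spec, seed=config.seed)
        graph, _ = train(graph, train_inputs, val_inputs, config)
        reports[subject] = evaluate(graph, val_inputs)
    if not reports:
        raise ValueError("no subject had validation trials")
    mean_accuracy = float(np.mean([r.overall_accuracy for r in reports.values()]))
    return reports, mean_accuracy
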