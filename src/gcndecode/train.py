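"""Joint end-to-end training of the eleven CNN streams and the GCN, with
subject-wise splitting and one-vs-rest evaluation metrics.

One optimizer drives the whole stack: the softmax cross-entropy gradient
flows from the class scores back through the GCN into every CNN stream in a
single backward pass. Splits are by subject — 3 train / 1 validation / 1
test under the 5-trial rotation — so reported accuracy is held-out-subject
accuracy. The functional-connectivity adjacency is estimated from training
subjects only and frozen before training starts.

Metrics: per-class precision, recall and F-score (beta = 1) from one-vs-rest
confusion counts, their unweighted (macro) averages, per-class one-vs-rest
accuracy, and total accuracy = #correct / n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .cnn import FeatureStream, StreamConfig, build_streams
from .gcn import GCNClassifier, GCNConfig, build_gcn
from .graph import AdjacencyMatrix, build_adjacency, normalize_adjacency, training_roi_signals
from .rois import ROI_NAMES, ROITemplate, Scan
from .synthetic import SyntheticDataset, normalize_by_subject


@dataclass
class TrainConfig:
    """Optimization settings: Adam, 200 epochs, lr 0.01, weight decay 0.001,
    batch size 16, dropout 0.5 by default; all overridable."""

    epochs: int = 200
    learning_rate: float = 0.01
    weight_decay: float = 0.001
    batch_size: int = 16
    dropout: float = 0.5
    optimizer: str = "adam"
    seed: int = 0


@dataclass(frozen=True)
class SplitScheme:
    """Subject roles for one trial: 3 train, 1 validation, 1 test, disjoint."""

    trial: int
    train_subjects: tuple[int, ...]
    val_subject: int
    test_subject: int

    def __post_init__(self):
        roles = set(self.train_subjects) | {self.val_subject, self.test_subject}
        if len(roles) != len(self.train_subjects) + 2:
            raise ValueError(f"trial {self.trial}: subject roles overlap")


def make_splits(subjects: list[int], n_trials: int = 5) -> list[SplitScheme]:
    """Deterministic rotation of subject roles across trials.

    Trial t holds out subject t as test and the next as validation; the rest
    train. Labels play no part in the split.
    """
    subjects = sorted(subjects)
    n = len(subjects)
    if n < 3:
        raise ValueError(f"need >= 3 subjects to form train/val/test, have {n}")
    if n < 5:
        import warnings

        warnings.warn(f"only {n} subjects; full 5-trial protocol needs 5", stacklevel=2)
    splits = []
    for t in range(min(n_trials, n)):
        test = subjects[t]
        val = subjects[(t + 1) % n]
        train = tuple(s for s in subjects if s not in (test, val))
        splits.append(SplitScheme(trial=t + 1, train_subjects=train,
                                  val_subject=val, test_subject=test))
    return splits


class DecodingModel:
    """The full decoder: per-ROI masked CNN streams feeding the residual GCN.

    ``use_gcn=False`` routes the stacked stream features straight to a dense
    classification head (the "no-GCN" ablation); everything else is shared.
    """

    def __init__(self, streams: list[FeatureStream], gcn: GCNClassifier | None,
                 template: ROITemplate, n_classes: int = 10,
                 head_rng: np.random.Generator | None = None):
        self.streams = streams
        self.gcn = gcn
        self.masks = template.mask_array().astype(np.float32)  # (11, d, h, w)
        self.shared = len(streams) > 1 and streams[0] is streams[1]
        if gcn is None:
            if head_rng is None:
                head_rng = np.random.default_rng(0)
            width = streams[0].out_features
            self.head = nn.Linear(len(ROI_NAMES) * width, n_classes, head_rng)
            self.flatten = nn.Flatten()
        else:
            self.head = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Batch of scans (B, 3, d, h, w) -> class scores (B, n_classes)."""
        if self.shared:
            B = x.shape[0]
            masked = (x[:, None] * self.masks[None, :, None]).reshape(
                (B * len(ROI_NAMES),) + x.shape[1:]
            )
            feats = self.streams[0].forward(masked, training)
            feats = feats.reshape(B, len(ROI_NAMES), -1)
        else:
            cols = []
            for r, stream in enumerate(self.streams):
                cols.append(stream.forward(x * self.masks[r][None, None], training))
            feats = np.stack(cols, axis=1)  # (B, 11, width)
        if self.gcn is not None:
            return self.gcn.forward(feats, training)
        return self.head.forward(self.flatten.forward(feats, training), training)

    def backward(self, gscores: np.ndarray) -> None:
        if self.gcn is not None:
            gfeats = self.gcn.backward(gscores)
        else:
            gfeats = self.flatten.backward(self.head.backward(gscores))
        if self.shared:
            B = gfeats.shape[0]
            self.streams[0].backward(gfeats.reshape(B * len(ROI_NAMES), -1))
        else:
            for r, stream in enumerate(self.streams):
                stream.backward(gfeats[:, r])

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        seen: set[int] = set()
        for stream in self.streams:
            if id(stream) not in seen:
                seen.add(id(stream))
                ps.extend(stream.params())
        if self.gcn is not None:
            ps.extend(self.gcn.params())
        else:
            ps.extend(self.head.params())
        return ps

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """0-based argmax class per scan; ties break toward the lowest index."""
        preds = []
        for i in range(0, x.shape[0], batch_size):
            scores = self.forward(x[i:i + batch_size], training=False)
            preds.append(scores.argmax(axis=1))
        return np.concatenate(preds)


def build_model(template: ROITemplate, a_hat: np.ndarray | None,
                stream_config: StreamConfig, gcn_config: GCNConfig,
                seed: int = 0, use_gcn: bool = True) -> DecodingModel:
    """Assemble the joint model with seeded initialization."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
    streams = build_streams(stream_config, rng=rng)
    width = streams[0].out_features
    if use_gcn:
        if a_hat is None:
            raise ValueError("use_gcn=True requires a normalized adjacency")
        gcn_config = GCNConfig(**{**asdict_gcn(gcn_config), "width": width})
        gcn = build_gcn(gcn_config, a_hat, rng)
        return DecodingModel(streams, gcn, template, gcn_config.n_classes)
    return DecodingModel(streams, None, template,
                         gcn_config.n_classes, head_rng=rng)


def asdict_gcn(config: GCNConfig) -> dict:
    return {
        "n_blocks": config.n_blocks, "residual_type": config.residual_type,
        "width": config.width, "dropout": config.dropout,
        "n_classes": config.n_classes, "n_nodes": config.n_nodes,
        "seed": config.seed,
    }


def cross_entropy(label: int, scores: np.ndarray) -> float:
    """Cross-entropy H(p, q) = -sum_x p(x) log q(x) for one sample.

    p is the one-hot truth at 0-based ``label``; q = softmax(scores).
    """
    scores = np.asarray(scores, dtype=np.float64)
    loss, _ = nn.cross_entropy_loss(scores[None], np.array([label]))
    return loss


def _stack(scans: list[Scan]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.data for s in scans]).astype(np.float32)
    y = np.array([s.label - 1 for s in scans])  # 0-based internally
    return x, y


@dataclass
class TrainResult:
    model: DecodingModel
    history: list[dict]  # per-epoch train/val loss
    best_epoch: int


def train(model: DecodingModel, train_scans: list[Scan], val_scans: list[Scan],
          config: TrainConfig) -> TrainResult:
    """Jointly optimize all streams and the GCN; checkpoint best on validation.

    One Adam optimizer over every trainable parameter; per-epoch history of
    mean train loss and validation loss; parameters are restored to the best
    validation epoch before returning.
    """
    if not train_scans or not val_scans:
        raise ValueError("empty split role: need nonempty train and validation sets")
    x_tr, y_tr = _stack(train_scans)
    x_va, y_va = _stack(val_scans)
    params = model.params()
    batchnorms = nn.collect_batchnorms(model)
    opt = nn.Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(20,))
    )
    history: list[dict] = []
    best_val = np.inf
    best_state = nn.get_state(params, batchnorms)
    best_epoch = 0
    n = len(train_scans)
    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            scores = model.forward(x_tr[idx], training=True)
            loss, gscores = nn.cross_entropy_loss(scores, y_tr[idx])
            opt.zero_grad()
            model.backward(gscores)
            opt.step()
            losses.append(loss)
        val_losses = []
        for start in range(0, len(val_scans), config.batch_size):
            sl = slice(start, start + config.batch_size)
            scores = model.forward(x_va[sl], training=False)
            loss, _ = nn.cross_entropy_loss(scores, y_va[sl])
            val_losses.append(loss * len(range(*sl.indices(len(val_scans)))))
        train_loss = float(np.mean(losses))
        val_loss = float(np.sum(val_losses) / len(val_scans))
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = nn.get_state(params, batchnorms)
            best_epoch = epoch
    nn.set_state(params, best_state, batchnorms)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


def save_checkpoint(model: DecodingModel, path) -> None:
    """Serialize all trainable parameters and BN running moments (npz)."""
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.value
    for i, bn in enumerate(nn.collect_batchnorms(model)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(path, **arrays)


def load_checkpoint(model: DecodingModel, path) -> DecodingModel:
    """Restore a checkpoint into a model built with the same configuration."""
    with np.load(path) as data:
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
        for i, bn in enumerate(nn.collect_batchnorms(model)):
            bn.running_mean = data[f"bn_mean_{i}"].copy()
            bn.running_var = data[f"bn_var_{i}"].copy()
    return model


# -- metrics -------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class, from the multi-class confusion matrix."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_samples: int


def confusion_counts(predictions: np.ndarray, truths: np.ndarray,
                     n_classes: int) -> ConfusionCounts:
    """Per-class one-vs-rest counts. Labels are 0-based class indices."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape or predictions.size < 1:
        raise ValueError("predictions and truths must be equal-length, nonempty")
    for arr, name in ((predictions, "prediction"), (truths, "truth")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} label out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (truths, predictions), 1)
    tp = np.diag(cm).copy()
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = predictions.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_samples=predictions.size)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged precision/recall/F-score plus accuracy.

    Values are fractions in [0, 1]. ``undefined_precision`` /
    ``undefined_recall`` flag classes whose denominator was zero (the metric
    is reported as 0 there so averages stay defined).
    """

    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray
    class_accuracy: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f_score: float
    total_accuracy: float
    undefined_precision: list[int] = field(default_factory=list)
    undefined_recall: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f_score": self.f_score.tolist(),
            "class_accuracy": self.class_accuracy.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f_score": self.macro_f_score,
            "total_accuracy": self.total_accuracy,
            "undefined_precision": self.undefined_precision,
            "undefined_recall": self.undefined_recall,
        }


def metrics(counts: ConfusionCounts, beta: float = 1.0) -> MetricsReport:
    """Precision, recall, F-score and accuracy from one-vs-rest counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    F = (1+beta^2) P R / (beta^2 P + R); per-class accuracy
    = (TP+TN)/(TP+FP+TN+FN); total accuracy = sum TP / n.
    """
    tp, fp, tn, fn = (a.astype(float) for a in
                      (counts.tp, counts.fp, counts.tn, counts.fn))
    undef_p = [int(i) for i in np.where(tp + fp == 0)[0]]
    undef_r = [int(i) for i in np.where(tp + fn == 0)[0]]
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = beta**2 * precision + recall
        f_score = np.where(denom > 0,
                           (1 + beta**2) * precision * recall / np.maximum(denom, 1e-300),
                           0.0)
    class_accuracy = (tp + tn) / counts.n_samples
    return MetricsReport(
        precision=precision, recall=recall, f_score=f_score,
        class_accuracy=class_accuracy,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f_score=float(f_score.mean()),
        total_accuracy=float(tp.sum() / counts.n_samples),
        undefined_precision=undef_p, undefined_recall=undef_r,
    )


def evaluate(model: DecodingModel, scans: list[Scan], n_classes: int = 10) -> MetricsReport:
    """Predict every scan and compute the metrics report."""
    x, y = _stack(scans)
    preds = model.predict(x)
    return metrics(confusion_counts(preds, y, n_classes))


# -- full experiment -----------------------------------------------------


@dataclass
class ExperimentRecord:
    """Everything needed to reproduce one experiment run."""

    per_trial: list[dict]
    mean_total_accuracy: float
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {"per_trial": self.per_trial,
             "mean_total_accuracy": self.mean_total_accuracy,
             "config": self.config},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExperimentRecord":
        d = json.loads(text)
        return cls(per_trial=d["per_trial"],
                   mean_total_accuracy=d["mean_total_accuracy"],
                   config=d["config"])


def run_trial(dataset: SyntheticDataset, split: SplitScheme,
              stream_config: StreamConfig, gcn_config: GCNConfig,
              train_config: TrainConfig, use_gcn: bool = True,
              adjacency_mode: str = "weighted_pearson",
              omega: float = 3.0) -> dict:
    """One subject-rotation trial: normalize, build adjacency, train, test."""
    scans = normalize_by_subject(dataset.scans)
    by_role = {
        "train": [s for s in scans if s.subject in split.train_subjects],
        "val": [s for s in scans if s.subject == split.val_subject],
        "test": [s for s in scans if s.subject == split.test_subject],
    }
    for role, group in by_role.items():
        if not group:
            raise ValueError(f"empty {role} split in trial {split.trial}")
    a_hat = None
    adjacency = None
    if use_gcn:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=train_config.seed, spawn_key=(30, split.trial))
        )
        signals = training_roi_signals(by_role["train"], dataset.template)
        adjacency = build_adjacency(signals, omega=omega, mode=adjacency_mode, rng=rng)
        a_hat = normalize_adjacency(adjacency)
    model = build_model(dataset.template, a_hat, stream_config, gcn_config,
                        seed=train_config.seed * 1000 + split.trial, use_gcn=use_gcn)
    result = train(model, by_role["train"], by_role["val"], train_config)
    report = evaluate(model, by_role["test"], gcn_config.n_classes)
    return {
        "trial": split.trial,
        "split": {"train": list(split.train_subjects),
                  "val": split.val_subject, "test": split.test_subject},
        "adjacency": None if adjacency is None else adjacency.A.tolist(),
        "best_epoch": result.best_epoch,
        "history": result.history,
        "metrics": report.to_dict(),
    }


def run_experiment(dataset: SyntheticDataset, stream_config: StreamConfig,
                   gcn_config: GCNConfig, train_config: TrainConfig,
                   n_trials: int = 5, use_gcn: bool = True,
                   adjacency_mode: str = "weighted_pearson",
                   omega: float = 3.0) -> ExperimentRecord:
    """The multi-trial protocol: rotate subject roles, train, aggregate.

    Returns per-trial records (adjacency, loss history, metrics) and the mean
    test accuracy over trials, with the full resolved configuration.
    """
    subjects = sorted({s.subject for s in dataset.scans})
    splits = make_splits(subjects, n_trials)
    per_trial = [
        run_trial(dataset, split, stream_config, gcn_config, train_config,
                  use_gcn=use_gcn, adjacency_mode=adjacency_mode, omega=omega)
        for split in splits
    ]
    mean_acc = float(np.mean([t["metrics"]["total_accuracy"] for t in per_trial]))
    config = {
        "stream": {"layers": stream_config.layers
                   if isinstance(stream_config.layers, str) else "custom",
                   "feature_width": stream_config.feature_width,
                   "input_grid": list(stream_config.input_grid),
                   "shared_weights": stream_config.shared_weights},
        "gcn": asdict_gcn(gcn_config) if use_gcn else None,
        "use_gcn": use_gcn,
        "adjacency_mode": adjacency_mode,
        "omega": omega,
        "train": asdict(train_config),
        "generator": {**asdict(dataset.config),
                      "grid": list(dataset.config.grid)},
    }
    return ExperimentRecord(per_trial=per_trial,
                            mean_total_accuracy=mean_acc, config=config)
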