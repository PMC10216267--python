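"""Staged build-and-train controller for the modular classifier.

The network grows through five stages, ``A -> A+B -> A+B||C -> A+B||C+D ->
(A+B||C+D)||E``.  At each stage every previously trained SubNet is frozen
and only the newest SubNet plus the (fresh) classification head receive
gradient updates.  Because the frozen part of the network is deterministic
at evaluation, its feature maps are computed once per stage and cached, so
a stage's cost is essentially that of training the new small SubNet alone —
the computational saving the modular scheme is designed around.

Training policy per stage: Adam, learning rate dropped by 0.1 once half the
epochs are done, validation every ``validation_every`` iterations, early
stop after ``validation_patience`` consecutive validation checks above the
running minimum, and L2 regularization (0.0001) on the trainable parameters
only.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from . import nn
from .gramnet_core import (
    SUBNET_PRESETS,
    GraMNetGraph,
    SubNetModule,
    _Leaf,
    _Parallel,
    _Series,
    build_subnet,
    combine_parallel,
    combine_series,
    graph_from_subnet,
    one_hot,
)
from .losses import cross_entropy_risk_and_dlogits
from .phantomgen import BENIGN, MALIGNANT, load_sample

__all__ = [
    "StageTrainConfig",
    "SECTION4_PRESET",
    "StageHistory",
    "ValidationPatience",
    "stage_lr",
    "train_stage",
    "build_and_train_gramnet",
    "predict_class",
    "manifest_to_arrays",
    "CLASSES",
]

CLASSES = (BENIGN, MALIGNANT)


@dataclasses.dataclass(frozen=True)
class StageTrainConfig:
    initial_lr: float = 1e-3
    lr_drop_factor: float = 0.1
    epochs: int = 8
    batch_size: int = 16
    validation_every: int = 50   # iterations between validation checks
    validation_patience: int = 50  # checks above the minimum before stopping
    l2: float = 1e-4
    max_iterations: int | None = None
    lr_drop_at_iteration: int | None = None  # overrides the half-epoch drop
    normalize: str = "classes"
    warm_start_head: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("initial_lr, epochs and batch_size must be positive")
        if not 0 < self.lr_drop_factor < 1:
            raise ValueError("lr_drop_factor must be in (0, 1)")


#: the alternative iteration-based protocol (500 iterations, LR 1e-4,
#: drop x0.1 after 20 iterations, batch 16)
SECTION4_PRESET = StageTrainConfig(initial_lr=1e-4, batch_size=16, epochs=10 ** 6,
                                   max_iterations=500, lr_drop_at_iteration=20)


def stage_lr(epoch: int, cfg: StageTrainConfig) -> float:
    """Learning rate for a 1-based epoch under the half-epoch drop policy.

    The rate is ``initial_lr`` until half the epochs are done, then
    ``initial_lr * lr_drop_factor``; the drop epoch is
    ``max(2, ceil(epochs / 2))``.
    """
    drop_epoch = max(2, math.ceil(cfg.epochs / 2))
    return cfg.initial_lr * (cfg.lr_drop_factor if epoch >= drop_epoch else 1.0)


class ValidationPatience:
    """Early-stop counter: stop once the validation loss has exceeded its
    running minimum for ``patience`` consecutive checks."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.bad_checks = 0

    def update(self, val_loss: float) -> bool:
        """Record one validation check; returns True when training should stop."""
        if val_loss > self.best:
            self.bad_checks += 1
        else:
            self.best = val_loss
            self.bad_checks = 0
        return self.bad_checks >= self.patience


@dataclasses.dataclass
class StageHistory:
    stage_name: str
    train_loss: list = dataclasses.field(default_factory=list)
    lr: list = dataclasses.field(default_factory=list)
    val_iterations: list = dataclasses.field(default_factory=list)
    val_loss: list = dataclasses.field(default_factory=list)
    val_accuracy: list = dataclasses.field(default_factory=list)
    stopped_early: bool = False
    trainable_parameters: int = 0
    total_parameters: int = 0

    @property
    def final_val_accuracy(self) -> float | None:
        return self.val_accuracy[-1] if self.val_accuracy else None


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        x, y = data
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        return x, np.asarray(y, dtype=np.float32)
    return manifest_to_arrays(data)


def manifest_to_arrays(manifest, split: str | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Load a manifest's images and one-hot labels as (N,H,W,D) / (N,M)."""
    records = manifest.records
    if split is not None:
        records = records[records["split"] == split]
    xs, labels = [], []
    for _, rec in records.iterrows():
        s = load_sample(rec, root=manifest.root)
        img = s.image if s.image.ndim == 3 else s.image[..., None]
        xs.append(img)
        labels.append(s.label)
    return np.stack(xs).astype(np.float32), one_hot(labels, CLASSES)


def _batched_forward(fn, x: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = [fn(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def train_stage(graph: GraMNetGraph, train_data, val_data,
                cfg: StageTrainConfig = StageTrainConfig(),
                ) -> tuple[GraMNetGraph, StageHistory]:
    """Train the single unfrozen SubNet (plus head) of ``graph``.

    ``train_data``/``val_data`` are either ``(X, y_onehot)`` array pairs in
    (N, H, W, D) layout or dataset manifests.  Frozen feature maps feeding
    the trainable SubNet are precomputed once for the whole dataset.
    """
    from .gramnet_core import count_parameters

    trainables = graph.trainable_subnets()
    if len(trainables) != 1:
        raise ValueError(f"expected exactly one unfrozen SubNet, found {len(trainables)}")
    tsub = trainables[0]
    root = graph.root
    if root.subnet is not tsub:
        raise ValueError("the trainable SubNet must be the newest (root-level) one")

    xtr, ytr = _as_arrays(train_data)
    xva, yva = _as_arrays(val_data)
    if len(xtr) == 0 or len(xva) == 0:
        raise ValueError("train and validation sets must be non-empty")
    xtr_n = np.ascontiguousarray(xtr.transpose(0, 3, 1, 2))
    xva_n = np.ascontiguousarray(xva.transpose(0, 3, 1, 2))

    # cache everything the frozen part of the network produces
    if isinstance(root, _Leaf):
        mode = "leaf"
        tr_in, va_in = xtr_n, xva_n
    elif isinstance(root, _Series):
        mode = "series"
        tr_in = _batched_forward(lambda b: root.left.forward(b), xtr_n)
        va_in = _batched_forward(lambda b: root.left.forward(b), xva_n)
    elif isinstance(root, _Parallel):
        mode = "parallel"
        tr_left = _batched_forward(lambda b: root.left.forward(b), xtr_n)
        va_left = _batched_forward(lambda b: root.left.forward(b), xva_n)
        tr_in, va_in = xtr_n, xva_n
    else:  # pragma: no cover
        raise TypeError(f"unknown graph node {type(root)!r}")

    def forward(xb, left_b=None, train=False):
        feats = tsub.forward(xb, train=train)
        if mode == "parallel":
            feats = root.join(left_b, feats, train=train)
        return graph.head.forward(feats, train=train)

    def evaluate(x_in, y, left=None):
        losses, correct = 0.0, 0
        n = len(x_in)
        for i in range(0, n, 64):
            sl = slice(i, i + 64)
            lb = left[sl] if left is not None else None
            logits = forward(x_in[sl], lb, train=False)
            loss, _ = cross_entropy_risk_and_dlogits(logits, y[sl], cfg.normalize)
            losses += loss * (min(i + 64, n) - i)
            correct += int((logits.argmax(1) == y[sl].argmax(1)).sum())
        return losses / n, correct / n

    params = tsub.parameters() + graph.head.parameters()
    opt = nn.Adam(params, lr=cfg.initial_lr, weight_decay=cfg.l2)
    hist = StageHistory(stage_name=graph.stage_name,
                        trainable_parameters=count_parameters([tsub, graph.head]),
                        total_parameters=count_parameters(graph))
    patience = ValidationPatience(cfg.validation_patience)
    rng = np.random.default_rng(cfg.seed)

    iteration = 0
    stop = False
    for epoch in range(1, cfg.epochs + 1):
        if cfg.lr_drop_at_iteration is None:
            opt.lr = stage_lr(epoch, cfg)
        order = rng.permutation(len(xtr))
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if cfg.lr_drop_at_iteration is not None and \
                    iteration >= cfg.lr_drop_at_iteration:
                opt.lr = cfg.initial_lr * cfg.lr_drop_factor
            left_b = (tr_left[idx] if mode == "parallel" else None)
            logits = forward(tr_in[idx], left_b, train=True)
            loss, dlog = cross_entropy_risk_and_dlogits(logits, ytr[idx], cfg.normalize)
            dfeats = graph.head.backward(dlog)
            if mode == "parallel":
                tsub.backward(root.split_grad_right(dfeats), need_dx=False)
            else:
                tsub.backward(dfeats, need_dx=False)
            opt.step()
            opt.zero_grad()
            iteration += 1
            hist.train_loss.append(float(loss))
            hist.lr.append(opt.lr)
            if iteration % cfg.validation_every == 0:
                vloss, vacc = evaluate(va_in, yva,
                                       va_left if mode == "parallel" else None)
                hist.val_iterations.append(iteration)
                hist.val_loss.append(vloss)
                hist.val_accuracy.append(vacc)
                if patience.update(vloss):
                    hist.stopped_early = True
                    stop = True
            if cfg.max_iterations is not None and iteration >= cfg.max_iterations:
                stop = True
            if stop:
                break
        if stop:
            break

    # final validation check so the history always ends with an accuracy
    vloss, vacc = evaluate(va_in, yva, va_left if mode == "parallel" else None)
    hist.val_iterations.append(iteration)
    hist.val_loss.append(vloss)
    hist.val_accuracy.append(vacc)
    graph.trained = True
    return graph, hist


_STAGE_PLAN = (("A", "initial"), ("B", "series"), ("C", "parallel"),
               ("D", "series"), ("E", "parallel"))


def build_and_train_gramnet(train_data, val_data, n_classes: int = 2,
                            cfg: StageTrainConfig = StageTrainConfig(),
                            seed: int = 0, subnet_presets=None,
                            ) -> tuple[GraMNetGraph, list[StageHistory]]:
    """Run the five growth stages A, A+B, A+B||C, A+B||C+D, (A+B||C+D)||E.

    After each stage the whole existing network is frozen; the next SubNet
    (and a fresh head) is trained on top.  Returns the final graph and one
    history per stage.
    """
    presets = subnet_presets or SUBNET_PRESETS
    xtr, _ = _as_arrays(train_data)
    in_channels = xtr.shape[-1]

    def child_seed(k: int) -> int:
        return (seed * 1000003 + k) % (2 ** 31)

    graph = None
    histories: list[StageHistory] = []
    for k, (name, how) in enumerate(_STAGE_PLAN):
        s = child_seed(k)
        if how == "initial":
            sub = build_subnet(presets[name], in_channels, seed=s)
            graph = graph_from_subnet(sub, n_classes, seed=s)
        elif how == "series":
            sub = build_subnet(presets[name], graph.root.out_channels, seed=s)
            graph = combine_series(graph, sub, seed=s)
        else:
            sub = build_subnet(presets[name], in_channels, seed=s)
            old_head = graph.head
            graph = combine_parallel(graph, sub, seed=s)
            if cfg.warm_start_head:
                # parallel joins keep the old channels as a prefix, so the
                # previous head slots straight into the first columns
                graph.head.fc.weight.data[:, :old_head.in_channels] = \
                    old_head.fc.weight.data
                graph.head.fc.bias.data[:] = old_head.fc.bias.data
        stage_cfg = dataclasses.replace(cfg, seed=child_seed(100 + k))
        graph, hist = train_stage(graph, train_data, val_data, stage_cfg)
        histories.append(hist)
    return graph, histories


def predict_class(graph: GraMNetGraph, images: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels and positive-class scores for (N, H, W, D) images.

    Ties in the softmax break toward the lower class index.  Scores are the
    softmax probability of the last (positive) class for binary problems,
    otherwise the maximum class probability.
    """
    if not getattr(graph, "trained", False):
        warnings.warn("graph has not been trained; predictions will be arbitrary")
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    probs = _batched_forward(
        lambda b: nn.softmax(graph.forward_logits(
            np.ascontiguousarray(b.transpose(0, 3, 1, 2)))), x)
    labels = probs.argmax(axis=1)
    scores = probs[:, 1] if graph.head.n_classes == 2 else probs.max(axis=1)
    return labels, scores
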