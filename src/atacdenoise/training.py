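"""Chromosome-split training with per-epoch shuffling and best-epoch selection.

Examples are partitioned by chromosome into train / validation / holdout sets
(default: validation on chr20 for human layouts or chr11 for mouse, holdout on
chr10, everything else trains). Training shuffles examples at the start of
every epoch, runs mini-batches through Adam, evaluates the validation set at
the end of each epoch, and returns the parameters from the epoch with the best
validation performance (lowest total validation loss by default, highest
validation AUPRC optionally).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .metrics import classification_metrics
from .model import (
    LossWeights,
    TrainedModel,
    composite_loss,
    composite_loss_grad,
)
from .preprocess import TrainingExample

__all__ = ["SplitSpec", "TrainConfig", "TrainingRun", "split_examples", "train", "validate"]


@dataclass(frozen=True)
class SplitSpec:
    """Chromosome assignment for train / validation / holdout sets.

    Chromosomes in neither special set are training chromosomes. The default
    validation set lists both the human (chr20) and mouse (chr11) conventions;
    only names present in the data matter.
    """

    validation_chroms: tuple[str, ...] = ("chr20", "chr11")
    holdout_chroms: tuple[str, ...] = ("chr10",)

    def __post_init__(self) -> None:
        overlap = set(self.validation_chroms) & set(self.holdout_chroms)
        if overlap:
            raise ValueError(f"chromosomes in both validation and holdout: {overlap}")

    def assign(self, chrom: str) -> str:
        if chrom in self.validation_chroms:
            return "validation"
        if chrom in self.holdout_chroms:
            return "holdout"
        return "train"


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (paper-reference defaults).

    lr 2e-4, 25 epochs, batches of 64, Adam with standard betas; examples
    reshuffled from ``seed`` every epoch. ``select_on`` picks the checkpoint
    criterion: "loss" (lowest total validation loss) or "auprc" (highest
    validation AUPRC). ``central_loss_only`` restricts the loss to the central
    interval of each window, excluding the padding.
    """

    lr: float = 2e-4
    epochs: int = 25
    batch_size: int = 64
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    select_on: str = "loss"
    central_loss_only: bool = False
    prior_bias_init: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.select_on not in ("loss", "auprc"):
            raise ValueError("select_on must be 'loss' or 'auprc'")


@dataclass
class TrainingRun:
    """Per-epoch history plus the selected checkpoint epoch."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    wall_time_s: float = 0.0
    manifest: dict = field(default_factory=dict)


def split_examples(
    examples: list[TrainingExample], splitspec: SplitSpec
) -> tuple[list[TrainingExample], list[TrainingExample], list[TrainingExample]]:
    """Partition examples by chromosome into (train, validation, holdout)."""
    buckets: dict[str, list[TrainingExample]] = {
        "train": [], "validation": [], "holdout": [],
    }
    for ex in examples:
        buckets[splitspec.assign(ex.chrom)].append(ex)
    return buckets["train"], buckets["validation"], buckets["holdout"]


def _stack_batch(batch: list[TrainingExample]):
    x = np.stack([ex.input for ex in batch]).astype(np.float32)
    ts = np.stack([ex.target_signal for ex in batch]).astype(np.float64)
    tl = np.stack([ex.target_labels for ex in batch]).astype(np.float64)
    return x, ts, tl


def _central(a: np.ndarray, pad: int) -> np.ndarray:
    return a[:, pad:-pad] if pad else a


def validate(
    model: TrainedModel,
    examples: list[TrainingExample],
    config: TrainConfig,
) -> dict:
    """Loss components plus AUPRC of labels vs probabilities over the set."""
    if not examples:
        raise ValueError("validation requires a nonempty example set")
    totals = np.zeros(4)
    n = 0
    probs: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for i in range(0, len(examples), config.batch_size):
        batch = examples[i : i + config.batch_size]
        x, ts, tl = _stack_batch(batch)
        sig, prob = model.forward(x, train=False)
        if config.central_loss_only:
            pad = batch[0].pad
            sig, prob = _central(sig, pad), _central(prob, pad)
            ts, tl = _central(ts, pad), _central(tl, pad)
        loss = composite_loss(sig, prob, ts, tl, config.weights)
        totals += np.array(loss) * len(batch)
        n += len(batch)
        probs.append(prob.ravel())
        labels.append(tl.ravel())
    totals /= n
    all_labels = np.concatenate(labels)
    auprc = auroc = None
    if 0 < all_labels.sum() < all_labels.size:
        auprc, auroc = classification_metrics(np.concatenate(probs), all_labels)
    return {
        "loss": float(totals[0]),
        "mse": float(totals[1]),
        "pearson_loss": float(totals[2]),
        "bce": float(totals[3]),
        "auprc": auprc,
        "auroc": auroc,
    }


def train(
    model: TrainedModel,
    train_examples: list[TrainingExample],
    val_examples: list[TrainingExample],
    config: TrainConfig = TrainConfig(),
) -> tuple[TrainedModel, TrainingRun]:
    """Train in place and return the model restored to its best-epoch parameters.

    Runs exactly ``config.epochs`` epochs, reshuffling the training examples
    with a seeded generator at the start of each. After every epoch the
    validation set is evaluated and the parameters of the epoch with the best
    validation performance are kept. A non-finite loss aborts with a
    diagnostic.
    """
    if not train_examples:
        raise ValueError("training requires a nonempty train set")
    if not val_examples:
        raise ValueError("training requires a nonempty validation set")
    rng = np.random.Generator(np.random.PCG64(config.seed))
    if config.prior_bias_init and not np.any(model.cls_out.W):
        # prior-probability initialization: start the (still uncommitted)
        # classification head at the label prevalence, so early gradients are
        # discriminative rather than rate-matching
        prev = float(np.mean([ex.target_labels.mean() for ex in train_examples]))
        prev = min(max(prev, 1e-4), 1 - 1e-4)
        model.cls_out.b[...] = np.log(prev / (1.0 - prev))
    optimizer = model.make_optimizer(lr=config.lr)
    run = TrainingRun(manifest={
        "lr": config.lr,
        "epochs": config.epochs,
        "batch_size": config.batch_size,
        "weights": [config.weights.w_mse, config.weights.w_pearson, config.weights.w_bce],
        "shuffle_seed": config.seed,
        "init_seed": model.config.seed,
        "select_on": config.select_on,
        "central_loss_only": config.central_loss_only,
        "optimizer": "adam(beta1=0.9, beta2=0.999, eps=1e-8)",
        "n_train": len(train_examples),
        "n_val": len(val_examples),
    })
    t0 = time.perf_counter()
    best_state: list[np.ndarray] | None = None
    best_key: float | None = None

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_examples))
        epoch_totals = np.zeros(4)
        n_seen = 0
        for i in range(0, len(order), config.batch_size):
            batch = [train_examples[j] for j in order[i : i + config.batch_size]]
            x, ts, tl = _stack_batch(batch)
            optimizer.zero_grad()
            sig, prob = model.forward(x, train=True)
            pad = batch[0].pad if config.central_loss_only else 0
            sig_l, prob_l = _central(sig, pad), _central(prob, pad)
            ts_l, tl_l = _central(ts, pad), _central(tl, pad)
            loss = composite_loss(sig_l, prob_l, ts_l, tl_l, config.weights)
            if not np.isfinite(loss[0]):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"total={loss[0]}, mse={loss[1]}, pearson={loss[2]}, bce={loss[3]}"
                )
            d_sig, d_prob = composite_loss_grad(sig_l, prob_l, ts_l, tl_l, config.weights)
            if pad:
                d_sig = np.pad(d_sig, ((0, 0), (pad, pad)))
                d_prob = np.pad(d_prob, ((0, 0), (pad, pad)))
            model.backward(d_sig, d_prob)
            optimizer.step()
            epoch_totals += np.array(loss) * len(batch)
            n_seen += len(batch)
        epoch_totals /= n_seen
        val = validate(model, val_examples, config)
        record = {
            "epoch": epoch,
            "train_loss": float(epoch_totals[0]),
            "train_mse": float(epoch_totals[1]),
            "train_pearson_loss": float(epoch_totals[2]),
            "train_bce": float(epoch_totals[3]),
            "val": val,
            "elapsed_s": time.perf_counter() - t0,
        }
        run.epochs.append(record)
        if config.select_on == "auprc" and val["auprc"] is not None:
            key = -val["auprc"]
        else:
            key = val["loss"]
        if best_key is None or key < best_key:
            best_key = key
            best_state = model.state_arrays()
            run.best_epoch = epoch

    assert best_state is not None
    model.load_state_arrays(best_state)
    run.wall_time_s = time.perf_counter() - t0
    run.manifest["best_epoch"] = run.best_epoch
    model.manifest.update(run.manifest)
    return model, run
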