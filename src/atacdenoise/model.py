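"""The dilated residual denoising/peak-calling network and its composite loss.

Architecture: the multi-channel input passes through R residual blocks (each
three dilated same-length convolutions with ReLUs plus a skip connection) and
a single-filter regression output layer with ReLU, producing the denoised
coverage (nonnegative, one value per base). That one-channel denoised signal
is then passed through S further residual blocks and a single-filter
classification output layer with a sigmoid, producing the per-base probability
of lying in a peak. No batch normalization anywhere.

The training loss is a weighted sum of three per-window terms averaged over
the batch: MSE and 1 - Pearson r on the regression output, binary
cross-entropy on the classification output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import Adam, Conv1d, Log1p, ReLU, ResidualBlock, Sigmoid

__all__ = [
    "ModelConfig",
    "LossWeights",
    "TrainedModel",
    "build_model",
    "receptive_field",
    "composite_loss",
    "load_model",
]

_CHECKPOINT_MAGIC = "atacdenoise-checkpoint"
_CHECKPOINT_VERSION = 1

#: epsilon clamping probabilities inside the BCE term
BCE_EPS = 1e-7
#: epsilon guarding the Pearson denominator
PEARSON_EPS = 1e-8


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 15 filters per convolution,
    kernel size 51, dilation 8, five residual blocks in the regression stage
    (15 conv layers, receptive field 6001 bp ~ 6 kb) and two in the
    classification stage. ``in_channels`` is 1 for plain coverage input, 3
    with forward/reverse motif indicator channels.
    """

    in_channels: int = 1
    filters: int = 15
    kernel: int = 51
    dilation: int = 8
    n_blocks_regression: int = 5
    n_blocks_classification: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        for name in ("in_channels", "filters", "kernel", "dilation",
                     "n_blocks_regression", "n_blocks_classification"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class LossWeights:
    """Relative weights of the three loss terms (all default to 1)."""

    w_mse: float = 1.0
    w_pearson: float = 1.0
    w_bce: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_mse, self.w_pearson, self.w_bce) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_mse == self.w_pearson == self.w_bce == 0:
            raise ValueError("at least one loss weight must be positive")


def receptive_field(config: ModelConfig, stage: str = "regression") -> int:
    """Receptive field in bp of one output base (odd integer).

    Each of the 3*R (or 3*S) stacked dilated convolutions widens the field by
    (kernel - 1) * dilation; skip connections and the kernel-1 output layers
    add nothing. 1 + 15 * 50 * 8 = 6001 bp at the default configuration.
    """
    if stage == "regression":
        n_layers = 3 * config.n_blocks_regression
    elif stage == "classification":
        n_layers = 3 * config.n_blocks_classification
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return 1 + n_layers * (config.kernel - 1) * config.dilation


class TrainedModel:
    """The network with its parameters and training manifest.

    Forward is deterministic given parameters and input; checkpoints reload to
    bit-identical forward outputs.
    """

    def __init__(self, config: ModelConfig, manifest: dict | None = None):
        self.config = config
        self.manifest = manifest or {}
        rng = np.random.Generator(np.random.PCG64(config.seed))
        c = config
        self.reg_blocks = []
        in_ch = c.in_channels
        for _ in range(c.n_blocks_regression):
            self.reg_blocks.append(
                ResidualBlock(in_ch, c.filters, c.kernel, c.dilation, rng)
            )
            in_ch = c.filters
        self.reg_out = Conv1d(c.filters, 1, 1, 1, rng)
        self.reg_relu = ReLU()
        self.cls_blocks = []
        in_ch = 1  # the classification stage consumes the denoised signal itself
        for _ in range(c.n_blocks_classification):
            self.cls_blocks.append(
                ResidualBlock(in_ch, c.filters, c.kernel, c.dilation, rng)
            )
            in_ch = c.filters
        self.cls_out = Conv1d(c.filters, 1, 1, 1, rng)
        # zero-init the classification output so the head starts uncommitted
        # (probability 0.5 everywhere): the cross-entropy gradient then sets
        # the ranking direction instead of an arbitrary random function
        self.cls_out.W[...] = 0.0
        self.sigmoid = Sigmoid()
        self.compress = Log1p()

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        return [*self.reg_blocks, self.reg_out, *self.cls_blocks, self.cls_out]

    def params(self) -> list[dict]:
        out: list[dict] = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def make_optimizer(self, lr: float = 2e-4) -> Adam:
        return Adam(self.params(), lr=lr)

    # -- forward / backward -------------------------------------------------

    def forward(
        self, x: np.ndarray, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run the network on a batch (B, C, W); returns (signal, prob), each (B, W)."""
        from . import nn as _nn

        x = np.asarray(x, dtype=_nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        h = x
        for block in self.reg_blocks:
            h = block.forward(h, train)
        signal = self.reg_relu.forward(self.reg_out.forward(h, train), train)
        # log-compress the (nonnegative) denoised signal before the
        # classification stage: peak probability stays a monotone-stable
        # function of the denoised coverage, and the stage's pre-activations
        # remain in a trainable range across the coverage dynamic range
        h2 = self.compress.forward(signal, train)
        for block in self.cls_blocks:
            h2 = block.forward(h2, train)
        prob = self.sigmoid.forward(self.cls_out.forward(h2, train), train)
        return signal[:, 0, :], prob[:, 0, :]

    def backward(self, d_signal: np.ndarray, d_prob: np.ndarray) -> None:
        """Backpropagate loss gradients w.r.t. the two outputs (each (B, W))."""
        from . import nn as _nn

        d = self.sigmoid.backward(np.asarray(d_prob, dtype=_nn.DTYPE)[:, None, :])
        d = self.cls_out.backward(d)
        for block in reversed(self.cls_blocks):
            d = block.backward(d)
        d = self.compress.backward(d)
        # the classification stage reads the regression output: gradients add
        d_sig_total = d + np.asarray(d_signal, dtype=_nn.DTYPE)[:, None, :]
        d = self.reg_relu.backward(d_sig_total)
        d = self.reg_out.backward(d)
        for block in reversed(self.reg_blocks):
            d = block.backward(d)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i}"] = p["value"]
        header = {
            "magic": _CHECKPOINT_MAGIC,
            "version": _CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "manifest": self.manifest,
        }
        arrays["header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:  # explicit handle: no implicit .npz suffix
            np.savez(fh, **arrays)

    def state_arrays(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p["value"].shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p["value"][...] = a


def build_model(config: ModelConfig) -> TrainedModel:
    """Instantiate an untrained model with deterministic seed-derived init."""
    return TrainedModel(config)


def load_model(path) -> TrainedModel:
    """Reload a checkpoint written by :meth:`TrainedModel.save`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("magic") != _CHECKPOINT_MAGIC:
            raise ValueError(f"{path}: not an atacdenoise checkpoint")
        if header.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"{path}: unsupported checkpoint version")
        model = TrainedModel(ModelConfig(**header["config"]), header["manifest"])
        n = len(model.params())
        model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    return model


# ---------------------------------------------------------------------------
# composite loss


def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a[None] if a.ndim == 1 else a


def composite_loss(
    pred_signal: np.ndarray,
    pred_prob: np.ndarray,
    target_signal: np.ndarray,
    target_labels: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> tuple[float, float, float, float]:
    """Weighted MSE + (1 - Pearson r) + BCE, per window, averaged over batch.

    Returns ``(total, mse, pearson_loss, bce)``. If either vector of a
    window's Pearson term is constant, r is defined as 0 (loss contribution
    1); probabilities are clamped to [eps, 1-eps] inside the BCE.
    """
    ps, pp = _as_batch(pred_signal), _as_batch(pred_prob)
    ts, tl = _as_batch(target_signal), _as_batch(target_labels)
    if not (ps.shape == pp.shape == ts.shape == tl.shape):
        raise ValueError("loss inputs must share one shape")
    B, W = ps.shape

    mse = float(np.mean((ps - ts) ** 2))

    a = ps - ps.mean(axis=1, keepdims=True)
    b = ts - ts.mean(axis=1, keepdims=True)
    na = np.sqrt((a**2).sum(axis=1))
    nb = np.sqrt((b**2).sum(axis=1))
    denom = na * nb
    r = np.where(denom > PEARSON_EPS, (a * b).sum(axis=1) / (denom + PEARSON_EPS), 0.0)
    pearson_loss = float(np.mean(1.0 - r))

    p = np.clip(pp, BCE_EPS, 1.0 - BCE_EPS)
    bce = float(-np.mean(tl * np.log(p) + (1.0 - tl) * np.log(1.0 - p)))

    total = weights.w_mse * mse + weights.w_pearson * pearson_loss + weights.w_bce * bce
    return total, mse, pearson_loss, bce


def composite_loss_grad(
    pred_signal: np.ndarray,
    pred_prob: np.ndarray,
    target_signal: np.ndarray,
    target_labels: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the composite loss w.r.t. the two network outputs.

    The returned ``d_signal`` covers only the MSE and Pearson terms; the BCE
    path into the regression output flows through the classification stage
    during network backprop.
    """
    ps, pp = _as_batch(pred_signal), _as_batch(pred_prob)
    ts, tl = _as_batch(target_signal), _as_batch(target_labels)
    B, W = ps.shape

    d_signal = weights.w_mse * 2.0 * (ps - ts) / (B * W)

    a = ps - ps.mean(axis=1, keepdims=True)
    b = ts - ts.mean(axis=1, keepdims=True)
    na = np.sqrt((a**2).sum(axis=1, keepdims=True))
    nb = np.sqrt((b**2).sum(axis=1, keepdims=True))
    denom = na * nb
    ok = denom > PEARSON_EPS
    r = np.where(ok, (a * b).sum(axis=1, keepdims=True) / (denom + PEARSON_EPS), 0.0)
    # d(1-r)/d pred = -(b/|a||b| - r a/|a|^2); zero where r is pinned to 0.
    # (b and a are centered, so the mean-subtraction Jacobian term vanishes.)
    dr = np.where(
        ok,
        b / (denom + PEARSON_EPS) - r * a / (na**2 + PEARSON_EPS),
        0.0,
    )
    d_signal = d_signal - weights.w_pearson * dr / B

    p = np.clip(pp, BCE_EPS, 1.0 - BCE_EPS)
    d_prob = weights.w_bce * (-(tl / p) + (1.0 - tl) / (1.0 - p)) / (B * W)
    # outside the clamp range the loss is constant in pp
    d_prob = np.where((pp > BCE_EPS) & (pp < 1.0 - BCE_EPS), d_prob, 0.0)
    return d_signal, d_prob
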