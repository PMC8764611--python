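"""Residual U-Net configuration, shape arithmetic and the estimator.

``ModelConfig`` captures the architecture family: ``n_blocks`` residual
blocks per side (2-5), ``convs_per_block`` convolutions per residual
unit (2-4), and a base filter count that doubles at every encoder level
(so the default 4-block/base-32 network runs 32-64-128-256 down the
encoder with a 512-channel bridge at 1/16 of the input resolution).

``ResidualUNetSegmenter`` wraps the network in the scikit-learn
estimator protocol: ``fit(X, y)`` on stacks of (H, W, 3) inputs with
binary masks, ``predict_proba`` / ``predict`` for per-pixel maps, and
``score`` returning mean IoU under the 0/1 conventions for fluid-free
slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator

from .nn import ResUNet

ALLOWED_BLOCKS = (2, 3, 4, 5)
ALLOWED_CONVS = (2, 3, 4)


@dataclass(frozen=True)
class ModelConfig:
    """Residual U-Net topology parameters."""

    n_blocks: int = 4
    convs_per_block: int = 2
    base_filters: int = 32
    kernel_size: int = 3
    input_size: int = 256
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks not in ALLOWED_BLOCKS:
            raise ValueError(
                f"n_blocks={self.n_blocks} unsupported; allowed: {ALLOWED_BLOCKS}"
            )
        if self.convs_per_block not in ALLOWED_CONVS:
            raise ValueError(
                f"convs_per_block={self.convs_per_block} unsupported; "
                f"allowed: {ALLOWED_CONVS}"
            )
        if self.base_filters <= 0 or self.input_size <= 0:
            raise ValueError("base_filters and input_size must be positive")
        if self.input_size % 2**self.n_blocks != 0:
            raise ValueError(
                f"input_size={self.input_size} must be divisible by "
                f"2^n_blocks={2 ** self.n_blocks}"
            )


class LayerShape(NamedTuple):
    name: str
    output: tuple[int, int, int]  # (height, width, channels)


def layer_shapes(config: ModelConfig) -> list[LayerShape]:
    """Declared output shape of every layer, by pure arithmetic.

    Lists the input, each residual block's main-path convolutions, the
    1x1 output convolution and the sigmoid layer, in forward order.
    """
    shapes: list[LayerShape] = [
        LayerShape("input", (config.input_size, config.input_size, config.in_channels))
    ]
    d = config.n_blocks
    size = config.input_size
    for i in range(d):
        ch = config.base_filters * 2**i
        if i > 0:
            size //= 2
        for j in range(config.convs_per_block):
            shapes.append(
                LayerShape(
                    f"encoder/residual_block_{i + 1}/conv_{j + 1}", (size, size, ch)
                )
            )
    size //= 2
    bridge_ch = config.base_filters * 2**d
    for j in range(config.convs_per_block):
        shapes.append(
            LayerShape(f"bridge/residual_block_{d + 1}/conv_{j + 1}", (size, size, bridge_ch))
        )
    for k, i in enumerate(range(d - 1, -1, -1)):
        size *= 2
        ch = config.base_filters * 2**i
        for j in range(config.convs_per_block):
            shapes.append(
                LayerShape(
                    f"decoder/residual_block_{d + 2 + k}/conv_{j + 1}", (size, size, ch)
                )
            )
    shapes.append(LayerShape("output/conv_1x1", (size, size, 1)))
    shapes.append(LayerShape("output/sigmoid", (size, size, 1)))
    return shapes


def build_model(config: ModelConfig) -> ResUNet:
    """Construct the network with seeded He-uniform initial weights."""
    return ResUNet(
        n_blocks=config.n_blocks,
        convs_per_block=config.convs_per_block,
        base_filters=config.base_filters,
        kernel_size=config.kernel_size,
        input_size=config.input_size,
        in_channels=config.in_channels,
        seed=config.seed,
    )


def realized_layer_shapes(net: ResUNet) -> dict[str, tuple[int, int, int]]:
    """Run one forward pass and record each convolution's tensor shape."""
    x = np.zeros((1, net.input_size, net.input_size, net.in_channels), dtype=np.float32)
    net.forward_logits(x, training=False)
    return {conv.name: conv.last_output_shape for conv in net.conv_layers()}


def count_parameters(net: ResUNet) -> tuple[int, int]:
    """(trainable, non-trainable) parameter counts.

    Trainable: convolution weights/biases and BN scale/shift.
    Non-trainable: BN running statistics.
    """
    trainable = sum(arr.size for _, arr, _ in net.named_params())
    non_trainable = sum(arr.size for _, arr in net.named_buffers())
    return trainable, non_trainable


class ResidualUNetSegmenter(BaseEstimator):
    """Scikit-learn-style residual U-Net for pixel-wise ascites maps.

    Parameters mirror the architecture/training protocol: Adam with
    ``learning_rate`` 1e-4 and ``batch_size`` 16, equal-weight BCE+Dice
    loss.  Fitted attributes: ``net_`` (the trained network),
    ``loss_curve_`` (per-epoch training loss), ``n_epochs_``.
    """

    def __init__(
        self,
        n_blocks: int = 4,
        convs_per_block: int = 2,
        base_filters: int = 32,
        input_size: int = 256,
        learning_rate: float = 1e-4,
        batch_size: int = 16,
        max_epochs: int = 10,
        bce_weight: float = 1.0,
        dice_weight: float = 1.0,
        random_state: int = 0,
    ):
        self.n_blocks = n_blocks
        self.convs_per_block = convs_per_block
        self.base_filters = base_filters
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.bce_weight = bce_weight
        self.dice_weight = dice_weight
        self.random_state = random_state

    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[3] != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"X must be (n, size, size, 3), got {X.shape}")
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError("X values must lie in [0, 1]")
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ValueError(f"y must be (n, size, size) matching X, got {y.shape}")
        return X, (y > 0.5).astype(np.float32)

    def fit(self, X, y):
        from .training import TrainConfig, train_loop  # local import: no cycle

        X, y = self._validate(X, y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        config = ModelConfig(
            n_blocks=self.n_blocks,
            convs_per_block=self.convs_per_block,
            base_filters=self.base_filters,
            input_size=X.shape[1],
            seed=self.random_state,
        )
        self.config_ = config
        self.net_ = build_model(config)
        train_cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            bce_weight=self.bce_weight,
            dice_weight=self.dice_weight,
            seed=self.random_state,
        )
        history = train_loop(self.net_, X, y, train_cfg, epochs=self.max_epochs)
        self.loss_curve_ = [h["train_cost"] for h in history]
        self.n_epochs_ = len(history)
        return self

    def predict_proba(self, X):
        """Per-pixel ascites probability maps, shape (n, size, size)."""
        self._check_fitted()
        X = self._validate(X)
        return self.net_.predict_proba(X)

    def predict(self, X, threshold: float = 0.5):
        """Binary masks at the given probability threshold (>= rule)."""
        from .evaluation import binarize

        return np.stack([binarize(p, threshold) for p in self.predict_proba(X)])

    def score(self, X, y):
        """Mean IoU over slices, with the 0/1 fluid-free conventions."""
        from .evaluation import iou, mean_iou

        preds = self.predict(X)
        y = np.asarray(y)
        return mean_iou([iou(p, t) for p, t in zip(preds, y)])

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
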