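"""Residual U-Net graph: encoder, bridge, decoder, sigmoid head.

Each residual unit is pre-activation: [BN -> ReLU -> conv] repeated
``convs_per_block`` times on the main path, added to a shortcut path
(identity, or a 1x1 projection convolution with matching stride when
the input and output shapes differ).  Encoder blocks 2+ halve the
spatial size with a stride-2 first convolution; decoder blocks
up-sample (nearest, x2) and concatenate the mirror encoder output
(up-sampled features first, then the skip) before their residual unit.
The head is a 1x1 convolution to one channel followed by a sigmoid.
"""

from __future__ import annotations

import numpy as np

from .layers import F32, BatchNorm2D, Conv2D, ReLU, Upsample2x


class ResidualBlock:
    def __init__(
        self,
        name: str,
        cin: int,
        cout: int,
        convs: int,
        stride: int,
        kernel: int,
        rng: np.random.Generator,
    ):
        self.name = name
        self.units: list[tuple[BatchNorm2D, ReLU, Conv2D]] = []
        for j in range(convs):
            c_in = cin if j == 0 else cout
            s = stride if j == 0 else 1  # only the first conv may stride
            self.units.append(
                (
                    BatchNorm2D(f"{name}/bn_{j + 1}", c_in),
                    ReLU(),
                    Conv2D(f"{name}/conv_{j + 1}", c_in, cout, kernel, s, rng),
                )
            )
        if stride != 1 or cin != cout:
            self.shortcut: Conv2D | None = Conv2D(
                f"{name}/shortcut", cin, cout, 1, stride, rng
            )
        else:
            self.shortcut = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for bn, relu, conv in self.units:
            h = conv.forward(relu.forward(bn.forward(h, training), training), training)
        sc = self.shortcut.forward(x, training) if self.shortcut is not None else x
        return h + sc

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.shortcut.backward(dout) if self.shortcut is not None else dout.copy()
        dh = dout
        for bn, relu, conv in reversed(self.units):
            dh = bn.backward(relu.backward(conv.backward(dh)))
        return dx + dh

    def layers(self):
        for bn, _, conv in self.units:
            yield bn
            yield conv
        if self.shortcut is not None:
            yield self.shortcut


class DecoderBlock:
    """Up-sample, concatenate the encoder skip, then a residual unit."""

    def __init__(
        self,
        name: str,
        cin_prev: int,
        cin_skip: int,
        cout: int,
        convs: int,
        kernel: int,
        rng: np.random.Generator,
    ):
        self.cin_prev = cin_prev
        self.up = Upsample2x()
        self.res = ResidualBlock(name, cin_prev + cin_skip, cout, convs, 1, kernel, rng)

    def forward(self, prev: np.ndarray, skip: np.ndarray, training: bool = False) -> np.ndarray:
        u = self.up.forward(prev, training)
        cat = np.concatenate([u, skip], axis=0)  # up-sampled first, then skip
        return self.res.forward(cat, training)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dcat = self.res.backward(dout)
        du, dskip = dcat[: self.cin_prev], dcat[self.cin_prev :]
        return self.up.backward(du), dskip

    def layers(self):
        yield from self.res.layers()


class ResUNet:
    """The assembled network.  Public arrays are NHWC; internals are
    channel-first (C, N, H, W) so convolutions flatten to single GEMMs."""

    def __init__(
        self,
        n_blocks: int,
        convs_per_block: int,
        base_filters: int,
        kernel_size: int,
        input_size: int,
        in_channels: int,
        seed: int,
    ):
        rng = np.random.default_rng(seed)
        self.n_blocks = n_blocks
        self.input_size = input_size
        self.in_channels = in_channels
        enc_ch = [base_filters * 2**i for i in range(n_blocks)]
        self.encoder: list[ResidualBlock] = []
        for i in range(n_blocks):
            cin = in_channels if i == 0 else enc_ch[i - 1]
            stride = 1 if i == 0 else 2
            self.encoder.append(
                ResidualBlock(
                    f"encoder/residual_block_{i + 1}",
                    cin,
                    enc_ch[i],
                    convs_per_block,
                    stride,
                    kernel_size,
                    rng,
                )
            )
        bridge_ch = base_filters * 2**n_blocks
        self.bridge = ResidualBlock(
            f"bridge/residual_block_{n_blocks + 1}",
            enc_ch[-1],
            bridge_ch,
            convs_per_block,
            2,
            kernel_size,
            rng,
        )
        self.decoder: list[DecoderBlock] = []
        prev_ch = bridge_ch
        for j, i in enumerate(range(n_blocks - 1, -1, -1)):
            self.decoder.append(
                DecoderBlock(
                    f"decoder/residual_block_{n_blocks + 2 + j}",
                    prev_ch,
                    enc_ch[i],
                    enc_ch[i],
                    convs_per_block,
                    kernel_size,
                    rng,
                )
            )
            prev_ch = enc_ch[i]
        self.head = Conv2D("output/conv_1x1", enc_ch[0], 1, 1, 1, rng)

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x_nhwc: np.ndarray, training: bool = False) -> np.ndarray:
        """Logit map (N, H, W) from inputs (N, H, W, C) in [0, 1]."""
        x = np.ascontiguousarray(np.transpose(x_nhwc, (3, 0, 1, 2)), dtype=F32)
        if x.shape[2] != self.input_size or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected input (N, {self.input_size}, {self.input_size}, "
                f"{self.in_channels}), got {x_nhwc.shape}"
            )
        skips = []
        h = x
        for enc in self.encoder:
            h = enc.forward(h, training)
            skips.append(h)
        h = self.bridge.forward(h, training)
        for dec, skip in zip(self.decoder, reversed(skips)):
            h = dec.forward(h, skip, training)
        z = self.head.forward(h, training)
        return z[0]

    def backward(self, dz: np.ndarray) -> None:
        """Backprop from d(loss)/d(logits) (N, H, W); fills layer grads."""
        d = self.head.backward(dz[None].astype(F32))
        dskips: list[np.ndarray] = []
        for dec in reversed(self.decoder):
            d, dskip = dec.backward(d)
            dskips.append(dskip)
        d = self.bridge.backward(d)
        # encoder block i's output feeds encoder i+1 / bridge AND its
        # mirror decoder block: gradients add.  Walking the decoder in
        # reverse visited the mirrors of encoder 0, 1, ... in order, so
        # dskips[i] is already the grad arriving at encoder block i.
        for i in range(self.n_blocks - 1, -1, -1):
            d = self.encoder[i].backward(d + dskips[i])

    def predict_proba(self, x_nhwc: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Sigmoid probability maps (N, H, W), inference mode (running BN)."""
        outs = []
        for i in range(0, len(x_nhwc), batch_size):
            z = self.forward_logits(x_nhwc[i : i + batch_size], training=False)
            outs.append(_sigmoid(z))
        p = np.concatenate(outs, axis=0)
        return np.clip(p, 1e-7, 1.0 - 1e-7)

    # -- parameter plumbing -------------------------------------------------

    def _all_layers(self):
        for blk in self.encoder:
            yield from blk.layers()
        yield from self.bridge.layers()
        for dec in self.decoder:
            yield from dec.layers()
        yield self.head

    def named_params(self):
        for layer in self._all_layers():
            yield from layer.named_params()

    def named_buffers(self):
        for layer in self._all_layers():
            yield from layer.named_buffers()

    def conv_layers(self):
        for layer in self._all_layers():
            if isinstance(layer, Conv2D):
                yield layer

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: arr for name, arr, _ in self.named_params()}
        state.update({name: arr for name, arr in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"checkpoint is missing arrays: {sorted(missing)[:5]}")
        for name, arr in own.items():
            arr[...] = state[name]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
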