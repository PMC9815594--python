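"""Encoder-decoder (U-Net style) network for motion-artifact filtering.

Geometry: four encoder blocks, each [3x3 conv, 3x3 conv, 1x1 conv] with
batch normalization and leaky ReLU after every convolution, with channel
counts ``base * (1, 2, 4, 8)`` and a 2x2 stride-2 max pool after blocks 1-3
only.  Four decoder blocks mirror them: each starts with a 2x2 transposed
convolution followed by leaky ReLU, concatenates the skip from the matching
encoder block, then runs [3x3 conv, 3x3 conv, 1x1 conv] with batch
normalization and leaky ReLU.  The first decoder block operates at the
bottleneck resolution (its transposed convolution uses stride 1 and its
skip is encoder block 4); the remaining three upsample by 2 and pair with
encoder blocks 3, 2, 1.  A final 1x1 convolution maps back to one channel.

Counting the 3x3 and 1x1 convolutions plus the final projection — and not
the four transposed convolutions — gives 25 convolutional layers.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, LeakyReLU, MaxPool2x2


def _conv_block(cin, cout, slope, rng):
    layers = []
    for k, ci in ((3, cin), (3, cout), (1, cout)):
        layers += [Conv2d(ci, cout, k, rng), BatchNorm2d(cout), LeakyReLU(slope)]
    return layers


def _run(layers, x, train):
    for layer in layers:
        x = layer.forward(x, train=train)
    return x


def _back(layers, gy):
    for layer in reversed(layers):
        gy = layer.backward(gy)
    return gy


class UNet:
    """The filtering network; input and output are (N, 1, H, W) images."""

    def __init__(
        self,
        input_size: tuple[int, int] = (256, 256),
        base_filters: int = 32,
        leaky_slope: float = 0.01,
        seed: int = 0,
    ):
        h, w = input_size
        if h % 8 or w % 8:
            raise ConfigurationError(
                f"input size must be divisible by 8 (three 2x poolings), got {input_size}"
            )
        self.input_size = (h, w)
        self.base_filters = base_filters
        self.leaky_slope = leaky_slope
        self.seed = seed
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = (base_filters * m for m in (1, 2, 4, 8))

        self.enc = [
            _conv_block(1, c1, leaky_slope, rng),
            _conv_block(c1, c2, leaky_slope, rng),
            _conv_block(c2, c3, leaky_slope, rng),
            _conv_block(c3, c4, leaky_slope, rng),
        ]
        self.pools = [MaxPool2x2(), MaxPool2x2(), MaxPool2x2()]
        # (up-conv, activation, conv block) per decoder stage; skips pair
        # with encoder blocks 4, 3, 2, 1 in that order.
        self.dec = [
            (ConvTranspose2d(c4, c4, rng, stride=1), LeakyReLU(leaky_slope),
             _conv_block(2 * c4, c4, leaky_slope, rng)),
            (ConvTranspose2d(c4, c3, rng, stride=2), LeakyReLU(leaky_slope),
             _conv_block(2 * c3, c3, leaky_slope, rng)),
            (ConvTranspose2d(c3, c2, rng, stride=2), LeakyReLU(leaky_slope),
             _conv_block(2 * c2, c2, leaky_slope, rng)),
            (ConvTranspose2d(c2, c1, rng, stride=2), LeakyReLU(leaky_slope),
             _conv_block(2 * c1, c1, leaky_slope, rng)),
        ]
        self.final = Conv2d(c1, 1, 1, rng)

    # -- introspection -----------------------------------------------------

    @property
    def conv_layer_count(self) -> int:
        """Number of convolutional layers (3x3 and 1x1; transposed excluded)."""
        n = sum(1 for block in self.enc for layer in block if isinstance(layer, Conv2d))
        n += sum(1 for _, _, block in self.dec for layer in block if isinstance(layer, Conv2d))
        return n + 1  # final projection

    def layers(self):
        for block in self.enc:
            yield from block
        yield from self.pools
        for up, act, block in self.dec:
            yield up
            yield act
            yield from block
        yield self.final

    def parameters(self):
        """Yield (layer, name, array) for every trainable parameter."""
        for layer in self.layers():
            for name, arr in layer.params.items():
                yield layer, name, arr

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        h = np.asarray(x, dtype=self.final.params["W"].dtype)
        for i, block in enumerate(self.enc):
            h = _run(block, h, train)
            skips.append(h)
            if i < 3:
                h = self.pools[i].forward(h, train)
        for (up, act, block), skip in zip(self.dec, reversed(skips)):
            h = act.forward(up.forward(h, train), train)
            h = np.concatenate([h, skip], axis=1)
            h = _run(block, h, train)
        return self.final.forward(h, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gh = self.final.backward(gy)
        gskips = [None] * 4  # encoder blocks 1..4
        for stage, (up, act, block) in reversed(list(enumerate(self.dec))):
            gcat = _back(block, gh)
            cup = up.cout
            gup, gskip = gcat[:, :cup], gcat[:, cup:]
            gskips[3 - stage] = gskip
            gh = up.backward(act.backward(gup))
        for i in reversed(range(4)):
            if i < 3:
                gh = self.pools[i].backward(gh)
            gh = gh + gskips[i]
            gh = _back(self.enc[i], gh)
        return gh

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for name, arr in layer.params.items():
                state[f"layer{i}.{name}"] = arr.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for name in layer.params:
                layer.params[name] = state[f"layer{i}.{name}"].copy()
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"layer{i}.running_mean"].copy()
                layer.running_var = state[f"layer{i}.running_var"].copy()

    def config(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "base_filters": self.base_filters,
            "leaky_slope": self.leaky_slope,
            "seed": self.seed,
        }
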