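"""Composite layers: sequential container, residual and squeeze-excite blocks."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool,
    Layer,
    Linear,
    ReLU,
    Sigmoid,
)

__all__ = ["Sequential", "ResidualBlock3d", "SEGate"]


class Sequential(Layer):
    """Applies child layers in order; backward runs them in reverse."""

    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self._layers = list(layers)

    def children(self):
        return tuple(self._layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self._layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self._layers):
            dout = layer.backward(dout)
        return dout


class SEGate(Layer):
    """Squeeze-and-excite channel gating.

    Squeeze: global average pool per channel.  Excite: a two-layer
    bottleneck MLP (reduction ratio *r*) ending in a sigmoid, whose output
    rescales each channel of the input feature map.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator) -> None:
        super().__init__()
        if reduction > channels:
            raise ValueError(
                f"SE reduction ratio {reduction} exceeds channel count {channels}"
            )
        hidden = max(channels // reduction, 1)
        self.squeeze = GlobalAvgPool()
        self.fc1 = Linear(channels, hidden, rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden, channels, rng)
        self.sigmoid = Sigmoid()

    def children(self):
        return (self.squeeze, self.fc1, self.relu, self.fc2, self.sigmoid)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.squeeze.forward(x, train=train)
        g = self.sigmoid.forward(
            self.fc2.forward(self.relu.forward(self.fc1.forward(s, train), train), train),
            train,
        )
        self._x, self._gate = x, g
        return x * g[:, :, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, g = self._x, self._gate
        dx = dout * g[:, :, None, None, None]
        dg = (dout * x).sum(axis=(2, 3, 4))
        ds = self.fc1.backward(
            self.relu.backward(self.fc2.backward(self.sigmoid.backward(dg)))
        )
        dx += self.squeeze.backward(ds)
        return dx

    @property
    def gate(self) -> np.ndarray:
        """Gating values of the last forward pass, each in (0, 1)."""
        return self._gate


class ResidualBlock3d(Layer):
    """conv-bn-relu-conv-bn with an identity shortcut, then ReLU.

    When the channel count changes, the shortcut is a 1x1x1 convolution
    followed by batch norm.  With ``se_reduction`` set, a squeeze-excite
    gate rescales the main path before the addition.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        kernel_size: int = 3,
        se_reduction: int | None = None,
    ) -> None:
        super().__init__()
        self.main = Sequential(
            Conv3d(in_channels, out_channels, kernel_size, rng),
            BatchNorm3d(out_channels),
            ReLU(),
            Conv3d(out_channels, out_channels, kernel_size, rng),
            BatchNorm3d(out_channels),
        )
        self.se: SEGate | None = (
            SEGate(out_channels, se_reduction, rng) if se_reduction else None
        )
        if in_channels != out_channels:
            self.shortcut: Layer | None = Sequential(
                Conv3d(in_channels, out_channels, 1, rng),
                BatchNorm3d(out_channels),
            )
        else:
            self.shortcut = None
        self.out_relu = ReLU()

    def children(self):
        kids = [self.main]
        if self.se is not None:
            kids.append(self.se)
        if self.shortcut is not None:
            kids.append(self.shortcut)
        kids.append(self.out_relu)
        return tuple(kids)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        main = self.main.forward(x, train=train)
        if self.se is not None:
            main = self.se.forward(main, train=train)
        short = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.out_relu.forward(main + short, train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.out_relu.backward(dout)
        dmain = dsum
        if self.se is not None:
            dmain = self.se.backward(dmain)
        dx = self.main.backward(dmain)
        if self.shortcut is None:
            dx = dx + dsum
        else:
            dx = dx + self.shortcut.backward(dsum)
        return dx
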