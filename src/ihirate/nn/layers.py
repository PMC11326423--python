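"""Minimal 3D neural-network layers on NumPy arrays.

Feature maps are ``(N, C, D, H, W)`` float64 arrays.  Every layer exposes
``forward(x, train)`` and ``backward(dout)``; ``backward`` must be called
after the matching ``forward`` and returns the gradient with respect to the
layer input, which makes input-saliency maps a by-product of ordinary
backpropagation.  Parameters live in ``layer.params`` with gradients in
``layer.grads`` under the same keys.

Convolutions are stride-1 cross-correlations with zero 'same' padding,
evaluated through sliding-window views and ``einsum``; the batch axis is
chunked to bound the temporary buffers einsum materializes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Dropout",
    "pooled_extents",
]

_CONV_CHUNK = 16  # batch rows convolved at once


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def children(self):
        return ()

    def walk(self):
        """Yield this layer and all descendants, depth-first."""
        yield self
        for child in self.children():
            yield from child.walk()

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.walk():
            if hasattr(layer, "_rng"):
                layer._rng = rng


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Layer):
    """3D convolution, odd kernel, stride 1, zero 'same' padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size**3
        self.params["weight"] = he_normal(
            rng, (out_channels, in_channels, self.k, self.k, self.k), fan_in
        )
        self.params["bias"] = np.zeros(out_channels)
        #: set False on a network's first conv during training to skip the
        #: (unused) input-gradient computation; saliency resets it to True.
        self.input_grad = True

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(chunk, C, D, H, W) -> (chunk * D*H*W, C*k^3) patch matrix."""
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        view = sliding_window_view(xp, (self.k, self.k, self.k), axis=(2, 3, 4))
        n, c = x.shape[:2]
        spatial = int(np.prod(x.shape[2:]))
        # (n, C, D, H, W, k,k,k) -> (n, D, H, W, C, k,k,k) -> matrix
        return np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * spatial, c * self.k**3
        )

    def _correlate(
        self, x: np.ndarray, weight: np.ndarray, cache: bool = False
    ) -> np.ndarray:
        """Cross-correlate (N,Ci,...) with (Co,Ci,k,k,k) -> (N,Co,...).

        im2col + matmul so the inner product runs through BLAS; the batch
        axis is chunked to bound the patch-matrix temporaries.  With
        ``cache`` the patch matrices are kept for reuse in backward.
        """
        n = x.shape[0]
        c_out = weight.shape[0]
        spatial_shape = x.shape[2:]
        spatial = int(np.prod(spatial_shape))
        wmat = weight.reshape(c_out, -1).T  # (C*k^3, Co)
        out = np.empty((n, c_out) + spatial_shape)
        cols_cache = [] if cache else None
        for i in range(0, n, _CONV_CHUNK):
            cols = self._im2col(x[i : i + _CONV_CHUNK])
            if cols_cache is not None:
                cols_cache.append(cols)
            chunk = cols.shape[0] // spatial
            out[i : i + _CONV_CHUNK] = (
                (cols @ wmat)
                .reshape((chunk,) + spatial_shape + (c_out,))
                .transpose(0, 4, 1, 2, 3)
            )
        if cols_cache is not None:
            self._cols = cols_cache
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        self._x = x
        out = self._correlate(x, self.params["weight"], cache=train)
        out += self.params["bias"][None, :, None, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, k = self._x, self.k
        self.grads["bias"] = dout.sum(axis=(0, 2, 3, 4))
        c_out = dout.shape[1]
        spatial = int(np.prod(x.shape[2:]))
        cached = getattr(self, "_cols", None)
        dw_mat = np.zeros((self.in_channels * k**3, c_out))
        for j, i in enumerate(range(0, x.shape[0], _CONV_CHUNK)):
            cols = cached[j] if cached else self._im2col(x[i : i + _CONV_CHUNK])
            chunk = cols.shape[0] // spatial
            dout_mat = (
                dout[i : i + _CONV_CHUNK]
                .transpose(0, 2, 3, 4, 1)
                .reshape(chunk * spatial, c_out)
            )
            dw_mat += cols.T @ dout_mat
        self.grads["weight"] = dw_mat.T.reshape(self.params["weight"].shape)
        self._cols = None
        if not self.input_grad:
            return np.zeros_like(x)
        # grad wrt input: correlate dout with the spatially flipped kernel,
        # transposed over the channel axes
        w_flip = self.params["weight"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        saved_cin = self.in_channels
        self.in_channels = self.out_channels  # reuse _correlate plumbing
        try:
            dx = self._correlate(dout, w_flip)
        finally:
            self.in_channels = saved_cin
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        self._std = std
        self._xhat = (x - mean[None, :, None, None, None]) / std[
            None, :, None, None, None
        ]
        self._train = train
        return (
            self.params["gamma"][None, :, None, None, None] * self._xhat
            + self.params["beta"][None, :, None, None, None]
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, std = self._xhat, self._std
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None, None]
        if not self._train:
            return dout * g / std[None, :, None, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dxhat = dout * g
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std[
            None, :, None, None, None
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


def pooled_extents(extents: tuple[int, int, int], n_pools: int) -> tuple[int, int, int]:
    """Spatial extents after *n_pools* size-2 floor-halving pools.

    Extents that reach 1 stop shrinking on that axis.
    """
    d, h, w = extents
    for _ in range(n_pools):
        d, h, w = max(d // 2, 1), max(h // 2, 1), max(w // 2, 1)
    return d, h, w


class MaxPool3d(Layer):
    """Size-2, stride-2 max pooling with floor semantics.

    Trailing odd voxels are dropped; axes already at extent 1 pass through.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        fd, fh, fw = (2 if d >= 2 else 1), (2 if h >= 2 else 1), (2 if w >= 2 else 1)
        od, oh, ow = max(d // 2, 1), max(h // 2, 1), max(w // 2, 1)
        self._in_shape = x.shape
        self._factors = (fd, fh, fw)
        self._out_spatial = (od, oh, ow)
        xt = x[:, :, : od * fd, : oh * fh, : ow * fw]
        windows = (
            xt.reshape(n, c, od, fd, oh, fh, ow, fw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, od, oh, ow, fd * fh * fw)
        )
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        fd, fh, fw = self._factors
        od, oh, ow = self._out_spatial
        dwin = np.zeros((n, c, od, oh, ow, fd * fh * fw))
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :, : od * fd, : oh * fh, : ow * fw] = (
            dwin.reshape(n, c, od, oh, ow, fd, fh, fw)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, od * fd, oh * fh, ow * fw)
        )
        return dx


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C) channel averages."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        return np.broadcast_to(
            dout[:, :, None, None, None] / (d * h * w), self._in_shape
        ).copy()


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params["weight"] = he_normal(
            rng, (in_features, out_features), in_features
        )
        self.params["bias"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["weight"] = self._x.T @ dout
        self.grads["bias"] = dout.sum(axis=0)
        return dout @ self.params["weight"].T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode.

    Draws its masks from the rng installed via ``Layer.set_rng`` so that a
    training run is reproducible from a single seed.
    """

    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self._rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if self._rng is None:
            raise RuntimeError("Dropout used in train mode without an rng; call set_rng")
        keep = 1.0 - self.p
        self._mask = (self._rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask
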