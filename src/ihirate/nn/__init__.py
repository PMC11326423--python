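"""A small NumPy neural-network toolkit used by the 3D regressors.

Provides stride-1 3D convolution, batch normalization, max pooling,
residual and squeeze-excite blocks, dropout, Adam, and weight snapshotting.
All backward passes are hand-written and covered by finite-difference
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from .blocks import ResidualBlock3d, SEGate, Sequential
from .layers import (
    BatchNorm3d,
    Conv3d,
    Dropout,
    Flatten,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool3d,
    ReLU,
    Sigmoid,
    pooled_extents,
)
from .optim import Adam

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
    "Sequential",
    "ResidualBlock3d",
    "SEGate",
    "Adam",
    "pooled_extents",
    "get_state",
    "set_state",
]


def get_state(model: Layer) -> list[np.ndarray]:
    """Deep-copy all parameters and batch-norm running statistics."""
    state: list[np.ndarray] = []
    for layer in model.walk():
        for name in sorted(layer.params):
            state.append(layer.params[name].copy())
        if isinstance(layer, BatchNorm3d):
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
    return state


def set_state(model: Layer, state: list[np.ndarray]) -> None:
    """Inverse of :func:`get_state`; shapes must match the model."""
    it = iter(state)
    for layer in model.walk():
        for name in sorted(layer.params):
            arr = next(it)
            if arr.shape != layer.params[name].shape:
                raise ValueError(
                    f"state shape {arr.shape} != parameter shape "
                    f"{layer.params[name].shape} for {type(layer).__name__}.{name}"
                )
            layer.params[name] = arr.copy()
        if isinstance(layer, BatchNorm3d):
            layer.running_mean = next(it).copy()
            layer.running_var = next(it).copy()
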