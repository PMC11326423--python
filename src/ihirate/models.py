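"""Regressors for per-criterion IHI rating.

Three 3D CNN families plus a linear baseline, all predicting a single
continuous criterion score from a grey-matter crop:

* ``conv5fc3`` — five [conv - batch norm - ReLU - max pool] blocks followed
  by three fully connected layers;
* ``resnet3d`` — five residual blocks separated by max pooling, with a
  FC - ReLU - dropout - FC head;
* ``secnn`` — the residual network with a squeeze-and-excite gate in every
  block;
* ``ridge`` — ridge regression on flattened crops, hyper-parameter chosen
  by nested cross-validation.

Training minimizes mean squared error with Adam (learning rate 1e-4,
weight decay 1e-4, batch size 16, at most 50 epochs); the weights from the
epoch with the lowest validation loss are retained.  One model is trained
per criterion and hemisphere frame; the composite IHI score is never a
direct regression target — it is reconstructed downstream as the sum of
the rounded per-criterion predictions, which keeps it interpretable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold

from . import nn
from .preprocess import unflatten

__all__ = [
    "TrainConfig",
    "ArchitectureSpec",
    "Regressor",
    "TrainedRegressor",
    "build_model",
    "build_conv5fc3",
    "build_resnet3d",
    "build_secnn",
    "train_regressor",
    "predict_criterion",
    "RidgeResult",
    "ridge_nested_cv",
    "DEFAULT_RIDGE_ALPHAS",
    "saliency_group_map",
    "top_k_support",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; defaults are the reference settings."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 50
    early_stop_tolerance: float = 0.0  # min-delta 0: run all epochs, keep best
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Widths and structural constants of one model family.

    The reference description fixes block counts and block contents but not
    channel or fully-connected widths; those live here so scaled-down
    presets are a config change, not a code change.
    """

    family: str = "conv5fc3"
    channels: tuple[int, ...] = (8, 16, 32, 64, 128)
    kernel_size: int = 3
    fc_widths: tuple[int, ...] = (1024, 64)
    dropout: float = 0.5
    se_reduction: int = 16

    def __post_init__(self) -> None:
        if self.family not in ("conv5fc3", "resnet3d", "secnn", "ridge"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family != "ridge" and len(self.channels) != 5:
            raise ValueError("deep families use exactly 5 blocks")

    @classmethod
    def tiny(cls, family: str = "conv5fc3") -> "ArchitectureSpec":
        """Reduced-width preset for CPU-scale experiments and tests."""
        return cls(
            family=family,
            channels=(4, 8, 16, 16, 16),
            fc_widths=(32, 16),
            se_reduction=4,
        )


class Regressor:
    """A network together with its input geometry and build provenance."""

    def __init__(
        self,
        net: nn.Layer,
        input_extents: tuple[int, int, int],
        spec: ArchitectureSpec,
        seed: int,
    ) -> None:
        self.net = net
        self.input_extents = tuple(int(e) for e in input_extents)
        self.spec = spec
        self.seed = seed

    def forward(self, crops: np.ndarray, train: bool = False) -> np.ndarray:
        """Crops ``(N, D, H, W)`` -> predictions ``(N,)``."""
        x = self._as_batch(crops)
        out = self.net.forward(x, train=train)
        return out[:, 0]

    def _as_batch(self, crops: np.ndarray) -> np.ndarray:
        x = np.asarray(crops, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != self.input_extents:
            raise ValueError(
                f"expected crops of shape (N, {self.input_extents}), got {x.shape}"
            )
        return x[:, None]  # single input channel


def _check_extents(input_extents: Sequence[int]) -> tuple[int, int, int]:
    ext = tuple(int(e) for e in input_extents)
    if len(ext) != 3 or any(e < 1 for e in ext):
        raise ValueError(f"input extents must be three positive ints, got {ext}")
    return ext


def build_conv5fc3(
    input_extents: Sequence[int],
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
) -> Regressor:
    """Five conv blocks (conv-BN-ReLU-maxpool) then three FC layers."""
    ext = _check_extents(input_extents)
    spec = spec or ArchitectureSpec(family="conv5fc3")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in spec.channels:
        layers += [
            nn.Conv3d(c_in, c_out, spec.kernel_size, rng),
            nn.BatchNorm3d(c_out),
            nn.ReLU(),
            nn.MaxPool3d(),
        ]
        c_in = c_out
    pooled = nn.pooled_extents(ext, n_pools=5)
    flat = spec.channels[-1] * int(np.prod(pooled))
    w1, w2 = spec.fc_widths
    layers += [
        nn.Flatten(),
        nn.Linear(flat, w1, rng),
        nn.ReLU(),
        nn.Linear(w1, w2, rng),
        nn.ReLU(),
        nn.Linear(w2, 1, rng),
    ]
    return Regressor(nn.Sequential(*layers), ext, spec, seed)


def _build_residual(
    input_extents: Sequence[int],
    spec: ArchitectureSpec,
    seed: int,
    se: bool,
) -> Regressor:
    ext = _check_extents(input_extents)
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in spec.channels:
        layers.append(
            nn.ResidualBlock3d(
                c_in,
                c_out,
                rng,
                kernel_size=spec.kernel_size,
                se_reduction=spec.se_reduction if se else None,
            )
        )
        layers.append(nn.MaxPool3d())
        c_in = c_out
    pooled = nn.pooled_extents(ext, n_pools=5)
    flat = spec.channels[-1] * int(np.prod(pooled))
    head_width = spec.fc_widths[0]
    layers += [
        nn.Flatten(),
        nn.Linear(flat, head_width, rng),
        nn.ReLU(),
        nn.Dropout(spec.dropout),
        nn.Linear(head_width, 1, rng),
    ]
    model = Regressor(nn.Sequential(*layers), ext, spec, seed)
    model.net.set_rng(np.random.default_rng(seed + 1))  # dropout stream
    return model


def build_resnet3d(
    input_extents: Sequence[int],
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
) -> Regressor:
    """Five residual blocks separated by max pooling, FC-ReLU-dropout-FC head."""
    return _build_residual(
        input_extents, spec or ArchitectureSpec(family="resnet3d"), seed, se=False
    )


def build_secnn(
    input_extents: Sequence[int],
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
) -> Regressor:
    """Residual network with squeeze-and-excite channel gating per block."""
    return _build_residual(
        input_extents, spec or ArchitectureSpec(family="secnn"), seed, se=True
    )


_BUILDERS = {
    "conv5fc3": build_conv5fc3,
    "resnet3d": build_resnet3d,
    "secnn": build_secnn,
}


def build_model(
    family: str,
    input_extents: Sequence[int],
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
) -> Regressor:
    if family not in _BUILDERS:
        raise ValueError(f"unknown deep model family {family!r}")
    if spec is not None and spec.family != family:
        raise ValueError(f"spec family {spec.family!r} does not match {family!r}")
    return _BUILDERS[family](input_extents, spec, seed)


@dataclass
class TrainedRegressor:
    """A fitted model plus its training provenance."""

    model: Regressor
    criterion: str
    hemisphere: str
    strategy: str
    best_epoch: int  # 1-based epoch whose weights are loaded
    best_val_loss: float
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    config: TrainConfig = field(default_factory=TrainConfig)


def _epoch_loss(model: Regressor, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    se = 0.0
    for i in range(0, len(x), batch):
        pred = model.forward(x[i : i + batch], train=False)
        se += float(np.sum((pred - y[i : i + batch]) ** 2))
    return se / len(x)


def train_regressor(
    model: Regressor,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
    criterion: str = "C1",
    hemisphere: str = "left",
    strategy: str = "",
) -> TrainedRegressor:
    """MSE training with Adam; returns the best-validation-epoch weights.

    Labels are the raw (continuous-valued but on-grid) criterion scores;
    rounding back onto the rating grid happens downstream at evaluation.
    """
    cfg = cfg or TrainConfig()
    x_train, y_train = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    x_val, y_val = np.asarray(val_set[0], float), np.asarray(val_set[1], float)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if len(x_train) != len(y_train) or len(x_val) != len(y_val):
        raise ValueError("crops and labels disagree in length")

    rng = np.random.default_rng(cfg.seed)
    model.net.set_rng(np.random.default_rng(rng.integers(2**31)))
    optimizer = nn.Adam(
        model.net, learning_rate=cfg.learning_rate, weight_decay=cfg.weight_decay
    )

    # the input gradient of the very first convolution is only needed for
    # saliency, not for weight updates — skip it while training
    first = model.net.children()[0] if model.net.children() else None
    if isinstance(first, nn.Conv3d):
        first.input_grad = False

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_state = None
    best_val = np.inf
    best_epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_train))
        epoch_se = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            pred = model.forward(x_train[idx], train=True)
            resid = pred - y_train[idx]
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}); aborting"
                )
            epoch_se += loss * len(idx)
            dpred = (2.0 / len(idx)) * resid
            model.net.backward(dpred[:, None])
            optimizer.step()
        train_losses.append(epoch_se / len(order))
        val_loss = _epoch_loss(model, x_val, y_val, cfg.batch_size)
        val_losses.append(val_loss)
        if val_loss < best_val - cfg.early_stop_tolerance:
            best_val = val_loss
            best_epoch = epoch
            best_state = nn.get_state(model.net)
    assert best_state is not None
    nn.set_state(model.net, best_state)
    if isinstance(first, nn.Conv3d):
        first.input_grad = True
    return TrainedRegressor(
        model=model,
        criterion=criterion,
        hemisphere=hemisphere,
        strategy=strategy,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        train_losses=train_losses,
        val_losses=val_losses,
        config=cfg,
    )


def predict_criterion(trained: TrainedRegressor, crops: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Raw (un-rounded) criterion predictions, one per crop."""
    x = np.asarray(crops, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    preds = [
        trained.model.forward(x[i : i + batch_size], train=False)
        for i in range(0, len(x), batch_size)
    ]
    out = np.concatenate(preds)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("model produced non-finite predictions")
    return out


#: 13 log-spaced ridge penalties, 1e-3 .. 1e9.
DEFAULT_RIDGE_ALPHAS: tuple[float, ...] = tuple(np.logspace(-3, 9, 13))


@dataclass
class RidgeResult:
    """Ridge fit with nested-CV provenance.

    ``outer_predictions`` are honest held-out predictions: each sample was
    predicted by a model that never saw it, with the penalty re-selected
    inside that outer fold.
    """

    model: Ridge
    alpha: float
    outer_predictions: np.ndarray
    outer_alphas: list[float]
    input_extents: tuple[int, int, int] | None = None


def ridge_nested_cv(
    features: np.ndarray,
    labels: np.ndarray,
    outer: int = 5,
    inner: int = 6,
    alphas: Sequence[float] = DEFAULT_RIDGE_ALPHAS,
    input_extents: tuple[int, int, int] | None = None,
) -> RidgeResult:
    """Ridge regression with nested cross-validation (5 outer, 6 inner folds)."""
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be (n, p) with one label per row")
    if len(x) < outer:
        raise ValueError(f"need at least {outer} samples for {outer} outer folds")
    if np.ptp(y) == 0:
        raise ValueError("labels are constant; ridge fit is degenerate")

    alphas = list(alphas)
    outer_preds = np.empty_like(y)
    outer_alphas: list[float] = []
    for train_idx, test_idx in KFold(n_splits=outer).split(x):
        search = GridSearchCV(
            Ridge(), {"alpha": alphas}, cv=KFold(n_splits=inner),
            scoring="neg_mean_squared_error",
        )
        search.fit(x[train_idx], y[train_idx])
        outer_alphas.append(float(search.best_params_["alpha"]))
        outer_preds[test_idx] = search.predict(x[test_idx])

    final_search = GridSearchCV(
        Ridge(), {"alpha": alphas}, cv=KFold(n_splits=inner),
        scoring="neg_mean_squared_error",
    )
    final_search.fit(x, y)
    alpha = float(final_search.best_params_["alpha"])
    model = Ridge(alpha=alpha).fit(x, y)
    return RidgeResult(
        model=model,
        alpha=alpha,
        outer_predictions=outer_preds,
        outer_alphas=outer_alphas,
        input_extents=input_extents,
    )


def top_k_support(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest entries; ties break by flat index order."""
    flat = values.ravel()
    if k > flat.size:
        raise ValueError(f"cannot retain {k} voxels from {flat.size}")
    order = np.argsort(-flat, kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(values.shape)


def saliency_group_map(
    trained: TrainedRegressor | RidgeResult,
    crops: np.ndarray | None = None,
    n_keep: int = 1000,
    batch_size: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Group saliency: mean |d output / d input| over crops, top-k thresholded.

    For the CNNs the per-voxel gradient is obtained by back-propagation;
    for the ridge model the gradient of a linear model is its coefficient
    vector, so |coefficients| reshaped to the ROI is used directly (crops
    are then ignored).  Returns ``(map, support)`` where *map* holds the
    mean gradient magnitudes and *support* is a boolean mask with exactly
    *n_keep* True voxels (ties broken by voxel index order).
    """
    if isinstance(trained, RidgeResult):
        if trained.input_extents is None:
            raise ValueError("RidgeResult lacks input_extents for saliency reshaping")
        grad = np.abs(unflatten(trained.model.coef_, trained.input_extents))
    else:
        if crops is None or len(crops) == 0:
            raise ValueError("saliency needs at least one crop")
        x = np.asarray(crops, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        total = np.zeros(trained.model.input_extents)
        for i in range(0, len(x), batch_size):
            batch = x[i : i + batch_size]
            trained.model.forward(batch, train=False)
            dx = trained.model.net.backward(np.ones((len(batch), 1)))
            total += np.abs(dx[:, 0]).sum(axis=0)
        grad = total / len(x)
    support = top_k_support(grad, n_keep)
    return grad, support


def save_checkpoint(trained: TrainedRegressor, path: str | Path) -> None:
    """Single-file archive: weights + architecture + training metadata."""
    meta = {
        "criterion": trained.criterion,
        "hemisphere": trained.hemisphere,
        "strategy": trained.strategy,
        "best_epoch": trained.best_epoch,
        "best_val_loss": trained.best_val_loss,
        "train_losses": trained.train_losses,
        "val_losses": trained.val_losses,
        "config": asdict(trained.config),
        "architecture": asdict(trained.model.spec),
        "input_extents": list(trained.model.input_extents),
        "build_seed": trained.model.seed,
    }
    state = nn.get_state(trained.model.net)
    arrays = {f"arr_{i}": a for i, a in enumerate(state)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainedRegressor:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        state = [archive[f"arr_{i}"] for i in range(len(archive.files) - 1)]
    arch = meta["architecture"]
    arch["channels"] = tuple(arch["channels"])
    arch["fc_widths"] = tuple(arch["fc_widths"])
    spec = ArchitectureSpec(**arch)
    model = build_model(
        spec.family, meta["input_extents"], spec, seed=meta["build_seed"]
    )
    nn.set_state(model.net, state)
    return TrainedRegressor(
        model=model,
        criterion=meta["criterion"],
        hemisphere=meta["hemisphere"],
        strategy=meta["strategy"],
        best_epoch=meta["best_epoch"],
        best_val_loss=meta["best_val_loss"],
        train_losses=meta["train_losses"],
        val_losses=meta["val_losses"],
        config=TrainConfig(**meta["config"]),
    )
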