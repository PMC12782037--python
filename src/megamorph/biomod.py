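"""Biomass and identification models: OLS allometric baselines and conv nets.

Two model families share the same curated dataset and fold definitions:

* Linear baselines — ordinary least squares of a transformed dry mass on
  log-transformed device features (any non-empty subset of area A, maximum
  Feret diameter MFD, perimeter P). In log space this is the classical
  allometric power law ``log m = b0 + b1 log A + ...``.
* Conv nets — a small backbone trained either as a rank-level taxonomic
  classifier (cross-entropy, single-random-op augmentation) or as a biomass
  regressor (L1 loss in transformed-target space, flip/rotation
  augmentation). A classifier base can be transferred to regression by
  swapping the head, optionally with the base frozen.

Every training run evaluates validation loss per epoch and keeps the
minimum-validation-loss checkpoint together with the full loss curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .imfeat import resize_with_global_aspect
from .nnet import AdamW, ConvNet, augment_batch, l1_loss, softmax_cross_entropy
from .synthgen import FrameImage

PREDICTOR_COLUMNS = {"A": "area_mm2", "MFD": "mfd_mm", "P": "perimeter_mm"}
TRANSFORMS = ("identity", "log", "log1p")


class SingularFitError(ValueError):
    """Raised when the OLS design matrix is rank-deficient."""


class InvalidFoldError(ValueError):
    """Raised when a fold's training set cannot support the task."""


def apply_transform(m: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return np.asarray(m, dtype=float)
    if transform == "log":
        return np.log(m)
    if transform == "log1p":
        return np.log1p(m)
    raise ValueError(f"unknown transform {transform!r}")


def invert_transform(t: np.ndarray, transform: str) -> np.ndarray:
    """Back to mg, clipped below at 0 (mass is non-negative)."""
    if transform == "identity":
        out = np.asarray(t, dtype=float)
    elif transform == "log":
        out = np.exp(t)
    elif transform == "log1p":
        out = np.expm1(t)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# linear baselines


@dataclass
class LinearModelSpec:
    """OLS spec 'linear (A,MFD,P)': transformed mass on log predictors."""

    predictors: tuple[str, ...]
    target_transform: str = "log"
    coef: np.ndarray | None = None  # [intercept, one slope per predictor]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictor subset must be non-empty")
        unknown = set(self.predictors) - set(PREDICTOR_COLUMNS)
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}")
        if self.target_transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.target_transform!r}")

    @property
    def name(self) -> str:
        return f"linear({','.join(self.predictors)})"


def _design(frames: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
    cols = []
    for p in predictors:
        v = frames[PREDICTOR_COLUMNS[p]].to_numpy(dtype=float)
        if (v <= 0).any():
            bad = frames.loc[v <= 0, ["specimen_id", "camera_id", "frame_index"]].iloc[0]
            raise ValueError(
                f"non-positive feature {p} in frame "
                f"{bad['specimen_id']}/cam{bad['camera_id']}/{bad['frame_index']}"
            )
        cols.append(np.log(v))
    return sm.add_constant(np.column_stack(cols), has_constant="add")


def fit_linear(
    frames: pd.DataFrame, spec: LinearModelSpec, train_specimens: list[str] | None = None
) -> LinearModelSpec:
    """OLS over training frames; ``frames`` needs feature columns + mass_mg."""
    df = frames if train_specimens is None else frames[frames["specimen_id"].isin(train_specimens)]
    if len(df) < len(spec.predictors) + 2:
        raise ValueError("not enough training frames for the predictor count")
    X = _design(df, spec.predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(f"singular design for predictors {spec.predictors}")
    y = apply_transform(df["mass_mg"].to_numpy(dtype=float), spec.target_transform)
    fit = sm.OLS(y, X).fit()
    return replace(spec, coef=np.asarray(fit.params))


def predict_linear(model: LinearModelSpec, frames: pd.DataFrame) -> pd.DataFrame:
    """Per-frame mass predictions (mg) with the inverse target transform."""
    if model.coef is None:
        raise ValueError("model is not fitted")
    X = _design(frames, model.predictors)
    pred = invert_transform(X @ model.coef, model.target_transform)
    out = frames[["specimen_id", "camera_id", "frame_index"]].copy()
    out["pred_mass_mg"] = pred
    if "mass_mg" in frames.columns:
        out["true_mass_mg"] = frames["mass_mg"].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# frame tensors


@dataclass
class FrameStore:
    """Normalized frame tensors plus per-row provenance, ready for training."""

    X: np.ndarray  # (N, 1, T, T) float32, foreground bright
    specimen_id: np.ndarray
    camera_id: np.ndarray
    frame_index: np.ndarray

    def rows_for(self, specimen_ids) -> np.ndarray:
        wanted = set(specimen_ids)
        return np.array([i for i, s in enumerate(self.specimen_id) if s in wanted], dtype=int)


def build_frame_store(
    frames: list[FrameImage],
    clean_keys: set[tuple[str, int, int]],
    global_max_dim: int,
    target: int,
    seed: int = 0,
) -> FrameStore:
    """Resize clean frames under the global-aspect convention and stack them.

    ``clean_keys`` holds (specimen_id, camera_id, frame_index) of frames that
    passed the non-target screen. Intensities are inverted so the specimen
    is bright on a dark background, the natural polarity for conv features.
    """
    xs, sids, cams, idxs = [], [], [], []
    for i, f in enumerate(frames):
        key = (f.specimen_id, f.camera_id, f.frame_index)
        if key not in clean_keys:
            continue
        img = resize_with_global_aspect(f.pixels, global_max_dim, target, seed=seed + i)
        xs.append(1.0 - img.astype(np.float32) / 255.0)
        sids.append(f.specimen_id)
        cams.append(f.camera_id)
        idxs.append(f.frame_index)
    if not xs:
        raise ValueError("no clean frames to build a frame store from")
    return FrameStore(
        X=np.stack(xs)[:, None, :, :],
        specimen_id=np.array(sids),
        camera_id=np.array(cams),
        frame_index=np.array(idxs),
    )


# ---------------------------------------------------------------------------
# conv-net training


@dataclass
class TrainConfig:
    task: str  # "classify" | "regress"
    rank: str = "species"
    target_transform: str = "log1p"
    frozen_base: bool = False
    epochs: int = 10
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    input_size: int = 64
    channels: tuple[int, ...] = (16, 32, 64, 64)
    augmentation: str = ""  # empty -> task default

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if not self.augmentation:
            # classification uses the richer single-op policy; regression is
            # restricted to flips and lattice rotations
            self.augmentation = "trivial" if self.task == "classify" else "flips_rotations"



@dataclass
class TrainedModel:
    task: str
    net: ConvNet
    loss_curve: list[tuple[float, float]]  # (train, validation) per epoch
    checkpoint_epoch: int
    classes: list[str] = field(default_factory=list)  # classify
    target_transform: str = "log1p"  # regress
    rank: str = ""


def _run_training(
    net: ConvNet,
    X: np.ndarray,
    y: np.ndarray,
    loss_fn,
    train_rows: np.ndarray,
    val_rows: np.ndarray,
    config: TrainConfig,
    trainable: list[str],
) -> tuple[list[tuple[float, float]], int]:
    rng = np.random.default_rng(config.seed)
    opt = AdamW(trainable, lr=config.lr)
    best_loss, best_params, best_epoch = np.inf, net.copy_params(), 0
    curve: list[tuple[float, float]] = []
    tset = set(trainable)
    for epoch in range(config.epochs):
        # cosine decay stabilizes the late epochs of the small-batch runs
        opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(config.epochs - 1, 1)))
        order = rng.permutation(train_rows)
        losses = []
        for lo in range(0, len(order), config.batch_size):
            rows = order[lo : lo + config.batch_size]
            xb = augment_batch(X[rows], rng, config.augmentation)
            out, cache = net.forward(xb, want_cache=True)
            loss, dout = loss_fn(out, y[rows])
            grads = net.backward(dout, cache, tset)
            opt.step(net.params, grads)
            losses.append(loss)
        val_loss = loss_fn(net.predict(X[val_rows]), y[val_rows])[0]
        curve.append((float(np.mean(losses)), float(val_loss)))
        if val_loss < best_loss:
            best_loss, best_params, best_epoch = val_loss, net.copy_params(), epoch
    net.params = best_params
    return curve, best_epoch


def train_classifier(
    store: FrameStore,
    label_of_specimen: dict[str, str],
    train_specimens: list[str],
    val_specimens: list[str],
    config: TrainConfig,
) -> TrainedModel:
    """Rank-level taxonomic classifier on normalized training frames."""
    classes = sorted(set(label_of_specimen.values()))
    train_labels = {label_of_specimen[s] for s in train_specimens}
    missing = set(classes) - train_labels
    if missing:
        raise InvalidFoldError(f"classes absent from the training set: {sorted(missing)}")
    cls_id = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_id.get(label_of_specimen.get(s, ""), -1) for s in store.specimen_id])
    net = ConvNet.init(config.input_size, len(classes), config.channels, config.seed)
    curve, best = _run_training(
        net,
        store.X,
        y,
        softmax_cross_entropy,
        store.rows_for(train_specimens),
        store.rows_for(val_specimens),
        config,
        trainable=net.base_keys + net.head_keys,
    )
    return TrainedModel(
        task="classify", net=net, loss_curve=curve, checkpoint_epoch=best,
        classes=classes, rank=config.rank,
    )


def fine_tune_regressor(
    base: TrainedModel | None,
    store: FrameStore,
    mass_of_specimen: dict[str, float],
    train_specimens: list[str],
    val_specimens: list[str],
    config: TrainConfig,
) -> TrainedModel:
    """Biomass regressor: fresh net, or a classifier base with a new 1-unit head.

    L1 loss in transformed-target space; ``frozen_base=True`` updates only
    the head, leaving the transferred base parameters bit-identical.
    """
    if config.frozen_base and base is None:
        raise ValueError("frozen_base requires a pre-trained base model")
    if base is not None:
        if base.net.input_size != config.input_size or base.net.channels != tuple(config.channels):
            raise ValueError("base architecture does not match config")
        net = base.net.replace_head(1, config.seed)
    else:
        net = ConvNet.init(config.input_size, 1, config.channels, config.seed)
    y = np.array(
        [mass_of_specimen.get(s, np.nan) for s in store.specimen_id], dtype=float
    )[:, None]
    yt = np.where(np.isnan(y), 0.0, apply_transform(np.where(np.isnan(y), 1.0, y), config.target_transform))
    trainable = net.head_keys if config.frozen_base else net.base_keys + net.head_keys
    curve, best = _run_training(
        net,
        store.X,
        yt,
        l1_loss,
        store.rows_for(train_specimens),
        store.rows_for(val_specimens),
        config,
        trainable=trainable,
    )
    return TrainedModel(
        task="regress", net=net, loss_curve=curve, checkpoint_epoch=best,
        target_transform=config.target_transform,
    )


def predict_frames(
    model: TrainedModel,
    store: FrameStore,
    specimen_ids: list[str],
    fold: int,
    truth: dict[str, str] | dict[str, float],
) -> pd.DataFrame:
    """Deterministic per-frame predictions on non-augmented images."""
    rows = store.rows_for(specimen_ids)
    out = model.net.predict(store.X[rows])
    df = pd.DataFrame(
        {
            "specimen_id": store.specimen_id[rows],
            "camera_id": store.camera_id[rows],
            "frame_index": store.frame_index[rows],
            "fold": fold,
        }
    )
    if model.task == "classify":
        df["pred_label"] = [model.classes[i] for i in out.argmax(axis=1)]
        df["true_label"] = [truth[s] for s in df["specimen_id"]]
    else:
        df["pred_mass_mg"] = invert_transform(out[:, 0], model.target_transform)
        df["true_mass_mg"] = [truth[s] for s in df["specimen_id"]]
    return df
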