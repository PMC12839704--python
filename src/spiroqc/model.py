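"""Training and application of the acceptability classifier.

The classifier maps a 224 × 224 graphical construct to the risk, in
[0, 1], that the underlying spirometry maneuver is unacceptable
(positive class = unacceptable). Training minimizes 2-class cross-entropy
with Adam under the reference configuration (mini-batch 64, learning rate
1e-4, up to 100 epochs), evaluates on a held-out validation split once
per epoch, stops early after ``validation_patience`` consecutive
evaluations without improvement, and returns the parameters from the
best-validation evaluation. Random geometric augmentation (rotation
±10°, translation ±5 px per axis, per-axis scaling in [0.9, 1.1]) is
applied to training images only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp
from sklearn.model_selection import train_test_split

from .construct import GraphicalConstruct
from .errors import InvalidParameterError, SpiroQCError
from .net import Adam, ConvNet, softmax, softmax_cross_entropy

__all__ = [
    "CLASS_NAMES",
    "TrainConfig",
    "AugmentConfig",
    "SplitSpec",
    "EarlyStopper",
    "SpiroClassifier",
    "TrainResult",
    "build_classifier",
    "train",
    "predict_risk",
    "split_dataset",
    "augment_image",
    "save_checkpoint",
    "load_checkpoint",
]

#: class index 0 = acceptable, 1 = unacceptable (the positive class)
CLASS_NAMES = ("acceptable", "unacceptable")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (reference configuration)."""

    mini_batch: int = 64
    max_epochs: int = 100
    learning_rate: float = 1e-4
    validation_patience: int = 20  # consecutive evaluations without improvement

    def __post_init__(self):
        if min(self.mini_batch, self.max_epochs, self.validation_patience) <= 0:
            raise InvalidParameterError("TrainConfig values must be positive")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    """Geometric augmentation ranges, sampled uniformly per image per epoch."""

    enabled: bool = True
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    translate_x_px: tuple[float, float] = (-5.0, 5.0)
    translate_y_px: tuple[float, float] = (-5.0, 5.0)
    scale_x: tuple[float, float] = (0.9, 1.1)
    scale_y: tuple[float, float] = (0.9, 1.1)


@dataclass(frozen=True)
class SplitSpec:
    """Train / validation / test partition of the dataset.

    ``validation`` is an absolute image count when ≥ 1 (e.g. 23), or a
    fraction of the training portion when < 1. Stratification keeps both
    classes present in every split at small n.
    """

    test_fraction: float = 0.10
    validation: float = 23
    stratified: bool = True
    seed: int = 0


def split_dataset(labels: np.ndarray, split: SplitSpec):
    """Return disjoint (train_idx, val_idx, test_idx) covering the dataset."""
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    strat = labels if split.stratified else None
    trainval, test = train_test_split(
        idx, test_size=split.test_fraction, random_state=split.seed, stratify=strat
    )
    val_size = (
        int(split.validation)
        if split.validation >= 1
        else max(1, int(round(split.validation * trainval.size)))
    )
    if val_size >= trainval.size:
        raise InvalidParameterError("validation split leaves no training data")
    strat2 = labels[trainval] if split.stratified else None
    tr, val = train_test_split(
        trainval, test_size=val_size, random_state=split.seed, stratify=strat2
    )
    return np.sort(tr), np.sort(val), np.sort(test)


def augment_image(img: np.ndarray, ac: AugmentConfig, rng: np.random.Generator):
    """Randomly rotate/translate/scale one grayscale image, filling with black.

    Draws five uniforms even when the result is the identity, so the
    augmentation RNG stream advances deterministically; the warp itself is
    skipped for an exact identity.
    """
    rot = rng.uniform(*ac.rotation_deg)
    tx = rng.uniform(*ac.translate_x_px)
    ty = rng.uniform(*ac.translate_y_px)
    sx = rng.uniform(*ac.scale_x)
    sy = rng.uniform(*ac.scale_y)
    if rot == 0 and tx == 0 and ty == 0 and sx == 1 and sy == 1:
        return img
    h, w = img.shape
    center = np.array([w / 2, h / 2])
    tf = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=np.deg2rad(rot), scale=(sx, sy))
        + AffineTransform(translation=center + [tx, ty])
    )
    return warp(img, tf.inverse, order=1, mode="constant", cval=0.0,
                preserve_range=True)


class EarlyStopper:
    """Best-so-far tracker with a consecutive-non-improvement patience.

    ``update`` is called once per validation evaluation with the current
    validation error; it returns True when training should stop, i.e.
    after ``patience`` consecutive evaluations without a new best.
    ``best_eval`` is the 1-based index of the best evaluation, whose
    parameters are the ones a caller should keep.
    """

    def __init__(self, patience: int):
        if patience <= 0:
            raise InvalidParameterError("patience must be positive")
        self.patience = patience
        self.best_loss = np.inf
        self.best_eval = 0
        self.n_evals = 0
        self._since_best = 0

    def update(self, val_loss: float) -> bool:
        self.n_evals += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_eval = self.n_evals
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience

    @property
    def improved(self) -> bool:
        return self._since_best == 0


@dataclass
class SpiroClassifier:
    """The binary acceptability classifier around :class:`ConvNet`."""

    net: ConvNet
    trained: bool = False

    @staticmethod
    def _to_batch(x) -> np.ndarray:
        """Coerce constructs / arrays into a (n, 1, H, W) standardized batch."""
        if isinstance(x, GraphicalConstruct):
            x = x.network_input
        x = np.asarray(x)
        if x.ndim == 3 and x.shape[-1] == 3:  # single (H, W, 3)
            x = x[None]
        if x.ndim == 2:  # single grayscale
            x = x[None, ..., None].repeat(3, axis=-1)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise InvalidParameterError(
                f"expected (H, W, 3) or (n, H, W, 3) input, got shape {x.shape}"
            )
        gray = x.astype(np.float32).mean(axis=-1)
        return standardize(gray)[:, None, :, :]

    def predict_proba(self, x) -> np.ndarray:
        """Class probabilities, columns ordered as :data:`CLASS_NAMES`."""
        if not self.trained:
            warnings.warn("classifier has not been trained; outputs are arbitrary")
        return softmax(self.net.forward(self._to_batch(x)))

    def predict_risk(self, x):
        """Risk that the maneuver is unacceptable, in [0, 1].

        Returns a scalar for a single construct, an array for a batch.
        """
        if isinstance(x, GraphicalConstruct):
            single = True
        else:
            single = np.asarray(x).ndim in (2, 3)
        risks = self.predict_proba(x)[:, 1]
        return float(risks[0]) if single else risks


def standardize(gray: np.ndarray) -> np.ndarray:
    """Map [0, 255] grays to the net's expected input scale (zero-centered)."""
    return (gray.astype(np.float32) / 255.0) - 0.5


def build_classifier(pretrained: bool = False, seed: int = 0) -> SpiroClassifier:
    """Create an untrained classifier.

    ``pretrained`` is accepted for interface symmetry with
    transfer-learning setups but no pretrained weights ship with this
    package, so requesting them raises.
    """
    if pretrained:
        raise InvalidParameterError(
            "no pretrained backbone weights are bundled; use pretrained=False"
        )
    return SpiroClassifier(net=ConvNet(rng=np.random.default_rng(seed)))


def encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        mapping = {name: i for i, name in enumerate(CLASS_NAMES)}
        try:
            arr = np.array([mapping[str(v)] for v in arr])
        except KeyError as exc:
            raise InvalidParameterError(f"unknown label {exc}") from exc
    arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise InvalidParameterError("labels must be binary")
    return arr


@dataclass
class TrainResult:
    classifier: SpiroClassifier
    history: pd.DataFrame  # per-evaluation train/validation losses
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    best_eval: int


def train(
    images,
    labels,
    tc: TrainConfig | None = None,
    ac: AugmentConfig | None = None,
    split: SplitSpec | None = None,
    seed: int = 0,
) -> TrainResult:
    """Fit the classifier on labeled constructs.

    ``images`` is an (n, 224, 224, 3) uint8 array (or a list of
    :class:`GraphicalConstruct`); ``labels`` are 0/1 or
    acceptable/unacceptable strings. The dataset is split into train /
    validation / test per ``split``; the test indices are returned
    untouched for downstream evaluation. Three independent RNG streams
    (initialization, shuffling, augmentation) are derived from ``seed``,
    so disabling augmentation does not perturb the rest of the run.
    """
    tc = tc or TrainConfig()
    ac = ac or AugmentConfig()
    split = split or SplitSpec(seed=seed)

    if isinstance(images, (list, tuple)):
        images = np.stack(
            [im.network_input if isinstance(im, GraphicalConstruct) else im
             for im in images]
        )
    y = encode_labels(labels)
    if min(np.bincount(y, minlength=2)) < 2:
        raise InvalidParameterError("need at least 2 examples of each class")

    tr_idx, val_idx, test_idx = split_dataset(y, split)
    if val_idx.size == 0:
        raise InvalidParameterError("validation set is empty")

    gray = images.astype(np.float32).mean(axis=-1)  # (n, H, W) on [0, 255]
    init_ss, shuffle_ss, aug_ss = np.random.SeedSequence(seed).spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    aug_rng = np.random.default_rng(aug_ss)

    clf = SpiroClassifier(net=ConvNet(rng=np.random.default_rng(init_ss)))
    opt = Adam(clf.net, lr=tc.learning_rate)
    stopper = EarlyStopper(tc.validation_patience)
    x_val = standardize(gray[val_idx])[:, None]
    y_val = y[val_idx]

    best_params = clf.net.get_params()
    rows = []
    for epoch in range(1, tc.max_epochs + 1):
        order = shuffle_rng.permutation(tr_idx)
        epoch_losses = []
        for start in range(0, order.size, tc.mini_batch):
            batch = order[start : start + tc.mini_batch]
            if ac.enabled:
                xb = np.stack(
                    [augment_image(gray[i], ac, aug_rng) for i in batch]
                ).astype(np.float32)
            else:
                xb = gray[batch]
            xb = standardize(xb)[:, None]
            logits = clf.net.forward(xb)
            loss, dlogits = softmax_cross_entropy(logits, y[batch])
            clf.net.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)

        val_loss, _ = softmax_cross_entropy(clf.net.forward(x_val), y_val)
        stop = stopper.update(val_loss)
        if stopper.improved:
            best_params = clf.net.get_params()
        rows.append(
            {"evaluation": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_loss": val_loss}
        )
        if stop:
            break

    clf.net.set_params(best_params)
    clf.trained = True
    return TrainResult(
        classifier=clf,
        history=pd.DataFrame(rows),
        train_idx=tr_idx,
        val_idx=val_idx,
        test_idx=test_idx,
        best_eval=stopper.best_eval,
    )


def predict_risk(classifier: SpiroClassifier, construct):
    """Module-level alias for :meth:`SpiroClassifier.predict_risk`."""
    return classifier.predict_risk(construct)


# --- checkpoints --------------------------------------------------------------


def save_checkpoint(classifier: SpiroClassifier, path: str | Path) -> None:
    """Write parameters + metadata as a single ``.npz`` archive."""
    meta = json.dumps({"class_names": CLASS_NAMES, "trained": classifier.trained})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **classifier.net.get_params())


def load_checkpoint(path: str | Path) -> SpiroClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    clf = SpiroClassifier(net=ConvNet())
    try:
        clf.net.set_params(params)
    except KeyError as exc:
        raise SpiroQCError(f"checkpoint {path} is incompatible: {exc}") from exc
    clf.trained = bool(meta.get("trained", True))
    return clf
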