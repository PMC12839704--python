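"""Grad-CAM heatmaps over the graphical construct.

The class score's gradient with respect to the last convolutional
block's activations is averaged per channel to weight those activation
maps; the rectified weighted sum, upsampled to the input size and
max-normalized, highlights the image regions with the greatest influence
on the prediction — e.g. a cough spike at the end of the flow-volume
curve on an unacceptable test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as sk_resize

from .construct import GraphicalConstruct
from .errors import InvalidParameterError
from .model import CLASS_NAMES, SpiroClassifier

__all__ = ["Heatmap", "grad_cam", "overlay"]


@dataclass
class Heatmap:
    """Non-negative attribution map on [0, 1], sized like the net input."""

    values: np.ndarray  # (H, W) float, min ≥ 0, max = 1 unless constant
    target_class: str


def grad_cam(
    classifier: SpiroClassifier, construct, target_class: str | int | None = None
) -> Heatmap:
    """Gradient-weighted class-activation map for one construct.

    ``target_class`` may be a class name, an index, or None for the
    predicted class. Works on untrained classifiers too (with a warning),
    since the map is then valid but uninformative.
    """
    if not classifier.trained:
        warnings.warn("classifier is untrained; heatmap will be uninformative")
    x = classifier._to_batch(construct)
    logits = classifier.net.forward(x)
    if target_class is None:
        target = int(np.argmax(logits[0]))
    elif isinstance(target_class, str):
        if target_class not in CLASS_NAMES:
            raise InvalidParameterError(f"unknown class {target_class!r}")
        target = CLASS_NAMES.index(target_class)
    else:
        target = int(target_class)
        if target not in (0, 1):
            raise InvalidParameterError(f"class index out of range: {target}")

    # gradient of the target logit w.r.t. the last conv activations
    dlogits = np.zeros_like(logits)
    dlogits[0, target] = 1.0
    grads = classifier.net.backward_to_features(dlogits)[0]  # (C, h, w)
    acts = classifier.net.features[0]
    weights = grads.mean(axis=(1, 2))  # channel-wise gradient average
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)

    h, w = x.shape[2], x.shape[3]
    cam = sk_resize(cam, (h, w), order=1, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return Heatmap(values=cam, target_class=CLASS_NAMES[target])


def overlay(
    construct,
    heatmap: Heatmap,
    alpha: float = 0.4,
    cmap: str = "inferno",
) -> np.ndarray:
    """Blend the heatmap over the grayscale construct.

    Returns an (H, W, 3) uint8 image: the construct rendered in gray,
    combined pixel-wise with the colormapped heatmap at opacity ``alpha``
    (0 → construct only, 1 → heatmap only).
    """
    img = construct.network_input if isinstance(construct, GraphicalConstruct) else construct
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    if img.shape[:2] != heatmap.values.shape:
        raise InvalidParameterError(
            f"shape mismatch: image {img.shape[:2]} vs heatmap {heatmap.values.shape}"
        )
    base = img.astype(float) / 255.0
    colored = colormaps[cmap](heatmap.values)[..., :3]
    blended = (1.0 - alpha) * base + alpha * colored
    return np.rint(blended * 255.0).astype(np.uint8)
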