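"""Network-attention heatmaps and the Heatmap Concordance Score (HCS).

Grad-CAM saliency is computed per output class at the classifier's last
convolutional layer: channel weights are the spatially pooled gradients of
that class's score, the map is the rectified weighted sum of activations,
up-sampled to the image and min-max normalised to [0, 1].  A single
"attention" heatmap per image is the probability-weighted average of the
four class maps; the left-lung and right-lung classifiers' heatmaps average
into a whole-lung heatmap.

HCS quantifies how much of that salience falls inside the lung boundary:

* ``intensity`` mode (default): sum(mask * heatmap) / sum(heatmap);
* ``count`` mode: the fraction of non-zero heatmap pixels inside the mask.

The two agree exactly on binary heatmaps.  The macro-averaged HCS (MA-HCS)
averages per-image HCS within each true grade, then unweighted across the
grades present — the same macro axis as the ordinal MAE.  Alternative
grouping axes (predicted grade, plain image mean) are exposed.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from skimage.transform import resize

from . import _nn
from .train import OpacityClassifier

__all__ = [
    "SaliencyMap",
    "HCSReport",
    "UndefinedHCS",
    "grad_cam",
    "class_saliency_maps",
    "weighted_heatmap",
    "combine_lr",
    "hcs",
    "macro_hcs",
    "attention_heatmap",
]


class UndefinedHCS(ValueError):
    """HCS is undefined for an all-zero heatmap."""


@dataclasses.dataclass
class SaliencyMap:
    values: np.ndarray      # [0, 1], image-aligned
    class_index: int
    source_layer: str


def grad_cam(model: OpacityClassifier, image: np.ndarray,
             class_index: int) -> SaliencyMap:
    """Grad-CAM map for one class at the last convolutional layer.

    ``image`` is a normalized (channels, H, W) or (H, W) raster.  The map is
    rectified, up-sampled to the image's spatial size and min-max scaled to
    [0, 1]; an all-zero map stays all-zero.
    """
    convs = model.conv_layers()
    if not convs:
        raise ValueError("model has no convolutional layers")
    if not 0 <= class_index < 4:
        raise ValueError("class_index must be in 0..3")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    x = x[None]  # batch of one
    logits = model.forward(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_index] = 1.0
    # propagate d(score)/d(activations); parameter grads are not needed
    flags = [(c, c.compute_param_grads) for c in
             _nn.iter_convs(model.features, include_shortcut=True)]
    for c, _ in flags:
        c.compute_param_grads = False
    head_flags = []
    for layer in model.head.layers:
        if hasattr(layer, "compute_param_grads"):
            head_flags.append((layer, layer.compute_param_grads))
            layer.compute_param_grads = False
    try:
        model.backward_from_logits(dlogits)
    finally:
        for c, f in flags:
            c.compute_param_grads = f
        for l, f in head_flags:
            l.compute_param_grads = f

    last = convs[-1]
    acts = last.out_cache[0]        # (C, h, w)
    grads = last.dout_cache[0]
    weights = grads.mean(axis=(1, 2))               # global pooling of gradients
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    cam = resize(cam, x.shape[2:], order=1)
    mx = cam.max()
    if mx > 0:
        cam = cam / mx
    return SaliencyMap(cam.astype(np.float32), class_index,
                       source_layer=last.name)


def class_saliency_maps(model: OpacityClassifier, image: np.ndarray) -> list[SaliencyMap]:
    return [grad_cam(model, image, c) for c in range(4)]


def weighted_heatmap(maps, probabilities) -> np.ndarray:
    """Pixelwise probability-weighted average of the class saliency maps."""
    probabilities = np.asarray(probabilities, dtype=float)
    rasters = [m.values if isinstance(m, SaliencyMap) else np.asarray(m)
               for m in maps]
    if len(rasters) != probabilities.size:
        raise ValueError("probability/map count mismatch")
    if not np.isclose(probabilities.sum(), 1.0, atol=1e-4):
        raise ValueError("probabilities must sum to 1")
    out = np.zeros_like(rasters[0], dtype=np.float64)
    for p, r in zip(probabilities, rasters):
        out += p * r
    return out.astype(np.float32)


def combine_lr(h_left: np.ndarray, h_right: np.ndarray) -> np.ndarray:
    """Whole-lung heatmap: pixelwise mean of the two sides' heatmaps."""
    h_left = np.asarray(h_left)
    h_right = np.asarray(h_right)
    if h_left.shape != h_right.shape:
        raise ValueError("heatmap shape mismatch")
    return ((h_left + h_right) / 2.0).astype(np.float32)


def hcs(heatmap: np.ndarray, lung_mask: np.ndarray, mode: str = "intensity") -> float:
    """Heatmap Concordance Score in [0, 1].

    ``intensity``: salience-weighted fraction inside the mask;
    ``count``: fraction of non-zero pixels inside the mask.
    """
    heatmap = np.asarray(heatmap, dtype=float)
    mask = np.asarray(lung_mask).astype(bool)
    if heatmap.shape != mask.shape:
        raise ValueError("mask not aligned with heatmap")
    if mode == "intensity":
        total = heatmap.sum()
        if total <= 0:
            raise UndefinedHCS("all-zero heatmap")
        return float((heatmap * mask).sum() / total)
    if mode == "count":
        nz = heatmap > 0
        total = int(nz.sum())
        if total == 0:
            raise UndefinedHCS("all-zero heatmap")
        return float((nz & mask).sum() / total)
    raise ValueError("mode must be 'intensity' or 'count'")


@dataclasses.dataclass
class HCSReport:
    per_image_hcs: list
    per_class_mean: dict     # true grade -> mean HCS
    ma_hcs: float
    group_by: str = "true_class"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)


def macro_hcs(hcs_values, classes, group_by: str = "true_class") -> HCSReport:
    """Macro-average per-image HCS over grades.

    ``classes`` carries each image's grade on the chosen axis
    (``true_class`` by default, ``pred_class``, or ``none`` for a plain
    image mean).
    """
    vals = np.asarray(list(hcs_values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty HCS input")
    if group_by == "none":
        m = float(vals.mean())
        return HCSReport(vals.tolist(), {}, m, group_by="none")
    cls = np.asarray(list(classes), dtype=int)
    if cls.shape != vals.shape:
        raise ValueError("classes and hcs_values must be parallel")
    per_class = {int(c): float(vals[cls == c].mean()) for c in np.unique(cls)}
    ma = float(np.mean(list(per_class.values())))
    return HCSReport(vals.tolist(), per_class, ma, group_by=group_by)


def attention_heatmap(model: OpacityClassifier, image: np.ndarray) -> np.ndarray:
    """One-call helper: class maps weighted by the model's probabilities."""
    x = np.asarray(image, dtype=np.float32)
    probs = model.predict_proba((x if x.ndim == 3 else x[None])[None])[0]
    maps = class_saliency_maps(model, image)
    return weighted_heatmap(maps, probs)
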