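"""ROI extraction for per-lung grading: none / lung-mask / spine-split.

Three schemes feed the classifiers:

* ``NONE`` — the full radiograph, both lungs visible;
* ``LUNG`` — a U-Net lung segmentation, the requested side masked out and
  (by default) cropped to its bounding box;
* ``SPINE`` — a U-Net spine segmentation whose per-row centroid, median
  smoothed, defines a vertical split curve dividing the frame into
  patient-left and patient-right halves.

The segmenter is a small encoder-decoder with skip connections trained on
binary masks.  It runs internally at a reduced resolution (64 x 64 by
default) and up-samples its prediction back to the input size; this keeps
CPU training at test scale while leaving the 256 x 256 external contract
unchanged.

Laterality is in patient coordinates throughout: the patient-left lung sits
on the viewer-right half of an AP/PA radiograph.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import warnings
from pathlib import Path

import numpy as np
from scipy.signal import medfilt
from skimage import measure
from skimage.transform import resize

from . import _nn

__all__ = [
    "SegScheme",
    "SegmenterModel",
    "SegmentationFailure",
    "train_segmenter",
    "segment_lungs",
    "split_by_spine",
    "extract_roi",
    "normalize_for_net",
    "iou",
    "save_segmenter",
    "load_segmenter",
]

log = logging.getLogger("cxrgrade.segment")


class SegScheme(str, enum.Enum):
    NONE = "none"
    LUNG = "lung"
    SPINE = "spine"


class SegmentationFailure(RuntimeError):
    """Lung ROI segmentation produced an empty component.

    ``side`` names the empty side: "left", "right", or "both".
    """

    def __init__(self, side: str, message: str | None = None) -> None:
        super().__init__(message or f"empty segmentation on side: {side}")
        self.side = side


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


class _UNet:
    """Encoder-decoder with two skip connections, sigmoid output."""

    def __init__(self, seed: int = 0, width: int = 8) -> None:
        rng = np.random.default_rng(seed)
        w = width
        self.c1 = _nn.Conv2d(1, w, rng=rng, name="enc1")
        self.c2 = _nn.Conv2d(w, 2 * w, rng=rng, name="enc2")
        self.c3 = _nn.Conv2d(2 * w, 4 * w, rng=rng, name="bottleneck")
        self.c4 = _nn.Conv2d(4 * w + 2 * w, 2 * w, rng=rng, name="dec1")
        self.c5 = _nn.Conv2d(2 * w + w, w, rng=rng, name="dec2")
        self.out = _nn.Conv2d(w, 1, k=1, rng=rng, name="head")
        self.r = [_nn.ReLU() for _ in range(5)]
        self.p1, self.p2 = _nn.MaxPool2(), _nn.MaxPool2()
        self.u1, self.u2 = _nn.Upsample2(), _nn.Upsample2()
        self.width = w

    def params(self) -> list[_nn.Param]:
        return [p for l in (self.c1, self.c2, self.c3, self.c4, self.c5, self.out)
                for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        a1 = self.r[0].forward(self.c1.forward(x))
        a2 = self.r[1].forward(self.c2.forward(self.p1.forward(a1)))
        a3 = self.r[2].forward(self.c3.forward(self.p2.forward(a2)))
        u1 = self.u1.forward(a3)
        a4 = self.r[3].forward(self.c4.forward(np.concatenate([u1, a2], axis=1)))
        u2 = self.u2.forward(a4)
        a5 = self.r[4].forward(self.c5.forward(np.concatenate([u2, a1], axis=1)))
        logits = self.out.forward(a5)
        self._w2 = a3.shape[1]
        return _nn.sigmoid(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        d5 = self.c5.backward(self.r[4].backward(self.out.backward(dlogits)))
        # c5 input was concat(u2[2w], a1[w]) -> split at 2w
        du2, da1b = d5[:, : 2 * self.width], d5[:, 2 * self.width:]
        d4 = self.u2.backward(du2)
        d4 = self.c4.backward(self.r[3].backward(d4))
        du1, da2b = d4[:, : 4 * self.width], d4[:, 4 * self.width:]
        d3 = self.u1.backward(du1)
        d3 = self.r[2].backward(d3)
        d2 = self.p2.backward(self.c3.backward(d3)) + da2b
        d2 = self.r[1].backward(d2)
        d1 = self.p1.backward(self.c2.backward(d2)) + da1b
        self.c1.backward(self.r[0].backward(d1))


@dataclasses.dataclass
class SegmenterModel:
    """A trained segmenter plus its provenance sidecar fields."""

    net: _UNet
    target: str                 # "lungs" or "spine"
    input_size: int = 256
    internal_size: int = 64
    seed: int = 0

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability raster in [0, 1], same shape as the input image."""
        if image.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        img = _to_float01(image)
        small = resize(img, (self.internal_size, self.internal_size),
                       anti_aliasing=True)
        x = small[None, None].astype(np.float32)
        p = self.net.forward(x)[0, 0]
        return resize(p, image.shape, order=1).astype(np.float32)


def _to_float01(image: np.ndarray) -> np.ndarray:
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float32) / np.iinfo(image.dtype).max
    return np.clip(image.astype(np.float32), 0, 1)


def train_segmenter(images, masks, target: str, epochs: int = 20, seed: int = 0,
                    internal_size: int = 64, lr: float = 3e-3,
                    batch_size: int = 8) -> SegmenterModel:
    """Train the encoder-decoder on image/mask pairs (binary cross-entropy).

    Requires at least 8 pairs.  Deterministic given ``seed``.
    """
    images = list(images)
    masks = list(masks)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(masks):
        raise ValueError("images and masks differ in count")
    if len(images) < 8:
        raise ValueError("need at least 8 image/mask pairs")
    if target not in ("lungs", "spine"):
        raise ValueError("target must be 'lungs' or 'spine'")
    shape = images[0].shape
    for im, mk in zip(images, masks):
        if im.shape != mk.shape:
            raise ValueError("mismatched image/mask shapes")

    xs = np.stack([
        resize(_to_float01(im), (internal_size, internal_size), anti_aliasing=True)
        for im in images]).astype(np.float32)[:, None]
    ts = np.stack([
        resize(mk.astype(float), (internal_size, internal_size), order=0)
        for mk in masks]).astype(np.float32)[:, None]

    net = _UNet(seed=seed)
    opt = _nn.Adam(net.params(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    n = len(xs)
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            p = net.forward(xs[idx])
            dlogits = (p - ts[idx]) / p.size  # d BCE / d logits through sigmoid
            opt.zero_grad()
            net.backward(dlogits.astype(np.float32))
            opt.step()
    return SegmenterModel(net=net, target=target, input_size=shape[0],
                          internal_size=internal_size, seed=seed)


def segment_lungs(model: SegmenterModel, image: np.ndarray,
                  threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Split the thresholded lung prediction into patient-left/right masks.

    Post-processing keeps the two largest connected components; the one
    centred on the viewer-left half is the patient-right lung.  An empty
    side raises :class:`SegmentationFailure` naming the side.
    """
    pred = model.predict(image) >= threshold
    labels = measure.label(pred)
    props = sorted(measure.regionprops(labels), key=lambda r: r.area, reverse=True)
    props = [p for p in props[:2] if p.area > 0]
    if not props:
        raise SegmentationFailure("both")
    mid = image.shape[1] / 2
    left = np.zeros_like(pred)   # patient-left (viewer right)
    right = np.zeros_like(pred)  # patient-right (viewer left)
    for p in props:
        comp = labels == p.label
        if p.centroid[1] < mid:
            right |= comp
        else:
            left |= comp
    if not right.any():
        raise SegmentationFailure("right")
    if not left.any():
        raise SegmentationFailure("left")
    return left, right


def split_by_spine(model: SegmenterModel, image: np.ndarray,
                   threshold: float = 0.5, smooth: int = 15):
    """Vertical split curve from the per-row spine-mask centroid.

    Rows with an empty spine prediction interpolate from neighbouring rows;
    a fully empty spine falls back to the midline with a logged warning.
    Returns (patient-left half, patient-right half, split curve), the halves
    zero-filled outside their side so they partition the original image.
    """
    h, w = image.shape
    pred = model.predict(image) >= threshold
    cols = np.arange(w)
    curve = np.full(h, np.nan)
    for r in range(h):
        row = pred[r]
        if row.any():
            curve[r] = (cols[row]).mean()
    valid = ~np.isnan(curve)
    if not valid.any():
        log.warning("spine mask empty everywhere; falling back to midline split")
        curve = np.full(h, w / 2.0)
    else:
        curve = np.interp(np.arange(h), np.flatnonzero(valid), curve[valid])
        k = min(smooth if smooth % 2 else smooth + 1, h if h % 2 else h - 1)
        curve = medfilt(curve, kernel_size=k)
    split = np.clip(np.round(curve).astype(int), 0, w)
    xs = np.arange(w)[None, :]
    right_region = xs < split[:, None]   # viewer-left = patient right
    img = _to_float01(image)
    right_half = np.where(right_region, img, 0.0)
    left_half = np.where(~right_region, img, 0.0)
    return left_half.astype(np.float32), right_half.astype(np.float32), curve


def extract_roi(image: np.ndarray, scheme: SegScheme, side: str = "left",
                masks: dict | None = None, crop: bool = True) -> np.ndarray:
    """Apply one ROI scheme for one lung side.

    ``masks`` supplies ``left``/``right`` lung masks for ``LUNG`` and
    ``left_half``/``right_half`` images for ``SPINE``.
    """
    scheme = SegScheme(scheme)
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    img = _to_float01(image)
    if scheme is SegScheme.NONE:
        return img
    if masks is None:
        raise ValueError(f"masks required for scheme {scheme.value}")
    if scheme is SegScheme.LUNG:
        mask = masks.get(side)
        if mask is None:
            raise ValueError(f"missing '{side}' lung mask")
        out = np.where(mask.astype(bool), img, 0.0)
        if crop and mask.any():
            rows = np.flatnonzero(mask.any(axis=1))
            colsnz = np.flatnonzero(mask.any(axis=0))
            out = out[rows[0]:rows[-1] + 1, colsnz[0]:colsnz[-1] + 1]
        return out.astype(np.float32)
    half = masks.get(f"{side}_half")
    if half is None:
        raise ValueError(f"missing '{side}_half' image for spine scheme")
    return _to_float01(half)


def normalize_for_net(image: np.ndarray, size: int = 224,
                      channels: int = 1) -> np.ndarray:
    """Resize to ``size`` x ``size`` and scale intensities to [0, 1].

    Integer inputs divide by their dtype maximum (preserving absolute
    intensity cues across images); float inputs are clipped to [0, 1].
    Output is (channels, size, size) float32 with the gray plane replicated.
    """
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    img = _to_float01(image)
    if img.shape != (size, size):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            img = resize(img, (size, size), anti_aliasing=True)
    out = np.repeat(img[None], channels, axis=0)
    return np.clip(out, 0, 1).astype(np.float32)


def save_segmenter(model: SegmenterModel, path) -> None:
    """Checkpoint as .npz with a JSON sidecar (target, sizes, seed)."""
    path = Path(path)
    arrays = {p.name: p.value for p in model.net.params()}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"target": model.target, "input_size": model.input_size,
               "internal_size": model.internal_size, "seed": model.seed,
               "width": model.net.width}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_segmenter(path) -> SegmenterModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    net = _UNet(seed=sidecar["seed"], width=sidecar["width"])
    data = np.load(path.with_suffix(".npz"))
    for p in net.params():
        p.value[...] = data[p.name]
    return SegmenterModel(net=net, target=sidecar["target"],
                          input_size=sidecar["input_size"],
                          internal_size=sidecar["internal_size"],
                          seed=sidecar["seed"])
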