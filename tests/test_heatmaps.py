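"""Saliency maps and the Heatmap Concordance Score."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cxrgrade import _nn, heatmaps


class _OneHotModel:
    """Hand-built model whose Grad-CAM map is known exactly.

    Channel 0 copies the input; the class-3 score is its global mean, so the
    class-3 saliency map must peak exactly at the brightest input pixel.
    """

    def __init__(self):
        rng = np.random.default_rng(0)
        conv = _nn.Conv2d(1, 2, 3, stride=1, pad=1, rng=rng, name="c1")
        W = np.zeros((2, 1, 3, 3), dtype=np.float32)
        W[0, 0, 1, 1] = 1.0     # channel 0 = identity
        W[1, 0, 1, 1] = -1.0    # channel 1 = negated input
        conv.W.value[...] = W.reshape(2, -1)
        conv.b.value[...] = 0
        self.features = _nn.Sequential([conv])
        self.gap = _nn.GlobalAvgPool()
        d = _nn.Dense(2, 4, rng=rng, name="fc")
        d.W.value[...] = 0
        d.W.value[0, 3] = 1.0   # class-3 score = mean(channel 0)
        d.b.value[...] = 0
        self.head = _nn.Sequential([d])

    def conv_layers(self):
        return list(_nn.iter_convs(self.features))

    def forward(self, x):
        return self.head.forward(self.gap.forward(self.features.forward(x)))

    def backward_from_logits(self, dl, through_features=True):
        d = self.head.backward(dl)
        if through_features:
            self.features.backward(self.gap.backward(d))


def test_grad_cam_matches_hand_built_oracle():
    model = _OneHotModel()
    img = np.zeros((8, 8), dtype=np.float32)
    img[1, 5] = 1.0
    sal = heatmaps.grad_cam(model, img, 3)
    assert sal.values.shape == img.shape
    assert np.unravel_index(sal.values.argmax(), (8, 8)) == (1, 5)
    assert sal.values.max() == pytest.approx(1.0)
    assert float(sal.values.sum() - sal.values.max()) == pytest.approx(0.0)
    assert sal.class_index == 3
    assert sal.source_layer == "c1"


def test_grad_cam_rejects_bad_class_index():
    model = _OneHotModel()
    img = np.zeros((8, 8), dtype=np.float32)
    with pytest.raises(ValueError):
        heatmaps.grad_cam(model, img, 4)
    with pytest.raises(ValueError):
        heatmaps.grad_cam(model, img, -1)


def test_grad_cam_on_real_model_is_normalized(tiny_trained, phantom_arrays):
    model, _ = tiny_trained
    X, _, _ = phantom_arrays["test"]
    sal = heatmaps.grad_cam(model, X[0], 2)
    assert sal.values.shape == X[0].shape[1:]
    assert sal.values.min() >= 0.0
    assert sal.values.max() <= 1.0
    if sal.values.any():
        assert sal.values.max() == pytest.approx(1.0)


def test_grad_cam_restores_freeze_flags(tiny_trained, phantom_arrays):
    model, _ = tiny_trained
    X, _, _ = phantom_arrays["test"]
    before = [c.compute_param_grads for c in model.conv_layers()]
    heatmaps.grad_cam(model, X[1], 0)
    after = [c.compute_param_grads for c in model.conv_layers()]
    assert before == after


def test_weighted_heatmap_is_convex_combination():
    a = np.zeros((4, 4)); a[0, 0] = 1.0
    b = np.zeros((4, 4)); b[3, 3] = 1.0
    out = heatmaps.weighted_heatmap([a, b, np.zeros((4, 4)), np.zeros((4, 4))],
                                    [0.25, 0.75, 0.0, 0.0])
    assert out[0, 0] == pytest.approx(0.25)
    assert out[3, 3] == pytest.approx(0.75)
    with pytest.raises(ValueError):
        heatmaps.weighted_heatmap([a, b], [0.5, 0.6])
    with pytest.raises(ValueError):
        heatmaps.weighted_heatmap([a], [0.5, 0.5])


def test_combine_lr_averages():
    a = np.full((4, 4), 0.2, np.float32)
    b = np.full((4, 4), 0.6, np.float32)
    np.testing.assert_allclose(heatmaps.combine_lr(a, b), 0.4)
    with pytest.raises(ValueError):
        heatmaps.combine_lr(a, np.zeros((2, 2)))


def test_hcs_support_inside_mask_is_one():
    h = np.zeros((10, 10)); h[2:4, 2:4] = 0.7
    mask = np.zeros((10, 10), bool); mask[:5, :5] = True
    assert heatmaps.hcs(h, mask) == 1.0
    assert heatmaps.hcs(h, mask, mode="count") == 1.0


def test_hcs_support_outside_mask_is_zero():
    h = np.zeros((10, 10)); h[8:, 8:] = 0.7
    mask = np.zeros((10, 10), bool); mask[:5, :5] = True
    assert heatmaps.hcs(h, mask) == 0.0
    assert heatmaps.hcs(h, mask, mode="count") == 0.0


def test_hcs_uniform_heatmap_equals_mask_fraction():
    h = np.full((10, 10), 0.5)
    mask = np.zeros((10, 10), bool)
    mask.flat[:30] = True      # 30 % of the image
    assert heatmaps.hcs(h, mask) == pytest.approx(0.3)
    assert heatmaps.hcs(h, mask, mode="count") == pytest.approx(0.3)


@given(st.integers(min_value=0, max_value=10_000))
def test_hcs_monotone_under_in_mask_mass(seed):
    rng = np.random.default_rng(seed)
    h = rng.random((8, 8))
    mask = rng.random((8, 8)) < 0.4
    if not mask.any() or h.sum() == 0:
        return
    before = heatmaps.hcs(h, mask)
    bumped = h.copy()
    rows, cols = np.nonzero(mask)
    bumped[rows[0], cols[0]] += 1.0
    assert heatmaps.hcs(bumped, mask) >= before


def test_hcs_undefined_and_invalid():
    mask = np.ones((4, 4), bool)
    with pytest.raises(heatmaps.UndefinedHCS):
        heatmaps.hcs(np.zeros((4, 4)), mask)
    with pytest.raises(heatmaps.UndefinedHCS):
        heatmaps.hcs(np.zeros((4, 4)), mask, mode="count")
    with pytest.raises(ValueError):
        heatmaps.hcs(np.ones((4, 4)), np.ones((2, 2), bool))
    with pytest.raises(ValueError):
        heatmaps.hcs(np.ones((4, 4)), mask, mode="area")


def test_intensity_and_count_agree_on_binary_maps():
    rng = np.random.default_rng(3)
    h = (rng.random((12, 12)) < 0.5).astype(float)
    mask = rng.random((12, 12)) < 0.5
    if h.sum():
        assert heatmaps.hcs(h, mask) == pytest.approx(
            heatmaps.hcs(h, mask, mode="count"))


def test_macro_hcs_grouping_and_json(tmp_path):
    vals = [0.2, 0.4, 0.8, 1.0]
    cls = [0, 0, 3, 3]
    rep = heatmaps.macro_hcs(vals, cls)
    assert rep.per_class_mean == {0: pytest.approx(0.3), 3: pytest.approx(0.9)}
    assert rep.ma_hcs == pytest.approx(0.6)
    plain = heatmaps.macro_hcs(vals, None, group_by="none")
    assert plain.ma_hcs == pytest.approx(np.mean(vals))
    with pytest.raises(ValueError):
        heatmaps.macro_hcs([], [])
    with pytest.raises(ValueError):
        heatmaps.macro_hcs([0.1, 0.2], [0])
    path = tmp_path / "hcs.json"
    rep.to_json(path)
    assert path.exists()


def test_attention_heatmap_shape(tiny_trained, phantom_arrays):
    model, _ = tiny_trained
    X, _, _ = phantom_arrays["test"]
    h = heatmaps.attention_heatmap(model, X[0])
    assert h.shape == X[0].shape[1:]
    assert h.min() >= 0.0
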