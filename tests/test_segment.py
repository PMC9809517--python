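"""Segmentation: IoU, segmenter training, ROI schemes, checkpointing."""

import numpy as np
import pytest
from PIL import Image

from cxrgrade import phantoms, segment


def test_iou_basics():
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    a[:2] = True
    b[1:3] = True
    assert segment.iou(a, a) == 1.0
    assert segment.iou(a, b) == pytest.approx(8 / 24)
    assert segment.iou(a, ~a) == 0.0
    assert segment.iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0


def test_train_segmenter_validation():
    imgs = [np.zeros((32, 32), np.float32)] * 8
    masks = [np.zeros((32, 32), bool)] * 8
    with pytest.raises(ValueError):
        segment.train_segmenter([], [], "lungs")
    with pytest.raises(ValueError):
        segment.train_segmenter(imgs, masks[:7], "lungs")
    with pytest.raises(ValueError):
        segment.train_segmenter(imgs[:7], masks[:7], "lungs")
    with pytest.raises(ValueError):
        segment.train_segmenter(imgs, masks, "heart")
    with pytest.raises(ValueError):
        segment.train_segmenter(imgs, [np.zeros((16, 16), bool)] * 8, "lungs")


def _cohort_pairs(manifest, n, attr):
    rows = manifest[~manifest["is_document"]
                    & ~manifest["is_filtered"]].head(n)
    images, masks = [], []
    for _, row in rows.iterrows():
        images.append(np.asarray(Image.open(row["image_path"]).convert("L")))
        truth = phantoms.load_truth(row["image_path"])
        if attr == "lungs":
            masks.append(truth.left_mask | truth.right_mask)
        else:
            masks.append(truth.spine_mask)
    return images, masks


@pytest.fixture(scope="module")
def lung_segmenter(cohort_manifest):
    images, masks = _cohort_pairs(cohort_manifest, 16, "lungs")
    return segment.train_segmenter(images, masks, "lungs", epochs=40, seed=2)


def test_lung_segmenter_learns_held_out_iou(lung_segmenter, cohort_manifest):
    rows = cohort_manifest[~cohort_manifest["is_document"] & ~cohort_manifest["is_filtered"]].iloc[16:20]
    scores = []
    for _, row in rows.iterrows():
        img = np.asarray(Image.open(row["image_path"]).convert("L"))
        truth = phantoms.load_truth(row["image_path"])
        pred = lung_segmenter.predict(img) >= 0.5
        scores.append(segment.iou(pred, truth.left_mask | truth.right_mask))
    assert np.mean(scores) > 0.5


def test_predict_shape_and_range(lung_segmenter):
    img = np.random.default_rng(0).random((128, 128)).astype(np.float32)
    p = lung_segmenter.predict(img)
    assert p.shape == img.shape
    assert p.min() >= 0.0 and p.max() <= 1.0
    with pytest.raises(ValueError):
        lung_segmenter.predict(img[None])


def test_segment_lungs_sides_in_patient_coordinates(lung_segmenter,
                                                    cohort_manifest):
    row = cohort_manifest[~cohort_manifest["is_document"] & ~cohort_manifest["is_filtered"]].iloc[17]
    img = np.asarray(Image.open(row["image_path"]).convert("L"))
    left, right = segment.segment_lungs(lung_segmenter, img)
    assert not (left & right).any()
    w = img.shape[1]
    assert np.flatnonzero(left.any(axis=0)).mean() > w / 2
    assert np.flatnonzero(right.any(axis=0)).mean() < w / 2


def test_segment_lungs_failure_names_side(lung_segmenter):
    blank = np.zeros((128, 128), np.float32)
    with pytest.raises(segment.SegmentationFailure):
        segment.segment_lungs(lung_segmenter, blank, threshold=1.1)


def test_split_by_spine_partitions_image(spine_segmenter, cohort_manifest):
    row = cohort_manifest[~cohort_manifest["is_document"] & ~cohort_manifest["is_filtered"]].iloc[3]
    img = np.asarray(Image.open(row["image_path"]).convert("L"))
    left_half, right_half, curve = segment.split_by_spine(spine_segmenter, img)
    assert curve.shape == (img.shape[0],)
    recombined = left_half + right_half
    np.testing.assert_allclose(recombined, img.astype(np.float32) / 255,
                               atol=1e-6)
    # each half is zero on the other side of the split curve
    assert (left_half * right_half == 0).all()
    w = img.shape[1]
    assert np.abs(curve - w / 2).max() < w / 4       # near-central spine


def test_split_by_spine_midline_fallback(spine_segmenter):
    blank = np.zeros((64, 64), np.float32)
    _, _, curve = segment.split_by_spine(spine_segmenter, blank, threshold=1.1)
    np.testing.assert_allclose(curve, 32.0)


def test_extract_roi_none_returns_full_image():
    img = (np.random.default_rng(1).random((32, 32)) * 255).astype(np.uint8)
    out = segment.extract_roi(img, segment.SegScheme.NONE)
    assert out.shape == img.shape
    np.testing.assert_allclose(out, img / 255, atol=1e-6)


def test_extract_roi_lung_masks_and_crops():
    img = np.ones((32, 32), np.float32)
    mask = np.zeros((32, 32), bool)
    mask[10:20, 5:15] = True
    out = segment.extract_roi(img, segment.SegScheme.LUNG, side="left",
                              masks={"left": mask})
    assert out.shape == (10, 10)
    assert (out == 1.0).all()
    full = segment.extract_roi(img, segment.SegScheme.LUNG, side="left",
                               masks={"left": mask}, crop=False)
    assert full.shape == img.shape
    assert full.sum() == mask.sum()


def test_extract_roi_spine_uses_half_images():
    img = np.ones((16, 16), np.float32)
    half = np.zeros((16, 16), np.float32)
    half[:, 8:] = 0.5
    out = segment.extract_roi(img, segment.SegScheme.SPINE, side="left",
                              masks={"left_half": half})
    np.testing.assert_allclose(out, half)


def test_extract_roi_errors():
    img = np.ones((16, 16), np.float32)
    with pytest.raises(ValueError):
        segment.extract_roi(img, segment.SegScheme.LUNG, side="top",
                            masks={})
    with pytest.raises(ValueError):
        segment.extract_roi(img, segment.SegScheme.LUNG)
    with pytest.raises(ValueError):
        segment.extract_roi(img, segment.SegScheme.LUNG, masks={"right": None})
    with pytest.raises(ValueError):
        segment.extract_roi(img, segment.SegScheme.SPINE, masks={})


def test_normalize_for_net_scaling_and_channels():
    img = np.full((100, 80), 128, np.uint8)
    out = segment.normalize_for_net(img, size=64, channels=3)
    assert out.shape == (3, 64, 64)
    assert out.dtype == np.float32
    np.testing.assert_allclose(out, 128 / 255, atol=1e-3)
    np.testing.assert_array_equal(out[0], out[1])
    u16 = np.full((64, 64), 2 ** 15, np.uint16)
    out16 = segment.normalize_for_net(u16, size=64)
    np.testing.assert_allclose(out16, 2 ** 15 / (2 ** 16 - 1), atol=1e-3)
    with pytest.raises(ValueError):
        segment.normalize_for_net(np.zeros((3, 64, 64), np.float32))


def test_save_load_round_trip(spine_segmenter, tmp_path):
    path = tmp_path / "seg"
    segment.save_segmenter(spine_segmenter, path)
    back = segment.load_segmenter(path)
    img = np.random.default_rng(2).random((64, 64)).astype(np.float32)
    np.testing.assert_array_equal(back.predict(img),
                                  spine_segmenter.predict(img))
    assert back.target == "spine"
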