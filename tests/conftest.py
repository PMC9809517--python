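"""Shared fixtures: a small on-disk phantom cohort and lightweight
trained models, all session-scoped so the suite stays fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cxrgrade import phantoms, segment, splits, train

settings.register_profile("suite", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A 24-patient cohort with every artifact type, images on disk."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = phantoms.generate_cohort(
        24, out_dir=out, seed=11,
        artifact_rates={"duplicate_copy": 0.15, "negative": 0.1,
                        "document": 0.1, "pediatric": 0.1},
        image_size=128)
    phantoms.write_manifest(manifest, out / "manifest.csv")
    return out


@pytest.fixture(scope="session")
def cohort_manifest(cohort_dir):
    return phantoms.read_manifest(cohort_dir / "manifest.csv")


@pytest.fixture(scope="session")
def clean_cohort(cohort_dir):
    """A separate artifact-free cohort for split/pipeline tests."""
    out = cohort_dir.parent / "clean_cohort"
    manifest = phantoms.generate_cohort(30, out_dir=out, seed=23,
                                        image_size=128)
    phantoms.write_manifest(manifest, out / "manifest.csv")
    return phantoms.read_manifest(out / "manifest.csv")


def _phantom_batch(n, seed0, size, rng):
    xs, ys, truths = [], [], []
    for i in range(n):
        spec = phantoms.PhantomSpec(left_grade=int(rng.integers(0, 4)),
                                    right_grade=int(rng.integers(0, 4)),
                                    image_size=128, seed=seed0 + i)
        img, truth = phantoms.generate_phantom(spec)
        xs.append(segment.normalize_for_net(img, size=size))
        ys.append(spec.left_grade)
        truths.append(truth)
    return np.stack(xs), np.asarray(ys), truths


@pytest.fixture(scope="session")
def phantom_arrays():
    """In-memory 64x64 phantom tensors: (train, val, test) triples."""
    rng = np.random.default_rng(202)
    return {
        "train": _phantom_batch(240, 0, 64, rng),
        "val": _phantom_batch(40, 5000, 64, rng),
        "test": _phantom_batch(40, 9000, 64, rng),
    }


@pytest.fixture(scope="session")
def tiny_trained(phantom_arrays):
    """A quickly fine-tuned tiny classifier at 64 px for unit tests."""
    Xtr, ytr, _ = phantom_arrays["train"]
    Xv, yv, _ = phantom_arrays["val"]
    plan = splits.BalancedTrainingPlan(
        pd.DataFrame({"i": range(len(ytr))}), pd.DataFrame({"i": []}),
        splits.BalancingScheme.UNDER, "left_grade")

    def loader(rows):
        return (Xtr, ytr) if len(rows) == len(ytr) else (Xv, yv)

    model = train.build_classifier("tiny", side="left", seed=0, input_size=64)
    schedule = train.TrainingSchedule(stage1_epochs_max=30, stage2_epochs_max=40,
                                      lr_reduce_patience=5,
                                      early_stop_patience=8, seed=0)
    model, history = train.fit_two_stage(
        model, plan, pd.DataFrame({"i": range(len(yv))}), schedule,
        loader=loader)
    return model, history


@pytest.fixture(scope="session")
def spine_segmenter(cohort_manifest):
    import PIL.Image
    rows = cohort_manifest[~cohort_manifest["is_document"]
                           & ~cohort_manifest["is_filtered"]].head(12)
    images, masks = [], []
    for _, row in rows.iterrows():
        images.append(np.asarray(PIL.Image.open(row["image_path"]).convert("L")))
        masks.append(phantoms.load_truth(row["image_path"]).spine_mask)
    return segment.train_segmenter(images, masks, "spine", epochs=10, seed=4)
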