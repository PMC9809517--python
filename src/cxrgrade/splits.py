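"""Leakage-free patient-level splits and class-balancing strategies.

A hold-out ("out-of-the-box", OOB) set of whole patients is carved off
first, by accumulating patients until its image count reaches the requested
size; the remaining patients are assigned to five train/validation/test
folds at an 80/10/10 patient ratio.  Every image of a patient lives in
exactly one part of each fold, so no patient ever straddles a split.

Training sets are rebalanced per lung side (a row's class is that side's
grade) by one of three strategies:

* ``UNDER`` — majority classes randomly down-sampled to the minority count;
* ``OVER`` — minority classes brought up to the majority count with
  augmented copies (rotation, scaling, translation), flagged synthetic;
* ``DOUBLE`` — two-stage: the under-sampled set for stage 1 (head-only
  fine-tuning) and the full unbalanced set for stage 2.

Validation and test sets keep their natural class distribution.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

__all__ = [
    "BalancingScheme",
    "FoldSet",
    "BalancedTrainingPlan",
    "make_patient_splits",
    "balance",
    "rows_for",
    "DEFAULT_AUG_PARAMS",
    "sample_augmentation",
    "augment_image",
]

import enum


class BalancingScheme(str, enum.Enum):
    UNDER = "under"
    OVER = "over"
    DOUBLE = "double"


#: augmentation ranges: rotation degrees, isotropic scale, translation
#: as a fraction of width/height, each sampled uniformly
DEFAULT_AUG_PARAMS = {
    "rotation_deg": (-10.0, 10.0),
    "scale": (0.9, 1.1),
    "translate_frac": (-0.05, 0.05),
}


@dataclasses.dataclass
class FoldSet:
    """OOB patient set plus five train/val/test patient assignments."""

    oob: set
    folds: list  # list of {"train": set, "val": set, "test": set}
    seed: int

    def check_disjoint(self) -> None:
        for f in self.folds:
            parts = [f["train"], f["val"], f["test"]]
            for i in range(3):
                for j in range(i + 1, 3):
                    if parts[i] & parts[j]:
                        raise AssertionError("patient overlap within a fold")
                if parts[i] & self.oob:
                    raise AssertionError("patient overlap with OOB")

    def to_json(self, path) -> None:
        data = {"seed": self.seed, "oob": sorted(self.oob),
                "folds": [{k: sorted(v) for k, v in f.items()} for f in self.folds]}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FoldSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(oob=set(d["oob"]),
                   folds=[{k: set(v) for k, v in f.items()} for f in d["folds"]],
                   seed=d["seed"])


def make_patient_splits(manifest: pd.DataFrame, oob_n_images: int = 0,
                        ratios=(0.8, 0.1, 0.1), n_folds: int = 5,
                        seed: int = 0) -> FoldSet:
    """Build the OOB hold-out and patient-level folds.

    OOB patients are taken whole, in seeded shuffled order, until the OOB
    image count reaches ``oob_n_images``.  Within each fold the remaining
    patients split by ``ratios`` of patient counts.  Deterministic per seed.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    patients = list(dict.fromkeys(manifest["patient_id"]))
    if len(patients) < 20:
        raise ValueError("need at least 20 patients")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    img_counts = manifest.groupby("patient_id").size()

    oob: set = set()
    n_img = 0
    i = 0
    while n_img < oob_n_images and i < len(order):
        pid = order[i]
        oob.add(pid)
        n_img += int(img_counts.get(pid, 0))
        i += 1
    rest = [p for p in order if p not in oob]

    folds = []
    n = len(rest)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    for f in range(n_folds):
        frng = np.random.default_rng(seed * 1000 + f + 1)
        perm = [rest[j] for j in frng.permutation(n)]
        folds.append({
            "train": set(perm[:n_train]),
            "val": set(perm[n_train:n_train + n_val]),
            "test": set(perm[n_train + n_val:]),
        })
    fs = FoldSet(oob=oob, folds=folds, seed=seed)
    fs.check_disjoint()
    return fs


def rows_for(manifest: pd.DataFrame, patient_ids: set) -> pd.DataFrame:
    return manifest[manifest["patient_id"].isin(patient_ids)].reset_index(drop=True)


def sample_augmentation(rng: np.random.Generator, params: dict | None = None) -> dict:
    p = dict(DEFAULT_AUG_PARAMS)
    p.update(params or {})
    return {
        "rotation_deg": float(rng.uniform(*p["rotation_deg"])),
        "scale": float(rng.uniform(*p["scale"])),
        "tx_frac": float(rng.uniform(*p["translate_frac"])),
        "ty_frac": float(rng.uniform(*p["translate_frac"])),
    }


def augment_image(image: np.ndarray, aug: dict) -> np.ndarray:
    """Apply a rotation/scale/translation triple about the image centre."""
    h, w = image.shape
    centre = np.array([w / 2, h / 2])
    shift = AffineTransform(translation=-centre)
    tf = AffineTransform(rotation=np.deg2rad(aug["rotation_deg"]),
                         scale=aug["scale"])
    unshift = AffineTransform(translation=centre + np.array(
        [aug["tx_frac"] * w, aug["ty_frac"] * h]))
    return warp(image, (shift + tf + unshift).inverse, order=1,
                mode="constant", cval=0.0, preserve_range=True).astype(image.dtype)


@dataclasses.dataclass
class BalancedTrainingPlan:
    """Rows for each fine-tuning stage; stage 2 empty unless DOUBLE."""

    stage1_rows: pd.DataFrame
    stage2_rows: pd.DataFrame
    scheme: BalancingScheme
    label_column: str
    augmentations: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_AUG_PARAMS))

    def to_csv(self, path) -> None:
        s1 = self.stage1_rows.assign(stage=1)
        s2 = self.stage2_rows.assign(stage=2)
        pd.concat([s1, s2], ignore_index=True).to_csv(path, index=False)


def balance(train_rows: pd.DataFrame, scheme: BalancingScheme, label_column: str,
            seed: int = 0, aug_params: dict | None = None,
            n_classes: int = 4) -> BalancedTrainingPlan:
    """Build the training plan for one balancing scheme and one lung side."""
    scheme = BalancingScheme(scheme)
    df = train_rows.reset_index(drop=True).copy()
    if "synthetic" not in df:
        df["synthetic"] = False
    if "aug" not in df:
        df["aug"] = ""
    labels = df[label_column].astype("Int64")
    counts = {c: int((labels == c).sum()) for c in range(n_classes)}
    for c, k in counts.items():
        if k == 0:
            raise ValueError(f"class {c} has zero rows in '{label_column}'")
    rng = np.random.default_rng(seed)

    def undersample() -> pd.DataFrame:
        m = min(counts.values())
        parts = []
        for c in range(n_classes):
            idx = np.flatnonzero((labels == c).to_numpy())
            pick = rng.choice(idx, size=m, replace=False)
            parts.append(df.iloc[np.sort(pick)])
        return pd.concat(parts, ignore_index=True)

    def oversample() -> pd.DataFrame:
        mx = max(counts.values())
        parts = [df]
        for c in range(n_classes):
            need = mx - counts[c]
            if need == 0:
                continue
            idx = np.flatnonzero((labels == c).to_numpy())
            pick = rng.choice(idx, size=need, replace=True)
            extra = df.iloc[pick].copy()
            extra["synthetic"] = True
            extra["aug"] = [json.dumps(sample_augmentation(rng, aug_params))
                            for _ in range(need)]
            parts.append(extra)
        return pd.concat(parts, ignore_index=True)

    empty = df.iloc[0:0]
    if scheme is BalancingScheme.UNDER:
        plan = BalancedTrainingPlan(undersample(), empty, scheme, label_column)
    elif scheme is BalancingScheme.OVER:
        plan = BalancedTrainingPlan(oversample(), empty, scheme, label_column)
    else:  # DOUBLE: balanced stage 1, full unbalanced stage 2
        plan = BalancedTrainingPlan(undersample(), df, scheme, label_column)
    if aug_params:
        plan.augmentations.update(aug_params)
    return plan
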