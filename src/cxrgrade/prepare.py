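"""Cohort preparation: de-duplication and exclusion rules with an audit trail.

The analysis set is built from a raw manifest by (a) keeping only the first
acquisition per accession, then (b) rejecting document-type images, rows with
read errors (missing acquisition time, unreadable files), pediatric records
(age below 18 by default), and post-processed filtered copies.  Intensity-
inverted "negative" radiographs are not rejected: their pixels are inverted
in place so they match regular radiographs.

Filtered copies and negatives are identified from manifest artifact flags;
an optional intensity heuristic (bright border vs. dark lung centre) can
flag negatives when the manifest carries no flag.

Every input row is accounted for exactly once in the
:class:`ExclusionReport`, and the rules are idempotent: re-running them on a
cleaned manifest removes nothing.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ExclusionReport",
    "deduplicate_by_accession",
    "apply_exclusions",
    "prepare_cohort",
    "invert_image_file",
    "looks_negative",
    "remove_segmentation_failures",
]


@dataclasses.dataclass
class ExclusionReport:
    """Per-rule removal counts; reconciles to the input row count."""

    input_rows: int = 0
    duplicates_removed: int = 0
    documents_removed: int = 0
    read_error_removed: int = 0
    pediatric_removed: int = 0
    filtered_removed: int = 0
    negatives_transformed: int = 0
    segmentation_failures_removed: int = 0
    surviving_images: int = 0
    surviving_patients: int = 0

    def removed_total(self) -> int:
        return (self.duplicates_removed + self.documents_removed
                + self.read_error_removed + self.pediatric_removed
                + self.filtered_removed + self.segmentation_failures_removed)

    def check(self) -> None:
        if self.input_rows != self.surviving_images + self.removed_total():
            raise AssertionError("exclusion report does not reconcile")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def deduplicate_by_accession(
    manifest: pd.DataFrame, strict: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Keep one row per accession: the earliest acquisition time.

    Ties on time are broken by stable input order.  Rows with no
    acquisition time are routed to read errors.  ``strict=True`` instead
    discards every accession that carries multiple acquisition times
    (the conservative variant of the first-image rule).
    """
    df = manifest.reset_index(drop=True)
    counts = {"duplicates_removed": 0, "read_error_removed": 0}
    times = pd.to_datetime(df["acquisition_time"], errors="coerce")
    no_time = times.isna()
    counts["read_error_removed"] += int(no_time.sum())
    df = df[~no_time]
    times = times[~no_time]
    if df.empty:
        return df.reset_index(drop=True), counts
    if strict:
        n_times = times.groupby(df["accession_id"]).transform("nunique")
        multi = n_times > 1
        counts["read_error_removed"] += int(multi.sum())
        kept = df[~multi]
    else:
        order = pd.DataFrame({"acc": df["accession_id"].values,
                              "t": times.values,
                              "pos": np.arange(len(df))})
        first_pos = (order.sort_values(["t", "pos"], kind="stable")
                     .groupby("acc", sort=False)["pos"].first())
        keep_mask = np.zeros(len(df), dtype=bool)
        keep_mask[first_pos.to_numpy()] = True
        counts["duplicates_removed"] += int((~keep_mask).sum())
        kept = df[keep_mask]
    return kept.reset_index(drop=True), counts


def looks_negative(image01: np.ndarray, border_frac: float = 0.05) -> bool:
    """Intensity heuristic: on a regular radiograph the frame border is
    brighter than the central lung region; on a negative, the reverse."""
    h, w = image01.shape
    b = max(int(border_frac * min(h, w)), 1)
    border = np.concatenate([
        image01[:b].ravel(), image01[-b:].ravel(),
        image01[:, :b].ravel(), image01[:, -b:].ravel()])
    ch, cw = int(0.2 * h), int(0.2 * w)
    centre = image01[ch:h - ch, cw:w - cw]
    return float(border.mean()) < float(centre.mean())


def invert_image_file(path: str | os.PathLike) -> None:
    """Invert an 8-bit grayscale image in place (exact involution)."""
    img = np.asarray(Image.open(path).convert("L"))
    Image.fromarray((255 - img).astype(np.uint8), mode="L").save(path)


def apply_exclusions(
    manifest: pd.DataFrame,
    min_age: int = 18,
    check_files: bool = False,
    negative_heuristic: bool = False,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the rejection rules to a de-duplicated manifest.

    Removes document rows, read-error rows, pediatric rows (age strictly
    below ``min_age``; exactly ``min_age`` is retained), and filtered-copy
    rows.  Negative-flagged rows are kept with pixels inverted on disk.
    ``check_files=True`` additionally verifies each image opens; unreadable
    files go to read errors.
    """
    rep = ExclusionReport(input_rows=len(manifest))
    df = manifest.reset_index(drop=True).copy()

    doc = df.get("is_document", pd.Series(False, index=df.index)).fillna(False).astype(bool)
    rep.documents_removed = int(doc.sum())
    df = df[~doc]

    no_time = pd.to_datetime(df["acquisition_time"], errors="coerce").isna()
    rep.read_error_removed += int(no_time.sum())
    df = df[~no_time]

    if check_files:
        bad = []
        for i, p in df["image_path"].items():
            try:
                with Image.open(p) as im:
                    im.verify()
            except Exception:
                bad.append(i)
        rep.read_error_removed += len(bad)
        df = df.drop(index=bad)

    ped = pd.to_numeric(df["age"], errors="coerce") < min_age
    rep.pediatric_removed = int(ped.sum())
    df = df[~ped]

    filt = df.get("is_filtered", pd.Series(False, index=df.index)).fillna(False).astype(bool)
    rep.filtered_removed = int(filt.sum())
    df = df[~filt]

    neg = df.get("is_negative", pd.Series(False, index=df.index)).fillna(False).astype(bool)
    if negative_heuristic:
        for i in df.index[~neg]:
            p = df.at[i, "image_path"]
            if p and os.path.exists(p):
                arr = np.asarray(Image.open(p).convert("L"), dtype=float) / 255.0
                if looks_negative(arr):
                    neg.at[i] = True
    for i in df.index[neg]:
        p = df.at[i, "image_path"]
        if p and os.path.exists(p):
            invert_image_file(p)
    rep.negatives_transformed = int(neg.sum())
    df = df.copy()
    if "is_negative" in df:
        df.loc[:, "is_negative"] = False  # transformed: now regular polarity

    df = df.reset_index(drop=True)
    rep.surviving_images = len(df)
    rep.surviving_patients = int(df["patient_id"].nunique()) if len(df) else 0
    rep.check()
    return df, rep


def remove_segmentation_failures(
    manifest: pd.DataFrame, failed_paths: set, report: ExclusionReport
) -> pd.DataFrame:
    """Drop rows whose lung ROI segmentation failed, updating the report."""
    bad = manifest["image_path"].isin(failed_paths)
    report.segmentation_failures_removed += int(bad.sum())
    report.surviving_images -= int(bad.sum())
    out = manifest[~bad].reset_index(drop=True)
    report.surviving_patients = int(out["patient_id"].nunique()) if len(out) else 0
    report.check()
    return out


def prepare_cohort(
    manifest: pd.DataFrame,
    min_age: int = 18,
    strict_time: bool = False,
    check_files: bool = False,
    negative_heuristic: bool = False,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """De-duplicate then apply exclusions; one reconciled report."""
    dedup, counts = deduplicate_by_accession(manifest, strict=strict_time)
    clean, rep = apply_exclusions(dedup, min_age=min_age, check_files=check_files,
                                  negative_heuristic=negative_heuristic)
    rep.input_rows = len(manifest)
    rep.duplicates_removed = counts["duplicates_removed"]
    rep.read_error_removed += counts["read_error_removed"]
    rep.check()
    return clean, rep
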