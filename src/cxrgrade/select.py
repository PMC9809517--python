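"""Three-stage model selection, reader comparison, and subgroup analysis.

Stage 1 trains every (architecture x balancing x segmentation) combination
on the first fold, evaluates side-averaged precision/recall/F1 and
macro-MAE, and keeps the top N (default 5) by macro-MAE.  Stage 2 retrains
the retained configurations across all folds, adding per-fold macro-averaged
heatmap concordance (MA-HCS) and binary-collapse metrics.  The best model
balances ordinal accuracy against saliency concordance with an equal-weight
rank-sum rule: rank by macro-MAE ascending and MA-HCS descending, pick the
minimum rank sum, break ties toward the lower macro-MAE.  Stage 3 retrains
the winner on a fresh split and compares its predictions on the held-out
OOB set against two reader annotations (the original reader OR and a
second, out-of-box test reader OOBTR), reporting the full metric set for
all three pairings; subgroup metrics stratify the stage-3 predictions by
race, sex, and COVID status.

Bundled reference tables (``cxrgrade/data``) carry published large-cohort
grid results so the ranking and selection rules can be exercised on real
benchmark numbers without any training.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import metrics as M
from . import phantoms, prepare, segment, splits, train
from .heatmaps import attention_heatmap, combine_lr, hcs, macro_hcs

__all__ = [
    "ModelConfig",
    "StageOneResult",
    "CrossValResult",
    "ReaderComparison",
    "enumerate_configs",
    "stage_one",
    "stage_two",
    "choose_best",
    "stage_three",
    "subgroup_metrics",
    "simulate_second_reader",
    "load_reference_stage1_table",
    "load_reference_crossval_table",
    "PipelineContext",
    "run_pipeline",
]

log = logging.getLogger("cxrgrade.select")

SELECTION_RULE = ("equal-weight rank-sum of macro-MAE (ascending) and MA-HCS "
                  "(descending); ties broken by lower macro-MAE")


@dataclasses.dataclass(frozen=True, order=True)
class ModelConfig:
    architecture: str
    balancing: str
    segmentation: str
    side: str | None = None

    def key(self) -> tuple:
        return (self.architecture, self.balancing, self.segmentation)


def enumerate_configs(architectures, balancers, schemes) -> list[ModelConfig]:
    """Cartesian grid of per-side configurations, lexicographic order."""
    if not (architectures and balancers and schemes):
        raise ValueError("all axis lists must be non-empty")
    return [ModelConfig(a, b, s) for a, b, s in
            itertools.product(sorted(architectures), sorted(balancers),
                              sorted(schemes))]


def load_reference_stage1_table() -> pd.DataFrame:
    with importlib.resources.files("cxrgrade.data").joinpath(
            "reference_stage1_grid.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_crossval_table() -> pd.DataFrame:
    with importlib.resources.files("cxrgrade.data").joinpath(
            "reference_crossval_top5.csv").open() as fh:
        return pd.read_csv(fh)


@dataclasses.dataclass
class StageOneResult:
    table: pd.DataFrame     # ranked, all configs
    top: pd.DataFrame       # first n_keep rows

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stage_one(results_table: pd.DataFrame, n_keep: int = 5) -> StageOneResult:
    """Rank the single-fold grid by macro-MAE and keep the top ``n_keep``.

    Ties break toward the higher F1, then lexicographic configuration.
    The ranking is a permutation of the input rows.
    """
    df = results_table.copy()
    keys = list(zip(df["architecture"], df["balancing"], df["segmentation"]))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate configurations in results table")
    if not np.isfinite(df["macro_mae"]).all():
        raise ValueError("non-finite macro_mae in results table")
    df = df.sort_values(
        by=["macro_mae", "f1", "architecture", "balancing", "segmentation"],
        ascending=[True, False, True, True, True], kind="stable",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return StageOneResult(table=df, top=df.head(min(n_keep, len(df))).copy())


@dataclasses.dataclass
class CrossValResult:
    """Per-config fold means/stds plus MA-HCS and binary-collapse blocks."""

    table: pd.DataFrame          # one row per config with *_mean/*_sd columns
    binary: dict = dataclasses.field(default_factory=dict)
    flagged: list = dataclasses.field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _sample_sd(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(v.std(ddof=1)) if v.size > 1 else 0.0


def choose_best(cv: CrossValResult) -> ModelConfig:
    """Equal-weight rank-sum over macro-MAE (asc) and MA-HCS (desc)."""
    df = cv.table
    ok = df[~df.apply(lambda r: (r["architecture"], r["balancing"],
                                 r["segmentation"]) in
                      set(map(tuple, cv.flagged)), axis=1)]
    if ok.empty:
        raise RuntimeError("all configurations flagged; no best model")
    mae_rank = ok["macro_mae_mean"].rank(method="min", ascending=True)
    hcs_rank = ok["ma_hcs_mean"].rank(method="min", ascending=False)
    score = mae_rank + hcs_rank
    cand = ok.assign(_score=score).sort_values(
        by=["_score", "macro_mae_mean"], kind="stable")
    row = cand.iloc[0]
    return ModelConfig(row["architecture"], row["balancing"], row["segmentation"])


def simulate_second_reader(grades, flip_rate: float = 0.1, seed: int = 0) -> np.ndarray:
    """Emulate a second annotator: each grade moves one ordinal step
    (direction random, clipped to 0..3) with probability ``flip_rate``."""
    rng = np.random.default_rng(seed)
    g = np.asarray(grades, dtype=int).copy()
    flip = rng.random(g.size) < flip_rate
    step = rng.choice([-1, 1], size=g.size)
    step[g == 0] = 1          # always a full one-step move, even at the ends
    step[g == 3] = -1
    g[flip] = g[flip] + step[flip]
    return g


@dataclasses.dataclass
class ReaderComparison:
    """Metric blocks for OOBTR-OR, Model-OR, and Model-OOBTR pairings."""

    pairings: dict               # name -> {metrics, binary: {t: metrics}}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.pairings, fh, indent=2, default=float)


def _pairing_block(y_a, y_b) -> dict:
    rep = M.evaluate_pair(y_a, y_b)
    block = {"mae": rep.macro_mae, **{k: v for k, v in rep.as_percent().items()
                                     if k != "macro_mae"}}
    block["binary"] = {}
    pair = M.LabelPair(np.asarray(y_a), np.asarray(y_b))
    for t in M.BINARY_THRESHOLDS:
        bp = M.binarize(pair, t)
        brep = M.evaluate_pair(bp.y_true, bp.y_pred, n_classes=2)
        block["binary"][t] = brep.as_percent()
    return block


def subgroup_metrics(predictions: pd.DataFrame, manifest: pd.DataFrame,
                     grouping: str) -> pd.DataFrame:
    """Per-subgroup left/right/average macro-MAE, F1, precision, recall.

    ``predictions`` carries image_path, pred_left, pred_right; truth grades
    join from the manifest.  Groups with no rows are omitted.
    """
    col = {"race": "race", "sex": "sex", "covid": "covid_status"}.get(grouping)
    if col is None:
        raise ValueError(f"unknown grouping variable: {grouping!r}")
    df = predictions.merge(
        manifest[["image_path", col, "left_grade", "right_grade"]],
        on="image_path", how="inner")
    rows = []
    for group, sub in df.groupby(col):
        if len(sub) == 0:
            continue
        side_reports = {}
        for side in ("left", "right"):
            rep = M.evaluate_pair(sub[f"{side}_grade"].astype(int),
                                  sub[f"pred_{side}"].astype(int),
                                  with_r2=False)
            side_reports[side] = rep
        lt, rt = side_reports["left"], side_reports["right"]
        rows.append({
            "group": group, "n": len(sub),
            "avg_macro_mae": (lt.macro_mae + rt.macro_mae) / 2,
            "left_macro_mae": lt.macro_mae, "right_macro_mae": rt.macro_mae,
            "avg_f1": 100 * (lt.f1_overall + rt.f1_overall) / 2,
            "left_f1": 100 * lt.f1_overall, "right_f1": 100 * rt.f1_overall,
            "avg_precision": 100 * (lt.precision_overall + rt.precision_overall) / 2,
            "avg_recall": 100 * (lt.recall_overall + rt.recall_overall) / 2,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end orchestration on a phantom cohort
# ---------------------------------------------------------------------------


class PipelineContext:
    """Shared data plumbing: manifest, segmenters, ROI loaders, caches."""

    def __init__(self, manifest: pd.DataFrame, input_size: int = 64,
                 lung_segmenter: segment.SegmenterModel | None = None,
                 spine_segmenter: segment.SegmenterModel | None = None,
                 seed: int = 0) -> None:
        self.manifest = manifest
        self.input_size = input_size
        self.lung_segmenter = lung_segmenter
        self.spine_segmenter = spine_segmenter
        self.seed = seed
        self._roi_cache: dict = {}
        self._mask_cache: dict = {}

    # -- raw image / truth-mask access ---------------------------------
    def _image(self, path: str) -> np.ndarray:
        return np.asarray(Image.open(path).convert("L")).astype(np.float32) / 255.0

    def lung_masks(self, path: str) -> tuple[np.ndarray, np.ndarray]:
        """Segmenter-predicted per-side lung masks (truth fallback when no
        segmenter is attached)."""
        if path in self._mask_cache:
            return self._mask_cache[path]
        img = self._image(path)
        if self.lung_segmenter is not None:
            masks = segment.segment_lungs(self.lung_segmenter, img)
        else:
            truth = phantoms.load_truth(path)
            masks = (truth.left_mask, truth.right_mask)
        self._mask_cache[path] = masks
        return masks

    def roi(self, path: str, scheme: segment.SegScheme, side: str) -> np.ndarray:
        key = (path, segment.SegScheme(scheme).value, side)
        if key in self._roi_cache:
            return self._roi_cache[key]
        img = self._image(path)
        scheme = segment.SegScheme(scheme)
        if scheme is segment.SegScheme.NONE:
            out = segment.extract_roi(img, scheme, side)
        elif scheme is segment.SegScheme.LUNG:
            left, right = self.lung_masks(path)
            out = segment.extract_roi(img, scheme, side,
                                      masks={"left": left, "right": right})
        else:
            if self.spine_segmenter is not None:
                lh, rh, _ = segment.split_by_spine(self.spine_segmenter, img)
            else:
                h, w = img.shape
                lh = np.where(np.arange(w)[None, :] >= w // 2, img, 0.0)
                rh = np.where(np.arange(w)[None, :] < w // 2, img, 0.0)
            out = segment.extract_roi(img, scheme, side,
                                      masks={"left_half": lh, "right_half": rh})
        self._roi_cache[key] = out
        return out

    def loader(self, scheme, side: str, label_column: str):
        """A rows -> (X, y) closure for :func:`cxrgrade.train.fit_two_stage`."""
        def _load(rows: pd.DataFrame):
            xs, ys = [], []
            for _, row in rows.iterrows():
                roi = self.roi(row["image_path"], scheme, side)
                if bool(row.get("synthetic", False)) and row.get("aug"):
                    roi = splits.augment_image(roi, json.loads(row["aug"]))
                xs.append(segment.normalize_for_net(roi, size=self.input_size))
                ys.append(int(row[label_column]))
            return np.stack(xs), np.asarray(ys, dtype=int)
        return _load

    def roi_mask(self, path: str, scheme, side: str) -> np.ndarray:
        """The union lung mask carried through the same ROI geometry as the
        network input, resized to the network frame (for HCS)."""
        left, right = self.lung_masks(path)
        union = left | right
        scheme = segment.SegScheme(scheme)
        if scheme is segment.SegScheme.NONE:
            geo = union.astype(float)
        elif scheme is segment.SegScheme.LUNG:
            mask = left if side == "left" else right
            geo = segment.extract_roi(union.astype(float), scheme, side,
                                      masks={"left": left, "right": right})
        else:
            h, w = union.shape
            half = (np.arange(w)[None, :] >= w // 2) if side == "left" else \
                   (np.arange(w)[None, :] < w // 2)
            geo = np.where(half, union.astype(float), 0.0)
        from skimage.transform import resize
        return resize(geo, (self.input_size, self.input_size), order=0) > 0.5


def _train_config_on_fold(ctx: PipelineContext, config: ModelConfig, side: str,
                          fold: dict, schedule: train.TrainingSchedule,
                          seed: int):
    label = f"{side}_grade"
    train_rows = splits.rows_for(ctx.manifest, fold["train"])
    val_rows = splits.rows_for(ctx.manifest, fold["val"])
    plan = splits.balance(train_rows, config.balancing, label, seed=seed)
    model = train.build_classifier(config.architecture, side=side, seed=seed,
                                   input_size=ctx.input_size,
                                   config=dataclasses.asdict(config))
    model, history = train.fit_two_stage(
        model, plan, val_rows, schedule,
        loader=ctx.loader(config.segmentation, side, label))
    return model, history


def _evaluate_pair_of_models(ctx, config, models, rows) -> dict:
    """Side-averaged metric block for a left/right model pair."""
    out = {}
    reports = {}
    for side in ("left", "right"):
        X, y = ctx.loader(config.segmentation, side, f"{side}_grade")(rows)
        _, grades = train.predict(models[side], X)
        reports[side] = M.evaluate_pair(y, grades, with_r2=False)
        out[f"pred_{side}"] = grades
        out[f"true_{side}"] = y
    lt, rt = reports["left"], reports["right"]
    out.update({
        "precision": 100 * (lt.precision_overall + rt.precision_overall) / 2,
        "recall": 100 * (lt.recall_overall + rt.recall_overall) / 2,
        "f1": 100 * (lt.f1_overall + rt.f1_overall) / 2,
        "macro_mae": (lt.macro_mae + rt.macro_mae) / 2,
    })
    return out


def _fold_ma_hcs(ctx, config, models, rows, max_images: int = 10) -> float:
    """MA-HCS over (a subsample of) a test set, grouped by true grade."""
    vals, classes = [], []
    sub = rows.head(max_images)
    for _, row in sub.iterrows():
        maps = {}
        for side in ("left", "right"):
            roi = ctx.roi(row["image_path"], config.segmentation, side)
            x = segment.normalize_for_net(roi, size=ctx.input_size)
            maps[side] = attention_heatmap(models[side], x)
        scheme = segment.SegScheme(config.segmentation)
        try:
            if scheme is segment.SegScheme.NONE:
                combined = combine_lr(maps["left"], maps["right"])
                mask = ctx.roi_mask(row["image_path"], scheme, "left")
                score = hcs(combined, mask)
            else:
                side_scores = [
                    hcs(maps[s], ctx.roi_mask(row["image_path"], scheme, s))
                    for s in ("left", "right")]
                score = float(np.mean(side_scores))
        except ValueError:
            continue
        vals.append(score)
        # grade on the macro axis: the worse of the two sides' true grades
        classes.append(int(max(row["left_grade"], row["right_grade"])))
    if not vals:
        return float("nan")
    return macro_hcs(vals, classes).ma_hcs


def stage_two(ctx: PipelineContext, top_configs: list[ModelConfig],
              fold_set: splits.FoldSet, schedule: train.TrainingSchedule,
              hcs_images_per_fold: int = 10) -> CrossValResult:
    """Retrain each retained config on every fold; aggregate mean/std."""
    rows_out = []
    binary = {}
    flagged = []
    for config in top_configs:
        per_fold = {k: [] for k in ("precision", "recall", "f1", "macro_mae",
                                    "ma_hcs")}
        per_fold_binary = {t: {k: [] for k in ("precision", "recall", "f1")}
                           for t in M.BINARY_THRESHOLDS}
        failed = False
        for f_idx, fold in enumerate(fold_set.folds):
            try:
                models = {}
                for side in ("left", "right"):
                    models[side], _ = _train_config_on_fold(
                        ctx, config, side, fold, schedule,
                        seed=schedule.seed + f_idx)
                test_rows = splits.rows_for(ctx.manifest, fold["test"])
                block = _evaluate_pair_of_models(ctx, config, models, test_rows)
            except (train.TrainingFailure, ValueError) as exc:
                log.warning("fold %d failed for %s: %s", f_idx, config, exc)
                failed = True
                break
            for k in ("precision", "recall", "f1", "macro_mae"):
                per_fold[k].append(block[k])
            per_fold["ma_hcs"].append(
                _fold_ma_hcs(ctx, config, models, test_rows,
                             max_images=hcs_images_per_fold))
            for t in M.BINARY_THRESHOLDS:
                sides = []
                for side in ("left", "right"):
                    bp = M.binarize(M.LabelPair(block[f"true_{side}"],
                                                block[f"pred_{side}"]), t)
                    sides.append(M.evaluate_pair(bp.y_true, bp.y_pred,
                                                 n_classes=2, with_r2=False))
                for k in ("precision", "recall", "f1"):
                    attr = {"precision": "precision_overall",
                            "recall": "recall_overall", "f1": "f1_overall"}[k]
                    per_fold_binary[t][k].append(
                        100 * np.mean([getattr(s, attr) for s in sides]))
        if failed:
            flagged.append(config.key())
            continue
        row = {"architecture": config.architecture,
               "balancing": config.balancing,
               "segmentation": config.segmentation}
        for k in ("precision", "recall", "f1", "macro_mae"):
            row[f"{k}_mean"] = float(np.mean(per_fold[k]))
            row[f"{k}_sd"] = _sample_sd(per_fold[k])
        row["ma_hcs_mean"] = float(np.nanmean(per_fold["ma_hcs"]))
        rows_out.append(row)
        binary[config.key()] = {
            t: {k: float(np.mean(v)) for k, v in per_fold_binary[t].items()}
            for t in M.BINARY_THRESHOLDS}
    return CrossValResult(table=pd.DataFrame(rows_out), binary=binary,
                          flagged=flagged)


def stage_three(ctx: PipelineContext, best_config: ModelConfig,
                fold_set: splits.FoldSet, schedule: train.TrainingSchedule,
                oobtr_labels: dict | None = None,
                fresh_seed: int = 9001) -> tuple[ReaderComparison, pd.DataFrame]:
    """Retrain the winner on a fresh split and evaluate on the OOB set.

    ``oobtr_labels`` maps side -> second-reader grade vector aligned with
    the OOB rows; when absent the OOBTR pairings are omitted with a warning.
    Returns the reader comparison and a per-image OOB prediction table.
    """
    non_oob = set(ctx.manifest["patient_id"]) - fold_set.oob
    sub = ctx.manifest[ctx.manifest["patient_id"].isin(non_oob)]
    fresh = splits.make_patient_splits(sub, oob_n_images=0, n_folds=1,
                                       seed=fresh_seed)
    fold = fresh.folds[0]
    models = {}
    for side in ("left", "right"):
        models[side], _ = _train_config_on_fold(ctx, best_config, side, fold,
                                                schedule, seed=fresh_seed)
    oob_rows = splits.rows_for(ctx.manifest, fold_set.oob)
    preds = {"image_path": oob_rows["image_path"].tolist()}
    ors = {}
    for side in ("left", "right"):
        X, y = ctx.loader(best_config.segmentation, side, f"{side}_grade")(oob_rows)
        _, grades = train.predict(models[side], X)
        preds[f"pred_{side}"] = grades
        ors[side] = y
    pred_df = pd.DataFrame(preds)

    def both(d):  # concatenate sides for pooled pairings
        return np.concatenate([np.asarray(d["left"]), np.asarray(d["right"])])

    model_vec = both({"left": preds["pred_left"], "right": preds["pred_right"]})
    or_vec = both(ors)
    pairings = {"model_vs_or": _pairing_block(or_vec, model_vec)}
    if oobtr_labels is not None:
        oobtr_vec = both(oobtr_labels)
        pairings["oobtr_vs_or"] = _pairing_block(or_vec, oobtr_vec)
        pairings["model_vs_oobtr"] = _pairing_block(oobtr_vec, model_vec)
    else:
        log.warning("no OOBTR labels supplied; reader pairings omitted")
    pairings["config"] = dataclasses.asdict(best_config)
    pairings["selection_rule"] = SELECTION_RULE
    return ReaderComparison(pairings), pred_df


def run_pipeline(manifest: pd.DataFrame, out_dir, architectures, balancers,
                 schemes, schedule: train.TrainingSchedule | None = None,
                 n_folds: int = 2, n_keep: int = 2, oob_n_images: int = 20,
                 input_size: int = 64, seed: int = 0,
                 oobtr_flip_rate: float = 0.1,
                 segmenters: tuple | None = None) -> dict:
    """End-to-end run on a prepared phantom cohort; emits all reports.

    Returns a dict with the stage-1 result, cross-validation result, chosen
    configuration, reader comparison, and subgroup tables; JSON/CSV copies
    land in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = schedule or train.TrainingSchedule(
        stage1_epochs_max=4, stage2_epochs_max=3, lr_reduce_patience=2,
        early_stop_patience=3, seed=seed)
    lung_seg = spine_seg = None
    if segmenters is not None:
        lung_seg, spine_seg = segmenters
    ctx = PipelineContext(manifest, input_size=input_size,
                          lung_segmenter=lung_seg, spine_segmenter=spine_seg,
                          seed=seed)
    fold_set = splits.make_patient_splits(manifest, oob_n_images=oob_n_images,
                                          n_folds=n_folds, seed=seed)
    fold_set.to_json(out_dir / "folds.json")

    # stage 1: full grid on fold 1
    grid = enumerate_configs(architectures, balancers, schemes)
    rows = []
    for config in grid:
        models = {}
        for side in ("left", "right"):
            models[side], _ = _train_config_on_fold(
                ctx, config, side, fold_set.folds[0], schedule, seed=seed)
        test_rows = splits.rows_for(ctx.manifest, fold_set.folds[0]["test"])
        block = _evaluate_pair_of_models(ctx, config, models, test_rows)
        rows.append({"architecture": config.architecture,
                     "balancing": config.balancing,
                     "segmentation": config.segmentation,
                     "precision": block["precision"], "recall": block["recall"],
                     "f1": block["f1"], "macro_mae": block["macro_mae"]})
    s1 = stage_one(pd.DataFrame(rows), n_keep=n_keep)
    s1.to_csv(out_dir / "stage1_grid.csv")

    top_configs = [ModelConfig(r["architecture"], r["balancing"],
                               r["segmentation"])
                   for _, r in s1.top.iterrows()]
    cv = stage_two(ctx, top_configs, fold_set, schedule)
    cv.to_csv(out_dir / "crossval.csv")
    best = choose_best(cv)
    (out_dir / "best_config.json").write_text(json.dumps(
        {"config": dataclasses.asdict(best), "selection_rule": SELECTION_RULE},
        indent=2))

    oob_rows = splits.rows_for(manifest, fold_set.oob)
    oobtr = {side: simulate_second_reader(
        oob_rows[f"{side}_grade"].astype(int).to_numpy(),
        flip_rate=oobtr_flip_rate, seed=seed + 7)
        for side in ("left", "right")}
    comparison, pred_df = stage_three(ctx, best, fold_set, schedule,
                                      oobtr_labels=oobtr,
                                      fresh_seed=seed + 9001)
    comparison.to_json(out_dir / "reader_comparison.json")
    pred_df.to_csv(out_dir / "oob_predictions.csv", index=False)

    subgroups = {}
    for grouping in ("race", "sex", "covid"):
        tbl = subgroup_metrics(pred_df, manifest, grouping)
        tbl.to_csv(out_dir / f"subgroups_{grouping}.csv", index=False)
        subgroups[grouping] = tbl
    return {"stage1": s1, "crossval": cv, "best_config": best,
            "reader_comparison": comparison, "oob_predictions": pred_df,
            "subgroups": subgroups, "fold_set": fold_set}
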