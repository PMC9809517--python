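"""Three-stage model selection, reader comparison, subgroup reporting."""

import json

import numpy as np
import pandas as pd
import pytest

from cxrgrade import select


def test_enumerate_configs_full_grid():
    grid = select.enumerate_configs(
        ["vgg16", "resnet50", "chexnet121"],
        ["under", "over", "double"],
        ["none", "lung", "spine"])
    assert len(grid) == 27
    assert len(set(grid)) == 27
    assert grid == sorted(grid)        # lexicographic
    with pytest.raises(ValueError):
        select.enumerate_configs([], ["under"], ["none"])


def test_reference_tables_load():
    s1 = select.load_reference_stage1_table()
    assert len(s1) == 27
    assert {"architecture", "balancing", "segmentation",
            "macro_mae", "f1"} <= set(s1.columns)
    cv = select.load_reference_crossval_table()
    assert len(cv) == 5


def test_stage_one_ranks_reference_grid():
    s1 = select.stage_one(select.load_reference_stage1_table(), n_keep=5)
    assert list(s1.table["rank"]) == list(range(1, 28))
    assert s1.table.iloc[0]["macro_mae"] == pytest.approx(0.3953)
    assert len(s1.top) == 5
    assert s1.top["macro_mae"].max() == pytest.approx(0.4151)
    assert s1.table["macro_mae"].is_monotonic_increasing


def test_stage_one_tie_break_prefers_higher_f1():
    df = pd.DataFrame({
        "architecture": ["a", "b"], "balancing": ["under"] * 2,
        "segmentation": ["none"] * 2,
        "precision": [50.0, 50.0], "recall": [50.0, 50.0],
        "f1": [40.0, 60.0], "macro_mae": [0.5, 0.5]})
    out = select.stage_one(df, n_keep=1)
    assert out.table.iloc[0]["architecture"] == "b"


def test_stage_one_rejects_bad_tables():
    base = select.load_reference_stage1_table()
    dup = pd.concat([base, base.iloc[[0]]])
    with pytest.raises(ValueError):
        select.stage_one(dup)
    nan = base.copy()
    nan.loc[0, "macro_mae"] = np.nan
    with pytest.raises(ValueError):
        select.stage_one(nan)


def test_choose_best_rank_sum():
    tbl = pd.DataFrame({
        "architecture": ["a", "b", "c"], "balancing": ["under"] * 3,
        "segmentation": ["none"] * 3,
        "macro_mae_mean": [0.40, 0.42, 0.50],
        "ma_hcs_mean": [0.50, 0.90, 0.60]})
    # ranks: a = 1 + 3, b = 2 + 1, c = 3 + 2 -> b wins
    cv = select.CrossValResult(table=tbl)
    best = select.choose_best(cv)
    assert best.architecture == "b"


def test_choose_best_skips_flagged_and_raises_when_all_flagged():
    tbl = pd.DataFrame({
        "architecture": ["a", "b"], "balancing": ["under"] * 2,
        "segmentation": ["none"] * 2,
        "macro_mae_mean": [0.40, 0.45], "ma_hcs_mean": [0.9, 0.8]})
    cv = select.CrossValResult(table=tbl, flagged=[("a", "under", "none")])
    assert select.choose_best(cv).architecture == "b"
    cv_all = select.CrossValResult(
        table=tbl, flagged=[("a", "under", "none"), ("b", "under", "none")])
    with pytest.raises(RuntimeError):
        select.choose_best(cv_all)


def test_simulate_second_reader_moves_one_step():
    grades = np.array([0, 1, 2, 3] * 100)
    other = select.simulate_second_reader(grades, flip_rate=1.0, seed=0)
    assert np.abs(other - grades).max() == 1
    assert np.abs(other - grades).min() == 1       # every grade moved
    assert other.min() >= 0 and other.max() <= 3
    assert (other[grades == 0] == 1).all()
    assert (other[grades == 3] == 2).all()
    same = select.simulate_second_reader(grades, flip_rate=0.0, seed=0)
    np.testing.assert_array_equal(same, grades)
    rate = (select.simulate_second_reader(grades, flip_rate=0.1, seed=1)
            != grades).mean()
    assert 0.02 < rate < 0.25


def test_subgroup_metrics_against_direct_computation(clean_cohort):
    rng = np.random.default_rng(0)
    preds = pd.DataFrame({
        "image_path": clean_cohort["image_path"],
        "pred_left": rng.integers(0, 4, len(clean_cohort)),
        "pred_right": rng.integers(0, 4, len(clean_cohort))})
    tbl = select.subgroup_metrics(preds, clean_cohort, "sex")
    assert set(tbl["group"]) <= set(clean_cohort["sex"])
    assert tbl["n"].sum() == len(clean_cohort)
    from cxrgrade import metrics as M
    row = tbl.iloc[0]
    sub = clean_cohort[clean_cohort["sex"] == row["group"]]
    merged = preds.merge(sub, on="image_path")
    rep = M.evaluate_pair(merged["left_grade"].astype(int),
                          merged["pred_left"].astype(int), with_r2=False)
    assert row["left_macro_mae"] == pytest.approx(rep.macro_mae)
    with pytest.raises(ValueError):
        select.subgroup_metrics(preds, clean_cohort, "age_decade")


def test_reader_comparison_json_round_trip(tmp_path):
    y = np.array([0, 1, 2, 3, 1, 2])
    p = np.array([0, 1, 2, 2, 1, 3])
    block = select._pairing_block(y, p)
    assert set(block["binary"]) == {1, 2, 3}
    comp = select.ReaderComparison({"model_vs_or": block})
    path = tmp_path / "cmp.json"
    comp.to_json(path)
    data = json.loads(path.read_text())
    assert data["model_vs_or"]["mae"] == pytest.approx(block["mae"])


def test_miniature_pipeline_emits_reports(clean_cohort, tmp_path):
    from cxrgrade import train
    schedule = train.TrainingSchedule(stage1_epochs_max=2, stage2_epochs_max=2,
                                      lr_reduce_patience=1,
                                      early_stop_patience=2, seed=0)
    out = tmp_path / "run"
    result = select.run_pipeline(
        clean_cohort, out, architectures=["tiny"], balancers=["under"],
        schemes=["none"], schedule=schedule, n_folds=2, n_keep=1,
        oob_n_images=6, input_size=64, seed=0)
    for fname in ("folds.json", "stage1_grid.csv", "crossval.csv",
                  "best_config.json", "reader_comparison.json",
                  "oob_predictions.csv", "subgroups_race.csv",
                  "subgroups_sex.csv", "subgroups_covid.csv"):
        assert (out / fname).exists(), fname
    assert result["best_config"].architecture == "tiny"
    preds = pd.read_csv(out / "oob_predictions.csv")
    assert {"image_path", "pred_left", "pred_right"} <= set(preds.columns)
    assert len(preds) >= 6
    comparison = json.loads((out / "reader_comparison.json").read_text())
    for key in ("model_vs_or", "oobtr_vs_or", "model_vs_oobtr"):
        assert "mae" in comparison[key]
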