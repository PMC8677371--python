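"""Metrics, stratified CV and the end-to-end pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from fetalmove import (
    ConfusionCounts,
    HyperParams,
    PipelineConfig,
    SimConfig,
    confusion,
    cross_validate,
    feature_count_sweep,
    metrics,
    roc_auc,
    run_pipeline,
    stratified_kfold,
)
from fetalmove.evaluation import StratificationError, UndefinedAUCError
from fetalmove.features import FEATURE_NAMES


# ------------------------------------------------------------ confusion counts

def test_perfect_predictions():
    y = np.array([1] * 10 + [0] * 5)
    c = confusion(y, y)
    assert (c.tp, c.tn, c.fp, c.fn) == (10, 5, 0, 0)
    m = metrics(c)
    assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1"))


def test_total_inversion():
    y = np.array([1] * 10 + [0] * 5)
    c = confusion(y, 1 - y)
    assert c.tp == 0 and c.tn == 0
    assert c.fp == 5 and c.fn == 10


def test_hand_counted_confusion_and_metrics():
    labels = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    preds = np.array([1, 1, 1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
    c = confusion(labels, preds, positive_class=1)
    assert (c.tp, c.fn, c.fp, c.tn) == (5, 1, 2, 4)
    m = metrics(c)
    assert m["accuracy"] == pytest.approx(0.75)
    assert m["precision"] == pytest.approx(5 / 7)
    assert m["recall"] == pytest.approx(5 / 6)
    assert m["f1"] == pytest.approx(10 / 13)


def test_no_predicted_positives_degenerate_precision():
    m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
    assert m["precision"] == 0.0
    assert m["degenerate"]


def test_f1_identity_and_accuracy_crosscheck(rng):
    for _ in range(50):
        y = rng.integers(0, 2, size=40)
        p = rng.integers(0, 2, size=40)
        c = confusion(y, p)
        m = metrics(c)
        denom = 2 * c.tp + c.fp + c.fn
        if denom:
            assert m["f1"] == pytest.approx(2 * c.tp / denom)
        assert m["accuracy"] == pytest.approx(np.mean(y == p))


def test_positive_class_swap_maps_precision_recall():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=60)
    p = rng.integers(0, 2, size=60)
    m_pos = metrics(confusion(y, p, positive_class=1))
    m_neg = metrics(confusion(y, p, positive_class=0))
    c = confusion(y, p, positive_class=1)
    assert m_neg["precision"] == pytest.approx(
        c.tn / (c.tn + c.fn) if c.tn + c.fn else 0.0
    )
    assert m_neg["recall"] == pytest.approx(
        c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    )
    assert m_neg["accuracy"] == pytest.approx(m_pos["accuracy"])


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion([0, 1], [0, 1, 1])


# -------------------------------------------------------------------- ROC/AUC

def test_auc_for_perfect_and_inverted_separation():
    y = np.array([0, 0, 0, 1, 1, 1])
    assert roc_auc(y, np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])) == 1.0
    assert roc_auc(y, np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])) == 0.0


def test_auc_equals_mann_whitney_rank_statistic(rng):
    """AUC is the probability a random positive outranks a random negative."""
    for _ in range(20):
        y = rng.integers(0, 2, size=50)
        if len(np.unique(y)) < 2:
            continue
        s = np.round(rng.normal(size=50), 1)  # ties on purpose
        ranks = rankdata(s)  # midranks handle ties
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
        assert roc_auc(y, s) == pytest.approx(u / (n_pos * n_neg), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, size=80)
    y[:2] = [0, 1]
    s = rng.normal(size=80)
    assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(3 * s)), abs=1e-12)


def test_auc_single_class_undefined():
    with pytest.raises(UndefinedAUCError):
        roc_auc(np.ones(10), np.random.default_rng(0).normal(size=10))


# ------------------------------------------------------------- stratified folds

def test_exactly_divisible_stratification():
    y = np.array([1] * 70 + [0] * 30)
    folds = stratified_kfold(y, k=10, seed=0)
    for f in range(10):
        sel = folds == f
        assert sel.sum() == 10
        assert y[sel].sum() == 7


def test_folds_partition_all_indices():
    y = np.array([1] * 72 + [0] * 31)
    folds = stratified_kfold(y, k=10, seed=1)
    assert sorted(np.unique(folds)) == list(range(10))
    sizes = np.bincount(folds)
    assert sizes.max() - sizes.min() <= 1
    pos = np.array([y[folds == f].sum() for f in range(10)])
    assert pos.max() - pos.min() <= 1


def test_stratification_determinism_and_small_class_error():
    y = np.array([1] * 20 + [0] * 20)
    assert np.array_equal(stratified_kfold(y, 5, seed=9),
                          stratified_kfold(y, 5, seed=9))
    with pytest.raises(StratificationError, match="smaller k"):
        stratified_kfold(np.array([1] * 50 + [0] * 5), k=10)


# ------------------------------------------------------------- cross-validation

def test_perfectly_predictable_labels():
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1], 100)
    X = pd.DataFrame({"f": y + 0.01 * rng.normal(size=200)})
    report = cross_validate(X, y, hp=HyperParams(n_estimators=20), k=10, seed=0)
    assert report.mean["accuracy"] >= 0.99


def test_report_means_are_arithmetic_means():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(120, 4)))
    y = rng.integers(0, 2, size=120)
    y[:20] = 1
    y[-20:] = 0
    report = cross_validate(X, y, hp=HyperParams(n_estimators=10), k=5, seed=2)
    for m in ("accuracy", "precision", "recall", "f1", "auc"):
        assert report.mean[m] == pytest.approx(report.per_fold[m].mean())
    assert len(report.per_fold) == 5


# ------------------------------------------------------------------- pipeline

def test_pipeline_produces_artifacts(tmp_path):
    cfg = PipelineConfig(
        sim=SimConfig(duration_s=128, burst_rate=12, seed=5),
        seed=5,
        out_dir=str(tmp_path),
    )
    report, artifacts = run_pipeline(cfg)
    assert len(report.per_fold) == 10
    feats = pd.read_csv(tmp_path / "features.csv")
    assert list(feats.columns) == FEATURE_NAMES + ["label"]
    payload = json.loads((tmp_path / "report.json").read_text())
    assert payload["positive_class"] == 1
    assert set(payload["mean"]) == {"accuracy", "precision", "recall", "f1", "auc"}
    assert (tmp_path / "model.txt").exists()
    assert artifacts["model"].feature_names == FEATURE_NAMES


def test_pipeline_requires_a_data_source():
    with pytest.raises(ValueError, match="data source"):
        run_pipeline(PipelineConfig())


def test_kalman_stage_does_not_hurt_at_low_snr():
    """Disabling the filter must not beat it by more than 0.02 (5-seed medians)."""
    accs = {True: [], False: []}
    for seed in range(5):
        for use_kalman in (True, False):
            cfg = PipelineConfig(
                sim=SimConfig(duration_s=256, burst_rate=12,
                              burst_amplitude=0.15, noise_sigma=0.1, seed=seed),
                use_kalman=use_kalman,
                seed=seed,
            )
            report, _ = run_pipeline(cfg)
            accs[use_kalman].append(report.mean["accuracy"])
    assert np.median(accs[False]) <= np.median(accs[True]) + 0.02


# ---------------------------------------------------------- feature-count sweep

def test_feature_sweep_consistent_with_full_cv(sim_features):
    df = sim_features.iloc[:120]
    hp = HyperParams(n_estimators=25)
    sweep = feature_count_sweep(df, hp=hp, k=5, seed=3)
    assert sweep["n_features"].tolist() == list(range(2, 23))
    assert sweep["accuracy"].between(0, 1).all()
    full = cross_validate(df, hp=hp, k=5, seed=3)
    assert sweep.loc[sweep["n_features"] == 22, "accuracy"].iloc[0] == pytest.approx(
        full.mean["accuracy"]
    )


def test_feature_sweep_flat_once_informative_column_included(rng):
    """With signal only in T_Energy, accuracy plateaus once it enters."""
    n = 160
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(rng.normal(size=(n, 22)), columns=FEATURE_NAMES)
    X["T_Energy"] = y * 2.0 + 0.05 * rng.normal(size=n)
    hp = HyperParams(n_estimators=20)
    sweep = feature_count_sweep(X, y, hp=hp, k=5, seed=1)
    idx = FEATURE_NAMES.index("T_Energy") + 1  # first m that includes it
    plateau = sweep.loc[sweep["n_features"] >= idx, "accuracy"]
    final = plateau.iloc[-1]
    assert np.all(np.abs(plateau - final) <= 0.05)
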