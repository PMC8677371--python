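"""Confusion-matrix metrics, ROC/AUC, stratified 10-fold CV and the pipeline.

Classification quality is summarized by the confusion-matrix metrics

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

plus the area under the ROC curve, evaluated with stratified tenfold
cross-validation.  Internally the positive class is "fetal movement" coded
as 1; recording-level ground truth from the simulator already uses that
convention, and reports state it explicitly because field data sometimes
codes fetal movement as 0 (re-coding then happens at the I/O boundary).

:func:`run_pipeline` drives the whole chain: simulate (or load) a recording,
segment into 2.56 s epochs, Kalman-denoise, extract the 22 TFWD features,
optionally tune hyperparameters, and cross-validate.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import gp_optimizer as gpo
from .classifier import FittedModel, HyperParams, predict_proba, train_model
from .features import FEATURE_NAMES, SpectrumConfig, WaveletConfig, feature_matrix
from .preprocess import EPOCH_SECONDS, preprocess_epoch, segment
from .synthetic import LabeledRecording, SimConfig, label_epochs, simulate_recording

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "PipelineConfig",
    "UndefinedAUCError",
    "StratificationError",
    "confusion",
    "metrics",
    "roc_auc",
    "stratified_kfold",
    "cross_validate",
    "tuning_objective",
    "run_pipeline",
    "feature_count_sweep",
    "roc_curve_data",
    "pr_curve_data",
]

METRIC_COLUMNS = ["accuracy", "precision", "recall", "f1", "auc"]


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


class StratificationError(ValueError):
    """A class has fewer members than the number of folds."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(labels, predictions, positive_class: int = 1) -> ConfusionCounts:
    """Count TP/FP/FN/TN with the stated positive class."""
    labels = np.asarray(labels).ravel()
    predictions = np.asarray(predictions).ravel()
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    pos = labels == positive_class
    pred_pos = predictions == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
    )


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from the counts.

    Zero-denominator cases (no predicted positives / no actual positives)
    yield 0 for the affected metric and set the ``degenerate`` flag.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    f1 = ratio(2.0 * precision * recall, precision + recall)
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "degenerate": degenerate,
    }


def roc_auc(labels, scores, positive_class: int = 1) -> float:
    """Area under the ROC curve; scores must be oriented toward the positive class."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, float).ravel()
    y = (labels == positive_class).astype(int)
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("AUC is undefined with a single class present")
    return float(roc_auc_score(y, scores))


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment per sample; folds preserve class proportions."""
    labels = np.asarray(labels).ravel()
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if len(too_small):
        raise StratificationError(
            f"classes {too_small.tolist()} have fewer than k={k} members; "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class CVReport:
    """Per-fold and mean metrics from stratified k-fold cross-validation."""

    per_fold: pd.DataFrame  # columns: fold + METRIC_COLUMNS
    k: int
    seed: int
    positive_class: int = 1

    @property
    def mean(self) -> dict:
        return {m: float(self.per_fold[m].mean()) for m in METRIC_COLUMNS}

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "positive_class": self.positive_class,
            "per_fold": self.per_fold.to_dict(orient="records"),
            "mean": self.mean,
        }

    def summary(self) -> str:
        lines = ["Stratified %d-fold cross-validation (positive class = %d)"
                 % (self.k, self.positive_class)]
        lines.append(self.per_fold.to_string(index=False,
                                             float_format=lambda v: f"{v:.4f}"))
        mean = self.mean
        lines.append("mean  " + "  ".join(f"{m}={mean[m]:.4f}" for m in METRIC_COLUMNS))
        return "\n".join(lines)


def _split_Xy(X, y):
    if y is None:
        if not isinstance(X, pd.DataFrame) or "label" not in X.columns:
            raise ValueError("y is required unless X has a 'label' column")
        return X.drop(columns=["label"]), X["label"].to_numpy(int)
    if isinstance(X, pd.DataFrame) and "label" in X.columns:
        X = X.drop(columns=["label"])
    return X, np.asarray(y).ravel().astype(int)


def cross_validate(
    X,
    y=None,
    hp: HyperParams = HyperParams(),
    k: int = 10,
    seed: int = 0,
    tune: str | None = None,
    tune_budget: tuple[int, int] = (8, 16),
    nested: bool = True,
    space: gpo.SearchSpace | None = None,
) -> CVReport:
    """Train on k-1 folds, score the held-out fold, for every fold.

    With ``tune`` in {'boa', 'grid', 'random'} the hyperparameters are tuned
    by minimizing inner 5-fold log-loss; ``nested=True`` (default) re-tunes
    inside each training portion to keep the held-out fold untouched, while
    ``nested=False`` tunes once on the full data (replication mode, leaks).
    """
    X, y = _split_Xy(X, y)
    folds = stratified_kfold(y, k=k, seed=seed)
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)

    hp_global = hp
    if tune is not None and not nested:
        hp_global = _tune(Xa, y, hp, tune, tune_budget, seed, space)

    rows = []
    for fold in range(k):
        test = folds == fold
        X_tr, y_tr = Xa[~test], y[~test]
        X_te, y_te = Xa[test], y[test]
        hp_fold = hp_global
        if tune is not None and nested:
            hp_fold = _tune(X_tr, y_tr, hp, tune, tune_budget, seed + fold, space)
        model = train_model(X_tr, y_tr, hp_fold)
        p = predict_proba(model, X_te)
        pred = (p >= 0.5).astype(int)
        m = metrics(confusion(y_te, pred, positive_class=1))
        row = {"fold": fold, **{k_: m[k_] for k_ in METRIC_COLUMNS[:-1]}}
        row["auc"] = roc_auc(y_te, p, positive_class=1)
        rows.append(row)
    return CVReport(per_fold=pd.DataFrame(rows), k=k, seed=seed)


def tuning_objective(
    X, y, base_hp: HyperParams = HyperParams(), inner_k: int = 5, seed: int = 0
) -> Callable[[dict], float]:
    """Mean inner-CV log-loss as a function of the tuned hyperparameters."""
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ya = np.asarray(y).ravel().astype(int)

    def objective(params: dict) -> float:
        hp = HyperParams.from_dict(
            {**params, "learning_rate": base_hp.learning_rate, "seed": base_hp.seed}
        )
        folds = stratified_kfold(ya, k=inner_k, seed=seed)
        losses = []
        for fold in range(inner_k):
            test = folds == fold
            model = train_model(Xa[~test], ya[~test], hp)
            p = predict_proba(model, Xa[test])
            losses.append(log_loss(ya[test], p, labels=[0, 1]))
        return float(np.mean(losses))

    return objective


def _tune(Xa, ya, base_hp, method, budget, seed, space):
    space = space or gpo.default_space()
    objective = tuning_objective(Xa, ya, base_hp=base_hp, seed=seed)
    n_init, n_iter = budget
    if method == "boa":
        best, _, _ = gpo.bayes_optimize(
            objective, space, n_init=n_init, n_iter=n_iter, seed=seed
        )
    elif method == "random":
        best, _, _ = gpo.random_search(objective, space, n_init + n_iter, seed=seed)
    elif method == "grid":
        ppd = max(2, int(round((n_init + n_iter) ** (1.0 / space.n_dims))))
        best, _, _ = gpo.grid_search(objective, space, ppd)
    else:
        raise ValueError(f"unknown tuner {method!r}")
    return HyperParams.from_dict(
        {**best, "learning_rate": base_hp.learning_rate, "seed": base_hp.seed}
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: data source and per-stage parameters."""

    sim: SimConfig | None = None
    recording_path: str | None = None
    epoch_seconds: float = EPOCH_SECONDS
    overlap_fraction: float = 0.25
    use_kalman: bool = True
    kalman_mode: str = "per_axis_then_magnitude"
    q_ratio: float = 0.1
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    hp: HyperParams = field(default_factory=HyperParams)
    tune: str | None = None
    tune_budget: tuple[int, int] = (8, 16)
    nested_tuning: bool = True
    k: int = 10
    seed: int = 0
    out_dir: str | None = None


def _pipeline_features(cfg: PipelineConfig, recording: LabeledRecording):
    labels = label_epochs(
        recording, epoch_seconds=cfg.epoch_seconds,
        overlap_fraction=cfg.overlap_fraction,
    )
    epochs = segment(recording, epoch_seconds=cfg.epoch_seconds, labels=labels)
    processed = []
    for ep in epochs:
        if cfg.use_kalman:
            processed.append(
                preprocess_epoch(ep, mode=cfg.kalman_mode, q_ratio=cfg.q_ratio)
            )
        else:
            mag = np.linalg.norm(np.asarray(ep.samples, float), axis=1)
            processed.append(
                type(ep)(mag, ep.fs, ep.index, ep.label)
            )
    return feature_matrix(processed, cfg.spectrum, cfg.wavelet)


def run_pipeline(config: PipelineConfig):
    """simulate/ingest -> segment -> Kalman -> TFWD -> (tune) -> 10-fold CV.

    Returns ``(report, artifacts)``; *artifacts* holds the feature matrix,
    the final model trained on all epochs, stage timings and every seed.
    When ``config.out_dir`` is set, features.csv, model.txt, tuning.json and
    report.json are written there.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    from .synthetic import read_recording  # local import to avoid cycle noise

    if config.sim is not None:
        recording = simulate_recording(config.sim)
    elif config.recording_path is not None:
        recording = read_recording(config.recording_path)
    else:
        raise ValueError("config must name a data source (sim or recording_path)")
    timings["ingest"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        features = _pipeline_features(config, recording)
    except Exception as exc:
        raise RuntimeError(f"feature stage failed: {exc}") from exc
    timings["features"] = time.perf_counter() - t0

    X, y = _split_Xy(features, None)

    tuning_record = None
    hp = config.hp
    t0 = time.perf_counter()
    if config.tune is not None and not config.nested_tuning:
        hp = _tune(
            X.to_numpy(float), y, config.hp, config.tune, config.tune_budget,
            config.seed, None,
        )
        tuning_record = asdict(hp)
    timings["tuning"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = cross_validate(
        X, y, hp=hp, k=config.k, seed=config.seed,
        tune=config.tune if config.nested_tuning else None,
        tune_budget=config.tune_budget, nested=True,
    )
    timings["cross_validation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    final_model = train_model(X, y, hp)
    timings["final_fit"] = time.perf_counter() - t0

    artifacts = {
        "features": features,
        "model": final_model,
        "hyperparams": hp,
        "tuning": tuning_record,
        "timings": timings,
        "seeds": {
            "pipeline": config.seed,
            "simulation": None if config.sim is None else config.sim.seed,
            "model": hp.seed,
        },
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        final_model.save(out / "model.txt")
        if tuning_record is not None:
            (out / "tuning.json").write_text(
                json.dumps(tuning_record, indent=1), encoding="utf-8"
            )
        cfg_hash = hashlib.sha256(
            repr(config).encode("utf-8")
        ).hexdigest()[:16]
        report_payload = {
            "config_hash": cfg_hash,
            "seeds": artifacts["seeds"],
            "per_fold": report.per_fold.to_dict(orient="records"),
            "mean": report.mean,
            "positive_class": report.positive_class,
            "timings": timings,
        }
        (out / "report.json").write_text(
            json.dumps(report_payload, indent=1), encoding="utf-8"
        )
    return report, artifacts


def feature_count_sweep(
    X, y=None, hp: HyperParams = HyperParams(), k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Mean CV accuracy using only the first m features, m = 2..n_features."""
    X, y = _split_Xy(X, y)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rows = []
    for m in range(2, X.shape[1] + 1):
        rep = cross_validate(X.iloc[:, :m], y, hp=hp, k=k, seed=seed)
        rows.append({"n_features": m, "accuracy": rep.mean["accuracy"]})
    return pd.DataFrame(rows)


def roc_curve_data(labels, scores, positive_class: int = 1) -> pd.DataFrame:
    """Threshold sweep: FPR/TPR points of the ROC curve."""
    from sklearn.metrics import roc_curve

    y = (np.asarray(labels).ravel() == positive_class).astype(int)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, float).ravel())
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def pr_curve_data(labels, scores, positive_class: int = 1) -> pd.DataFrame:
    """Threshold sweep: precision/recall points."""
    from sklearn.metrics import precision_recall_curve

    y = (np.asarray(labels).ravel() == positive_class).astype(int)
    prec, rec, thr = precision_recall_curve(y, np.asarray(scores, float).ravel())
    return pd.DataFrame(
        {
            "threshold": np.append(thr, np.nan),
            "precision": prec,
            "recall": rec,
        }
    )
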