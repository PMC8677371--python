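"""Gradient-boosted classifier plus reference split-gain computations.

Production training delegates to LightGBM under a deterministic-given-seed,
single-threaded contract.  The split criteria that drive its leaf-wise tree
growth are additionally implemented here as standalone, independently
testable functions:

* :func:`split_gain` — the variance gain of a candidate threshold d on one
  feature: V(d) = (1/n0) [ (sum_{left} g)^2 / n_l + (sum_{right} g)^2 / n_r ]
  with g the per-instance negative gradients of the loss.
* :func:`goss_gain` — the same gain under gradient-based one-side sampling:
  the top-a fraction of instances by |g| is kept, a b fraction of the rest is
  sampled, and the sampled gradient sums are reweighted by (1 - a) / b so the
  estimated gain stays centred on the full-data value.  The denominators n0,
  n_l, n_r keep their full-data meaning, so at a = 1 the two gains coincide
  exactly.

These reference functions are used for testing and education; they do not
re-implement histogram binning, exclusive feature bundling, or tree growth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

__all__ = [
    "HyperParams",
    "SplitContext",
    "UndefinedSplitError",
    "TrainingError",
    "SchemaError",
    "split_gain",
    "goss_gain",
    "best_split",
    "FittedModel",
    "train_model",
    "predict_proba",
]


class UndefinedSplitError(ValueError):
    """A candidate split leaves one side empty."""


class TrainingError(ValueError):
    """The training set cannot be fitted (e.g. a single class)."""


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the training schema."""


@dataclass(frozen=True)
class HyperParams:
    """The six tuned hyperparameters plus learning rate and seed.

    Defaults are the Bayesian-optimization incumbent of the reference study
    (learning_rate was not among the tuned parameters; 0.1 is the documented
    default).
    """

    n_estimators: int = 51
    max_depth: int = 5
    num_leaves: int = 63
    subsample: float = 0.8863
    colsample_bytree: float = 0.9079
    min_child_samples: int = 8
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.num_leaves < 2:
            raise ValueError("num_leaves must be >= 2")
        if not (0 < self.subsample <= 1):
            raise ValueError("subsample must be in (0, 1]")
        if not (0 < self.colsample_bytree <= 1):
            raise ValueError("colsample_bytree must be in (0, 1]")
        if self.min_child_samples < 1:
            raise ValueError("min_child_samples must be >= 1")

    # Table-style aliases (N_estimators, Max_depth, ...) -> constructor kwargs
    _ALIASES = {
        "n_estimators": "n_estimators",
        "max_depth": "max_depth",
        "num_leaves": "num_leaves",
        "subsample": "subsample",
        "colsample_bytree": "colsample_bytree",
        "min_child_samples": "min_child_samples",
        "learning_rate": "learning_rate",
        "seed": "seed",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        """Build from a mapping with case-insensitive keys."""
        kwargs = {}
        for key, value in d.items():
            canon = cls._ALIASES.get(key.lower())
            if canon is None:
                raise ValueError(f"unknown hyperparameter {key!r}")
            kwargs[canon] = value
        return cls(**kwargs)


@dataclass
class SplitContext:
    """Everything a gain evaluation needs for one candidate threshold.

    ``top_idx`` (set A: large-|g| instances kept) and ``sampled_idx`` (set B:
    random sample of the rest) are only used by :func:`goss_gain`; the plain
    gain uses every instance.
    """

    gradients: np.ndarray
    values: np.ndarray
    threshold: float
    a: float = 1.0
    b: float = 1.0
    top_idx: np.ndarray | None = None
    sampled_idx: np.ndarray | None = None

    def __post_init__(self):
        self.gradients = np.asarray(self.gradients, float).ravel()
        self.values = np.asarray(self.values, float).ravel()
        if self.gradients.shape != self.values.shape:
            raise ValueError("gradients and feature values must align")
        if not (0 < self.a <= 1) or not (0 < self.b <= 1):
            raise ValueError("a and b must lie in (0, 1]")
        if self.a + self.b > 1 + 1e-12 and self.a < 1:
            raise ValueError("GOSS sampling requires a + b <= 1")

    @classmethod
    def plain(cls, gradients, values, threshold) -> "SplitContext":
        n = len(np.asarray(gradients).ravel())
        ctx = cls(gradients, values, threshold)
        ctx.top_idx = np.arange(n)
        ctx.sampled_idx = np.array([], dtype=int)
        return ctx

    @classmethod
    def goss(
        cls, gradients, values, threshold, a: float, b: float,
        rng: np.random.Generator,
    ) -> "SplitContext":
        """Construct the GOSS instance sets with a seeded RNG.

        Keeps the top ``round(a*n)`` instances by |g| and samples
        ``round(b*n)`` of the remainder uniformly without replacement.  The
        chosen sets are stored on the context so hand oracles can reproduce
        the exact computation.
        """
        ctx = cls(gradients, values, threshold, a=a, b=b)
        g = ctx.gradients
        n = len(g)
        n_top = int(round(a * n))
        order = np.argsort(-np.abs(g), kind="stable")
        ctx.top_idx = np.sort(order[:n_top])
        rest = np.sort(order[n_top:])
        n_samp = min(int(round(b * n)), len(rest))
        ctx.sampled_idx = np.sort(rng.choice(rest, size=n_samp, replace=False))
        return ctx


def split_gain(ctx: SplitContext) -> float:
    """Variance gain of the threshold over the *full* instance set."""
    left = ctx.values <= ctx.threshold
    n0 = len(ctx.gradients)
    n_l = int(left.sum())
    n_r = n0 - n_l
    if n_l == 0 or n_r == 0:
        raise UndefinedSplitError(
            f"threshold {ctx.threshold} leaves an empty side (n_l={n_l}, n_r={n_r})"
        )
    g_l = float(ctx.gradients[left].sum())
    g_r = float(ctx.gradients[~left].sum())
    return (g_l * g_l / n_l + g_r * g_r / n_r) / n0


def goss_gain(ctx: SplitContext) -> float:
    """GOSS-adjusted gain: sampled small-gradient sums reweighted by (1-a)/b.

    Denominators (n0, n_l, n_r) keep their full-data values, so this reduces
    exactly to :func:`split_gain` when a = 1 (everything kept, B empty).
    """
    if ctx.top_idx is None or ctx.sampled_idx is None:
        raise ValueError("GOSS sets not constructed; use SplitContext.goss(...)")
    left_all = ctx.values <= ctx.threshold
    n0 = len(ctx.gradients)
    n_l = int(left_all.sum())
    n_r = n0 - n_l
    if n_l == 0 or n_r == 0:
        raise UndefinedSplitError("threshold leaves an empty side")
    used = np.concatenate([ctx.top_idx, ctx.sampled_idx])
    if not left_all[used].any() or not (~left_all[used]).any():
        raise UndefinedSplitError("a side is empty after GOSS sampling")
    w = (1.0 - ctx.a) / ctx.b if ctx.a < 1 else 0.0
    g = ctx.gradients
    top_left = left_all[ctx.top_idx]
    samp_left = left_all[ctx.sampled_idx]
    s_l = float(g[ctx.top_idx][top_left].sum()) + w * float(
        g[ctx.sampled_idx][samp_left].sum()
    )
    s_r = float(g[ctx.top_idx][~top_left].sum()) + w * float(
        g[ctx.sampled_idx][~samp_left].sum()
    )
    return (s_l * s_l / n_l + s_r * s_r / n_r) / n0


def best_split(gradients, feature_values):
    """Exhaustive threshold scan: the gain-maximizing midpoint, or None.

    Candidates are midpoints of consecutive sorted unique values; ties break
    toward the smallest threshold.  A constant feature admits no split.
    """
    values = np.asarray(feature_values, float).ravel()
    uniq = np.unique(values)
    if len(uniq) < 2:
        return None
    best_d, best_v = None, -np.inf
    for d in (uniq[:-1] + uniq[1:]) / 2.0:
        v = split_gain(SplitContext(gradients, values, float(d)))
        if v > best_v:
            best_d, best_v = float(d), v
    return best_d, best_v


@dataclass
class FittedModel:
    """A trained booster plus its training schema and hyperparameters."""

    booster: LGBMClassifier
    feature_names: list[str]
    hyperparams: HyperParams

    def save(self, path: str | Path) -> None:
        """Write the native booster model text plus a JSON sidecar."""
        path = Path(path)
        self.booster.booster_.save_model(str(path))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "hyperparams": asdict(self.hyperparams),
                },
                indent=1,
            ),
            encoding="utf-8",
        )


def train_model(X, y, hp: HyperParams = HyperParams()) -> FittedModel:
    """Fit the leaf-wise GBDT with binary log-loss, deterministic given seed."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        names = [f"f{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X rows must match y length")
    if len(np.unique(ya)) < 2:
        raise TrainingError("training labels contain a single class")
    clf = LGBMClassifier(
        objective="binary",
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        num_leaves=hp.num_leaves,
        subsample=hp.subsample,
        subsample_freq=1 if hp.subsample < 1 else 0,
        colsample_bytree=hp.colsample_bytree,
        min_child_samples=hp.min_child_samples,
        learning_rate=hp.learning_rate,
        random_state=hp.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
    )
    clf.fit(pd.DataFrame(Xa, columns=names), ya)
    return FittedModel(booster=clf, feature_names=names, hyperparams=hp)


def predict_proba(model: FittedModel, X) -> np.ndarray:
    """Per-row probability of the positive (fetal movement) class."""
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != model.feature_names:
            missing = [c for c in model.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in model.feature_names]
            raise SchemaError(
                "feature columns do not match the training schema "
                f"(missing={missing}, unexpected={extra}, "
                f"expected order={model.feature_names})"
            )
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        if Xa.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} feature columns, "
                f"got {Xa.shape[1]}"
            )
    Xdf = pd.DataFrame(Xa, columns=model.feature_names)
    return model.booster.predict_proba(Xdf)[:, 1]
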