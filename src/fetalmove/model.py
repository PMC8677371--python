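"""Model/Results facade over the recognition pipeline.

`FetalMovementModel` is constructed from data (a feature matrix, a recording,
or a simulation config); `fit()` runs stratified tenfold cross-validation,
optionally preceded by Bayesian hyperparameter tuning, and returns a
`FetalMovementResults` carrying per-fold and mean metrics, the final model
trained on all epochs, and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classifier import FittedModel, HyperParams, predict_proba
from .evaluation import CVReport, PipelineConfig, cross_validate, run_pipeline, _split_Xy
from .features import FEATURE_NAMES
from .preprocess import EPOCH_SECONDS
from .synthetic import LabeledRecording, SimConfig

__all__ = ["FetalMovementModel", "FetalMovementResults"]


class FetalMovementModel:
    """Per-epoch fetal-movement classifier specification bound to data.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per epoch; the 22 TFWD feature columns (optionally with a
        ``label`` column).
    labels : array-like of {0, 1}, optional
        Per-epoch ground truth (1 = fetal movement); may instead come from a
        ``label`` column of *features*.
    hyperparams : HyperParams, optional
        Boosting hyperparameters; defaults to the tuned reference values.

    Examples
    --------
    >>> from fetalmove import FetalMovementModel, SimConfig
    >>> model = FetalMovementModel.from_simulation(SimConfig(duration_s=128, seed=1))
    >>> res = model.fit(k=10, seed=1)
    >>> print(res.summary())                        # doctest: +SKIP
    """

    def __init__(self, features: pd.DataFrame, labels=None,
                 hyperparams: HyperParams | None = None):
        X, y = _split_Xy(features, labels)
        self.exog = X.reset_index(drop=True)
        self.endog = np.asarray(y, dtype=int)
        self.hyperparams = hyperparams or HyperParams()
        self._pipeline_config: PipelineConfig | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       hyperparams: HyperParams | None = None) -> "FetalMovementModel":
        """Build from a single DataFrame holding features plus a label column."""
        if label_col != "label":
            df = df.rename(columns={label_col: "label"})
        return cls(df, hyperparams=hyperparams)

    @classmethod
    def from_recording(
        cls,
        recording: LabeledRecording,
        epoch_seconds: float = EPOCH_SECONDS,
        q_ratio: float = 0.1,
        use_kalman: bool = True,
        overlap_fraction: float = 0.25,
        hyperparams: HyperParams | None = None,
    ) -> "FetalMovementModel":
        """Segment, denoise and featurize a labeled recording."""
        from .evaluation import _pipeline_features

        cfg = PipelineConfig(
            epoch_seconds=epoch_seconds, q_ratio=q_ratio, use_kalman=use_kalman,
            overlap_fraction=overlap_fraction,
        )
        feats = _pipeline_features(cfg, recording)
        model = cls(feats, hyperparams=hyperparams)
        model._pipeline_config = cfg
        return model

    @classmethod
    def from_simulation(
        cls, sim: SimConfig, hyperparams: HyperParams | None = None, **kwargs
    ) -> "FetalMovementModel":
        """Simulate a recording and build the model from it."""
        from .synthetic import simulate_recording

        return cls.from_recording(
            simulate_recording(sim), hyperparams=hyperparams, **kwargs
        )

    # ------------------------------------------------------------------
    def fit(
        self,
        k: int = 10,
        seed: int = 0,
        tune: str | None = None,
        tune_budget: tuple[int, int] = (8, 16),
    ) -> "FetalMovementResults":
        """Cross-validate (optionally with nested tuning) and fit on all data."""
        from .classifier import train_model

        hp = replace(self.hyperparams, seed=seed)
        report = cross_validate(
            self.exog, self.endog, hp=hp, k=k, seed=seed,
            tune=tune, tune_budget=tune_budget,
        )
        final = train_model(self.exog, self.endog, hp)
        return FetalMovementResults(self, report, final, hp)


class FetalMovementResults:
    """Cross-validated performance plus the final fitted classifier."""

    def __init__(self, model: FetalMovementModel, cv: CVReport,
                 fitted: FittedModel, hyperparams: HyperParams):
        self.model = model
        self.cv = cv
        self.fitted = fitted
        self.hyperparams = hyperparams

    @property
    def mean_metrics(self) -> dict:
        return self.cv.mean

    def predict_proba(self, X) -> np.ndarray:
        """P(fetal movement) per epoch row."""
        return predict_proba(self.fitted, X)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def summary(self) -> str:
        hp = self.hyperparams
        head = [
            "Fetal movement recognition — gradient-boosted classifier",
            "=" * 58,
            f"epochs: {len(self.model.endog)}   "
            f"positives: {int(self.model.endog.sum())}   "
            f"features: {self.model.exog.shape[1]}",
            f"hyperparameters: n_estimators={hp.n_estimators}, "
            f"max_depth={hp.max_depth}, num_leaves={hp.num_leaves},",
            f"    subsample={hp.subsample}, colsample_bytree={hp.colsample_bytree}, "
            f"min_child_samples={hp.min_child_samples}, "
            f"learning_rate={hp.learning_rate}",
            "-" * 58,
        ]
        return "\n".join(head) + "\n" + self.cv.summary()
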