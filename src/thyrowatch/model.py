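"""Quantile-transform + gradient-boosted tree classifier, and importance.

The classifier maps the 8 case features through a per-feature empirical
quantile transform (fitted on training cases only, uniform output) and
feeds the transformed features to a LightGBM binary classifier.  The
quantile step makes predictions invariant to any monotone rescaling of a
raw feature.  This module emits probabilities only; the decision
threshold lives in :mod:`thyrowatch.evaluation`.

Feature importance is reported by *gain* (total loss reduction
attributable to a feature, normalized to sum to 1) and by *split*
(relative count of splits using the feature); the combined criterion is
the per-model mean of the gain rank and the split rank, averaged across
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy.stats import rankdata
from sklearn.preprocessing import QuantileTransformer

from .dataset import CaseRecord
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "SingleClassError",
    "fit",
    "fit_matrix",
    "predict_proba",
    "feature_importance",
    "ImportanceReport",
]


class SingleClassError(ValueError):
    """Training data contained only one class."""


@dataclass(frozen=True)
class ModelConfig:
    """Training settings.

    Defaults favour determinism: no row/column subsampling, single thread,
    deterministic histogram construction.  ``n_quantiles=None`` lets the
    transformer use ``min(1000, n_train)``.
    """

    n_estimators: int = 200
    learning_rate: float = 0.05
    num_leaves: int = 31
    min_child_samples: int = 20
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    n_quantiles: int | None = None
    #: histogram resolution of the boosting backend; the library defaults
    #: (255 bins, >= 3 rows per bin) bin by row count, so exact invariance
    #: to uniform case duplication requires max_bin >= n distinct values
    #: and min_data_in_bin = 1
    max_bin: int = 255
    min_data_in_bin: int = 3

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedModel:
    transform: QuantileTransformer
    booster: LGBMClassifier
    config: ModelConfig
    seed: int


def _as_matrix(cases_or_X) -> np.ndarray:
    if isinstance(cases_or_X, np.ndarray):
        return cases_or_X
    return np.array([c.features.as_array() for c in cases_or_X], dtype=float)


def fit_matrix(X: np.ndarray, y: np.ndarray, config: ModelConfig = ModelConfig(), seed: int = 0) -> TrainedModel:
    """Fit transform + booster on a feature matrix and binary labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError(
            f"training data holds a single class ({classes.tolist()}); "
            "both thyrotoxic and non-thyrotoxic cases are required"
        )
    n_q = config.n_quantiles or min(1000, X.shape[0])
    transform = QuantileTransformer(
        n_quantiles=n_q,
        output_distribution="uniform",
        subsample=None,
        random_state=seed,
    )
    Xt = pd.DataFrame(transform.fit_transform(X), columns=list(FEATURE_NAMES))
    booster = LGBMClassifier(
        objective="binary",
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        num_leaves=config.num_leaves,
        min_child_samples=config.min_child_samples,
        subsample=config.subsample,
        colsample_bytree=config.colsample_bytree,
        max_bin=config.max_bin,
        min_data_in_bin=config.min_data_in_bin,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    booster.fit(Xt, y)
    return TrainedModel(transform=transform, booster=booster, config=config, seed=seed)


def fit(
    training_cases: Sequence[CaseRecord] | np.ndarray,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> TrainedModel:
    """Fit from case records (or a raw matrix plus explicit labels)."""
    X = _as_matrix(training_cases)
    if labels is None:
        if isinstance(training_cases, np.ndarray):
            raise ValueError("labels are required when passing a raw matrix")
        labels = np.array([c.label for c in training_cases], dtype=int)
    if X.shape[0] < 20:
        raise ValueError(f"need >= 20 training cases, got {X.shape[0]}")
    return fit_matrix(X, labels, config=config, seed=seed)


def predict_proba(model: TrainedModel, features) -> np.ndarray | float:
    """Probability of the positive (thyrotoxic) class.

    Accepts a single :class:`FeatureVector` (returns a float) or an
    ``(n, 8)`` matrix / case sequence (returns an array).
    """
    single = isinstance(features, FeatureVector)
    if single:
        X = features.as_array()[None, :]
    else:
        X = _as_matrix(features)
        if X.ndim == 1:
            X = X[None, :]
    Xt = pd.DataFrame(model.transform.transform(X), columns=list(FEATURE_NAMES))
    probs = model.booster.predict_proba(Xt)[:, 1]
    return float(probs[0]) if single else probs


@dataclass
class ImportanceReport:
    """Gain/split importances and ranks, averaged across fitted models."""

    frame: pd.DataFrame = field(repr=False)

    def average_ranks(self) -> pd.DataFrame:
        return (
            self.frame.groupby("feature")[["rank_gain", "rank_split", "rank_combined"]]
            .mean()
            .sort_values("rank_combined")
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")


def _ranks(values: np.ndarray) -> np.ndarray:
    # rank 1 = most important; ordinal tie-break keeps ranks a permutation of 1..n
    return rankdata(-values, method="ordinal").astype(int)


def feature_importance(models: Sequence[TrainedModel]) -> ImportanceReport:
    """Per-feature gain and split importance with per-model ranks."""
    if not models:
        raise ValueError("feature_importance requires at least one fitted model")
    rows = []
    for k, m in enumerate(models):
        gain = m.booster.booster_.feature_importance(importance_type="gain").astype(float)
        split = m.booster.booster_.feature_importance(importance_type="split").astype(float)
        gain_norm = gain / gain.sum() if gain.sum() > 0 else gain
        split_norm = split / split.sum() if split.sum() > 0 else split
        r_gain = _ranks(gain)
        r_split = _ranks(split)
        combined = (r_gain + r_split) / 2.0
        for i, name in enumerate(FEATURE_NAMES):
            rows.append(
                {
                    "model": k,
                    "feature": name,
                    "gain": gain_norm[i],
                    "split": split_norm[i],
                    "rank_gain": r_gain[i],
                    "rank_split": r_split[i],
                    "rank_combined": combined[i],
                }
            )
    return ImportanceReport(frame=pd.DataFrame(rows))
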