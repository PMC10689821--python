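"""Modified leave-one-out cross-validation and clinical metrics.

Each *observed* HR-TFT pair P takes a turn as the evaluation target.  The
training pool is every case (observed and interpolated, all patients)
except those that involve P as referred or target — the exclusion that
keeps the held-out pair's data out of training.  The test cases are
``Q -> P`` for every other observed pair Q of the same patient; one model
is fitted per target fold (all test cases of a fold share the same
exclusion set, so per-case refits would be identical), the per-referred
probabilities are averaged arithmetically, and the decision applies a
threshold (default 0.5) to the average.

Metrics are the standard 2x2 diagnostics — sensitivity, specificity,
positive and negative predictive value — reported as percentages.  A
variant drops targets whose true state is subclinical thyrotoxicosis
(normal free T4, suppressed TSH) before counting, which only removes
label-negative targets and therefore never changes TP or FN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .dataset import Dataset
from .hr_windows import HRTFTPair
from .model import ModelConfig, fit_matrix, predict_proba
from .thyroid import ThyroidState

__all__ = [
    "TargetPrediction",
    "FoldAudit",
    "LoocvResult",
    "ConfusionMatrix",
    "MetricReport",
    "loocv_predict",
    "confusion",
    "metrics",
    "window_sweep",
    "compare_groups",
    "compare_proportions",
    "GroupComparison",
]

logger = logging.getLogger(__name__)


@dataclass
class TargetPrediction:
    """Averaged thyrotoxicosis prediction for one observed target pair."""

    patient_id: str
    target: HRTFTPair
    referred_probabilities: dict
    averaged_probability: float
    decision: bool
    true_label: bool
    true_state: ThyroidState


@dataclass
class FoldAudit:
    """Bookkeeping for one LOOCV fold: exclusion counts and a leakage scan."""

    target_key: tuple
    n_train: int
    n_excluded: int
    n_test_referred: int
    leaked: bool
    train_cases: list[tuple] | None = None  # (referred.key, target.key) per case


@dataclass
class LoocvResult:
    predictions: list[TargetPrediction]
    folds: list[FoldAudit]
    skipped: list[tuple] = field(default_factory=list)

    def n_leaky_folds(self) -> int:
        return sum(f.leaked for f in self.folds)


def loocv_predict(
    dataset: Dataset,
    model_config: ModelConfig = ModelConfig(),
    threshold: float = 0.5,
    seed: int = 0,
    test_dataset: Dataset | None = None,
    collect_train_cases: bool = False,
) -> LoocvResult:
    """Run the modified LOOCV over every observed pair of the dataset.

    ``dataset`` supplies the training pool (typically augmented).  When
    ``test_dataset`` is given, test-case features are looked up there by
    (referred, target) identity instead — used by the window-length sweep
    to train on 10-day windows while testing on N-day windows.  Patients
    with a single observed pair are skipped with a logged warning.
    """
    X, y, ref_idx, tgt_idx = dataset.matrices()
    observed = [i for i, p in enumerate(dataset.pairs) if p.origin == "observed"]
    obs_by_patient: dict[str, list[int]] = {}
    for i in observed:
        obs_by_patient.setdefault(dataset.pairs[i].patient_id, []).append(i)

    test_lookup: dict[tuple, "np.ndarray"] | None = None
    test_pairs_by_key: dict[tuple, HRTFTPair] = {}
    if test_dataset is not None:
        test_lookup = {}
        for c in test_dataset.cases:
            test_lookup[(c.referred.key, c.target.key)] = c.features.as_array()
        test_pairs_by_key = {p.key: p for p in test_dataset.pairs}

    predictions: list[TargetPrediction] = []
    folds: list[FoldAudit] = []
    skipped: list[tuple] = []
    for p_idx in observed:
        target_pair = dataset.pairs[p_idx]
        siblings = [q for q in obs_by_patient[target_pair.patient_id] if q != p_idx]
        if not siblings:
            logger.warning(
                "patient %s has a single observed pair; target %s skipped",
                target_pair.patient_id,
                target_pair.tft.test_date,
            )
            skipped.append(target_pair.key)
            continue
        if test_dataset is not None and target_pair.key not in test_pairs_by_key:
            skipped.append(target_pair.key)
            continue

        train_mask = (ref_idx != p_idx) & (tgt_idx != p_idx)
        model = fit_matrix(X[train_mask], y[train_mask], config=model_config, seed=seed)

        # test cases: sibling observed pair -> target, same patient
        probs: dict[tuple, float] = {}
        for q_idx in siblings:
            if test_lookup is None:
                rows = np.where((ref_idx == q_idx) & (tgt_idx == p_idx))[0]
                if rows.size == 0:
                    continue
                fv = X[rows[0]]
            else:
                key = (dataset.pairs[q_idx].key, target_pair.key)
                if key not in test_lookup:
                    continue
                fv = test_lookup[key]
            p_hat = predict_proba(model, fv[None, :])[0]
            probs[dataset.pairs[q_idx].key] = float(p_hat)
        if not probs:
            skipped.append(target_pair.key)
            continue

        avg = float(np.mean(list(probs.values())))
        leaked = bool(
            np.any((ref_idx[train_mask] == p_idx) | (tgt_idx[train_mask] == p_idx))
        )
        folds.append(
            FoldAudit(
                target_key=target_pair.key,
                n_train=int(train_mask.sum()),
                n_excluded=int((~train_mask).sum()),
                n_test_referred=len(probs),
                leaked=leaked,
                train_cases=(
                    [
                        (dataset.cases[i].referred.key, dataset.cases[i].target.key)
                        for i in np.where(train_mask)[0]
                    ]
                    if collect_train_cases
                    else None
                ),
            )
        )
        predictions.append(
            TargetPrediction(
                patient_id=target_pair.patient_id,
                target=target_pair,
                referred_probabilities=probs,
                averaged_probability=avg,
                decision=avg >= threshold,
                true_label=bool(y[np.where(tgt_idx == p_idx)[0][0]])
                if np.any(tgt_idx == p_idx)
                else target_pair.tft.free_t4 > dataset.ranges.ft4_high,
                true_state=target_pair.tft.state(dataset.ranges),
            )
        )
    return LoocvResult(predictions=predictions, folds=folds, skipped=skipped)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(
    predictions: Sequence[TargetPrediction], exclude_subclinical: bool = False
) -> ConfusionMatrix:
    """Count decisions against true labels.

    With ``exclude_subclinical``, targets whose true state is subclinical
    thyrotoxicosis are dropped before counting.
    """
    tp = fn = fp = tn = 0
    for p in predictions:
        if (
            exclude_subclinical
            and p.true_state is ThyroidState.SUBCLINICAL_THYROTOXICOSIS
        ):
            continue
        if p.true_label and p.decision:
            tp += 1
        elif p.true_label and not p.decision:
            fn += 1
        elif not p.true_label and p.decision:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _ratio_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


@dataclass(frozen=True)
class MetricReport:
    """Sensitivity/specificity/PPV/NPV in percent; NaN marks undefined ratios."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            k: round(v, ndigits) if not math.isnan(v) else math.nan
            for k, v in self.as_dict().items()
        }

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """The four diagnostic ratios of a 2x2 table, as percentages."""
    return MetricReport(
        sensitivity=_ratio_pct(cm.tp, cm.tp + cm.fn),
        specificity=_ratio_pct(cm.tn, cm.tn + cm.fp),
        ppv=_ratio_pct(cm.tp, cm.tp + cm.fp),
        npv=_ratio_pct(cm.tn, cm.tn + cm.fn),
    )


def window_sweep(
    dataset_builder: Callable[[int], Dataset],
    day_lengths: Sequence[int],
    mode: str = "joint",
    model_config: ModelConfig = ModelConfig(),
    threshold: float = 0.5,
    seed: int = 0,
    train_days: int = 10,
) -> pd.DataFrame:
    """Diagnostic performance as a function of the HR-window length N.

    ``mode='joint'`` rebuilds training and test windows at each N;
    ``mode='fixed_train_10'`` trains once on ``train_days`` windows and
    varies only the test windows.  ``dataset_builder(n_days)`` must return
    the (augmented) dataset at that window length.
    """
    if mode not in ("joint", "fixed_train_10"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    if any(n < 1 or n > 30 for n in day_lengths):
        raise ValueError("day_lengths must lie in [1, 30]")
    rows = []
    train_ds = dataset_builder(train_days) if mode == "fixed_train_10" else None
    for n in day_lengths:
        if mode == "joint":
            result = loocv_predict(
                dataset_builder(n), model_config=model_config, threshold=threshold, seed=seed
            )
        else:
            result = loocv_predict(
                train_ds,
                model_config=model_config,
                threshold=threshold,
                seed=seed,
                test_dataset=dataset_builder(n) if n != train_days else train_ds,
            )
        rep = metrics(confusion(result.predictions))
        rows.append(
            {
                "n_days": n,
                "mode": mode,
                "n_targets": len(result.predictions),
                **rep.as_dict(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    summary_a: dict
    summary_b: dict


def _summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "median": float(med),
        "iqr": float(q3 - q1),
    }


def compare_groups(a, b, method: str = "auto") -> GroupComparison:
    """Two-group comparison of a continuous variable.

    ``method='t'`` uses Student's t test (normal-shaped variables, summary
    mean +- SD); ``'ranksum'`` the Mann-Whitney U test (summary median and
    IQR); ``'auto'`` picks by a Shapiro-Wilk normality check on both
    groups (p > 0.05 in each).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "auto":
        normal = all(
            x.std() == 0 or sstats.shapiro(x[:500]).pvalue > 0.05 for x in (a, b)
        )
        method = "t" if normal else "ranksum"
    if method == "t":
        res = sstats.ttest_ind(a, b)
        pvalue = 1.0 if np.isnan(res.pvalue) and a.mean() == b.mean() else float(res.pvalue)
        return GroupComparison("t", float(res.statistic), pvalue, _summary(a), _summary(b))
    if method == "ranksum":
        res = sstats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(
            "mannwhitneyu", float(res.statistic), float(res.pvalue), _summary(a), _summary(b)
        )
    raise ValueError(f"unknown method {method!r}")


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> GroupComparison:
    """Chi-square comparison of two proportions (e.g. TSH < 0.1 fractions)."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    chi2, p, _, _ = sstats.chi2_contingency(table)
    return GroupComparison(
        "chi2",
        float(chi2),
        float(p),
        {"k": k1, "n": n1, "proportion": k1 / n1},
        {"k": k2, "n": n2, "proportion": k2 / n2},
    )
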