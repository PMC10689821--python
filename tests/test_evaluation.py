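"""Modified LOOCV exclusion, confusion/metrics, sweep, group statistics."""

import datetime

import numpy as np
import pytest

from conftest import make_night
from thyrowatch.dataset import build_dataset
from thyrowatch.evaluation import (
    ConfusionMatrix,
    TargetPrediction,
    compare_groups,
    compare_proportions,
    confusion,
    loocv_predict,
    metrics,
    window_sweep,
)
from thyrowatch.hr_windows import CoverageRule
from thyrowatch.model import ModelConfig
from thyrowatch.thyroid import TFTResult, ThyroidState

D = datetime.date
TD = datetime.timedelta

TINY_MODEL = ModelConfig(n_estimators=15, min_child_samples=2)


def _two_patient_dataset():
    """Two patients x three observed pairs each, full HR coverage."""
    specs = {
        "a": [(D(2023, 3, 1), 2.5, 0.03), (D(2023, 4, 1), 1.9, 0.05), (D(2023, 5, 1), 1.3, 0.8)],
        "b": [(D(2023, 3, 5), 1.2, 1.5), (D(2023, 4, 5), 2.2, 0.04), (D(2023, 5, 5), 1.1, 2.0)],
    }
    tfts, nights = [], []
    for pid, visits in specs.items():
        dates = [v[0] for v in visits]
        day = min(dates) - TD(days=12)
        i = 0
        while day <= max(dates):
            nights.append(make_night(pid, day, 62, n=40, seed=i))
            day += TD(days=1)
            i += 1
        tfts.extend(TFTResult(pid, d, ft4, tsh) for d, ft4, tsh in visits)
    return build_dataset(tfts, nights, coverage=CoverageRule(min_nights=3, min_samples=60))


class TestLoocvExclusion:
    def test_worked_example_training_set_for_target_ta2(self):
        """Testing patient a's second pair must exclude the four cases that
        involve it and retain a's remaining ordered pair plus all six of
        patient b's within-patient cases."""
        ds = _two_patient_dataset()
        result = loocv_predict(ds, model_config=TINY_MODEL, collect_train_cases=True)
        ta = [p.key for p in ds.pairs if p.patient_id == "a"]
        ta1, ta2, ta3 = ta
        fold = next(f for f in result.folds if f.target_key == ta2)
        train = set(fold.train_cases)
        assert all(ta2 not in case for case in train)
        assert (ta1, ta3) in train and (ta3, ta1) in train
        b_cases = {c for c in train if c[0][0] == "b"}
        assert len(b_cases) == 6
        assert len(train) == 8
        assert fold.n_excluded == 4

    def test_every_fold_is_leakage_free(self):
        ds = _two_patient_dataset()
        result = loocv_predict(ds, model_config=TINY_MODEL, collect_train_cases=True)
        assert result.n_leaky_folds() == 0
        for f in result.folds:
            assert all(f.target_key not in case for case in f.train_cases)

    def test_averaged_probability_is_mean_of_referred_probabilities(self):
        ds = _two_patient_dataset()
        result = loocv_predict(ds, model_config=TINY_MODEL)
        assert len(result.predictions) == 6
        for p in result.predictions:
            assert p.averaged_probability == pytest.approx(
                np.mean(list(p.referred_probabilities.values()))
            )
            assert len(p.referred_probabilities) == 2

    def test_single_pair_patient_skipped_with_warning(self, caplog):
        ds = _two_patient_dataset()
        lone = TFTResult("c", D(2023, 4, 1), 1.2, 1.5)
        nights = [make_night("c", D(2023, 3, 20) + TD(days=i), 60, n=40, seed=i) for i in range(12)]
        ds2 = build_dataset(
            ds.tfts + [lone], ds.nights + nights,
            coverage=CoverageRule(min_nights=3, min_samples=60),
        )
        with caplog.at_level("WARNING"):
            result = loocv_predict(ds2, model_config=TINY_MODEL)
        assert ("c", "2023-04-01", "observed") in result.skipped
        assert len(result.predictions) == 6


class TestConfusionAndMetrics:
    def _pred(self, decision, label, state=ThyroidState.EUTHYROID):
        return TargetPrediction(
            patient_id="x", target=None, referred_probabilities={},
            averaged_probability=float(decision), decision=decision,
            true_label=label, true_state=state,
        )

    def test_all_correct_predictions_have_no_errors(self):
        preds = [self._pred(True, True), self._pred(False, False)]
        cm = confusion(preds)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 0, 0, 1)

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(0)
        preds = [
            self._pred(bool(rng.random() < 0.5), bool(rng.random() < 0.3))
            for _ in range(137)
        ]
        assert confusion(preds).total == 137

    def test_subclinical_exclusion_never_touches_tp_or_fn(self):
        rng = np.random.default_rng(1)
        preds = []
        for _ in range(200):
            label = bool(rng.random() < 0.2)
            state = (
                ThyroidState.OVERT_THYROTOXICOSIS
                if label
                else rng.choice(
                    [ThyroidState.SUBCLINICAL_THYROTOXICOSIS, ThyroidState.EUTHYROID]
                )
            )
            preds.append(self._pred(bool(rng.random() < 0.5), label, state))
        full = confusion(preds, exclude_subclinical=False)
        excl = confusion(preds, exclude_subclinical=True)
        assert (full.tp, full.fn) == (excl.tp, excl.fn)
        assert excl.total <= full.total

    def test_metrics_against_brute_force_recount(self):
        rng = np.random.default_rng(2)
        preds = [
            self._pred(bool(rng.random() < 0.4), bool(rng.random() < 0.4))
            for _ in range(500)
        ]
        cm = confusion(preds)
        rep = metrics(cm)
        tp = sum(p.decision and p.true_label for p in preds)
        fn = sum(not p.decision and p.true_label for p in preds)
        fp = sum(p.decision and not p.true_label for p in preds)
        tn = sum(not p.decision and not p.true_label for p in preds)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (tp, fn, fp, tn)
        assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert rep.npv == pytest.approx(100 * tn / (tn + fn))

    def test_zero_denominator_reported_as_nan_not_zero(self):
        rep = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
        assert np.isnan(rep.sensitivity)
        assert rep.specificity == 100.0
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=0)


class TestWindowSweep:
    def test_single_length_and_mode_consistency(self, sweep_cohort):
        """At N = 10 the fixed-training mode must reproduce the joint run."""
        from thyrowatch.dataset import augment_dataset

        def builder(n_days):
            cov = CoverageRule(min_nights=min(3, n_days), min_samples=80 * min(3, n_days))
            ds = build_dataset(sweep_cohort.tfts, sweep_cohort.nights, n_days=n_days, coverage=cov)
            return augment_dataset(ds, step_days=7)

        mc = ModelConfig(n_estimators=60)
        joint = window_sweep(builder, [10], mode="joint", model_config=mc, seed=1)
        fixed = window_sweep(builder, [10], mode="fixed_train_10", model_config=mc, seed=1)
        assert len(joint) == 1 and len(fixed) == 1
        for col in ("sensitivity", "specificity", "ppv", "npv", "n_targets"):
            assert joint[col].iloc[0] == pytest.approx(fixed[col].iloc[0], nan_ok=True)

    def test_invalid_mode_and_day_range_rejected(self):
        with pytest.raises(ValueError):
            window_sweep(lambda n: None, [10], mode="bogus")
        with pytest.raises(ValueError):
            window_sweep(lambda n: None, [0], mode="joint")


class TestGroupComparisons:
    def test_identical_groups_are_not_distinguishable(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(x, x.copy(), method="t")
        assert res.pvalue == pytest.approx(1.0)

    def test_large_shift_detected_with_high_power(self):
        rng = np.random.default_rng(3)
        res = compare_groups(rng.normal(0, 1, 100), rng.normal(2, 1, 100), method="t")
        assert res.pvalue < 0.001
        assert res.summary_a["mean"] < res.summary_b["mean"]

    def test_skewed_variables_fall_back_to_rank_sum(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(0, 1, 200)
        b = rng.lognormal(1, 1, 200)
        res = compare_groups(a, b, method="auto")
        assert res.test == "mannwhitneyu"
        assert res.pvalue < 0.001

    def test_proportion_gap_flagged_by_chi_square(self):
        res = compare_proportions(82, 100, 33, 100)
        assert res.pvalue < 0.001

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
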