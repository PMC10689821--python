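"""Moments, histograms, Jensen-Shannon divergence, and the feature vector."""

import datetime
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_night
from thyrowatch.features import (
    FEATURE_NAMES,
    HRHistogram,
    InsufficientDataError,
    build_histogram,
    compute_moments,
    featurize,
    js_divergence,
)
from thyrowatch.hr_windows import HRTFTPair, HRWindow, extract_window
from thyrowatch.thyroid import TFTResult

D = datetime.date
LN2 = math.log(2.0)


def brute_force_moments(samples):
    """Independent oracle: direct summation formulas in pure Python."""
    n = len(samples)
    mean = sum(samples) / n
    var = sum((x - mean) ** 2 for x in samples) / n
    sd = math.sqrt(var)
    if sd == 0:
        return mean, 0.0, 0.0, 0.0
    skew = sum(((x - mean) / sd) ** 3 for x in samples) / n
    kurt = sum(((x - mean) / sd) ** 4 for x in samples) / n - 3.0
    return mean, sd / mean, skew, kurt


class TestMoments:
    def test_constant_series_convention(self):
        m = compute_moments([60, 60, 60, 60])
        assert (m.mean, m.rsd, m.skewness, m.kurtosis) == (60.0, 0.0, 0.0, 0.0)

    def test_symmetric_three_point_series(self):
        m = compute_moments([50, 60, 70])
        assert m.mean == 60.0
        assert m.rsd == pytest.approx(math.sqrt(200 / 3) / 60, abs=1e-12)
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_matches_distribution_moments(self):
        rng = np.random.default_rng(2023)
        x = rng.normal(65, 5, size=10_000)
        m = compute_moments(x)
        assert m.mean == pytest.approx(65, abs=0.2)
        assert m.rsd == pytest.approx(5 / 65, abs=0.003)
        assert abs(m.skewness) < 0.1
        assert abs(m.kurtosis) < 0.2

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for n in (2, 3, 10, 257):
            x = rng.uniform(40, 120, size=n).tolist()
            m = compute_moments(x)
            mean, rsd, skew, kurt = brute_force_moments(x)
            assert m.mean == pytest.approx(mean, abs=1e-10)
            assert m.rsd == pytest.approx(rsd, abs=1e-10)
            assert m.skewness == pytest.approx(skew, abs=1e-10)
            assert m.kurtosis == pytest.approx(kurt, abs=1e-10)

    def test_too_few_samples_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_moments([60])


class TestHistogram:
    def test_simple_two_bin_case(self):
        h = build_histogram([60, 60, 61], (60, 62))
        assert np.allclose(h.probabilities, [2 / 3, 1 / 3])
        assert np.array_equal(h.bin_edges, [60, 61, 62])

    def test_degenerate_one_hot(self):
        h = build_histogram([70, 70, 70], (70, 71))
        assert np.allclose(h.probabilities, [1.0])

    def test_uniform_integers_fill_bins_evenly(self):
        rng = np.random.default_rng(11)
        x = rng.integers(60, 70, size=10_000)
        h = build_histogram(x, (60, 70))
        assert h.probabilities.size == 10
        assert np.all(np.abs(h.probabilities - 0.1) < 0.01)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            HRHistogram(bin_edges=np.array([0.0, 1, 2]), probabilities=np.array([0.7, 0.7]))
        with pytest.raises(InsufficientDataError):
            build_histogram([], (60, 62))


class TestJSDivergence:
    def _hist(self, probs):
        edges = np.arange(len(probs) + 1, dtype=float)
        return HRHistogram(bin_edges=edges, probabilities=np.asarray(probs, dtype=float))

    def test_identity_is_zero(self):
        p = self._hist([0.2, 0.3, 0.5])
        assert js_divergence(p, p) == 0.0

    def test_disjoint_supports_reach_ln2(self):
        p = self._hist([1.0, 0.0])
        q = self._hist([0.0, 1.0])
        assert js_divergence(p, q) == pytest.approx(LN2, abs=1e-12)

    def test_hand_computed_value(self):
        # 0.5*KL(p||m) + 0.5*KL(q||m), m = (p+q)/2, natural log
        p = self._hist([0.5, 0.5])
        q = self._hist([0.9, 0.1])
        assert js_divergence(p, q) == pytest.approx(0.1017492250791968, abs=1e-9)

    def test_base_two_rescales_by_ln2(self):
        p = self._hist([0.5, 0.5])
        q = self._hist([0.9, 0.1])
        assert js_divergence(p, q, base="2") == pytest.approx(
            js_divergence(p, q) / LN2, abs=1e-12
        )

    def test_matches_independent_scipy_distance(self):
        from scipy.spatial.distance import jensenshannon

        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.dirichlet(np.ones(15))
            b = rng.dirichlet(np.ones(15))
            expected = jensenshannon(a, b, base=np.e) ** 2
            assert js_divergence(self._hist(a), self._hist(b)) == pytest.approx(
                expected, abs=1e-10
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        k=st.integers(min_value=2, max_value=30),
    )
    def test_symmetry_and_range(self, seed, k):
        rng = np.random.default_rng(seed)
        p = self._hist(rng.dirichlet(np.ones(k)))
        q = self._hist(rng.dirichlet(np.ones(k)))
        d_pq = js_divergence(p, q)
        d_qp = js_divergence(q, p)
        assert d_pq == pytest.approx(d_qp, abs=1e-12)
        assert 0.0 <= d_pq <= LN2

    def test_mismatched_bins_rejected(self):
        p = self._hist([0.5, 0.5])
        q = HRHistogram(bin_edges=np.array([5.0, 6, 7]), probabilities=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            js_divergence(p, q)


def _pair(pid, anchor, nights, ft4=1.2, tsh=1.0):
    window = extract_window(nights, anchor, n_days=10, patient_id=pid)
    return HRTFTPair(
        tft=TFTResult(pid, anchor, ft4, tsh), window=window, origin="observed"
    )


def _nights(pid, start, days, mean, seed=0, n=150):
    return [
        make_night(pid, start + datetime.timedelta(days=i), mean, n=n, seed=seed + i)
        for i in range(days)
    ]


class TestFeaturize:
    def test_identical_windows_give_zero_changes(self):
        nights = _nights("p1", D(2023, 3, 1), 10, 62)
        ref = _pair("p1", D(2023, 3, 11), nights, tsh=1.0)
        fv = featurize(ref, ref.window)
        assert fv.d_mean == 0 and fv.d_rsd == 0 and fv.d_skew == 0 and fv.d_kurt == 0
        assert fv.js_div == 0 and fv.d_mean_over_tsh == 0
        assert fv.ft4_ref == 1.2 and fv.tsh_ref == 1.0

    def test_mean_shift_and_quotient_arithmetic(self):
        ref_w = HRWindow("p1", D(2023, 3, 11), 10, tuple(_nights("p1", D(2023, 3, 1), 5, 65)))
        ref = HRTFTPair(TFTResult("p1", D(2023, 3, 11), 1.2, 1.0), ref_w)
        tgt_nights = [
            make_night("p1", D(2023, 4, 1) + datetime.timedelta(days=i), 65, n=150, seed=i)
            for i in range(5)
        ]
        shifted = [
            type(n)(n.patient_id, n.date, tuple(s + 11 for s in n.samples))
            for n in tgt_nights
        ]
        tgt_w = HRWindow("p1", D(2023, 4, 11), 10, tuple(shifted))
        fv = featurize(ref, tgt_w)
        assert fv.d_mean == pytest.approx(11.0, abs=1e-9)
        assert fv.d_mean_over_tsh == pytest.approx(11.0, abs=1e-9)
        # shifting preserves shape: dispersion change only through the mean
        assert fv.js_div > 0

    def test_antisymmetry_of_moment_changes_and_symmetric_jsd(self):
        n_a = _nights("p1", D(2023, 3, 1), 8, 62, seed=1)
        n_b = _nights("p1", D(2023, 4, 1), 8, 71, seed=50)
        a = _pair("p1", D(2023, 3, 11), n_a, tsh=0.8)
        b = _pair("p1", D(2023, 4, 11), n_b, tsh=0.8)
        fab = featurize(a, b.window)
        fba = featurize(b, a.window)
        for name in ("d_mean", "d_rsd", "d_skew", "d_kurt"):
            assert getattr(fab, name) == pytest.approx(-getattr(fba, name), abs=1e-10)
        assert fab.js_div == pytest.approx(fba.js_div, abs=1e-12)

    def test_suppressed_tsh_is_floored_in_quotient(self):
        nights = _nights("p1", D(2023, 3, 1), 10, 62)
        ref = _pair("p1", D(2023, 3, 11), nights, tsh=0.001)
        tgt = _pair("p1", D(2023, 3, 12), nights, tsh=1.0)
        fv = featurize(ref, tgt.window)
        assert fv.d_mean_over_tsh == pytest.approx(fv.d_mean / 0.025, abs=1e-9)

    def test_feature_vector_ordering_matches_names(self):
        nights = _nights("p1", D(2023, 3, 1), 10, 62)
        ref = _pair("p1", D(2023, 3, 11), nights)
        fv = featurize(ref, ref.window)
        arr = fv.as_array()
        assert arr.shape == (len(FEATURE_NAMES),)
        assert arr[0] == fv.ft4_ref and arr[6] == fv.js_div

    def test_unusable_window_raises(self):
        nights = _nights("p1", D(2023, 3, 1), 10, 62)
        ref = _pair("p1", D(2023, 3, 11), nights)
        empty = HRWindow("p1", D(2023, 5, 1), 10, ())
        with pytest.raises(InsufficientDataError):
            featurize(ref, empty)


def test_cached_stats_path_equals_direct_featurization():
    """The dataset module's cached per-pair statistics must reproduce the
    reference featurization exactly (global-grid JSD == union-range JSD)."""
    from thyrowatch.dataset import _PairStats, feature_vector_from_stats

    rng = np.random.default_rng(99)
    for trial in range(10):
        mean_a, mean_b = rng.uniform(55, 75, size=2)
        n_a = _nights("p1", D(2023, 3, 1), 6, mean_a, seed=trial * 31)
        n_b = _nights("p1", D(2023, 4, 1), 6, mean_b, seed=trial * 31 + 7)
        a = _pair("p1", D(2023, 3, 11), n_a, ft4=float(rng.uniform(0.8, 3)), tsh=float(rng.uniform(0.01, 5)))
        b = _pair("p1", D(2023, 4, 11), n_b)
        direct = featurize(a, b.window)
        cached = feature_vector_from_stats(a, _PairStats(a), _PairStats(b))
        assert np.allclose(direct.as_array(), cached.as_array(), atol=1e-12)
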