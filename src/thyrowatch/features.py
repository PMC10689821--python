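"""Feature extraction for (referred pair -> target window) combinations.

The classifier input is an 8-dimensional vector describing how a patient's
sleep heart-rate distribution changed between the date of a known blood
test (the *referred* TFT) and a *target* date, together with the referred
blood values themselves:

======================  =====================================================
``ft4_ref``             referred serum free T4, ng/dL
``tsh_ref``             referred serum TSH, mIU/L
``d_mean``              change in mean sleep HR, bpm (target - referred)
``d_rsd``               change in relative standard deviation (SD/mean)
``d_skew``              change in skewness
``d_kurt``              change in excess kurtosis
``js_div``              Jensen-Shannon divergence of the two HR histograms
``d_mean_over_tsh``     ``d_mean`` divided by the referred TSH (floored)
======================  =====================================================

Moments are the biased (population) estimators; skewness and kurtosis of a
zero-variance series are defined as 0 so constant-HR windows stay usable.
Histograms use 1-bpm bins (device resolution) and the divergence is
computed in nats, hence bounded by ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .hr_windows import HRTFTPair, HRWindow

__all__ = [
    "FEATURE_NAMES",
    "InsufficientDataError",
    "HRMoments",
    "HRHistogram",
    "FeatureVector",
    "compute_moments",
    "build_histogram",
    "js_divergence",
    "featurize",
    "DEFAULT_TSH_FLOOR",
]

FEATURE_NAMES: tuple[str, ...] = (
    "ft4_ref",
    "tsh_ref",
    "d_mean",
    "d_rsd",
    "d_skew",
    "d_kurt",
    "js_div",
    "d_mean_over_tsh",
)

#: Referred-TSH floor for the quotient feature, mIU/L.  Matches the assay
#: reporting floor; prevents division blow-up in fully suppressed TSH.
DEFAULT_TSH_FLOOR = 0.025


class InsufficientDataError(ValueError):
    """Raised when a window holds too few samples for a statistic."""


@dataclass(frozen=True)
class HRMoments:
    """Distribution moments of a sleep-HR sample pool."""

    mean: float
    rsd: float
    skewness: float
    kurtosis: float  # excess


@dataclass(frozen=True)
class HRHistogram:
    """Relative-frequency histogram over integer-spaced 1-bpm bins."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class FeatureVector:
    ft4_ref: float
    tsh_ref: float
    d_mean: float
    d_rsd: float
    d_skew: float
    d_kurt: float
    js_div: float
    d_mean_over_tsh: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature vector contains non-finite values")

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in FEATURE_NAMES], dtype=float
        )


def compute_moments(samples) -> HRMoments:
    """Biased (population) mean, RSD, skewness, and excess kurtosis.

    Requires at least two samples.  For a zero-variance series the
    standardized moments are undefined; they are set to 0 by convention.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 samples for moments, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        return HRMoments(mean=mean, rsd=0.0, skewness=0.0, kurtosis=0.0)
    z = (x - mean) / sd
    return HRMoments(
        mean=mean,
        rsd=sd / mean,
        skewness=float(np.mean(z**3)),
        kurtosis=float(np.mean(z**4) - 3.0),
    )


def build_histogram(samples, shared_range: tuple[float, float]) -> HRHistogram:
    """Bin samples into 1-bpm-wide bins covering ``shared_range``.

    Edges are the integers from ``floor(low)`` to ``ceil(high)``; bins are
    half-open ``[edge, edge + 1)`` with the final bin closed (numpy
    convention).  Two windows compared by JS divergence must be binned
    over the same shared range so their edges coincide.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("cannot build a histogram from zero samples")
    lo = math.floor(shared_range[0])
    hi = math.ceil(shared_range[1])
    if hi <= lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1, dtype=float)
    counts, _ = np.histogram(x, bins=edges)
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError("no samples fall inside the shared range")
    return HRHistogram(bin_edges=edges, probabilities=counts / total)


def _jsd_probs(p: np.ndarray, q: np.ndarray, base: str = "e") -> float:
    m = 0.5 * (p + q)
    jsd = 0.5 * float(rel_entr(p, m).sum()) + 0.5 * float(rel_entr(q, m).sum())
    # guard tiny negative round-off and the ln 2 ceiling
    jsd = min(max(jsd, 0.0), math.log(2.0))
    if base == "2":
        jsd /= math.log(2.0)
    elif base != "e":
        raise ValueError(f"unknown JSD base {base!r} (use 'e' or '2')")
    return jsd


def js_divergence(p: HRHistogram, q: HRHistogram, base: str = "e") -> float:
    """Jensen-Shannon divergence between two aligned histograms.

    ``JSD(p, q) = 1/2 KL(p || m) + 1/2 KL(q || m)`` with ``m = (p + q)/2``,
    using the ``0 * log 0 = 0`` convention.  In nats (default) the result
    lies in ``[0, ln 2]``; with ``base='2'`` it lies in ``[0, 1]``.
    """
    if p.bin_edges.shape != q.bin_edges.shape or not np.array_equal(
        p.bin_edges, q.bin_edges
    ):
        raise ValueError("JS divergence requires identical bin edges")
    return _jsd_probs(
        np.asarray(p.probabilities, dtype=float),
        np.asarray(q.probabilities, dtype=float),
        base=base,
    )


def featurize(
    referred: HRTFTPair,
    target_window: HRWindow,
    tsh_floor: float = DEFAULT_TSH_FLOOR,
    jsd_base: str = "e",
) -> FeatureVector:
    """Build the 8-feature vector for a referred pair and a target window.

    Each ``d_*`` feature is target minus referred; the histograms for the
    divergence share 1-bpm bins over the union range of the two windows.
    The quotient feature divides ``d_mean`` by ``max(tsh_ref, tsh_floor)``.
    """
    ref_samples = referred.window.pooled_samples
    tgt_samples = target_window.pooled_samples
    if ref_samples.size < 2 or tgt_samples.size < 2:
        raise InsufficientDataError("both windows need >= 2 pooled samples")
    ref_m = compute_moments(ref_samples)
    tgt_m = compute_moments(tgt_samples)
    lo = min(ref_samples.min(), tgt_samples.min())
    # top edge extended past the maximum so an integer-valued maximum
    # occupies its own 1-bpm bin instead of the closed final bin
    hi = max(ref_samples.max(), tgt_samples.max()) + 1.0
    shared = (float(lo), float(hi))
    jsd = js_divergence(
        build_histogram(ref_samples, shared),
        build_histogram(tgt_samples, shared),
        base=jsd_base,
    )
    d_mean = tgt_m.mean - ref_m.mean
    tsh_ref = referred.tft.tsh
    return FeatureVector(
        ft4_ref=referred.tft.free_t4,
        tsh_ref=tsh_ref,
        d_mean=d_mean,
        d_rsd=tgt_m.rsd - ref_m.rsd,
        d_skew=tgt_m.skewness - ref_m.skewness,
        d_kurt=tgt_m.kurtosis - ref_m.kurtosis,
        js_div=jsd,
        d_mean_over_tsh=d_mean / max(tsh_ref, tsh_floor),
    )
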