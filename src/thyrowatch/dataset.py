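"""Case construction and interpolation-based training augmentation.

A *case* joins two HR-TFT pairs of the same patient: the earlier-known
*referred* pair supplies its blood values and HR window, the *target*
pair supplies the HR window whose date is being predicted, and the label
is whether the target free T4 exceeds the thyrotoxicosis threshold.  All
ordered within-patient combinations are enumerated (both directions), so
a patient with k usable pairs contributes k(k-1) cases; combinations never
cross patients.

Training data are augmented with synthetic HR-TFT pairs: free T4 and TSH
linearly interpolated in time between adjacent observed TFTs on a weekly
grid strictly inside each gap, wrapped with the *actual* sleep-HR window
of the interpolated date.  Interpolated pairs join training as referred
and as target, but are flagged so evaluation never tests them.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .features import (
    DEFAULT_TSH_FLOOR,
    FEATURE_NAMES,
    FeatureVector,
    _jsd_probs,
    compute_moments,
)
from .hr_windows import (
    HR_VALID_BPM,
    CoverageRule,
    HRTFTPair,
    SleepNight,
    extract_window,
)
from .thyroid import DEFAULT_RANGES, ReferenceRanges, TFTResult, is_thyrotoxic

__all__ = [
    "CaseRecord",
    "Dataset",
    "iter_case_index",
    "enumerate_cases",
    "interpolate_tft",
    "interpolate_pairs",
    "build_dataset",
    "augment_dataset",
    "write_dataset_csv",
    "read_cases_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaseRecord:
    """One ordered (referred pair -> target pair) training/evaluation case."""

    referred: HRTFTPair
    target: HRTFTPair
    features: FeatureVector
    label: bool

    def __post_init__(self) -> None:
        if self.referred.patient_id != self.target.patient_id:
            raise ValueError("a case must combine pairs of a single patient")
        if self.referred.key == self.target.key:
            raise ValueError("referred and target pairs must differ")

    @property
    def patient_id(self) -> str:
        return self.referred.patient_id


class _PairStats:
    """Per-pair moments and a shared-grid histogram, computed once.

    Histogram counts are held on the global 1-bpm grid spanning the valid
    HR range; restricting a JS divergence to the union range of two
    windows is equivalent to evaluating it on the global grid, because
    bins empty in both histograms contribute nothing.
    """

    _edges = np.arange(int(HR_VALID_BPM[0]), int(HR_VALID_BPM[1]) + 1, dtype=float)

    def __init__(self, pair: HRTFTPair):
        samples = pair.window.pooled_samples
        self.moments = compute_moments(samples)
        counts, _ = np.histogram(samples, bins=self._edges)
        self.probs = counts / counts.sum()


def feature_vector_from_stats(
    referred: HRTFTPair,
    ref_stats: _PairStats,
    tgt_stats: _PairStats,
    tsh_floor: float = DEFAULT_TSH_FLOOR,
    jsd_base: str = "e",
) -> FeatureVector:
    """Assemble a feature vector from cached per-pair statistics."""
    d_mean = tgt_stats.moments.mean - ref_stats.moments.mean
    tsh_ref = referred.tft.tsh
    return FeatureVector(
        ft4_ref=referred.tft.free_t4,
        tsh_ref=tsh_ref,
        d_mean=d_mean,
        d_rsd=tgt_stats.moments.rsd - ref_stats.moments.rsd,
        d_skew=tgt_stats.moments.skewness - ref_stats.moments.skewness,
        d_kurt=tgt_stats.moments.kurtosis - ref_stats.moments.kurtosis,
        js_div=_jsd_probs(ref_stats.probs, tgt_stats.probs, base=jsd_base),
        d_mean_over_tsh=d_mean / max(tsh_ref, tsh_floor),
    )


def iter_case_index(
    pairs: Sequence[HRTFTPair], include_interpolated: bool
) -> Iterator[tuple[int, int]]:
    """Yield index pairs (referred, target) of all ordered within-patient cases.

    This is the single source of truth for case combinatorics; feature
    computation is layered on top.  With ``include_interpolated=False``
    only observed-observed combinations are produced.
    """
    by_patient: dict[str, list[int]] = {}
    for i, p in enumerate(pairs):
        if include_interpolated or p.origin == "observed":
            by_patient.setdefault(p.patient_id, []).append(i)
    for pid in sorted(by_patient):
        idx = by_patient[pid]
        for i in idx:
            for j in idx:
                if i != j:
                    yield i, j


def enumerate_cases(
    pairs: Sequence[HRTFTPair],
    include_interpolated: bool = False,
    ranges: ReferenceRanges = DEFAULT_RANGES,
    tsh_floor: float = DEFAULT_TSH_FLOOR,
    jsd_base: str = "e",
) -> list[CaseRecord]:
    """Build all ordered within-patient cases with their feature vectors.

    The label derives only from the target pair's free T4.
    """
    stats = [_PairStats(p) for p in pairs]
    cases: list[CaseRecord] = []
    for i, j in iter_case_index(pairs, include_interpolated):
        fv = feature_vector_from_stats(
            pairs[i], stats[i], stats[j], tsh_floor=tsh_floor, jsd_base=jsd_base
        )
        cases.append(
            CaseRecord(
                referred=pairs[i],
                target=pairs[j],
                features=fv,
                label=is_thyrotoxic(pairs[j].tft.free_t4, ranges),
            )
        )
    return cases


def interpolate_tft(
    tft_a: TFTResult,
    tft_b: TFTResult,
    on_date: datetime.date,
    log_tsh: bool = False,
) -> TFTResult:
    """Linearly interpolate free T4 and TSH between two TFTs at a date.

    Interpolation is linear in the raw concentrations by default; with
    ``log_tsh`` the TSH track is interpolated on a log scale instead,
    since TSH spans orders of magnitude.
    """
    if tft_a.patient_id != tft_b.patient_id:
        raise ValueError("cannot interpolate between different patients")
    if not tft_a.test_date < tft_b.test_date:
        raise ValueError("tft_a must precede tft_b")
    span = (tft_b.test_date - tft_a.test_date).days
    frac = (on_date - tft_a.test_date).days / span
    ft4 = tft_a.free_t4 + frac * (tft_b.free_t4 - tft_a.free_t4)
    if log_tsh:
        tsh = float(np.exp(np.log(tft_a.tsh) + frac * (np.log(tft_b.tsh) - np.log(tft_a.tsh))))
    else:
        tsh = tft_a.tsh + frac * (tft_b.tsh - tft_a.tsh)
    return TFTResult(
        patient_id=tft_a.patient_id, test_date=on_date, free_t4=ft4, tsh=tsh
    )


def interpolate_pairs(
    tft_a: TFTResult,
    tft_b: TFTResult,
    nights: Sequence[SleepNight],
    step_days: int = 7,
    n_days: int = 10,
    coverage: CoverageRule = CoverageRule(),
    include_anchor_morning: bool = False,
    log_tsh: bool = False,
) -> list[HRTFTPair]:
    """Synthetic pairs on a grid strictly between two adjacent TFTs.

    Grid dates are ``a + step, a + 2*step, ...`` strictly before ``b``;
    each interpolated TFT is wrapped with the actual HR window preceding
    its date, and pairs failing window coverage are dropped.
    """
    if step_days < 1:
        raise ValueError("step_days must be >= 1")
    out: list[HRTFTPair] = []
    d = tft_a.test_date + datetime.timedelta(days=step_days)
    while d < tft_b.test_date:
        tft = interpolate_tft(tft_a, tft_b, d, log_tsh=log_tsh)
        window = extract_window(
            nights,
            d,
            n_days=n_days,
            include_anchor_morning=include_anchor_morning,
            patient_id=tft_a.patient_id,
        )
        if coverage.reason_unusable(window) is None:
            out.append(HRTFTPair(tft=tft, window=window, origin="interpolated"))
        d += datetime.timedelta(days=step_days)
    return out


@dataclass
class Dataset:
    """Pairs, cases, and the raw material needed to rebuild or augment them."""

    pairs: list[HRTFTPair]
    cases: list[CaseRecord]
    tfts: list[TFTResult]
    nights: list[SleepNight]
    n_days: int = 10
    coverage: CoverageRule = field(default_factory=CoverageRule)
    include_anchor_morning: bool = False
    ranges: ReferenceRanges = field(default_factory=ReferenceRanges)
    tsh_floor: float = DEFAULT_TSH_FLOOR
    jsd_base: str = "e"
    rejected: list = field(default_factory=list)

    @property
    def observed_pairs(self) -> list[HRTFTPair]:
        return [p for p in self.pairs if p.origin == "observed"]

    def pair_index(self) -> dict[tuple, int]:
        return {p.key: i for i, p in enumerate(self.pairs)}

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Feature matrix, labels, and referred/target pair indices per case."""
        index = self.pair_index()
        X = np.array([c.features.as_array() for c in self.cases], dtype=float)
        y = np.array([c.label for c in self.cases], dtype=int)
        ref_idx = np.array([index[c.referred.key] for c in self.cases], dtype=int)
        tgt_idx = np.array([index[c.target.key] for c in self.cases], dtype=int)
        return X, y, ref_idx, tgt_idx


def build_dataset(
    tfts: Sequence[TFTResult],
    nights: Sequence[SleepNight],
    n_days: int = 10,
    coverage: CoverageRule = CoverageRule(),
    include_anchor_morning: bool = False,
    ranges: ReferenceRanges = DEFAULT_RANGES,
    tsh_floor: float = DEFAULT_TSH_FLOOR,
    jsd_base: str = "e",
) -> Dataset:
    """Build the observed-only dataset: usable pairs plus all ordered cases."""
    from .hr_windows import build_pairs

    usable, rejected = build_pairs(
        tfts,
        nights,
        n_days=n_days,
        coverage=coverage,
        include_anchor_morning=include_anchor_morning,
    )
    cases = enumerate_cases(
        usable, include_interpolated=False, ranges=ranges, tsh_floor=tsh_floor, jsd_base=jsd_base
    )
    return Dataset(
        pairs=list(usable),
        cases=cases,
        tfts=list(tfts),
        nights=list(nights),
        n_days=n_days,
        coverage=coverage,
        include_anchor_morning=include_anchor_morning,
        ranges=ranges,
        tsh_floor=tsh_floor,
        jsd_base=jsd_base,
        rejected=rejected,
    )


def augment_dataset(
    dataset: Dataset, step_days: int = 7, log_tsh: bool = False
) -> Dataset:
    """Append interpolated pairs and re-enumerate cases with them included.

    Adjacency is taken over each patient's observed TFTs sorted by date;
    the observed case set is a subset of the augmented case set.
    """
    nights_by_patient: dict[str, list[SleepNight]] = {}
    for n in dataset.nights:
        nights_by_patient.setdefault(n.patient_id, []).append(n)
    tfts_by_patient: dict[str, list[TFTResult]] = {}
    for t in dataset.tfts:
        tfts_by_patient.setdefault(t.patient_id, []).append(t)

    interpolated: list[HRTFTPair] = []
    for pid in sorted(tfts_by_patient):
        patient_tfts = sorted(tfts_by_patient[pid], key=lambda t: t.test_date)
        for a, b in zip(patient_tfts, patient_tfts[1:]):
            interpolated.extend(
                interpolate_pairs(
                    a,
                    b,
                    nights_by_patient.get(pid, []),
                    step_days=step_days,
                    n_days=dataset.n_days,
                    coverage=dataset.coverage,
                    include_anchor_morning=dataset.include_anchor_morning,
                    log_tsh=log_tsh,
                )
            )
    all_pairs = list(dataset.pairs) + interpolated
    cases = enumerate_cases(
        all_pairs,
        include_interpolated=True,
        ranges=dataset.ranges,
        tsh_floor=dataset.tsh_floor,
        jsd_base=dataset.jsd_base,
    )
    logger.info(
        "augmentation: %d observed + %d interpolated pairs -> %d cases",
        len(dataset.pairs),
        len(interpolated),
        len(cases),
    )
    return replace(dataset, pairs=all_pairs, cases=cases)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def cases_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for c in dataset.cases:
        row = {
            "patient_id": c.patient_id,
            "referred_date": c.referred.tft.test_date.isoformat(),
            "referred_origin": c.referred.origin,
            "target_date": c.target.tft.test_date.isoformat(),
            "target_origin": c.target.origin,
        }
        row.update(dict(zip(FEATURE_NAMES, c.features.as_array())))
        row["label"] = int(c.label)
        rows.append(row)
    return pd.DataFrame(rows)


def pairs_frame(dataset: Dataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in dataset.pairs],
            "test_date": [p.tft.test_date.isoformat() for p in dataset.pairs],
            "origin": [p.origin for p in dataset.pairs],
            "free_t4": [p.tft.free_t4 for p in dataset.pairs],
            "tsh": [p.tft.tsh for p in dataset.pairs],
            "n_nights": [p.window.n_nights for p in dataset.pairs],
            "n_samples": [p.window.n_samples for p in dataset.pairs],
        }
    )


def write_dataset_csv(
    dataset: Dataset, outdir: str | Path, header_comment: str | None = None
) -> tuple[Path, Path]:
    """Write cases.csv and pairs.csv; numeric round-trip is exact to 1e-9."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases_path = outdir / "cases.csv"
    pairs_path = outdir / "pairs.csv"
    for frame, path in ((cases_frame(dataset), cases_path), (pairs_frame(dataset), pairs_path)):
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            frame.to_csv(fh, index=False, float_format="%.12g")
    return cases_path, pairs_path


def read_cases_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"patient_id": str})
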