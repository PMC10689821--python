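"""Thyroid function test results and thyroid-state labeling.

A thyroid function test (TFT) measures serum free thyroxine (free T4,
ng/dL) and thyroid-stimulating hormone (TSH, mIU/L).  The pair of values
maps onto one of five thyroid function states relative to a laboratory
reference range; the binary label used throughout the classifier is
*overt thyrotoxicosis*: free T4 strictly above the upper reference limit.

Boundary convention: the reference intervals are closed
(``[ft4_low, ft4_high]`` and ``[tsh_low, tsh_high]``); the overt states
require a strict inequality outside them.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "ThyroidState",
    "ReferenceRanges",
    "TFTResult",
    "DEFAULT_RANGES",
    "classify_state",
    "is_thyrotoxic",
    "read_tft_csv",
    "write_tft_csv",
]


class ThyroidState(str, enum.Enum):
    """Five-way thyroid function state derived from a single TFT."""

    OVERT_THYROTOXICOSIS = "overt_thyrotoxicosis"
    SUBCLINICAL_THYROTOXICOSIS = "subclinical_thyrotoxicosis"
    EUTHYROID = "euthyroid"
    SUBCLINICAL_HYPOTHYROIDISM = "subclinical_hypothyroidism"
    OVERT_HYPOTHYROIDISM = "overt_hypothyroidism"


@dataclass(frozen=True)
class ReferenceRanges:
    """Assay reference intervals for free T4 (ng/dL) and TSH (mIU/L).

    Defaults are the immunoassay intervals used by the source cohort
    (free T4 0.89-1.78 ng/dL, TSH 0.3-4.0 mIU/L); other laboratories use
    different intervals, hence configurability.
    """

    ft4_low: float = 0.89
    ft4_high: float = 1.78
    tsh_low: float = 0.3
    tsh_high: float = 4.0

    def __post_init__(self) -> None:
        if not self.ft4_low < self.ft4_high:
            raise ValueError("ft4_low must be < ft4_high")
        if not self.tsh_low < self.tsh_high:
            raise ValueError("tsh_low must be < tsh_high")


DEFAULT_RANGES = ReferenceRanges()


def _validate(ft4: float, tsh: float) -> None:
    if not ft4 > 0:
        raise ValueError(f"free T4 must be positive, got {ft4!r}")
    if tsh < 0:
        raise ValueError(f"TSH must be non-negative, got {tsh!r}")


@dataclass(frozen=True)
class TFTResult:
    """One blood draw: free T4 and TSH for a patient on a calendar date."""

    patient_id: str
    test_date: datetime.date
    free_t4: float
    tsh: float

    def __post_init__(self) -> None:
        _validate(self.free_t4, self.tsh)
        if not isinstance(self.test_date, datetime.date):
            raise TypeError("test_date must be a datetime.date")

    def state(self, ranges: ReferenceRanges = DEFAULT_RANGES) -> ThyroidState:
        return classify_state(self.free_t4, self.tsh, ranges)


def classify_state(
    ft4: float, tsh: float, ranges: ReferenceRanges = DEFAULT_RANGES
) -> ThyroidState:
    """Map a (free T4, TSH) pair to its thyroid function state.

    Free T4 dominates: values outside its reference range define the overt
    states regardless of TSH; with normal free T4, TSH below / within /
    above its range distinguishes subclinical thyrotoxicosis, euthyroid,
    and subclinical hypothyroidism.
    """
    _validate(ft4, tsh)
    if ft4 > ranges.ft4_high:
        return ThyroidState.OVERT_THYROTOXICOSIS
    if ft4 < ranges.ft4_low:
        return ThyroidState.OVERT_HYPOTHYROIDISM
    if tsh < ranges.tsh_low:
        return ThyroidState.SUBCLINICAL_THYROTOXICOSIS
    if tsh > ranges.tsh_high:
        return ThyroidState.SUBCLINICAL_HYPOTHYROIDISM
    return ThyroidState.EUTHYROID


def is_thyrotoxic(ft4: float, ranges: ReferenceRanges = DEFAULT_RANGES) -> bool:
    """Binary label used for training and evaluation: free T4 > upper limit."""
    if not ft4 > 0:
        raise ValueError(f"free T4 must be positive, got {ft4!r}")
    return ft4 > ranges.ft4_high


def read_tft_csv(path: str | Path) -> list[TFTResult]:
    """Read TFT results from CSV with header patient_id,test_date,free_t4,tsh."""
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    required = {"patient_id", "test_date", "free_t4", "tsh"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TFT CSV missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                TFTResult(
                    patient_id=str(row.patient_id),
                    test_date=datetime.date.fromisoformat(str(row.test_date)),
                    free_t4=float(row.free_t4),
                    tsh=float(row.tsh),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid TFT record at data row {i}: {exc}") from exc
    return out


def write_tft_csv(tfts: Iterable[TFTResult], path: str | Path, header_comment: str | None = None) -> None:
    tfts = list(tfts)
    df = pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in tfts],
            "test_date": [t.test_date.isoformat() for t in tfts],
            "free_t4": [t.free_t4 for t in tfts],
            "tsh": [t.tsh for t in tfts],
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
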