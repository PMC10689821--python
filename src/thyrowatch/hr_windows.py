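"""Sleep heart-rate sessions, nightly aggregation, and pre-TFT windows.

Wearable devices report sleep sessions (start/end timestamps plus a series
of heart-rate samples).  Each session is filed under the calendar date on
which the sleep *ends*; multiple sessions ending on the same date (e.g. an
overnight sleep plus a nap) are concatenated in chronological order into a
single :class:`SleepNight`.

An :class:`HRWindow` collects the nights in the N days preceding a TFT
date (default N = 10, dates ``[anchor - N, anchor - 1]``).  Missing nights
are simply absent — no imputation.  A window joined to its TFT forms an
:class:`HRTFTPair`; a pair is usable only if the window meets a minimum
coverage rule, because distribution moments and divergences estimated from
a handful of samples are unstable.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .thyroid import TFTResult

__all__ = [
    "HR_VALID_BPM",
    "SleepSession",
    "SleepNight",
    "HRWindow",
    "CoverageRule",
    "HRTFTPair",
    "clean_samples",
    "assign_sessions_to_dates",
    "extract_window",
    "build_pairs",
    "read_sleep_csv",
    "read_sleep_json",
    "write_sleep_csv",
]

logger = logging.getLogger(__name__)

#: Physiologically plausible heart-rate bounds, bpm (exclusive).
HR_VALID_BPM = (20.0, 250.0)


@dataclass(frozen=True)
class SleepSession:
    """One device-detected sleep session with its HR sample series."""

    patient_id: str
    start: datetime.datetime
    end: datetime.datetime
    samples: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"session end {self.end} precedes start {self.start} "
                f"(patient {self.patient_id})"
            )


@dataclass(frozen=True)
class SleepNight:
    """All sleep HR samples of one patient filed under one calendar date."""

    patient_id: str
    date: datetime.date
    samples: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("SleepNight requires at least one sample")


@dataclass(frozen=True)
class HRWindow:
    """Sleep nights inside the N-day span preceding an anchor (TFT) date."""

    patient_id: str
    anchor_date: datetime.date
    n_days: int
    nights: tuple[SleepNight, ...]

    @property
    def pooled_samples(self) -> np.ndarray:
        if not self.nights:
            return np.empty(0, dtype=float)
        return np.concatenate([np.asarray(n.samples, dtype=float) for n in self.nights])

    @property
    def n_nights(self) -> int:
        return len(self.nights)

    @property
    def n_samples(self) -> int:
        return sum(len(n.samples) for n in self.nights)


@dataclass(frozen=True)
class CoverageRule:
    """Minimum window content for a pair to be usable."""

    min_nights: int = 3
    min_samples: int = 300

    def reason_unusable(self, window: HRWindow) -> str | None:
        if window.n_nights < self.min_nights:
            return f"only {window.n_nights} night(s) in window (need {self.min_nights})"
        if window.n_samples < self.min_samples:
            return f"only {window.n_samples} sample(s) in window (need {self.min_samples})"
        return None


@dataclass(frozen=True)
class HRTFTPair:
    """A TFT result joined to the sleep-HR window preceding its date."""

    tft: TFTResult
    window: HRWindow
    origin: str = "observed"  # "observed" | "interpolated"

    def __post_init__(self) -> None:
        if self.origin not in ("observed", "interpolated"):
            raise ValueError(f"unknown pair origin {self.origin!r}")
        if self.window.anchor_date != self.tft.test_date:
            raise ValueError("window anchor must equal the TFT date")
        if self.window.patient_id != self.tft.patient_id:
            raise ValueError("window and TFT belong to different patients")

    @property
    def patient_id(self) -> str:
        return self.tft.patient_id

    @property
    def key(self) -> tuple[str, str, str]:
        """Stable identity of a pair: (patient, ISO date, origin)."""
        return (self.tft.patient_id, self.tft.test_date.isoformat(), self.origin)


def clean_samples(samples: Sequence[float]) -> tuple[tuple[float, ...], int]:
    """Drop HR samples outside the plausible (20, 250) bpm range.

    Returns the kept samples and the count dropped (logged by callers).
    """
    arr = np.asarray(samples, dtype=float)
    lo, hi = HR_VALID_BPM
    keep = (arr > lo) & (arr < hi) & np.isfinite(arr)
    dropped = int((~keep).sum())
    return tuple(arr[keep].tolist()), dropped


def assign_sessions_to_dates(sessions: Iterable[SleepSession]) -> list[SleepNight]:
    """File each session's samples under the date its sleep ends.

    Sessions of the same patient ending on the same date are merged in
    chronological order of their start time.  Out-of-range HR samples are
    dropped (with a logged count); sessions left empty contribute nothing.
    """
    by_key: dict[tuple[str, datetime.date], list[SleepSession]] = {}
    total_dropped = 0
    for s in sessions:
        by_key.setdefault((s.patient_id, s.end.date()), []).append(s)
    nights: list[SleepNight] = []
    for (pid, date), group in sorted(by_key.items()):
        group.sort(key=lambda s: (s.start, s.end))
        merged: list[float] = []
        for s in group:
            kept, dropped = clean_samples(s.samples)
            total_dropped += dropped
            merged.extend(kept)
        if merged:
            nights.append(SleepNight(patient_id=pid, date=date, samples=tuple(merged)))
    if total_dropped:
        logger.info("dropped %d HR sample(s) outside %s bpm", total_dropped, HR_VALID_BPM)
    return nights


def window_span(
    anchor_date: datetime.date, n_days: int, include_anchor_morning: bool = False
) -> tuple[datetime.date, datetime.date]:
    """Inclusive [first, last] night dates of an N-day window.

    Default convention is the N days strictly before the anchor,
    ``[anchor - N, anchor - 1]``.  With ``include_anchor_morning`` the span
    shifts to ``[anchor - N + 1, anchor]``: the sleep ending on the test
    morning still precedes a daytime blood draw.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if include_anchor_morning:
        return anchor_date - datetime.timedelta(days=n_days - 1), anchor_date
    return anchor_date - datetime.timedelta(days=n_days), anchor_date - datetime.timedelta(days=1)


def extract_window(
    nights: Iterable[SleepNight],
    anchor_date: datetime.date,
    n_days: int = 10,
    include_anchor_morning: bool = False,
    patient_id: str | None = None,
) -> HRWindow:
    """Collect the nights falling inside the N-day span before a TFT date.

    Order-independent: nights are sorted by date.  Missing days are
    absent, never imputed; an empty window is representable.
    """
    first, last = window_span(anchor_date, n_days, include_anchor_morning)
    selected = sorted(
        (n for n in nights if first <= n.date <= last), key=lambda n: n.date
    )
    if patient_id is None:
        patient_id = selected[0].patient_id if selected else ""
    for n in selected:
        if n.patient_id != patient_id:
            raise ValueError("extract_window received nights from multiple patients")
    return HRWindow(
        patient_id=patient_id,
        anchor_date=anchor_date,
        n_days=n_days,
        nights=tuple(selected),
    )


def build_pairs(
    tfts: Sequence[TFTResult],
    nights: Sequence[SleepNight],
    n_days: int = 10,
    coverage: CoverageRule = CoverageRule(),
    include_anchor_morning: bool = False,
) -> tuple[list[HRTFTPair], list[tuple[HRTFTPair, str]]]:
    """Join each TFT to its preceding sleep-HR window.

    Returns ``(usable, rejected)`` where rejected pairs carry the coverage
    reason.  A TFT with no HR data at all yields a rejected (empty-window)
    pair, never an exception.
    """
    nights_by_patient: dict[str, list[SleepNight]] = {}
    for n in nights:
        nights_by_patient.setdefault(n.patient_id, []).append(n)
    usable: list[HRTFTPair] = []
    rejected: list[tuple[HRTFTPair, str]] = []
    for tft in tfts:
        window = extract_window(
            nights_by_patient.get(tft.patient_id, []),
            tft.test_date,
            n_days=n_days,
            include_anchor_morning=include_anchor_morning,
            patient_id=tft.patient_id,
        )
        pair = HRTFTPair(tft=tft, window=window, origin="observed")
        reason = coverage.reason_unusable(window)
        if reason is None:
            usable.append(pair)
        else:
            rejected.append((pair, reason))
    if rejected:
        logger.info("%d of %d TFTs failed window coverage", len(rejected), len(tfts))
    return usable, rejected


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sleep_csv(path: str | Path) -> list[SleepNight]:
    """Read per-sample sleep HR rows and aggregate them into nights.

    Expected header: ``patient_id,session_start,session_end,timestamp,hr_bpm``
    (one row per HR sample, ISO-8601 timestamps).
    """
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    required = {"patient_id", "session_start", "session_end", "hr_bpm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sleep CSV missing columns: {sorted(missing)}")
    sessions: list[SleepSession] = []
    grouped = df.groupby(["patient_id", "session_start", "session_end"], sort=True)
    for (pid, start, end), g in grouped:
        if "timestamp" in g.columns:
            g = g.sort_values("timestamp")
        sessions.append(
            SleepSession(
                patient_id=str(pid),
                start=datetime.datetime.fromisoformat(str(start)),
                end=datetime.datetime.fromisoformat(str(end)),
                samples=tuple(float(v) for v in g["hr_bpm"].to_numpy()),
            )
        )
    return assign_sessions_to_dates(sessions)


def write_sleep_csv(
    sessions: Iterable[SleepSession], path: str | Path, header_comment: str | None = None
) -> None:
    """Write sessions in the per-sample CSV dialect read by :func:`read_sleep_csv`.

    Sample timestamps are spaced evenly across the session span.
    """
    rows_pid, rows_start, rows_end, rows_ts, rows_hr = [], [], [], [], []
    for s in sessions:
        n = len(s.samples)
        span = (s.end - s.start).total_seconds()
        step = span / n if n else 0.0
        for i, v in enumerate(s.samples):
            rows_pid.append(s.patient_id)
            rows_start.append(s.start.isoformat())
            rows_end.append(s.end.isoformat())
            rows_ts.append((s.start + datetime.timedelta(seconds=i * step)).isoformat())
            rows_hr.append(v)
    df = pd.DataFrame(
        {
            "patient_id": rows_pid,
            "session_start": rows_start,
            "session_end": rows_end,
            "timestamp": rows_ts,
            "hr_bpm": rows_hr,
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_sleep_json(path: str | Path) -> list[SleepNight]:
    """Read the pre-aggregated JSON form: {patient_id: [{date, samples}]}."""
    with open(path) as fh:
        payload = json.load(fh)
    nights: list[SleepNight] = []
    for pid, entries in payload.items():
        for entry in entries:
            kept, _ = clean_samples(entry["samples"])
            if kept:
                nights.append(
                    SleepNight(
                        patient_id=str(pid),
                        date=datetime.date.fromisoformat(entry["date"]),
                        samples=kept,
                    )
                )
    return nights
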