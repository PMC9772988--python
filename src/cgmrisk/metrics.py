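"""Range-metric summaries of continuous glucose monitoring (CGM) records.

A CGM device on a nominal 5-minute grid yields up to 288 interstitial
glucose readings per calendar day, reported within the device range of
40–400 mg/dL.  This module parses long-format traces, retains complete
wear days, and summarises each record into the standard time-in-range
metrics:

* TIR — percentage of readings in the closed range [70, 140] mg/dL,
* TAR — percentage strictly above 140 mg/dL,
* TBR — percentage strictly below 70 mg/dL.

The three percentages partition the retained readings, so they sum to
100 exactly (up to floating-point rounding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CGMRecord",
    "WearSummary",
    "RangeMetrics",
    "CGMDataError",
    "filter_complete_days",
    "compute_time_in_ranges",
    "read_cgm_csv",
    "write_metrics_csv",
    "range_metrics_table",
    "DEVICE_MIN_MGDL",
    "DEVICE_MAX_MGDL",
    "SAMPLES_PER_DAY",
]

DEVICE_MIN_MGDL = 40.0
DEVICE_MAX_MGDL = 400.0
#: 24 h on a 5-minute grid.
SAMPLES_PER_DAY = 288
TIR_LOW = 70.0
TIR_HIGH = 140.0


class CGMDataError(ValueError):
    """Malformed CGM input: empty record, unordered timestamps, no valid samples."""


@dataclass
class CGMRecord:
    """One subject's timestamped glucose series.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    times : numpy.ndarray of datetime64[ns]
        Sample timestamps; expected strictly increasing on or near a
        5-minute grid.
    glucose : numpy.ndarray of float
        Interstitial glucose, mg/dL.  Values outside the device range
        are clamped to [40, 400] with a warning.
    """

    subject_id: str
    times: np.ndarray
    glucose: np.ndarray
    nominal_interval_min: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape:
            raise CGMDataError(
                f"subject {self.subject_id}: {self.times.size} timestamps "
                f"vs {self.glucose.size} glucose values"
            )
        out = (self.glucose < DEVICE_MIN_MGDL) | (self.glucose > DEVICE_MAX_MGDL)
        out &= np.isfinite(self.glucose)
        if out.any():
            warnings.warn(
                f"subject {self.subject_id}: {int(out.sum())} readings outside "
                f"[{DEVICE_MIN_MGDL:.0f}, {DEVICE_MAX_MGDL:.0f}] mg/dL clamped",
                stacklevel=2,
            )
            self.glucose = np.clip(self.glucose, DEVICE_MIN_MGDL, DEVICE_MAX_MGDL)

    def __len__(self) -> int:
        return self.glucose.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str | None = None) -> "CGMRecord":
        """Build a record from a long-format frame (timestamp, glucose_mg_dl)."""
        sid = subject_id if subject_id is not None else str(df["subject_id"].iloc[0])
        return cls(
            subject_id=sid,
            times=pd.to_datetime(df["timestamp"]).to_numpy(),
            glucose=df["glucose_mg_dl"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class WearSummary:
    """Wear-time bookkeeping after day-completeness filtering."""

    complete_days: int
    total_valid_samples: int
    eligible: bool


@dataclass(frozen=True)
class RangeMetrics:
    """TIR/TAR/TBR percentages for one record; they partition 100%."""

    tir_pct: float
    tar_pct: float
    tbr_pct: float
    n_samples_used: int


def filter_complete_days(
    record: CGMRecord,
    completeness_fraction: float = 0.8,
    min_days: int = 2,
) -> tuple[CGMRecord, WearSummary]:
    """Retain only complete calendar days of a record.

    A calendar day (local midnight boundaries) is *complete* when it holds
    at least ``completeness_fraction × 288`` valid samples — with the 0.8
    default, 231 of the nominal 288.  Eligibility follows the enrolment
    rule of at least ``min_days`` (default 2) complete days.

    Returns the filtered record and a :class:`WearSummary`.

    Raises
    ------
    CGMDataError
        If the record is empty or timestamps are not strictly increasing
        (the message names the first offending sample index).
    """
    if len(record) == 0:
        raise CGMDataError(f"subject {record.subject_id}: empty record")
    bad = np.where(np.diff(record.times) <= np.timedelta64(0, "ns"))[0]
    if bad.size:
        raise CGMDataError(
            f"subject {record.subject_id}: timestamps not strictly increasing "
            f"at sample index {int(bad[0]) + 1}"
        )
    valid = np.isfinite(record.glucose)
    days = record.times.astype("datetime64[D]")
    uniq, counts = np.unique(days[valid], return_counts=True)
    threshold = completeness_fraction * SAMPLES_PER_DAY
    complete = uniq[counts >= threshold]
    keep = valid & np.isin(days, complete)
    filtered = CGMRecord(
        subject_id=record.subject_id,
        times=record.times[keep],
        glucose=record.glucose[keep],
        nominal_interval_min=record.nominal_interval_min,
    )
    summary = WearSummary(
        complete_days=int(complete.size),
        total_valid_samples=int(keep.sum()),
        eligible=bool(complete.size >= min_days),
    )
    return filtered, summary


def compute_time_in_ranges(record: CGMRecord) -> RangeMetrics:
    """Compute TIR/TAR/TBR percentages over the record's valid samples.

    Boundary readings of exactly 70 or 140 mg/dL count as in-range: TAR
    and TBR are the strict inequalities ``>140`` and ``<70``.  Each
    retained sample carries equal weight (the grid is nominally uniform),
    so sample proportions equal time proportions.
    """
    g = record.glucose[np.isfinite(record.glucose)]
    n = g.size
    if n == 0:
        raise CGMDataError(f"subject {record.subject_id}: no valid samples")
    tar = np.count_nonzero(g > TIR_HIGH)
    tbr = np.count_nonzero(g < TIR_LOW)
    tir = n - tar - tbr
    return RangeMetrics(
        tir_pct=100.0 * tir / n,
        tar_pct=100.0 * tar / n,
        tbr_pct=100.0 * tbr / n,
        n_samples_used=int(n),
    )


def read_cgm_csv(path) -> dict[str, CGMRecord]:
    """Read long-format CGM CSV (subject_id, timestamp, glucose_mg_dl)."""
    df = pd.read_csv(path)
    required = {"subject_id", "timestamp", "glucose_mg_dl"}
    missing = required - set(df.columns)
    if missing:
        raise CGMDataError(f"CGM CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    records: dict[str, CGMRecord] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("timestamp")
        records[str(sid)] = CGMRecord(
            subject_id=str(sid),
            times=grp["timestamp"].to_numpy(),
            glucose=grp["glucose_mg_dl"].to_numpy(dtype=float),
        )
    return records


def range_metrics_table(
    records: dict[str, CGMRecord],
    completeness_fraction: float = 0.8,
    min_days: int = 2,
) -> pd.DataFrame:
    """Per-subject wear summary + range metrics for a set of records.

    Ineligible subjects (fewer than ``min_days`` complete days) are kept
    in the table with ``eligible = False`` so callers can report exclusions.
    """
    rows = []
    for sid in sorted(records):
        filtered, summary = filter_complete_days(
            records[sid], completeness_fraction, min_days
        )
        row = {
            "subject_id": sid,
            "complete_days": summary.complete_days,
            "n_samples": summary.total_valid_samples,
            "eligible": summary.eligible,
            "tir_pct": np.nan,
            "tar_pct": np.nan,
            "tbr_pct": np.nan,
        }
        if summary.total_valid_samples > 0:
            m = compute_time_in_ranges(filtered)
            row.update(tir_pct=m.tir_pct, tar_pct=m.tar_pct, tbr_pct=m.tbr_pct)
        rows.append(row)
    return pd.DataFrame(rows)


def write_metrics_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
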