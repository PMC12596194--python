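"""Core data containers shared across the pipeline stages.

All times are seconds from session start (sample 0 at ``t0``); intervals are
half-open ``[start, end)``.  PAT values are milliseconds, pressures mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

__all__ = [
    "WaveformRecord",
    "BeatSeries",
    "SmoothedPAT",
    "BPReading",
    "SessionData",
    "PeriodAverages",
    "ChangeObservation",
    "GroundTruth",
    "PERIODS",
    "INTERVALS",
]

#: canonical period names, in session order
PERIODS = ("beginning", "middle", "end")
#: the two comparison intervals formed from the three periods
INTERVALS = ("beginning_to_middle", "middle_to_end")


@dataclass
class WaveformRecord:
    """Synchronized ECG + PPG sample arrays on a shared clock."""

    ecg: np.ndarray
    ppg: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.ecg.shape != self.ppg.shape:
            raise ValueError("ecg and ppg must have equal lengths")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.ecg.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class BeatSeries:
    """Per-beat fiducials: R-peak times, pulse-onset times, RR, PAT, validity.

    ``rr[i]`` is the interval from beat ``i`` to beat ``i+1`` (NaN for the
    last beat).  ``pat`` is in milliseconds, NaN where no onset was paired.
    ``reason`` holds the rejection reason for invalid beats ('' if valid).
    """

    r_peak_times: np.ndarray
    onset_times: np.ndarray
    pat: np.ndarray
    valid: np.ndarray
    reason: np.ndarray

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.pat = np.asarray(self.pat, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        n = self.r_peak_times.size
        for arr in (self.onset_times, self.pat, self.valid, self.reason):
            if arr.size != n:
                raise ValueError("all beat arrays must have equal length")
        if n > 1 and np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return self.r_peak_times.size

    @property
    def rr(self) -> np.ndarray:
        out = np.full(self.n_beats, np.nan)
        if self.n_beats > 1:
            out[:-1] = np.diff(self.r_peak_times)
        return out

    def copy(self) -> "BeatSeries":
        return BeatSeries(
            self.r_peak_times.copy(),
            self.onset_times.copy(),
            self.pat.copy(),
            self.valid.copy(),
            self.reason.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_peak_time_s": self.r_peak_times,
                "onset_time_s": self.onset_times,
                "rr_s": self.rr,
                "pat_ms": self.pat,
                "valid": self.valid,
                "reason": self.reason,
            }
        )


@dataclass
class SmoothedPAT:
    """Windowed-average PAT series evaluated at the valid beat times."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        if self.n == 0:
            raise ValueError("empty PAT series has no span")
        return float(self.times[0]), float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "pat_ms": self.values})


@dataclass(frozen=True)
class BPReading:
    """One oscillometric cuff measurement."""

    time: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError("readings must satisfy sbp > dbp > 0")


def readings_to_frame(readings: list[BPReading]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp_s": [r.time for r in readings],
            "sbp_mmhg": [r.sbp for r in readings],
            "dbp_mmhg": [r.dbp for r in readings],
        }
    )


@dataclass
class SessionData:
    """One aligned dialysis session: smoothed PAT + cuff readings + covariates."""

    session_id: str
    smoothed: SmoothedPAT
    readings: list[BPReading]
    covariates: dict[str, float] = field(default_factory=dict)
    visit: int = 0
    out_of_recording: np.ndarray | None = None
    usable: bool = True
    valid_beat_fraction: float = 1.0

    @property
    def n_bp(self) -> int:
        return len(self.readings)


@dataclass
class PeriodAverages:
    """Hour-period means of PAT and BP with sample counts per period."""

    bounds: dict[str, tuple[float, float]]
    mean_pat: dict[str, float]
    mean_sbp: dict[str, float]
    mean_dbp: dict[str, float]
    n_pat: dict[str, int]
    n_bp: dict[str, int]

    def missing_periods(self) -> list[str]:
        return [p for p in PERIODS if self.n_pat[p] == 0 or self.n_bp[p] == 0]

    @property
    def complete(self) -> bool:
        return not self.missing_periods()


@dataclass
class ChangeObservation:
    """Per-interval changes in BP and PAT.

    ``icpat`` is the sign-inverted PAT change, which aligns in sign with the
    BP change under the inverse PAT-BP relationship; relative changes are in
    percent of the earlier period's mean.
    """

    interval: str
    d_sbp: float
    d_dbp: float
    d_pat: float
    rel_sbp: float
    rel_dbp: float
    rel_pat: float
    session_id: str = ""

    @property
    def icpat(self) -> float:
        return -self.d_pat


def changes_to_frame(
    observations: list[ChangeObservation],
    covariates: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Tabulate change observations, optionally joining per-session covariates."""
    rows = []
    for o in observations:
        row: dict[str, Any] = {
            "session_id": o.session_id,
            "interval": o.interval,
            "d_sbp": o.d_sbp,
            "d_dbp": o.d_dbp,
            "d_pat": o.d_pat,
            "icpat": o.icpat,
            "rel_sbp": o.rel_sbp,
            "rel_dbp": o.rel_dbp,
            "rel_pat": o.rel_pat,
        }
        if covariates is not None and o.session_id in covariates:
            row.update(covariates[o.session_id])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Designed truth behind a synthetic session, for recovery checks."""

    beat_times: np.ndarray
    true_onset_times: np.ndarray
    true_pat: np.ndarray  # ms, includes beat-level jitter
    sbp_curve: Callable[[np.ndarray], np.ndarray] | None = None
    dbp_curve: Callable[[np.ndarray], np.ndarray] | None = None
    class_label: dict[str, str] = field(default_factory=dict)
    period_means: dict[str, dict[str, float]] = field(default_factory=dict)
    artifacts: list[dict[str, Any]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "true_onset_time_s": self.true_onset_times,
                "true_pat_ms": self.true_pat,
            }
        )
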