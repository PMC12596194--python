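"""Session-level aggregation: alignment, hour-period averages, change
observations, exclusion rules, and intradialytic-hypotension (IDH) drops.

The analysis compares three predefined 1-hour periods (beginning, middle,
end of dialysis).  Because recordings often end before the nominal 4 h, the
default period definition anchors the beginning and end hours to the PAT
recording span and centres the middle hour on the recording midpoint,
truncating the periods to non-overlap for recordings shorter than 3 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import AnalysisConfig, PeriodConfig
from .core import (
    BPReading,
    ChangeObservation,
    PeriodAverages,
    SessionData,
    SmoothedPAT,
    INTERVALS,
    PERIODS,
)

__all__ = [
    "align",
    "period_bounds",
    "period_averages",
    "compute_changes",
    "apply_exclusions",
    "detect_idh_drops",
    "ExclusionLog",
]


def align(
    smoothed: SmoothedPAT,
    readings: list[BPReading],
    covariates: dict[str, float] | None = None,
    session_id: str = "",
    valid_beat_fraction: float = 1.0,
) -> SessionData:
    """Join the smoothed PAT series with the cuff readings on the shared clock.

    Readings outside the PAT recording span are kept but flagged
    ``out_of_recording``; a session with no overlap at all (or no PAT data)
    is marked unusable.
    """
    if smoothed.n == 0 or not readings:
        flags = np.ones(len(readings), dtype=bool)
        return SessionData(
            session_id=session_id,
            smoothed=smoothed,
            readings=readings,
            covariates=covariates or {},
            out_of_recording=flags,
            usable=False,
            valid_beat_fraction=valid_beat_fraction,
        )
    start, end = smoothed.span
    times = np.array([r.time for r in readings])
    flags = (times < start) | (times > end)
    return SessionData(
        session_id=session_id,
        smoothed=smoothed,
        readings=readings,
        covariates=covariates or {},
        out_of_recording=flags,
        usable=bool(np.any(~flags)),
        valid_beat_fraction=valid_beat_fraction,
    )


def period_bounds(
    recording_span: tuple[float, float], config: PeriodConfig | None = None
) -> dict[str, tuple[float, float]]:
    """Bounds (half-open, seconds) of the beginning/middle/end periods.

    ``recording_centered`` mode: beginning = first ``period_s`` of the
    recording, end = last ``period_s``, middle = ``period_s`` centred on the
    recording midpoint.  For recordings shorter than 3 periods the middle is
    truncated to the gap between beginning and end; shorter than 2 periods,
    beginning and end split the recording at its midpoint and the middle is
    empty.  ``clock`` mode uses fixed session clock hours 1, 2 and 4.
    """
    config = config or PeriodConfig()
    h = config.period_s
    a, b = recording_span
    if b <= a:
        raise ValueError("recording span must have positive length")
    if config.mode == "clock":
        return {
            "beginning": (0.0, h),
            "middle": (h, 2 * h),
            "end": (max(b - h, 2 * h), max(b, 3 * h)),
        }
    length = b - a
    mid = (a + b) / 2.0
    if length >= 3 * h:
        return {
            "beginning": (a, a + h),
            "middle": (mid - h / 2, mid + h / 2),
            "end": (b - h, b),
        }
    if length >= 2 * h:
        return {"beginning": (a, a + h), "middle": (a + h, b - h), "end": (b - h, b)}
    return {"beginning": (a, mid), "middle": (mid, mid), "end": (mid, b)}


def period_averages(
    session: SessionData, bounds: dict[str, tuple[float, float]] | None = None
) -> PeriodAverages:
    """Arithmetic means of smoothed PAT and cuff readings per period.

    Values are attributed to a period when their timestamp falls in the
    period's ``[start, end)``; an empty period is marked missing (count 0)
    and later feeds the exclusion rules.
    """
    if bounds is None:
        bounds = period_bounds(session.smoothed.span)
    for p in PERIODS:
        if p not in bounds:
            raise ValueError(f"missing period {p!r} in bounds")
    mean_pat, mean_sbp, mean_dbp = {}, {}, {}
    n_pat, n_bp = {}, {}
    t_pat = session.smoothed.times
    v_pat = session.smoothed.values
    t_bp = np.array([r.time for r in session.readings])
    sbp = np.array([r.sbp for r in session.readings])
    dbp = np.array([r.dbp for r in session.readings])
    for p in PERIODS:
        lo, hi = bounds[p]
        m = (t_pat >= lo) & (t_pat < hi)
        n_pat[p] = int(np.sum(m))
        mean_pat[p] = float(np.mean(v_pat[m])) if n_pat[p] else float("nan")
        mb = (t_bp >= lo) & (t_bp < hi) if t_bp.size else np.array([], dtype=bool)
        n_bp[p] = int(np.sum(mb))
        mean_sbp[p] = float(np.mean(sbp[mb])) if n_bp[p] else float("nan")
        mean_dbp[p] = float(np.mean(dbp[mb])) if n_bp[p] else float("nan")
    return PeriodAverages(
        bounds=dict(bounds),
        mean_pat=mean_pat,
        mean_sbp=mean_sbp,
        mean_dbp=mean_dbp,
        n_pat=n_pat,
        n_bp=n_bp,
    )


def compute_changes(
    pa: PeriodAverages, session_id: str = ""
) -> list[ChangeObservation]:
    """Per-interval changes (later minus earlier period mean).

    Relative changes are percentages of the earlier period's mean; no
    observations are produced when any period is missing.
    """
    if not pa.complete:
        return []
    out = []
    for interval, (p0, p1) in zip(INTERVALS, (PERIODS[:2], PERIODS[1:])):
        d_sbp = pa.mean_sbp[p1] - pa.mean_sbp[p0]
        d_dbp = pa.mean_dbp[p1] - pa.mean_dbp[p0]
        d_pat = pa.mean_pat[p1] - pa.mean_pat[p0]
        out.append(
            ChangeObservation(
                interval=interval,
                d_sbp=d_sbp,
                d_dbp=d_dbp,
                d_pat=d_pat,
                rel_sbp=100.0 * d_sbp / pa.mean_sbp[p0],
                rel_dbp=100.0 * d_dbp / pa.mean_dbp[p0],
                rel_pat=100.0 * d_pat / pa.mean_pat[p0],
                session_id=session_id,
            )
        )
    return out


@dataclass
class ExclusionLog:
    """Per-session exclusion reasons, for flow accounting."""

    excluded: dict[str, str] = field(default_factory=dict)

    def add(self, session_id: str, reason: str) -> None:
        self.excluded[session_id] = reason

    def __len__(self) -> int:
        return len(self.excluded)


def apply_exclusions(
    sessions: list[SessionData],
    config: AnalysisConfig | None = None,
    period_config: PeriodConfig | None = None,
) -> tuple[list[SessionData], ExclusionLog]:
    """Apply the study's exclusion rules, logging a reason per dropped session.

    A session is excluded when it has fewer than ``min_bp_readings`` cuff
    readings (``lt6_bp``), when any of the three hour periods contains no PAT
    or no BP value (``missing_period``), when fewer than half of its beats
    survived plausibility filtering (``low_quality_ecg``), or when the BP and
    PAT streams do not overlap at all (``no_overlap``).
    """
    config = config or AnalysisConfig()
    retained = []
    log = ExclusionLog()
    for s in sessions:
        if not s.usable:
            log.add(s.session_id, "no_overlap")
            continue
        if s.n_bp < config.min_bp_readings:
            log.add(s.session_id, "lt6_bp")
            continue
        if s.valid_beat_fraction < config.min_valid_beat_fraction:
            log.add(s.session_id, "low_quality_ecg")
            continue
        pa = period_averages(s, period_bounds(s.smoothed.span, period_config))
        if not pa.complete:
            log.add(s.session_id, "missing_period")
            continue
        retained.append(s)
    return retained, log


def detect_idh_drops(
    session: SessionData,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> dict[str, Any]:
    """Flag intradialytic hypotension drops per comparison interval.

    The threshold depends on the session's initial systolic pressure (first
    cuff reading): a drop is an intradialytic SBP reading below 90 mmHg when
    the initial SBP is below 160 mmHg, below 100 mmHg otherwise.  Each
    interval is flagged from the *raw* readings falling in its later period.
    """
    if not session.readings:
        return {"initial_sbp": None, "threshold": None, "flags": {}, "n_drops": 0}
    readings = sorted(session.readings, key=lambda r: r.time)
    initial = readings[0].sbp
    threshold = 90.0 if initial < 160.0 else 100.0
    if bounds is None:
        bounds = period_bounds(session.smoothed.span)
    flags = {}
    for interval, later in zip(INTERVALS, PERIODS[1:]):
        lo, hi = bounds[later]
        vals = [r.sbp for r in readings if lo <= r.time < hi]
        flags[interval] = bool(vals) and min(vals) < threshold
    return {
        "initial_sbp": float(initial),
        "threshold": threshold,
        "flags": flags,
        "n_drops": int(sum(flags.values())),
    }
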