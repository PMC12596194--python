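"""Delimited-text readers/writers and the JSON report.

All tabular artefacts are tab-separated text with a header row; the cohort
report is canonical JSON (sorted keys) so that identical runs are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import BeatSeries, BPReading, SmoothedPAT, WaveformRecord

__all__ = [
    "write_waveforms",
    "read_waveforms",
    "write_bp_readings",
    "read_bp_readings",
    "write_beats",
    "read_beats",
    "write_smoothed",
    "read_smoothed",
    "write_report",
    "read_report",
    "validate_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

_REPORT_REQUIRED_KEYS = {"schema_version", "provenance", "analysis", "exclusions"}


def _read_numeric_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def write_waveforms(record: WaveformRecord, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": record.times(), "ecg": record.ecg, "ppg": record.ppg}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_waveforms(path: str | Path, fs: float | None = None) -> WaveformRecord:
    """Read a (time_s, ecg, ppg) table; fs is inferred from the time column
    unless given explicitly (mismatch beyond 1% is rejected)."""
    df = _read_numeric_table(path, ["time_s", "ecg", "ppg"])
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: sample times are not uniform")
    fs_inferred = 1.0 / float(np.mean(dt))
    if fs is not None and abs(fs_inferred - fs) / fs > 0.01:
        raise ValueError(
            f"{path}: sampling rate {fs_inferred:.1f} Hz does not match expected {fs} Hz"
        )
    return WaveformRecord(
        ecg=df["ecg"].to_numpy(), ppg=df["ppg"].to_numpy(),
        fs=fs if fs is not None else fs_inferred, t0=float(t[0]),
    )


def write_bp_readings(readings: list[BPReading], path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp_s": [r.time for r in readings],
            "sbp_mmhg": [r.sbp for r in readings],
            "dbp_mmhg": [r.dbp for r in readings],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_bp_readings(path: str | Path) -> list[BPReading]:
    df = _read_numeric_table(path, ["timestamp_s", "sbp_mmhg", "dbp_mmhg"])
    return [
        BPReading(time=row.timestamp_s, sbp=row.sbp_mmhg, dbp=row.dbp_mmhg)
        for row in df.itertuples()
    ]


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    beats.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_beats(path: str | Path) -> BeatSeries:
    df = _read_numeric_table(
        path, ["r_peak_time_s", "onset_time_s", "rr_s", "pat_ms"]
    )
    return BeatSeries(
        r_peak_times=df["r_peak_time_s"].to_numpy(),
        onset_times=df["onset_time_s"].to_numpy(),
        pat=df["pat_ms"].to_numpy(),
        valid=df["valid"].astype(bool).to_numpy(),
        reason=df["reason"].fillna("").to_numpy(dtype=object),
    )


def write_smoothed(smoothed: SmoothedPAT, path: str | Path) -> None:
    smoothed.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_smoothed(path: str | Path) -> SmoothedPAT:
    df = _read_numeric_table(path, ["time_s", "pat_ms"])
    return SmoothedPAT(times=df["time_s"].to_numpy(), values=df["pat_ms"].to_numpy())


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Write the cohort report as canonical JSON after schema validation."""
    report = _jsonify(report)
    validate_report(report)
    Path(path).write_text(
        json.dumps(report, sort_keys=True, indent=1, separators=(",", ": ")) + "\n"
    )


def read_report(path: str | Path) -> dict[str, Any]:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report


def validate_report(report: dict[str, Any]) -> None:
    missing = _REPORT_REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {report['schema_version']!r}"
        )
    prov = report["provenance"]
    for key in ("version", "config_hash", "seed"):
        if key not in prov:
            raise ValueError(f"provenance missing {key!r}")
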