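"""Configuration objects for the synthetic generator and the analysis pipeline.

Every tunable threshold in the pipeline lives here so that a single
serialisable object fully determines a run: the synthetic-session generator
(:class:`SynthConfig`), the beat-filter bounds (:class:`FilterBounds`), the
hour-period definition (:class:`PeriodConfig`) and the statistical settings
(:class:`AnalysisConfig`).  :class:`PipelineConfig` bundles them and exposes a
stable content hash used for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import yaml

__all__ = [
    "SynthConfig",
    "FilterBounds",
    "PeriodConfig",
    "AnalysisConfig",
    "PipelineConfig",
]


@dataclass
class SynthConfig:
    """Parameters of a synthetic hemodialysis session.

    Defaults emulate the monitoring setting the pipeline was designed for: a
    4-hour dialysis session with synchronized single-lead ECG and finger-PPG
    sampled at 512 Hz on a shared clock, oscillometric cuff readings every
    15-20 minutes, and an inverse PAT<->SBP coupling of ~1 ms per mmHg.

    Parameters
    ----------
    session_duration : float
        Session length in seconds (default 14400 s = 4 h).
    fs : float
        Waveform sampling rate in Hz (default 512).
    mean_hr : float
        Mean heart rate in beats per minute.
    rsa_amplitude : float
        Fractional RR modulation by respiratory sinus arrhythmia (default 5%).
    rsa_frequency : float
        Respiration frequency in Hz (default 0.25, i.e. 15 breaths/min).
    pat0 : float
        Baseline pulse arrival time in ms (default 233).
    coupling_k : float
        Inverse PAT-SBP coupling in ms per mmHg: PAT(t) = pat0 - k*(SBP(t)-sbp0).
    sbp0, dbp0 : float
        Baseline systolic / diastolic pressure in mmHg.
    sbp_breakpoints, dbp_breakpoints : sequence of (t_s, mmHg) or None
        Piecewise-linear BP trajectory; None means flat at sbp0/dbp0.
    bp_interval : (float, float)
        Uniform bounds, in seconds, of the gap between cuff readings.
    bp_noise_sd : float
        Gaussian measurement noise on each cuff reading, mmHg.
    pat_jitter_sd : float
        Beat-to-beat Gaussian jitter on the true PAT, ms.
    artifact_rate : float
        Expected artifact events per hour (dropouts, ectopics, PPG spikes).
    ecg_noise_sd, ppg_noise_sd : float
        Additive Gaussian noise on the rendered waveforms (signal units;
        nominal beat amplitude is 1).
    ppg_rise_time : float
        Systolic upstroke duration in seconds (default 150 ms).
    ecg_r_width : float
        Gaussian R-deflection width (standard deviation) in seconds.
    seed : int
        Seed for the generator's single random stream.
    """

    session_duration: float = 14400.0
    fs: float = 512.0
    mean_hr: float = 70.0
    rsa_amplitude: float = 0.05
    rsa_frequency: float = 0.25
    pat0: float = 233.0
    coupling_k: float = 1.0
    sbp0: float = 130.0
    dbp0: float = 68.0
    sbp_breakpoints: Sequence[tuple[float, float]] | None = None
    dbp_breakpoints: Sequence[tuple[float, float]] | None = None
    bp_interval: tuple[float, float] = (900.0, 1200.0)
    bp_noise_sd: float = 3.0
    pat_jitter_sd: float = 3.0
    artifact_rate: float = 2.0
    ecg_noise_sd: float = 0.02
    ppg_noise_sd: float = 0.01
    ppg_rise_time: float = 0.150
    ecg_r_width: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if self.coupling_k < 0:
            raise ValueError("coupling_k must be >= 0")
        if not (0 < self.rsa_frequency < self.fs / 2):
            raise ValueError("rsa_frequency must lie in (0, fs/2)")
        for name in ("bp_noise_sd", "pat_jitter_sd", "ecg_noise_sd", "ppg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (20 < self.mean_hr < 220):
            raise ValueError("mean_hr must lie in (20, 220) bpm")
        if self.rsa_amplitude >= 1 or self.rsa_amplitude < 0:
            raise ValueError("rsa_amplitude must lie in [0, 1)")
        lo, hi = self.bp_interval
        if not (0 < lo <= hi):
            raise ValueError("bp_interval bounds must satisfy 0 < lo <= hi")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


@dataclass
class FilterBounds:
    """Plausibility bounds for beat rejection.

    Defaults span a typical dialysis cohort (mean PAT 233 +/- 42 ms) by a wide
    margin: RR in [0.3, 2.0] s, PAT in [100, 500] ms, and a beat-to-beat jump
    limit of 30 ms against the median of the 5 nearest valid neighbours.
    """

    rr_min: float = 0.3
    rr_max: float = 2.0
    pat_min: float = 100.0
    pat_max: float = 500.0
    jump_max: float = 30.0
    jump_neighbors: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.rr_min < self.rr_max):
            raise ValueError("need 0 < rr_min < rr_max")
        if not (0 < self.pat_min < self.pat_max):
            raise ValueError("need 0 < pat_min < pat_max")
        if self.jump_max <= 0 or self.jump_neighbors < 1:
            raise ValueError("jump_max must be > 0 and jump_neighbors >= 1")


@dataclass
class PeriodConfig:
    """Definition of the beginning / middle / end 1-hour averaging periods.

    ``mode="recording_centered"`` anchors the beginning and end periods to the
    PAT recording span and centres the middle period on the recording
    midpoint, truncating to non-overlap for recordings shorter than 3 h.
    ``mode="clock"`` uses fixed dialysis clock hours instead.
    """

    period_s: float = 3600.0
    mode: str = "recording_centered"

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.mode not in ("recording_centered", "clock"):
            raise ValueError("mode must be 'recording_centered' or 'clock'")


@dataclass
class AnalysisConfig:
    """Statistical settings: TOST margin, significance level, class thresholds."""

    margin: float = 5.0
    alpha: float = 0.05
    class_threshold: float = 2.0
    predictor_threshold: float = 2.0
    pooled: bool = True
    min_bp_readings: int = 6
    min_valid_beat_fraction: float = 0.5
    smoothing_window_s: float = 180.0

    def __post_init__(self) -> None:
        if self.margin <= 0 or not (0 < self.alpha < 1):
            raise ValueError("margin must be > 0 and alpha in (0, 1)")
        if self.smoothing_window_s <= 0:
            raise ValueError("smoothing_window_s must be positive")


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations plus cohort composition."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    filters: FilterBounds = field(default_factory=FilterBounds)
    periods: PeriodConfig = field(default_factory=PeriodConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_decliner: int = 10
    n_stable: int = 10
    n_riser: int = 10
    render_waveforms: bool = False
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kw: dict[str, Any] = {}
        for name, sub in (
            ("synth", SynthConfig),
            ("filters", FilterBounds),
            ("periods", PeriodConfig),
            ("analysis", AnalysisConfig),
        ):
            if name in d:
                v = d.pop(name)
                sect = dict(v)
                for key in ("bp_interval",):
                    if key in sect and isinstance(sect[key], list):
                        sect[key] = tuple(sect[key])
                for key in ("sbp_breakpoints", "dbp_breakpoints"):
                    if key in sect and sect[key] is not None:
                        sect[key] = [tuple(p) for p in sect[key]]
                kw[name] = sub(**sect)
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form; changes iff any field changes."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()
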