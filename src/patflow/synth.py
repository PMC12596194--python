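"""Synthetic dialysis-session generator.

Emulates the signals the pipeline consumes: a beat schedule modulated by
respiratory sinus arrhythmia, synchronized ECG/PPG waveforms in which each
PPG pulse onset lags its R-peak by a time-varying pulse arrival time (PAT),
interval oscillometric cuff readings, and per-patient covariates.  The
beat-to-beat PAT follows the session's systolic-pressure trajectory through
an inverse coupling of ``coupling_k`` ms per mmHg, so blood-pressure
decliners present as PAT risers and vice versa.

Waveform morphology is deliberately minimal but chosen so that fiducial
recovery is provable rather than approximate:

* the ECG is a train of Gaussian R-deflections on a flat baseline (no P/T
  waves) — sufficient for R-peak timing;
* each PPG pulse rises from a flat diastolic foot with a *linear* systolic
  upstroke that blends into a quarter-cosine shoulder at half rise-time.
  Because maximal slope is attained from the onset itself, the
  intersecting-tangents fiducial (horizontal tangent through the diastolic
  minimum x tangent at steepest ascent) analytically equals the true onset.

All randomness is drawn from a single :class:`numpy.random.Generator` passed
explicitly; identical config + seed yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any

import numpy as np

from .config import SynthConfig
from .core import (
    BeatSeries,
    BPReading,
    GroundTruth,
    SessionData,
    WaveformRecord,
    INTERVALS,
    PERIODS,
)

__all__ = [
    "Trajectory",
    "build_bp_trajectory",
    "build_beat_schedule",
    "render_waveforms",
    "sample_bp_readings",
    "generate_session",
    "generate_cohort",
    "SynthSession",
    "CLASS_REL_RANGES",
]

#: designed relative BP change (%) drawn per interval for each session class;
#: decliner/riser magnitudes sit well outside the +/-2% band, stables well inside
CLASS_REL_RANGES = {
    "decliner": (-10.0, -4.0),
    "stable": (-1.0, 1.0),
    "riser": (4.0, 10.0),
}


class Trajectory:
    """Piecewise-linear pressure curve with exact interval means.

    Evaluable at any time; constant extrapolation beyond the first/last
    breakpoint.  ``mean(a, b)`` integrates the piecewise-linear curve in
    closed form (trapezoid over the exact knots).
    """

    def __init__(self, breakpoints: list[tuple[float, float]]):
        if not breakpoints:
            raise ValueError("need at least one breakpoint")
        pts = sorted((float(t), float(v)) for t, v in breakpoints)
        self.ts = np.array([p[0] for p in pts])
        self.vs = np.array([p[1] for p in pts])
        if np.any(np.diff(self.ts) < 0):  # pragma: no cover - sorted above
            raise ValueError("breakpoint times must be non-decreasing")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.ts, self.vs)

    def mean(self, a: float, b: float) -> float:
        """Exact mean of the curve over ``[a, b]``."""
        if b < a:
            raise ValueError("need a <= b")
        if b == a:
            return float(self(a))
        inner = self.ts[(self.ts > a) & (self.ts < b)]
        knots = np.concatenate(([a], inner, [b]))
        vals = self(knots)
        return float(np.trapezoid(vals, knots) / (b - a))


def build_bp_trajectory(config: SynthConfig) -> tuple[Trajectory, Trajectory]:
    """Continuous SBP(t) and DBP(t) from the config's breakpoints.

    A ``None`` breakpoint list yields a flat trajectory at ``sbp0``/``dbp0``.
    Breakpoints must lie within ``[0, session_duration]``.
    """
    out = []
    for bps, base in (
        (config.sbp_breakpoints, config.sbp0),
        (config.dbp_breakpoints, config.dbp0),
    ):
        if bps is None:
            bps = [(0.0, base)]
        for t, _ in bps:
            if not (0 <= t <= config.session_duration):
                raise ValueError(
                    f"breakpoint time {t} s outside [0, {config.session_duration}] s"
                )
        out.append(Trajectory(list(bps)))
    return out[0], out[1]


def build_beat_schedule(config: SynthConfig) -> np.ndarray:
    """Beat times over the session with respiratory sinus arrhythmia.

    The instantaneous RR interval follows
    ``RR(t) = 60/mean_hr * (1 + rsa_amplitude * sin(2 pi rsa_frequency t))``;
    each beat is advanced by the RR evaluated at the previous beat.  The
    schedule is deterministic given the config.
    """
    if config.rsa_amplitude >= 1:
        raise ValueError("rsa_amplitude >= 1 would allow non-positive RR")
    rr0 = 60.0 / config.mean_hr
    times = []
    t = 0.0
    w = 2 * math.pi * config.rsa_frequency
    while t < config.session_duration:
        times.append(t)
        t += rr0 * (1.0 + config.rsa_amplitude * math.sin(w * t))
    return np.array(times)


def _pulse_shape(u: np.ndarray, tau: float, gap: float) -> np.ndarray:
    """PPG pulse value at time ``u`` past the onset.

    Linear rise (slope ``s``) on ``[0, tau/2]``, quarter-cosine shoulder to the
    peak at ``tau`` (C1-continuous), exponential decay rescaled to reach zero
    at ``gap`` (start of the next diastolic foot), zero afterwards.
    """
    amp = 1.0
    s = amp / (tau * (0.5 + 1.0 / math.pi))
    y1 = s * tau / 2.0
    y = np.zeros_like(u)
    m1 = (u >= 0) & (u < tau / 2)
    y[m1] = s * u[m1]
    m2 = (u >= tau / 2) & (u < tau)
    y[m2] = y1 + (amp - y1) * np.sin(math.pi * (u[m2] - tau / 2) / tau)
    decay_len = gap - tau
    m3 = (u >= tau) & (u < gap)
    if decay_len > 0:
        tau_d = decay_len / 5.0
        e0 = math.exp(-5.0)
        y[m3] = amp * (np.exp(-(u[m3] - tau) / tau_d) - e0) / (1.0 - e0)
    return y


def render_waveforms(
    beat_times: np.ndarray,
    true_pat: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[WaveformRecord, GroundTruth]:
    """Render synchronized ECG/PPG sampled at ``fs`` on the shared clock.

    ``true_pat`` is the per-beat PAT in ms; the PPG upstroke of beat *i*
    begins exactly at ``beat_times[i] + true_pat[i]/1000``.  Additive
    Gaussian noise and artifact events (dropouts, ectopic beats, PPG spikes)
    are injected according to the config; an empty beat list yields a valid
    baseline-only record.

    Raises ``ValueError`` if any beat's PAT is not within ``(0, RR)``.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    true_pat = np.asarray(true_pat, dtype=float)
    if beat_times.size != true_pat.size:
        raise ValueError("beat_times and true_pat must have equal length")
    if beat_times.size:
        if np.any(true_pat <= 0):
            raise ValueError("true_pat must be positive")
        rr = np.diff(beat_times)
        if rr.size and np.any(true_pat[:-1] / 1000.0 >= rr):
            raise ValueError("true_pat must be smaller than the beat's RR interval")

    fs = config.fs
    n = int(round(config.session_duration * fs))
    ecg = np.zeros(n)
    ppg = np.zeros(n)

    def add_r_peak(t_peak: float, amp: float = 1.0) -> None:
        sig = config.ecg_r_width
        i0 = max(0, int(np.ceil((t_peak - 5 * sig) * fs)))
        i1 = min(n, int(np.floor((t_peak + 5 * sig) * fs)) + 1)
        if i1 > i0:
            tt = np.arange(i0, i1) / fs
            ecg[i0:i1] += amp * np.exp(-0.5 * ((tt - t_peak) / sig) ** 2)

    for bt in beat_times:
        add_r_peak(bt)

    onsets = beat_times + true_pat / 1000.0
    foot = 0.020  # flat diastolic foot before the next onset, s
    for i, o in enumerate(onsets):
        o_next = onsets[i + 1] if i + 1 < onsets.size else min(o + 1.0, n / fs)
        seg = o_next - o
        gap = max(seg - foot, 0.5 * seg)
        tau = min(config.ppg_rise_time, 0.6 * gap)
        i0 = max(0, int(np.ceil(o * fs)))
        i1 = min(n, int(np.ceil(o_next * fs)))
        if i1 > i0:
            u = np.arange(i0, i1) / fs - o
            ppg[i0:i1] += _pulse_shape(u, tau, gap)

    artifacts: list[dict[str, Any]] = []
    if rng is not None and config.artifact_rate > 0:
        n_events = rng.poisson(config.artifact_rate * config.session_duration / 3600.0)
        for _ in range(n_events):
            kind = rng.choice(["dropout", "ectopic", "ppg_spike"])
            t_ev = float(rng.uniform(0, config.session_duration))
            artifacts.append({"kind": str(kind), "time_s": t_ev})

    # ectopic beats ride on the clean render, before noise
    for ev in artifacts:
        if ev["kind"] == "ectopic" and beat_times.size > 1:
            i = int(np.searchsorted(beat_times, ev["time_s"]))
            i = min(max(i, 0), beat_times.size - 2)
            t_ect = beat_times[i] + 0.4 * (beat_times[i + 1] - beat_times[i])
            ev["time_s"] = float(t_ect)
            add_r_peak(t_ect, amp=0.8)

    if rng is not None:
        if config.ecg_noise_sd > 0:
            ecg += rng.normal(0, config.ecg_noise_sd, n)
        if config.ppg_noise_sd > 0:
            ppg += rng.normal(0, config.ppg_noise_sd, n)

    for ev in artifacts:
        if ev["kind"] == "ppg_spike":
            width = 0.050
            i0 = max(0, int(ev["time_s"] * fs))
            i1 = min(n, i0 + int(width * fs))
            if i1 > i0:
                tt = np.arange(i1 - i0) / fs
                ppg[i0:i1] += 2.0 * np.sin(math.pi * tt / width)
        elif ev["kind"] == "dropout":
            dur = float(rng.uniform(1.0, 5.0)) if rng is not None else 2.0
            ev["duration_s"] = dur
            i0 = max(0, int(ev["time_s"] * fs))
            i1 = min(n, i0 + int(dur * fs))
            ecg[i0:i1] = 0.0
            ppg[i0:i1] = 0.0

    record = WaveformRecord(ecg=ecg, ppg=ppg, fs=fs, t0=0.0)
    truth = GroundTruth(
        beat_times=beat_times,
        true_onset_times=onsets,
        true_pat=true_pat,
        artifacts=artifacts,
    )
    return record, truth


def sample_bp_readings(
    sbp_traj: Trajectory,
    dbp_traj: Trajectory,
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[BPReading]:
    """Interval cuff readings: gap times uniform in ``bp_interval``.

    Reading times are cumulative sums of the gaps (the first reading falls
    after the first gap); values are the trajectory plus Gaussian noise of SD
    ``bp_noise_sd``.  A full 4-h session with 15-20 min gaps yields 12-16
    readings.
    """
    lo, hi = config.bp_interval
    readings: list[BPReading] = []
    t = float(rng.uniform(lo, hi))
    while t < config.session_duration:
        sbp = float(sbp_traj(t)) + float(rng.normal(0, config.bp_noise_sd))
        dbp = float(dbp_traj(t)) + float(rng.normal(0, config.bp_noise_sd))
        dbp = min(dbp, sbp - 1.0)  # oscillometric devices never report dbp >= sbp
        readings.append(BPReading(time=t, sbp=sbp, dbp=dbp))
        t += float(rng.uniform(lo, hi))
    return readings


@dataclass
class SynthSession:
    """One generated session: inputs for the pipeline plus the designed truth."""

    session_id: str
    readings: list[BPReading]
    covariates: dict[str, float]
    ground_truth: GroundTruth
    waveforms: WaveformRecord | None = None
    session_data: SessionData | None = None


def _designed_breakpoints(
    base: float, r1_pct: float, r2_pct: float, duration: float
) -> tuple[list[tuple[float, float]], tuple[float, float, float]]:
    """Plateau-per-period trajectory whose hour means are exact by design.

    The curve is flat at ``v1`` over the beginning hour, ramps to ``v2`` held
    flat over the (recording-centred) middle hour, then ramps to ``v3`` over
    the end hour, where v2/v1 - 1 = r1% and v3/v2 - 1 = r2%.
    """
    if duration < 10800:
        raise ValueError("designed sessions need duration >= 3 h")
    v1 = base
    v2 = v1 * (1 + r1_pct / 100.0)
    v3 = v2 * (1 + r2_pct / 100.0)
    h = 3600.0
    mid_lo, mid_hi = duration / 2 - h / 2, duration / 2 + h / 2
    pts = [
        (0.0, v1),
        (h, v1),
        (mid_lo, v2),
        (mid_hi, v2),
        (duration - h, v3),
        (duration, v3),
    ]
    return pts, (v1, v2, v3)


def generate_session(
    class_label: str,
    config: SynthConfig,
    rng: np.random.Generator,
    session_id: str,
    render: bool = False,
    smoothing_window_s: float = 180.0,
) -> SynthSession:
    """Generate one session of the requested class (decliner/stable/riser).

    Per-session baselines (resting SBP/DBP, PAT, heart rate, covariates) are
    drawn around the config values with cohort-scale spread; the designed
    relative BP change for each of the two comparison intervals is drawn from
    :data:`CLASS_REL_RANGES`.  The beat-to-beat PAT is
    ``pat0 - coupling_k * (SBP(t) - sbp0)`` plus Gaussian jitter.

    With ``render=False`` the session skips waveform synthesis: the true
    beat-level PAT series is smoothed directly into the ``SessionData`` the
    aggregation stage consumes.  With ``render=True`` full ECG/PPG waveforms
    are produced for the extraction stage.
    """
    if class_label not in CLASS_REL_RANGES:
        raise ValueError(f"unknown class {class_label!r}")
    lo, hi = CLASS_REL_RANGES[class_label]
    r1_s, r2_s = rng.uniform(lo, hi, 2)
    r1_d, r2_d = rng.uniform(lo, hi, 2)

    s1 = config.sbp0 + float(rng.normal(0, 12))
    d1 = config.dbp0 + float(rng.normal(0, 6))
    d1 = min(d1, s1 - 25.0)
    pat0 = config.pat0 + float(rng.normal(0, 25))
    hr = float(np.clip(config.mean_hr + rng.normal(0, 8), 45, 110))

    sbp_pts, (s_beg, s_mid, s_end) = _designed_breakpoints(
        s1, r1_s, r2_s, config.session_duration
    )
    dbp_pts, (d_beg, d_mid, d_end) = _designed_breakpoints(
        d1, r1_d, r2_d, config.session_duration
    )
    cfg = dataclasses.replace(
        config,
        mean_hr=hr,
        pat0=pat0,
        sbp0=s1,
        dbp0=d1,
        sbp_breakpoints=sbp_pts,
        dbp_breakpoints=dbp_pts,
    )
    sbp_traj, dbp_traj = build_bp_trajectory(cfg)

    beats = build_beat_schedule(cfg)
    pat_curve = pat0 - cfg.coupling_k * (sbp_traj(beats) - s1)
    jitter = rng.normal(0, cfg.pat_jitter_sd, beats.size) if cfg.pat_jitter_sd else 0.0
    true_pat = pat_curve + jitter
    rr_floor = 60.0 / hr * (1 - cfg.rsa_amplitude)
    true_pat = np.clip(true_pat, 50.0, rr_floor * 1000.0 - 50.0)

    readings = sample_bp_readings(sbp_traj, dbp_traj, cfg, rng)
    covariates = {
        "age": float(np.clip(rng.normal(64.9, 18.1), 20, 95)),
        "sex": float(rng.random() < 0.34),
        "height": float(rng.normal(172, 10)),
        "weight": float(np.clip(rng.normal(78, 15), 40, 150)),
    }

    pat_means = {
        "beginning": pat0 - cfg.coupling_k * (s_beg - s1),
        "middle": pat0 - cfg.coupling_k * (s_mid - s1),
        "end": pat0 - cfg.coupling_k * (s_end - s1),
    }
    labels = {}
    for var, (rel1, rel2) in (("sbp", (r1_s, r2_s)), ("dbp", (r1_d, r2_d))):
        for interval, rel in zip(INTERVALS, (rel1, rel2)):
            labels[f"{var}_{interval}"] = class_label
    truth = GroundTruth(
        beat_times=beats,
        true_onset_times=beats + true_pat / 1000.0,
        true_pat=true_pat,
        sbp_curve=sbp_traj,
        dbp_curve=dbp_traj,
        class_label=labels,
        period_means={
            "sbp": dict(zip(PERIODS, (s_beg, s_mid, s_end))),
            "dbp": dict(zip(PERIODS, (d_beg, d_mid, d_end))),
            "pat": pat_means,
        },
    )

    session = SynthSession(
        session_id=session_id,
        readings=readings,
        covariates=covariates,
        ground_truth=truth,
    )
    if render:
        record, wf_truth = render_waveforms(beats, true_pat, cfg, rng)
        truth.artifacts = wf_truth.artifacts
        session.waveforms = record
    else:
        # bypass waveform synthesis: feed the true beat-level PAT through the
        # same smoother the extraction stage uses
        from .extract import smooth_hanning

        beat_series = BeatSeries(
            r_peak_times=beats,
            onset_times=beats + true_pat / 1000.0,
            pat=true_pat,
            valid=np.ones(beats.size, dtype=bool),
            reason=np.array([""] * beats.size, dtype=object),
        )
        smoothed = smooth_hanning(beat_series, window_s=smoothing_window_s)
        session.session_data = SessionData(
            session_id=session_id,
            smoothed=smoothed,
            readings=readings,
            covariates=covariates,
        )
    return session


def generate_cohort(
    n_decliner: int,
    n_stable: int,
    n_riser: int,
    config: SynthConfig | None = None,
    seed: int | None = None,
    render: bool = False,
    smoothing_window_s: float = 180.0,
) -> list[SynthSession]:
    """Generate a mixed cohort with known class composition.

    One seeded generator drives every session in order, so the cohort is
    reproducible bit-for-bit from (config, seed).
    """
    if min(n_decliner, n_stable, n_riser) < 0:
        raise ValueError("class counts must be >= 0")
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sessions = []
    plan = (
        [("decliner", i) for i in range(n_decliner)]
        + [("stable", i) for i in range(n_stable)]
        + [("riser", i) for i in range(n_riser)]
    )
    for label, i in plan:
        sid = f"{label[:3]}{i:03d}"
        sessions.append(
            generate_session(
                label, config, rng, sid, render=render,
                smoothing_window_s=smoothing_window_s,
            )
        )
    return sessions
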