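"""Beat-to-beat pulse arrival time extraction from synchronized ECG/PPG.

The stage chain is: R-peak detection (Pan-Tompkins-style), pulse-onset
detection by the intersecting-tangents method, R-peak/onset pairing into a
:class:`~patflow.core.BeatSeries`, plausibility filtering of
non-physiological beats, and smoothing with a 180-s symmetric Hanning window
to suppress respiratory sinus arrhythmia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .config import FilterBounds
from .core import BeatSeries, SmoothedPAT, WaveformRecord

__all__ = [
    "detect_r_peaks",
    "OnsetResult",
    "detect_pulse_onset",
    "compute_pat",
    "filter_nonphysiological",
    "smooth_hanning",
    "extract_beats",
]

#: rejection reasons owned by filter_nonphysiological (recomputed each call)
_FILTER_REASONS = ("rr_range", "pat_range", "pat_jump")


def detect_r_peaks(record: WaveformRecord, refractory_s: float = 0.2) -> np.ndarray:
    """Detect R-peak times with a Pan-Tompkins-style pipeline.

    Band-pass (5-15 Hz, zero-phase), differentiate, square, moving-window
    integrate (150 ms), adaptive signal/noise thresholding, then refine each
    detection to the local raw-ECG maximum.  A refractory period of
    ``refractory_s`` (default 200 ms) is enforced between detections.

    Returns times in seconds on the record's clock; an all-flat signal
    yields an empty array.  ``fs < 100`` is rejected.
    """
    if record.fs < 100:
        raise ValueError("detect_r_peaks requires fs >= 100 Hz")
    ecg = record.ecg
    if ecg.size == 0 or np.ptp(ecg) < 1e-12:
        return np.array([])
    fs = record.fs

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(filt) * fs
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(refractory_s * fs))
    cand, _ = sps.find_peaks(mwi, distance=max(1, refractory))
    if cand.size == 0:
        return np.array([])

    # adaptive signal/noise threshold in the classic running-estimate form
    init = mwi[: int(min(mwi.size, 2 * fs))]
    spki = float(np.max(init)) * 0.6
    npki = float(np.mean(init)) * 0.5
    accepted: list[int] = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            spki = 0.125 * mwi[p] + 0.875 * spki
            accepted.append(p)
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
    if not accepted:
        return np.array([])

    # refine to the local raw-ECG maximum around each integrator peak
    half = int(round(0.10 * fs))
    idx = []
    for p in accepted:
        i0, i1 = max(0, p - half), min(ecg.size, p + half + 1)
        idx.append(i0 + int(np.argmax(ecg[i0:i1])))
    idx_arr = np.unique(idx)

    # enforce the refractory period on refined positions, keeping the taller peak
    kept: list[int] = []
    for i in idx_arr:
        if kept and i - kept[-1] < refractory:
            if ecg[i] > ecg[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return record.t0 + np.array(kept, dtype=float) / fs


class OnsetResult(NamedTuple):
    """Outcome of onset detection: time (s, NaN if invalid) and failure reason."""

    time: float
    reason: str | None


def _moving_average(x: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average with edge renormalization (no zero-padding bias)."""
    if k <= 1:
        return x.astype(float)
    kernel = np.ones(k)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_pulse_onset(
    ppg_segment: np.ndarray,
    fs: float,
    search_window: tuple[float, float] | None = None,
    smooth_s: float = 0.010,
) -> OnsetResult:
    """Pulse-onset fiducial by the intersecting-tangents method.

    The onset is the abscissa where the line tangent to the waveform at the
    point of maximal systolic upstroke slope crosses the horizontal tangent
    through the diastolic minimum (the minimum preceding the steepest-ascent
    point).  The slope is estimated on the first difference of a 10-ms
    moving-average-smoothed segment, which makes the derivative robust at
    512 Hz while leaving piecewise-linear pulses exactly recoverable.

    Parameters
    ----------
    ppg_segment : array
        Samples spanning one beat, from the R-peak to before the next one.
    fs : float
        Sampling rate, Hz.
    search_window : (float, float), optional
        Restrict the steepest-ascent search to these segment-relative times.

    Returns
    -------
    OnsetResult
        ``time`` is seconds from the segment start; invalid beats carry
        ``reason`` in {'no_upstroke', 'onset_out_of_range', 'too_short'}.
    """
    x = np.asarray(ppg_segment, dtype=float)
    if x.size < 3:
        return OnsetResult(np.nan, "too_short")
    k = max(1, int(round(smooth_s * fs)))
    if k % 2 == 0:
        k += 1
    sm = _moving_average(x, k)
    slope = np.gradient(sm) * fs

    lo, hi = 0, x.size
    if search_window is not None:
        lo = max(0, int(np.floor(search_window[0] * fs)))
        hi = min(x.size, int(np.ceil(search_window[1] * fs)) + 1)
        if hi - lo < 3:
            return OnsetResult(np.nan, "too_short")
    m = lo + int(np.argmax(slope[lo:hi]))
    s_m = slope[m]
    if s_m <= 0:
        return OnsetResult(np.nan, "no_upstroke")

    y_min = float(np.min(sm[: m + 1]))
    t_m = m / fs
    t_star = t_m - (sm[m] - y_min) / s_m
    if not (0.0 <= t_star <= (x.size - 1) / fs):
        return OnsetResult(np.nan, "onset_out_of_range")
    return OnsetResult(float(t_star), None)


def compute_pat(
    r_peak_times: np.ndarray,
    onset_times: np.ndarray,
    pairing_window: float = 0.6,
) -> BeatSeries:
    """Pair each R-peak with the first pulse onset that follows it.

    A beat's effective window is ``min(next RR, pairing_window)`` — the pulse
    must arrive before the next beat's pulse.  Each onset is consumed by at
    most one beat.  Unpaired beats are flagged invalid (reason 'unpaired');
    PAT is ``(onset - r_peak) * 1000`` ms.
    """
    r = np.sort(np.asarray(r_peak_times, dtype=float))
    o = np.sort(np.asarray(onset_times, dtype=float))
    n = r.size
    onset = np.full(n, np.nan)
    pat = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    reason = np.array(["unpaired"] * n, dtype=object)
    j = 0
    for i in range(n):
        w = pairing_window
        if i + 1 < n:
            w = min(w, r[i + 1] - r[i])
        while j < o.size and o[j] <= r[i]:
            j += 1
        if j < o.size and o[j] <= r[i] + w:
            onset[i] = o[j]
            pat[i] = (o[j] - r[i]) * 1000.0
            valid[i] = True
            reason[i] = ""
            j += 1
    return BeatSeries(r, onset, pat, valid, reason)


def filter_nonphysiological(
    beats: BeatSeries, bounds: FilterBounds | None = None
) -> tuple[BeatSeries, dict[str, int]]:
    """Flag beats with implausible RR, PAT, or beat-to-beat PAT jumps.

    Checks, per beat: RR outside ``[rr_min, rr_max]`` (reason ``rr_range``),
    PAT outside ``[pat_min, pat_max]`` (``pat_range``), and deviation from the
    median of the nearest ``jump_neighbors`` range-valid beats exceeding
    ``jump_max`` ms (``pat_jump``).  Survivor values are unchanged.

    The filter's own flags are recomputed from the raw values on every call
    (flags from other sources are preserved), so applying it twice equals
    applying it once.  Returns the filtered series and removal counts per
    reason.
    """
    bounds = bounds or FilterBounds()
    out = beats.copy()
    n = out.n_beats
    base_valid = out.valid | np.isin(out.reason, _FILTER_REASONS)
    # reset this filter's previous verdicts
    out.reason[np.isin(out.reason, _FILTER_REASONS)] = ""

    rr = out.rr
    rr_bad = np.isfinite(rr) & ((rr < bounds.rr_min) | (rr > bounds.rr_max))
    pat_bad = base_valid & (
        ~np.isfinite(out.pat) | (out.pat < bounds.pat_min) | (out.pat > bounds.pat_max)
    )

    counts = {"rr_range": 0, "pat_range": 0, "pat_jump": 0}
    new_reason = np.array([""] * n, dtype=object)
    new_reason[base_valid & rr_bad] = "rr_range"
    new_reason[base_valid & pat_bad & (new_reason == "")] = "pat_range"

    # jump check among beats passing the range checks
    cand = np.flatnonzero(base_valid & ~rr_bad & ~pat_bad & np.isfinite(out.pat))
    k = bounds.jump_neighbors
    for pos, i in enumerate(cand):
        left = list(cand[max(0, pos - k) : pos])
        right = list(cand[pos + 1 : pos + 1 + k])
        neigh = sorted(left + right, key=lambda j: abs(j - i))[:k]
        if not neigh:
            continue
        med = float(np.median(out.pat[neigh]))
        if abs(out.pat[i] - med) > bounds.jump_max:
            new_reason[i] = "pat_jump"

    flagged = new_reason != ""
    for r in _FILTER_REASONS:
        counts[r] = int(np.sum(base_valid & (new_reason == r)))
    out.valid = base_valid & ~flagged
    keep_old = ~base_valid
    out.reason[~keep_old] = new_reason[~keep_old]
    return out, counts


def smooth_hanning(beats: BeatSeries, window_s: float = 180.0) -> SmoothedPAT:
    """Smooth the valid-beat PAT series with a symmetric Hanning window.

    For each valid beat at time ``t`` the smoothed value is the Hann-weighted
    mean of the valid-beat PATs within ``|t_i - t| <= window_s / 2``; the
    weights are renormalized where the window is truncated at the record
    edges, so constants are preserved exactly and a single valid beat maps to
    its raw value.  A 180-s window removes respiratory-frequency PAT
    fluctuations while tracking within-session trends.
    """
    t = beats.r_peak_times[beats.valid]
    p = beats.pat[beats.valid]
    if t.size == 0:
        return SmoothedPAT(np.array([]), np.array([]))
    half = window_s / 2.0
    out = np.empty(t.size)
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    for i in range(t.size):
        dt = t[lo[i] : hi[i]] - t[i]
        # Hann shape on [-half, half]: w(dt) = cos^2(pi dt / window_s)
        w = np.cos(np.pi * dt / window_s) ** 2
        out[i] = np.sum(w * p[lo[i] : hi[i]]) / np.sum(w)
    return SmoothedPAT(times=t.copy(), values=out)


@dataclass
class ExtractionResult:
    """Full extraction output: beat series, smoothed PAT, removal counts."""

    beats: BeatSeries
    smoothed: SmoothedPAT
    removal_counts: dict[str, int]

    @property
    def valid_fraction(self) -> float:
        n = self.beats.n_beats
        return float(np.mean(self.beats.valid)) if n else 0.0


def extract_beats(
    record: WaveformRecord,
    bounds: FilterBounds | None = None,
    window_s: float = 180.0,
    pairing_window: float = 0.6,
) -> ExtractionResult:
    """Run the full chain: R-peaks -> onsets -> PAT -> filter -> smooth."""
    r_times = detect_r_peaks(record)
    onsets: list[float] = []
    fs = record.fs
    for i, rt in enumerate(r_times):
        t_next = r_times[i + 1] if i + 1 < r_times.size else rt + pairing_window
        w = min(pairing_window, t_next - rt)
        i0 = int(round((rt - record.t0) * fs))
        i1 = min(record.n_samples, int(round((rt - record.t0 + w) * fs)) + 1)
        res = detect_pulse_onset(record.ppg[i0:i1], fs)
        if res.reason is None:
            onsets.append(rt + res.time)
    beats = compute_pat(r_times, np.array(onsets), pairing_window)
    beats, counts = filter_nonphysiological(beats, bounds)
    smoothed = smooth_hanning(beats, window_s)
    return ExtractionResult(beats=beats, smoothed=smoothed, removal_counts=counts)
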