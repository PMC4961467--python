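"""Conditioning of raw continuous signals and saccade detection.

The LFP chain reproduces the recording-side processing the analysis assumes:
line-noise notch, 42 Hz low-pass, resampling at 90 Hz and cubic oversampling
back to 1 kHz (which scrubs residual spike-waveform energy), all applied
forward-backward so the chain is zero-phase. Eye velocity is obtained with a
differentiating Savitzky-Golay filter (order 5, 25 ms window), and saccades
with an iterative adaptive velocity threshold.
"""
from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .core import EyeTrace, SaccadeEvent, TimeSeries

LFP_OUT_RATE = 1000.0  # Hz
LFP_LOWPASS_HZ = 42.0
LFP_RESAMPLE_HZ = 90.0


def condition_lfp(raw: TimeSeries, line_freq: float = 50.0) -> TimeSeries:
    """Extract the slow (< 42 Hz) LFP component at 1 kHz.

    Steps: notch at ``line_freq``, zero-phase low-pass at 42 Hz, cubic
    resampling to 90 Hz, cubic interpolation back to 1 kHz. DC is preserved.
    """
    if raw.rate < 200.0:
        raise ValueError("LFP sampling rate must be >= 200 Hz")
    # warm-up check: filtfilt needs ~3x the longest filter's impulse settling
    if raw.duration < 0.25:
        raise ValueError("signal too short")
    x = raw.samples.astype(float)
    b, a = signal.iirnotch(line_freq, Q=30.0, fs=raw.rate)
    x = signal.filtfilt(b, a, x)
    sos = signal.butter(4, LFP_LOWPASS_HZ, btype="low", fs=raw.rate, output="sos")
    x = signal.sosfiltfilt(sos, x)

    t = raw.times
    t90 = np.arange(t[0], t[-1], 1.0 / LFP_RESAMPLE_HZ)
    x90 = CubicSpline(t, x)(t90)
    t1k = np.arange(t[0], t90[-1], 1.0 / LFP_OUT_RATE)
    x1k = CubicSpline(t90, x90)(t1k)
    return TimeSeries(x1k, LFP_OUT_RATE, t0=t[0])


def compute_eye_velocity(
    eye: EyeTrace, window_ms: float = 25.0, polyorder: int = 5
) -> TimeSeries:
    """Eye velocity (deg/s) via a differentiating Savitzky-Golay filter.

    Returns a 2-vector TimeSeries with columns (horizontal, vertical).
    """
    if eye.rate < 500.0:
        raise ValueError("eye sampling rate must be >= 500 Hz")
    win = int(round(window_ms * 1e-3 * eye.rate))
    if win % 2 == 0:
        win += 1
    if win <= polyorder:
        win = polyorder + 2 if (polyorder + 2) % 2 == 1 else polyorder + 3
    n = len(eye.horizontal)
    if win > n:
        raise ValueError("Savitzky-Golay window longer than the trace")
    cols = []
    for comp in (eye.horizontal, eye.vertical):
        v = signal.savgol_filter(
            comp.samples, win, polyorder, deriv=1, delta=1.0 / eye.rate
        )
        cols.append(v)
    return TimeSeries(np.column_stack(cols), eye.rate, t0=eye.t0)


def eye_speed(velocity: TimeSeries) -> TimeSeries:
    """Euclidean norm of a 2-vector velocity trace (deg/s)."""
    if velocity.samples.ndim != 2:
        raise ValueError("expected a 2-vector velocity trace")
    return TimeSeries(
        np.linalg.norm(velocity.samples, axis=1), velocity.rate, velocity.t0
    )


def _adaptive_threshold(speed: np.ndarray, init: float = 100.0) -> float:
    """Iterate T = mean + 6*SD of sub-threshold samples until |dT| < 1 deg/s."""
    T = init
    for _ in range(200):
        sub = speed[speed < T]
        if len(sub) < 2:
            break
        Tn = sub.mean() + 6.0 * sub.std()
        if abs(Tn - T) < 1.0:
            T = Tn
            break
        T = Tn
    return T


def detect_saccades(
    speed: TimeSeries,
    eye: EyeTrace | None = None,
    min_duration_ms: float = 10.0,
    merge_gap_ms: float = 20.0,
    init_threshold: float = 100.0,
) -> list[SaccadeEvent]:
    """Detect saccades from eye speed with an iterative adaptive threshold.

    Events are contiguous supra-threshold runs extended outward to the nearest
    local speed minima; runs shorter than ``min_duration_ms`` are dropped and
    runs separated by less than ``merge_gap_ms`` merged. When an ``eye`` trace
    is supplied, direction and amplitude come from the net positional
    displacement over the event; otherwise the angle is 0 and the amplitude is
    the integral of speed.
    """
    s = speed.samples
    T = _adaptive_threshold(s, init_threshold)
    above = s > T
    if not above.any():
        return []
    # contiguous supra-threshold runs
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(s))
    runs = []
    for i0, i1 in zip(starts, ends):
        # extend to nearest local minima
        while i0 > 0 and s[i0 - 1] < s[i0]:
            i0 -= 1
        while i1 < len(s) and s[i1] < s[i1 - 1]:
            i1 += 1
        runs.append([i0, i1])
    # merge runs closer than the merge gap
    gap = int(round(merge_gap_ms * 1e-3 * speed.rate))
    merged = [runs[0]]
    for r in runs[1:]:
        if r[0] - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], r[1])
        else:
            merged.append(r)
    min_len = int(round(min_duration_ms * 1e-3 * speed.rate))
    events: list[SaccadeEvent] = []
    for i0, i1 in merged:
        if i1 - i0 < min_len:
            continue
        onset = speed.t0 + i0 / speed.rate
        offset = speed.t0 + i1 / speed.rate
        if eye is not None:
            j0 = eye.horizontal.index_of(onset)
            j1 = eye.horizontal.index_of(offset)
            dx = eye.horizontal.samples[j1] - eye.horizontal.samples[j0]
            dy = eye.vertical.samples[j1] - eye.vertical.samples[j0]
            theta = np.degrees(np.arctan2(dy, dx)) % 360.0
            amp = float(np.hypot(dx, dy))
        else:
            theta = 0.0
            amp = float(np.sum(s[i0:i1]) / speed.rate)
        events.append(
            SaccadeEvent(
                onset=onset,
                offset=offset,
                angle_theta=theta,
                amplitude=amp,
                peak_speed=float(s[i0:i1].max()),
            )
        )
    return events
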