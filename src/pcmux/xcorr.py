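"""Shift-corrected cross-correlation functions (CCF / STA), directional
variants, the noise-to-signal ratio of direction tuning, and onset-triggered
averages.

The CCF between signals x and y is

    CCF(t) = (1/Z) sum_s x(s+t) y(s)  -  (1/M) sum_m (1/Z) sum_s x(s+t) y(s + m*T)

where the second term (the "shift predictor") estimates the chance baseline
from M copies of y time-shifted by multiples of T. Shifts wrap around the
recording, so a single FFT cross-correlation provides both the raw term and
every control exactly. Two normalizations are supported: "ccf"
(Z = sqrt(Var x * Var y) * L, both signals continuous) and "sta"
(Z = sqrt(Var x) * N_spike, y a spike train binned at the sample width), in
which case the result is the shift-corrected spike-triggered average of the
normalized x.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .core import SpikeTrain, TimeSeries, circ_distance_deg

DEFAULT_T = 1.0  # s, shift period
DEFAULT_M_SHIFT = 200
ANGLES_8 = np.arange(0.0, 360.0, 45.0)


@dataclass
class CCFResult:
    """Lag grid (ms), shift-corrected values and the control ensemble stats."""

    lags_ms: np.ndarray
    value: np.ndarray
    control_mean: np.ndarray
    control_sd: np.ndarray
    normalization: str
    n_shifts: int
    # raw circular correlation divided by Z, full length; kept so controls at
    # arbitrary extra shifts can be read without recomputation
    _raw_over_z: np.ndarray | None = field(default=None, repr=False)
    _rate: float = field(default=1000.0, repr=False)
    _T: float = field(default=DEFAULT_T, repr=False)


@dataclass
class DirectionalCCF:
    """One shift-corrected CCF per rectified eye-velocity direction."""

    angles: np.ndarray  # degrees
    lags_ms: np.ndarray
    ccf_matrix: np.ndarray  # (n_angles, n_lags)
    results: list[CCFResult] = field(default=None, repr=False)  # type: ignore


def _aligned_pair(x: TimeSeries, y) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Return x samples, y samples (spikes binned), spike count, on x's grid."""
    xs = x.samples
    if xs.ndim != 1:
        raise ValueError("x must be a 1-D continuous signal")
    if isinstance(y, SpikeTrain):
        ys = y.binned(x.rate, len(xs), t0=x.t0)
        n_spk = int(ys.sum())
        return xs, ys, x.rate, n_spk
    if isinstance(y, TimeSeries):
        if y.rate != x.rate:
            raise ValueError("x and y must share the sampling rate")
        n = min(len(xs), len(y.samples))
        return xs[:n], y.samples[:n], x.rate, 0
    raise TypeError("y must be a TimeSeries or SpikeTrain")


def _circular_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """C[k] = sum_s x[(s+k) mod L] * y[s], k = 0..L-1."""
    fx = np.fft.rfft(x)
    fy = np.fft.rfft(y)
    return np.fft.irfft(fx * np.conj(fy), n=len(x))


def shift_corrected_ccf(
    x: TimeSeries,
    y,
    normalization: str = "ccf",
    T: float = DEFAULT_T,
    M_shift: int = DEFAULT_M_SHIFT,
    max_lag_ms: float = 300.0,
) -> CCFResult:
    """Shift-corrected CCF between a continuous signal x and y (continuous or
    spike train), on lags -max_lag..+max_lag ms.

    Positive lag means a feature of x occurs *after* y.
    """
    xs, ys, rate, n_spk = _aligned_pair(x, y)
    ys = ys[: len(xs)]
    xs = xs[: len(ys)]
    L = len(xs)
    if M_shift * T >= L / rate:
        raise ValueError("M_shift * T exceeds the signal length")
    var_x = xs.var()
    if var_x <= 0:
        raise ValueError("zero-variance x")
    if normalization == "ccf":
        var_y = ys.var()
        if var_y <= 0:
            raise ValueError("zero-variance y")
        Z = np.sqrt(var_x * var_y) * L
    elif normalization == "sta":
        if n_spk == 0:
            n_spk = max(int(round(ys.sum())), 1)
        Z = np.sqrt(var_x) * n_spk
    else:
        raise ValueError("normalization must be 'ccf' or 'sta'")

    C = _circular_corr(xs, ys) / Z
    n_lag = int(round(max_lag_ms * 1e-3 * rate))
    if n_lag >= L // 2:
        raise ValueError("lag window too wide for the signal")
    lags = np.arange(-n_lag, n_lag + 1)
    raw = C[lags % L]

    T_samp = int(round(T * rate))
    shifts = (np.arange(1, M_shift + 1) * T_samp)[:, None]
    controls = C[(lags[None, :] + shifts) % L]  # (M, n_lags)
    cmean = controls.mean(axis=0)
    csd = controls.std(axis=0, ddof=1)
    return CCFResult(
        lags_ms=lags * 1000.0 / rate,
        value=raw - cmean,
        control_mean=cmean,
        control_sd=csd,
        normalization=normalization,
        n_shifts=M_shift,
        _raw_over_z=C,
        _rate=rate,
        _T=T,
    )


def ccf_significance(
    ccf: CCFResult, window_ms: tuple[float, float] = (-100.0, 100.0), level: float = 0.01
) -> dict:
    """One-sided empirical test of whether the CCF departs from baseline.

    The statistic is max |value| / control_sd over the lag window; its null
    distribution is taken from the shift-predictor controls themselves, which
    handles the multiplicity of lags without a parametric correction.
    """
    m = (ccf.lags_ms >= window_ms[0]) & (ccf.lags_ms <= window_ms[1])
    if not m.any():
        raise ValueError("window outside the lag range")
    sd = np.where(ccf.control_sd[m] > 0, ccf.control_sd[m], np.inf)
    obs = float(np.max(np.abs(ccf.value[m]) / sd))
    if ccf._raw_over_z is None:
        # fall back to a t-score interpretation against the control SD
        p = float(sstats.norm.sf(obs))
        return {"t_score_max": obs, "p": p, "significant": p < level}
    C = ccf._raw_over_z
    L = len(C)
    rate = ccf._rate
    lags = np.round(ccf.lags_ms[m] * 1e-3 * rate).astype(int)
    T_samp = int(round(ccf._T * rate))
    null = []
    for k in range(1, ccf.n_shifts + 1):
        ctrl = C[(lags + k * T_samp) % L]
        null.append(np.max(np.abs(ctrl - ccf.control_mean[m]) / sd))
    null = np.asarray(null)
    p = (1.0 + np.sum(null >= obs)) / (1.0 + len(null))
    return {"t_score_max": obs, "p": float(p), "significant": bool(p < level)}


def rectified_projection(eyevel: TimeSeries, angle_deg: float) -> TimeSeries:
    """v_theta = max(0, v . e_theta): eye speed along one direction."""
    if eyevel.samples.ndim != 2 or eyevel.samples.shape[1] != 2:
        raise ValueError("eyevel must be a 2-vector TimeSeries")
    th = np.radians(angle_deg)
    proj = eyevel.samples @ np.array([np.cos(th), np.sin(th)])
    return TimeSeries(np.maximum(proj, 0.0), eyevel.rate, eyevel.t0)


def directional_ccf(
    sig,
    eyevel: TimeSeries,
    angles: np.ndarray = ANGLES_8,
    T: float = DEFAULT_T,
    M_shift: int = DEFAULT_M_SHIFT,
    max_lag_ms: float = 300.0,
) -> DirectionalCCF:
    """One shift-corrected CCF per rectified eye-velocity direction.

    ``sig`` may be a continuous TimeSeries (ccf normalization, x = sig) or a
    SpikeTrain (sta normalization, x = v_theta, y = the binned train).
    """
    rows, results = [], []
    n_lag = int(round(max_lag_ms * 1e-3 * eyevel.rate))
    lags = np.arange(-n_lag, n_lag + 1) * 1000.0 / eyevel.rate
    for a in np.asarray(angles, float):
        v = rectified_projection(eyevel, a)
        if v.samples.var() == 0:
            # no motion along this direction: flat zero CCF by convention
            z = np.zeros_like(lags)
            r = CCFResult(lags, z, z, z, "ccf", M_shift, _rate=eyevel.rate)
        elif isinstance(sig, SpikeTrain):
            r = shift_corrected_ccf(v, sig, "sta", T, M_shift, max_lag_ms)
        else:
            r = shift_corrected_ccf(sig, v, "ccf", T, M_shift, max_lag_ms)
        rows.append(r.value)
        results.append(r)
        lags = r.lags_ms
    return DirectionalCCF(
        angles=np.asarray(angles, float),
        lags_ms=lags,
        ccf_matrix=np.vstack(rows),
        results=results,
    )


def nsr(d: DirectionalCCF) -> float:
    """Noise-to-signal ratio of direction tuning:
    Tr Cov[CCF rows] / ||mean row||^2. 0 when all rows are identical; grows
    with across-direction variability of the CCF."""
    M = np.asarray(d.ccf_matrix, float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 angle rows")
    mean_row = M.mean(axis=0)
    denom = float(np.sum(mean_row**2))
    if denom == 0:
        raise ValueError("undefined NSR")
    tr_cov = float(np.sum(M.var(axis=0, ddof=0)))
    return tr_cov / denom


def _control_nsrs(d: DirectionalCCF, n_controls: int, T: float) -> np.ndarray:
    """Sampling variability of the observed NSR: each control adds one
    realization of shift-predictor noise (a time-shifted CCF minus the
    control mean, read from the cached circular correlations) onto the
    observed CCF rows and recomputes the NSR."""
    cached = [r for r in (d.results or []) if r._raw_over_z is not None]
    if not cached:
        raise ValueError("directional CCF lacks cached correlations")
    rate = cached[0]._rate
    L = len(cached[0]._raw_over_z)
    lags = np.round(d.lags_ms * 1e-3 * rate).astype(int)
    T_samp = int(round(T * rate))
    base_shift = (d.results[0].n_shifts + 2) * T_samp  # avoid the predictor's own shifts
    out = []
    for k in range(1, n_controls + 1):
        rows = []
        for r in d.results:
            if r._raw_over_z is None:
                rows.append(r.value)
                continue
            ctrl = r._raw_over_z[(lags + base_shift + k * T_samp) % L]
            rows.append(r.value + (ctrl - r.control_mean))
        out.append(nsr(DirectionalCCF(d.angles, d.lags_ms, np.vstack(rows))))
    return np.asarray(out)


def nsr_compare(
    sig_a,
    sig_b,
    eyevel: TimeSeries,
    n_controls: int = 200,
    T: float = DEFAULT_T,
    M_shift: int = 50,
    max_lag_ms: float = 300.0,
    level: float = 0.05,
) -> dict:
    """t-test for a difference in direction-tuning NSR between two signals.

    The NSR variance under the null comes from time-shifted control CCFs.
    Returns the three-way classification: 'a_more', 'a_less' or 'none'.
    """
    da = directional_ccf(sig_a, eyevel, T=T, M_shift=M_shift, max_lag_ms=max_lag_ms)
    db = directional_ccf(sig_b, eyevel, T=T, M_shift=M_shift, max_lag_ms=max_lag_ms)
    na, nb = nsr(da), nsr(db)
    ca = _control_nsrs(da, n_controls, T)
    cb = _control_nsrs(db, n_controls, T)
    va, vb = ca.var(ddof=1), cb.var(ddof=1)
    if va + vb <= 0:
        raise ValueError("degenerate controls")
    t = (na - nb) / np.sqrt(va + vb)
    p = 2.0 * float(sstats.norm.sf(abs(t)))
    if p < level:
        direction = "a_more" if na > nb else "a_less"
    else:
        direction = "none"
    return {"nsr_a": na, "nsr_b": nb, "t": float(t), "p": p, "direction": direction}


def onset_triggered_average(
    sig: TimeSeries,
    saccades,
    bin_by: str = "theta",
    bin_centers: np.ndarray | None = None,
    half_width: float | None = None,
    window_ms: tuple[float, float] = (-100.0, 300.0),
    normalize: bool = False,
) -> dict:
    """Saccade-onset-aligned averages of a signal in sliding parameter bins.

    ``bin_by='theta'`` averages saccades with direction within +-45 deg of
    each bin center (circular); ``bin_by='duration'`` uses +-4 ms around each
    duration center. ``normalize`` divides by the signal's SD. Empty bins are
    returned as NaN waveforms and flagged.
    """
    i0 = int(round(window_ms[0] * 1e-3 * sig.rate))
    i1 = int(round(window_ms[1] * 1e-3 * sig.rate))
    lags_ms = np.arange(i0, i1 + 1) * 1000.0 / sig.rate
    if bin_by == "theta":
        centers = ANGLES_8 if bin_centers is None else np.asarray(bin_centers, float)
        hw = 45.0 if half_width is None else half_width
        keys = np.array([s.angle_theta for s in saccades])
    elif bin_by == "duration":
        durs = np.array([s.duration_L for s in saccades])
        if bin_centers is None:
            centers = np.linspace(durs.min(), durs.max(), 9) if len(durs) else np.array([])
        else:
            centers = np.asarray(bin_centers, float)
        hw = 4.0 if half_width is None else half_width
        keys = durs
    else:
        raise ValueError("bin_by must be 'theta' or 'duration'")

    snippets, onsets_idx = [], []
    for s in saccades:
        j = sig.index_of(s.onset)
        if j + i0 < 0 or j + i1 + 1 > len(sig.samples):
            snippets.append(None)
            continue
        snippets.append(sig.samples[j + i0 : j + i1 + 1])
    scale = sig.samples.std() if normalize else 1.0
    if normalize and scale == 0:
        raise ValueError("zero-variance signal cannot be normalized")

    mat = np.full((len(centers), len(lags_ms)), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for b, c in enumerate(centers):
        if bin_by == "theta":
            sel = np.abs(circ_distance_deg(keys, c)) <= hw
        else:
            sel = np.abs(keys - c) <= hw
        chunk = [snippets[i] for i in np.where(sel)[0] if snippets[i] is not None]
        counts[b] = len(chunk)
        if chunk:
            mat[b] = np.mean(chunk, axis=0) / scale
    return {
        "bin_centers": centers,
        "lags_ms": lags_ms,
        "matrix": mat,
        "counts": counts,
        "empty_bins": np.where(counts == 0)[0],
    }


def subset_ccf_similarity(full: DirectionalCCF, subset: DirectionalCCF) -> float:
    """Pearson correlation between two directional CCFs, rows concatenated."""
    a = np.asarray(full.ccf_matrix, float).ravel()
    b = np.asarray(subset.ccf_matrix, float).ravel()
    if a.shape != b.shape:
        raise ValueError("directional CCF shapes differ")
    return float(np.corrcoef(a, b)[0, 1])
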