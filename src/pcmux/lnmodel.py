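"""Eye-motion-to-rate inverse model (linear-nonlinear).

The model predicts the firing rate from the history of eye velocity: the
rectified velocity in four directions (0, 90, 180, 270 deg) is filtered by a
motion feature f (one kernel per direction, lags -300..+300 ms) estimated
from the shift-corrected spike-triggered average of each rectified component;
their sum, affinely calibrated against the observed smoothed rate, is the
linear prediction m(t); a binned, isotonic-smoothed map m -> rate is the
static nonlinearity P(spike|m).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .core import SpikeTrain, TimeSeries
from .xcorr import rectified_projection, shift_corrected_ccf

LN_DIRECTIONS = np.array([0.0, 90.0, 180.0, 270.0])
LN_LAG_MS = 300.0


@dataclass
class MotionFeature:
    """STA kernels of rectified eye velocity, one per direction."""

    directions: np.ndarray  # degrees
    lags_ms: np.ndarray  # symmetric about 0
    kernels: np.ndarray  # (n_dir, n_lags)
    scale: float = 1.0  # (spikes/s) calibration gain
    baseline: float = 0.0  # spikes/s
    control_sd: np.ndarray | None = None  # shift-predictor SD per kernel sample
    low_n_warning: bool = False


@dataclass
class LNModel:
    feature: MotionFeature
    nl_bin_centers: np.ndarray = field(default=None)  # type: ignore
    nl_values: np.ndarray = field(default=None)  # type: ignore
    r2_linear: float = np.nan


def smoothed_rate(
    train: SpikeTrain, rate: float, n_samples: int, t0: float, sigma: float = 0.010
) -> np.ndarray:
    """Observed firing rate (spikes/s) via Gaussian kernel smoothing."""
    counts = train.binned(rate, n_samples, t0)
    k = int(round(4 * sigma * rate))
    x = np.arange(-k, k + 1) / rate
    kern = np.exp(-0.5 * (x / sigma) ** 2)
    kern /= kern.sum() / rate  # unit area in time -> spikes/s
    return np.convolve(counts, kern, mode="same")


def estimate_motion_feature(
    eyevel: TimeSeries,
    train: SpikeTrain,
    directions: np.ndarray = LN_DIRECTIONS,
    lag_ms: float = LN_LAG_MS,
    T: float = 1.0,
    M_shift: int = 100,
) -> MotionFeature:
    """Motion feature from shift-corrected STAs of rectified eye velocity.

    A motion-independent cell yields kernels fluctuating around zero because
    the shift predictor removes the velocity's own baseline.
    """
    rows, sds, lags = [], [], None
    for a in directions:
        v = rectified_projection(eyevel, a)
        r = shift_corrected_ccf(
            v, train, normalization="sta", T=T, M_shift=M_shift, max_lag_ms=lag_ms
        )
        rows.append(r.value)
        sds.append(r.control_sd)
        lags = r.lags_ms
    return MotionFeature(
        directions=np.asarray(directions, float),
        lags_ms=lags,
        kernels=np.vstack(rows),
        control_sd=np.vstack(sds),
        low_n_warning=len(train) < 500,
    )


def linear_prediction(feature: MotionFeature, eyevel: TimeSeries) -> TimeSeries:
    """m(t) = baseline + scale * sum_dirs (f_theta correlated with v_theta).

    The kernel lag convention matches the STA: f(tau) is the average velocity
    at spike time + tau, so the prediction at t reads the velocity forward,
    m(t) ~ sum_tau f(tau) v(t + tau).
    """
    n_lag = (len(feature.lags_ms) - 1) // 2
    m = np.zeros(len(eyevel.samples))
    for a, k in zip(feature.directions, feature.kernels):
        v = rectified_projection(eyevel, a).samples
        # correlation: out[t] = sum_tau k[tau] * v[t + tau - n_lag .. ]
        m += np.correlate(v, k, mode="same")
    return TimeSeries(feature.baseline + feature.scale * m, eyevel.rate, eyevel.t0)


def estimate_nonlinearity(
    m: np.ndarray, observed_rate: np.ndarray, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned conditional mean rate given m, isotonic-smoothed.

    Returns (bin_centers, map_values, transformed_prediction). Empty bins are
    linearly interpolated from their neighbors.
    """
    m = np.asarray(m, float)
    r = np.asarray(observed_rate, float)
    edges = np.linspace(m.min(), m.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(m, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=r, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    vals = np.full(n_bins, np.nan)
    nz = cnts > 0
    vals[nz] = sums[nz] / cnts[nz]
    if (~nz).any():
        vals[~nz] = np.interp(centers[~nz], centers[nz], vals[nz])
    vals = IsotonicRegression(increasing=True, out_of_bounds="clip").fit_transform(
        centers, vals
    )
    transformed = np.interp(m, centers, vals)
    return centers, vals, transformed


def goodness_of_fit(prediction: np.ndarray, observed_rate: np.ndarray) -> float:
    """Coefficient of determination R^2 of the prediction against the rate,
    sample by sample over the session."""
    p = np.asarray(prediction, float)
    r = np.asarray(observed_rate, float)
    ss_tot = np.sum((r - r.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance rate")
    return float(1.0 - np.sum((r - p) ** 2) / ss_tot)


def linearity_r2(m: np.ndarray, observed_rate: np.ndarray, n_bins: int = 50) -> float:
    """R^2 of the predicted-vs-measured rate relation on binned means.

    The observed rate is averaged within bins of the linear prediction m and
    compared with the per-bin mean prediction (the identity line of a
    predicted-vs-measured scatter). Averaging within bins removes the shot
    noise of the kernel-smoothed rate, so the statistic measures how linear
    the rate code is rather than how noisy the spike count is — and is stable
    under random subsampling of the train (with the rate rescaled).
    """
    m = np.asarray(m, float)
    r = np.asarray(observed_rate, float)
    edges = np.linspace(m.min(), m.max(), n_bins + 1)
    idx = np.clip(np.digitize(m, edges) - 1, 0, n_bins - 1)
    cnt = np.bincount(idx, minlength=n_bins)
    ok = cnt > 0
    r_b = np.bincount(idx, weights=r, minlength=n_bins)[ok] / cnt[ok]
    m_b = np.bincount(idx, weights=m, minlength=n_bins)[ok] / cnt[ok]
    w = cnt[ok].astype(float)
    r_mean = np.average(r_b, weights=w)
    ss_tot = np.sum(w * (r_b - r_mean) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance rate")
    return float(1.0 - np.sum(w * (r_b - m_b) ** 2) / ss_tot)


def fit_ln_model(
    eyevel: TimeSeries,
    train: SpikeTrain,
    sigma: float = 0.010,
    n_bins: int = 50,
    rate_scale: float = 1.0,
    M_shift: int = 100,
) -> LNModel:
    """Full LN identification: feature -> calibrated linear prediction m ->
    binned nonlinearity. ``rate_scale`` rescales the observed rate (used to
    compensate subsampled spike categories)."""
    feature = estimate_motion_feature(eyevel, train, M_shift=M_shift)
    obs = rate_scale * smoothed_rate(
        train, eyevel.rate, len(eyevel.samples), eyevel.t0, sigma
    )
    raw = linear_prediction(feature, eyevel).samples
    # affine calibration of the raw filtered sum to spikes/s (least squares)
    A = np.column_stack([raw, np.ones_like(raw)])
    coef, *_ = np.linalg.lstsq(A, obs, rcond=None)
    feature.scale = float(coef[0])
    feature.baseline = float(coef[1])
    m = feature.baseline + feature.scale * raw
    r2 = linearity_r2(m, obs, n_bins)
    centers, vals, _ = estimate_nonlinearity(m, obs, n_bins)
    return LNModel(
        feature=feature, nl_bin_centers=centers, nl_values=vals, r2_linear=r2
    )


def subset_rate_model(
    train: SpikeTrain,
    category_masks: dict[str, np.ndarray],
    eyevel: TimeSeries,
    sigma: float = 0.010,
    min_spikes: int = 100,
    M_shift: int = 100,
) -> dict:
    """LN pipeline per spike category, with the category rate rescaled by
    N_all / N_category to compensate for subsampling. Returns per-category
    R^2 (linear) and a too-small flag."""
    n_all = len(train)
    out = {}
    for name, mask in category_masks.items():
        n = int(np.asarray(mask).sum())
        if n < min_spikes:
            out[name] = {"r2": np.nan, "n": n, "too_small": True}
            continue
        sub = train.subset(np.asarray(mask))
        model = fit_ln_model(
            eyevel, sub, sigma=sigma, rate_scale=n_all / n, M_shift=M_shift
        )
        out[name] = {"r2": model.r2_linear, "n": n, "too_small": False, "model": model}
    return out
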