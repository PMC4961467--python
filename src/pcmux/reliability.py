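"""Cross-saccade reliability of the LFP phase and of spike timing.

R_LFP is the time-averaged across-trial mean resultant length of the
beta/gamma LFP phase aligned to saccade onsets. R_spike follows the
unitary-events logic: coincidences (|dt| <= 3 ms) between every pair of
trial spike trains are counted in a 50 ms moving window, compared with the
rate-based expectation, and the Poisson tail probability jp(t) flags windows
with significantly many coincidences; R_spike is the fraction of all
coincidences that fall in such windows.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .core import SpikeTrain, TimeSeries
from .phase import PhaseSeries

WINDOW_DEFAULT = (-0.100, 0.150)  # s, [T_b, T_e]


def align_phase_traces(
    phase: PhaseSeries, onsets: np.ndarray, t_b: float = -0.100, t_e: float = 0.150
) -> np.ndarray:
    """Per-saccade phase snippets over [T_b, T_e]; trials whose window falls
    outside the recording are dropped."""
    i0 = int(round(t_b * phase.rate))
    i1 = int(round(t_e * phase.rate))
    rows = []
    for t in np.asarray(onsets, float):
        j = int(round((t - phase.t0) * phase.rate))
        if j + i0 < 0 or j + i1 + 1 > len(phase.phase):
            continue
        rows.append(phase.phase[j + i0 : j + i1 + 1])
    if not rows:
        raise ValueError("no saccade window fits inside the recording")
    return np.vstack(rows)


def lfp_phase_reliability(phase_traces: np.ndarray) -> tuple[float, np.ndarray]:
    """R_LFP and Z(t) from onset-aligned phase traces (trials x time).

    Z(t) is the modulus of the across-trial mean unit phasor; R_LFP is its
    time average over the window.
    """
    traces = np.asarray(phase_traces, float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 aligned phase traces")
    Z = np.abs(np.exp(1j * traces).mean(axis=0))
    return float(Z.mean()), Z


def r_lfp_significance(
    phase: PhaseSeries,
    onsets: np.ndarray,
    n_controls: int = 200,
    t_b: float = -0.100,
    t_e: float = 0.150,
    shift_T: float = 1.0,
    seed: int = 0,
) -> dict:
    """One-sided t-test of R_LFP against time-shifted control alignments."""
    traces = align_phase_traces(phase, onsets, t_b, t_e)
    r_obs, _ = lfp_phase_reliability(traces)
    duration = len(phase.phase) / phase.rate
    rng = np.random.default_rng(seed)
    ctrl = []
    for k in range(1, n_controls + 1):
        shift = k * shift_T + rng.uniform(0, shift_T)
        shifted = phase.t0 + (np.asarray(onsets) - phase.t0 + shift) % duration
        try:
            tr = align_phase_traces(phase, shifted, t_b, t_e)
        except ValueError:
            continue
        ctrl.append(lfp_phase_reliability(tr)[0])
    ctrl = np.asarray(ctrl)
    sd = ctrl.std(ddof=1)
    if sd == 0:
        return {"r_lfp": r_obs, "p": np.nan, "degenerate_controls": True}
    t = (r_obs - ctrl.mean()) / sd
    return {
        "r_lfp": r_obs,
        "t": float(t),
        "p": float(sstats.norm.sf(t)),
        "degenerate_controls": False,
    }


def coincidence_counts(
    trials: list[np.ndarray],
    t_grid: np.ndarray,
    window: float = 0.050,
    delta: float = 0.003,
    bin_width: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical and expected pairwise coincidence counts in a moving window.

    ``trials`` are spike-time arrays relative to saccade onset, discretized
    to ``bin_width`` bins. For each window center t, n_emp sums, over all
    trial pairs i<j, the spike pairs with |t_i - t_j| <= delta whose midpoint
    lies in [t - W/2, t + W/2]; n_exp is the rate-based expectation
    sum_pairs n_i * n_j * (2*delta + bin) / W (the bin term reflects the
    discretization: |dt| <= delta spans 2*delta/bin + 1 bin offsets).
    """
    if len(trials) < 2:
        raise ValueError("need >= 2 trials")
    t_grid = np.asarray(t_grid, float)
    n_emp = np.zeros(len(t_grid))
    n_exp = np.zeros(len(t_grid))
    half = window / 2.0
    trials = [
        np.sort(np.round(np.asarray(t, float) / bin_width) * bin_width)
        for t in trials
    ]
    p_coin = (2.0 * delta + bin_width) / window
    delta = delta + 1e-9  # guard float round-off at exact-delta differences
    for i in range(len(trials)):
        a = trials[i]
        for j in range(i + 1, len(trials)):
            b = trials[j]
            if len(a) and len(b):
                # all coincident pairs between the two trains
                lo = np.searchsorted(b, a - delta, side="left")
                hi = np.searchsorted(b, a + delta, side="right")
                mids = [
                    (a[k] + b[m]) / 2.0
                    for k in range(len(a))
                    for m in range(lo[k], hi[k])
                ]
                mids = np.asarray(mids)
            else:
                mids = np.empty(0)
            for w, t in enumerate(t_grid):
                if len(mids):
                    n_emp[w] += np.count_nonzero(np.abs(mids - t) <= half)
                na = np.count_nonzero(np.abs(a - t) <= half) if len(a) else 0
                nb = np.count_nonzero(np.abs(b - t) <= half) if len(b) else 0
                n_exp[w] += na * nb * p_coin
    return n_emp, n_exp


def jp(n_emp: float, n_exp: float, mode: str = "tail") -> float:
    """Probability of observing >= n_emp coincidences under Poisson(n_exp).

    ``mode='tail'`` (default) is the upper tail P(N >= n_emp). ``'literal'``
    evaluates the historical printed sum sum_{r<=n_emp} n_emp^r/r! e^{-n_exp}
    kept for replication only.
    """
    if n_emp < 0 or n_exp < 0:
        raise ValueError("counts must be nonnegative")
    k = int(np.floor(n_emp))
    if mode == "tail":
        return float(sstats.poisson.sf(k - 1, n_exp))
    if mode == "literal":
        r = np.arange(0, k + 1)
        from scipy.special import gammaln

        return float(np.exp(-n_exp) * np.exp(r * np.log(max(n_emp, 1e-300)) - gammaln(r + 1)).sum())
    raise ValueError("mode must be 'tail' or 'literal'")


def spike_reliability(n_emp: np.ndarray, jp_of_t: np.ndarray, level: float = 0.05) -> float:
    """R_spike: fraction of coincidences lying in windows with jp < level."""
    n_emp = np.asarray(n_emp, float)
    total = n_emp.sum()
    if total == 0:
        return 0.0
    return float(n_emp[np.asarray(jp_of_t) < level].sum() / total)


def unitary_events(
    trials: list[np.ndarray],
    t_b: float = -0.100,
    t_e: float = 0.150,
    window: float = 0.050,
    delta: float = 0.003,
    step: float = 0.001,
) -> dict:
    """Full unitary-event analysis: n_emp(t), n_exp(t), jp(t) and R_spike."""
    t_grid = np.arange(t_b, t_e + step / 2, step)
    n_emp, n_exp = coincidence_counts(trials, t_grid, window, delta)
    jp_t = np.array([jp(ne, nx) for ne, nx in zip(n_emp, n_exp)])
    return {
        "t": t_grid,
        "n_emp": n_emp,
        "n_exp": n_exp,
        "jp": jp_t,
        "r_spike": spike_reliability(n_emp, jp_t),
    }


def peri_saccade_zscore(
    train: SpikeTrain,
    onsets: np.ndarray,
    sigma: float = 0.005,
    n_controls: int = 200,
    t_b: float = -0.100,
    t_e: float = 0.150,
    rate: float = 1000.0,
    control_mode: str = "time_shifted",
    shift_T: float = 1.0,
    seed: int = 0,
) -> dict:
    """Z-score of onset-aligned firing probability vs randomized controls.

    The spike probability per 1 ms bin, averaged over saccades and smoothed
    with a Gaussian kernel (sigma = 5 ms by default), is compared against
    ``n_controls`` time-shifted versions of the train. Reports the z trace,
    the peak z, its timing and an empirical p-value.
    """
    onsets = np.asarray(onsets, float)
    if len(onsets) == 0:
        raise ValueError("no saccades")
    duration = train.times[-1] - train.times[0]
    t0 = train.times[0]
    grid = np.arange(t_b, t_e + 0.5 / rate, 1.0 / rate)

    def aligned_prob(times: np.ndarray) -> np.ndarray:
        counts = np.zeros(len(grid))
        n_tr = 0
        for on in onsets:
            rel = times - on
            sel = rel[(rel >= t_b - 4 * sigma) & (rel <= t_e + 4 * sigma)]
            idx = np.round((sel - t_b) * rate).astype(int)
            idx = idx[(idx >= 0) & (idx < len(grid))]
            np.add.at(counts, idx, 1.0)
            n_tr += 1
        p = counts / max(n_tr, 1)
        k = int(round(4 * sigma * rate))
        x = np.arange(-k, k + 1) / rate
        kern = np.exp(-0.5 * (x / sigma) ** 2)
        kern /= kern.sum()
        return np.convolve(p, kern, mode="same")

    obs = aligned_prob(train.times)
    rng = np.random.default_rng(seed)
    ctrl = np.empty((n_controls, len(grid)))
    for k in range(n_controls):
        if control_mode == "time_shifted":
            shift = (k + 1) * shift_T + rng.uniform(0, shift_T)
            shifted = t0 + (train.times - t0 + shift) % duration
            shifted = np.sort(shifted)
        else:  # rate_matched: shuffle ISIs
            isis = rng.permutation(np.diff(train.times))
            shifted = t0 + np.concatenate([[0.0], np.cumsum(isis)])
        ctrl[k] = aligned_prob(shifted)
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (obs - mu) / sd
    peak_i = int(np.argmax(np.abs(z)))
    zc = (ctrl - mu) / sd
    null_max = np.max(np.abs(zc), axis=1)
    p = (1.0 + np.sum(null_max >= abs(z[peak_i]))) / (1.0 + n_controls)
    return {
        "t": grid,
        "z": z,
        "peak_z": float(z[peak_i]),
        "peak_time": float(grid[peak_i]),
        "p": float(p),
        "significant": p < 0.01,
    }
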