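"""Band-limited LFP phase and spike-LFP phase locking.

The beta/gamma band (15-42 Hz) carries the pause-spike coupling: the LFP is
band-passed (zero phase), the instantaneous phase extracted by the Hilbert
transform with the convention phi = 0 at local maxima of the signal, and
phase locking of a spike subset is quantified by the pairwise phase
consistency (PPC), the mean cosine of all pairwise spike-phase differences —
an estimator of the squared resultant length that is unbiased in the number
of spikes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.special import i0

from .core import SpikeTrain, TimeSeries, wrap_angle
from .xcorr import CCFResult, shift_corrected_ccf

BETA_GAMMA = (15.0, 42.0)
BANDS = {
    "beta_gamma": (15.0, 42.0),
    "low_beta": (10.0, 15.0),
    "theta": (4.0, 10.0),
    "delta": (0.0, 4.0),
}


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians, wrapped to [-pi, pi)) of a band signal."""

    phase: np.ndarray
    rate: float
    t0: float = 0.0
    band: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.phase)

    def at_times(self, times: np.ndarray) -> np.ndarray:
        idx = np.round((np.asarray(times) - self.t0) * self.rate).astype(int)
        idx = np.clip(idx, 0, len(self.phase) - 1)
        return self.phase[idx]


@dataclass
class PhaseLockingResult:
    ppc: float
    peak_phase: float  # radians
    hist_edges: np.ndarray
    hist_density: np.ndarray
    kde_grid: np.ndarray
    kde_density: np.ndarray
    n: int


def bandpass_beta_gamma(
    lfp: TimeSeries, band: tuple[float, float] = BETA_GAMMA, order: int = 4
) -> TimeSeries:
    """Zero-phase band-pass of the LFP; a low edge of 0 means low-pass."""
    lo, hi = band
    nyq = lfp.rate / 2.0
    if hi >= nyq or hi <= 0:
        raise ValueError("band outside the Nyquist range")
    if lo <= 0:
        sos = signal.butter(order, hi, btype="low", fs=lfp.rate, output="sos")
    else:
        sos = signal.butter(order, (lo, hi), btype="band", fs=lfp.rate, output="sos")
    return TimeSeries(signal.sosfiltfilt(sos, lfp.samples), lfp.rate, lfp.t0)


def instantaneous_phase(x: TimeSeries) -> PhaseSeries:
    """Analytic-signal phase; phi = 0 at local maxima of x (cosine phase)."""
    s = x.samples
    if np.ptp(s) == 0:
        raise ValueError("no oscillation")
    analytic = signal.hilbert(s - s.mean())
    return PhaseSeries(np.angle(analytic), x.rate, x.t0)


def sta_lfp(
    lfp: TimeSeries,
    spikes: SpikeTrain,
    window_ms: float = 150.0,
    h_window_ms: float = 100.0,
    T: float = 1.0,
    M_shift: int = 200,
    all_spike_h: float | None = None,
) -> dict:
    """Shift-corrected spike-triggered average of the (SD-normalized) LFP.

    Returns the STA as a CCFResult, the peak-to-peak amplitude ``h`` measured
    within +-``h_window_ms``, and ``h_rel`` = h / all-spike h when provided.
    A warning flag is set for < 50 spikes (the STA is still returned).
    """
    ccf = shift_corrected_ccf(
        lfp, spikes, normalization="sta", T=T, M_shift=M_shift, max_lag_ms=window_ms
    )
    m = np.abs(ccf.lags_ms) <= h_window_ms
    h = float(ccf.value[m].max() - ccf.value[m].min())
    return {
        "sta": ccf,
        "h": h,
        "h_rel": (h / all_spike_h) if all_spike_h else None,
        "low_n_warning": len(spikes) < 50,
    }


def vonmises_kde(
    phases: np.ndarray, kappa: float = 10.0, n_grid: int = 360
) -> tuple[np.ndarray, np.ndarray]:
    """Von Mises kernel density on the circle; integrates to 1 over 2*pi."""
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    d = grid[:, None] - phases[None, :]
    dens = np.exp(kappa * np.cos(d)).sum(axis=1) / (2 * np.pi * i0(kappa) * len(phases))
    return grid, dens


def spike_phase_distribution(
    phases: np.ndarray, n_bins: int = 36, kde_kappa: float = 10.0
) -> PhaseLockingResult:
    """Circular histogram + von Mises KDE of spike phases; the preferred
    phase is the KDE argmax."""
    phases = wrap_angle(np.asarray(phases, float))
    if len(phases) < 10:
        raise ValueError("need at least 10 phases")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _ = np.histogram(phases, bins=edges, density=True)
    grid, dens = vonmises_kde(phases, kde_kappa)
    return PhaseLockingResult(
        ppc=ppc(phases),
        peak_phase=float(grid[np.argmax(dens)]),
        hist_edges=edges,
        hist_density=hist,
        kde_grid=grid,
        kde_density=dens,
        n=len(phases),
    )


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency: mean cos(phi_m - phi_n) over all pairs.

    Computed in O(n) via the resultant: sum_{m<n} cos = (|R|^2 - n) / 2 with
    R = sum exp(i phi).
    """
    phases = np.asarray(phases, float)
    n = len(phases)
    if n < 2:
        raise ValueError("need at least 2 phases")
    C = np.cos(phases).sum()
    S = np.sin(phases).sum()
    return float((C * C + S * S - n) / (n * (n - 1)))


def circular_mean(phases: np.ndarray) -> float:
    """Mean direction (radians) of a phase sample."""
    return float(np.angle(np.exp(1j * np.asarray(phases)).mean()))


def ppc_by_band(
    lfp: TimeSeries,
    spikes: SpikeTrain,
    bands: dict | None = None,
    normalize_by: str | None = None,
) -> dict:
    """PPC of the spike phases per LFP frequency band; optionally normalized
    by one band's value (conventionally the beta/gamma band)."""
    bands = BANDS if bands is None else bands
    out = {}
    for name, band in bands.items():
        bp = bandpass_beta_gamma(lfp, band)
        ph = instantaneous_phase(bp)
        out[name] = ppc(ph.at_times(spikes.times))
    if normalize_by is not None:
        ref = out[normalize_by]
        if ref == 0:
            raise ValueError("reference band PPC is zero")
        out = {k: v / ref for k, v in out.items()}
    return out
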