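"""Synthetic recording sessions with known ground truth.

A generated session emulates the statistical structure the analysis pipeline
assumes of a Purkinje cell recording during saccades:

- saccadic eye motion toward 8 target directions, amplitudes 2.5-20 deg with
  main-sequence-like amplitude/duration scaling and Gaussian speed profiles;
- an LFP made of 1/f background noise plus a beta/gamma-band carrier whose
  phase resets at each saccade onset with von Mises jitter;
- a highly regular simple-spike train (gamma renewal, ~55 Hz) whose rate is
  modulated by a linear kernel of the rectified eye velocity;
- intermittent pauses whose initiating spikes are locked to a preferred
  carrier phase, whose durations follow a power-law tail, and whose
  terminating spikes are locked to a second phase ~3/4 cycle away;
- sparse complex spikes (~0.8 Hz), each followed by a short pause.

Every random draw comes from a named substream of the session seed, so the
same (config, seed) is bit-reproducible and changing one component leaves
the others untouched.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import COMPLEX, SIMPLE, EyeTrace, SaccadeEvent, SpikeTrain, TimeSeries, wrap_angle
from .phase import PhaseSeries

RATE_HZ = 1000.0


@dataclass
class SynthConfig:
    duration_s: float = 120.0
    # spikes
    simple_rate_hz: float = 55.0
    complex_rate_hz: float = 0.8
    regular_cv: float = 0.2
    refractory_s: float = 0.004
    # pauses
    pause_rate_hz: float = 3.0
    pause_alpha: float = 3.78
    pause_xmin_s: float = 0.030
    # phase locking
    carrier_hz: float = 25.0
    mu_init_deg: float = 48.7
    mu_offset_deg: float = 278.3  # terminating minus initiating
    lock_kappa: float = 4.0
    kappa_reset: float = 0.408
    # LFP composition
    lfp_osc_amp: float = 1.0
    lfp_noise_sd: float = 1.0
    lfp_evoked_amp: float = 1.0  # saccade-evoked slow wave, direction-free
    lfp_evoked_sigma_s: float = 0.030
    # saccades
    saccade_rate_hz: float = 2.0
    saccade_min_gap_s: float = 0.25
    amp_range_deg: tuple = (2.5, 20.0)
    target_angles_deg: tuple = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    # kinematic kernel (rate drive per rectified velocity)
    kernel_gain: float = 0.3  # (spikes/s)/(deg/s): ~100 spikes/s burst at 350 deg/s
    kernel_center_s: float = 0.05  # velocity follows the spike by this lag
    kernel_width_s: float = 0.03
    preferred_dir_deg: float = 0.0
    tuning_floor: float = 0.1

    @property
    def mu_term_deg(self) -> float:
        return (self.mu_init_deg + self.mu_offset_deg) % 360.0


@dataclass
class GroundTruth:
    category: np.ndarray  # per emitted spike
    saccades: list
    phase: PhaseSeries  # the carrier's true phase
    kernel_lags_ms: np.ndarray
    kernels: np.ndarray  # (4, n_lags), directions 0/90/180/270
    kernel_directions: np.ndarray
    pauses: list = field(default_factory=list)  # (t_init, t_term)


@dataclass
class Session:
    eye: EyeTrace
    velocity: TimeSeries  # 2-vector, deg/s
    lfp: TimeSeries
    spikes: SpikeTrain
    truth: GroundTruth
    config: SynthConfig
    seed: int


def gen_powerlaw_isis(
    alpha: float, xmin: float, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Inverse-CDF samples from P(x) ~ x^-alpha on [xmin, inf):
    x = xmin * (1 - u)^(-1/(alpha-1))."""
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, n)
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def _next_phase_time(
    phase_arr: np.ndarray, rate: float, i_from: int, target: float, carrier_hz: float
) -> int | None:
    """Index of the first sample at/after i_from where the wrapped phase is
    closest to ``target`` (searches up to two carrier cycles)."""
    span = int(round(2.0 * rate / carrier_hz))
    seg = phase_arr[i_from : i_from + span]
    if len(seg) == 0:
        return None
    d = np.abs(wrap_angle(seg - target))
    j = int(np.argmin(d))
    if d[j] > 0.5:  # no good phase match (e.g. end of recording)
        return None
    return i_from + j


def _nearest_phase_time(
    phase_arr: np.ndarray, rate: float, i_center: int, target: float, carrier_hz: float
) -> int | None:
    """Index of the sample nearest i_center (within +-half a carrier cycle)
    where the wrapped phase is closest to ``target``; keeps symmetric jitter
    so durations anchored at i_center are not biased long."""
    half = int(round(0.5 * rate / carrier_hz))
    lo = max(i_center - half, 0)
    seg = phase_arr[lo : i_center + half + 1]
    if len(seg) == 0:
        return None
    d = np.abs(wrap_angle(seg - target))
    j = int(np.argmin(d))
    if d[j] > 0.5:
        return None
    return lo + j


def gen_locked_spikes(
    phase: PhaseSeries,
    mu: float,
    kappa: float,
    n: int,
    seed: int | np.random.Generator = 0,
    carrier_hz: float = 25.0,
) -> np.ndarray:
    """Spike times placed where the instantaneous phase matches von Mises
    draws around ``mu`` (radians). kappa = 0 gives uniform phases."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = rng.vonmises(mu, kappa, n) if kappa > 0 else rng.uniform(-np.pi, np.pi, n)
    if kappa > 1e6:
        targets = np.full(n, wrap_angle(mu))
    n_samp = len(phase.phase)
    starts = rng.integers(0, max(n_samp - int(2 * phase.rate / carrier_hz) - 1, 1), n)
    times = []
    for i0, tg in zip(starts, targets):
        j = _next_phase_time(phase.phase, phase.rate, int(i0), float(tg), carrier_hz)
        if j is not None:
            times.append(phase.t0 + j / phase.rate)
    return np.sort(np.asarray(times))


def _gen_saccades(cfg: SynthConfig, rng: np.random.Generator) -> list[SaccadeEvent]:
    events = []
    t = 0.5
    angles = np.asarray(cfg.target_angles_deg, float)
    pos = np.zeros(2)
    while True:
        t += cfg.saccade_min_gap_s + rng.exponential(1.0 / cfg.saccade_rate_hz)
        amp = rng.uniform(*cfg.amp_range_deg)
        dur = 0.020 + 0.0018 * amp  # main-sequence-like scaling
        if t + dur > cfg.duration_s - 0.5:
            break
        if np.linalg.norm(pos) > 30.0:
            back = np.degrees(np.arctan2(-pos[1], -pos[0])) % 360.0
            theta = angles[np.argmin(np.abs((angles - back + 180) % 360 - 180))]
        else:
            theta = rng.choice(angles)
        events.append(
            SaccadeEvent(onset=t, offset=t + dur, angle_theta=float(theta), amplitude=amp)
        )
        pos += amp * np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
    return events


def _eye_from_saccades(
    cfg: SynthConfig, saccades: list[SaccadeEvent], rng: np.random.Generator
) -> tuple[EyeTrace, TimeSeries]:
    n = int(round(cfg.duration_s * RATE_HZ))
    t = np.arange(n) / RATE_HZ
    vx = np.zeros(n)
    vy = np.zeros(n)
    for s in saccades:
        dur = s.offset - s.onset
        sd = dur / 6.0
        center = (s.onset + s.offset) / 2.0
        peak = s.amplitude / (sd * np.sqrt(2 * np.pi))
        lo = max(int((s.onset - 3 * sd) * RATE_HZ), 0)
        hi = min(int((s.offset + 3 * sd) * RATE_HZ), n)
        prof = peak * np.exp(-0.5 * ((t[lo:hi] - center) / sd) ** 2)
        th = np.radians(s.angle_theta)
        vx[lo:hi] += prof * np.cos(th)
        vy[lo:hi] += prof * np.sin(th)
    # small measurement noise on position, then positions by integration
    x = np.cumsum(vx) / RATE_HZ + 0.02 * rng.standard_normal(n)
    y = np.cumsum(vy) / RATE_HZ + 0.02 * rng.standard_normal(n)
    eye = EyeTrace(TimeSeries(x, RATE_HZ), TimeSeries(y, RATE_HZ))
    vel = TimeSeries(np.column_stack([vx, vy]), RATE_HZ)
    return eye, vel


def _carrier_phase(
    cfg: SynthConfig, saccades: list[SaccadeEvent], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Wrapped carrier phase: linear 2*pi*f_c drift, reset at saccade onsets
    to a von Mises draw around 0 (concentration kappa_reset)."""
    t = np.arange(n) / RATE_HZ
    onsets = np.array([s.onset for s in saccades])
    phi = 2 * np.pi * cfg.carrier_hz * t + rng.uniform(-np.pi, np.pi)
    if len(onsets):
        resets = rng.vonmises(0.0, cfg.kappa_reset, len(onsets))
        seg = np.searchsorted(onsets, t, side="right")  # 0 before first onset
        for k, (on, ps) in enumerate(zip(onsets, resets)):
            m = seg == k + 1
            phi[m] = 2 * np.pi * cfg.carrier_hz * (t[m] - on) + ps
    return wrap_angle(phi)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / RATE_HZ)
    shape = np.ones_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    shape[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
    return x / x.std()


def _regular_train(
    cfg: SynthConfig, rate_t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-renewal spike times with time-varying rate via time rescaling."""
    shape = 1.0 / cfg.regular_cv**2
    cum = np.concatenate([[0.0], np.cumsum(rate_t) / RATE_HZ])  # integrated rate
    total = cum[-1]
    times = []
    lam = 0.0
    while True:
        lam += rng.gamma(shape, 1.0 / shape)
        if lam >= total:
            break
        i = np.searchsorted(cum, lam) - 1
        frac = (lam - cum[i]) / max(cum[i + 1] - cum[i], 1e-12)
        times.append((i + frac) / RATE_HZ)
    return np.asarray(times)


def kinematic_kernel(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The generating kernels: Gaussian bump (per direction, cosine tuning)
    mapping rectified velocity to rate. Kernel values are
    (spikes/s)/(deg/s) per second, so the drive is the time integral
    sum_tau k(tau) v(t+tau) dtau and ``kernel_gain`` is the steady-state gain
    in (spikes/s)/(deg/s). Returns (lags_ms, kernels, dirs)."""
    lags = np.arange(-300, 301) / 1000.0
    bump = np.exp(-0.5 * ((lags - cfg.kernel_center_s) / cfg.kernel_width_s) ** 2)
    bump /= bump.sum() / RATE_HZ  # unit time integral
    dirs = np.array([0.0, 90.0, 180.0, 270.0])
    gains = cfg.tuning_floor + (1.0 - cfg.tuning_floor) * 0.5 * (
        1.0 + np.cos(np.radians(dirs - cfg.preferred_dir_deg))
    )
    kernels = cfg.kernel_gain * gains[:, None] * bump[None, :]
    return lags * 1000.0, kernels, dirs


def _rate_from_velocity(cfg: SynthConfig, vel: TimeSeries) -> np.ndarray:
    """r(t) = base + sum_dirs (g_theta * v_theta)(t), clipped at 1 Hz.

    The kernel reads velocity forward: rate at t is driven by velocity at
    t + tau for tau near kernel_center_s (the cell leads the movement).
    """
    lags_ms, kernels, dirs = kinematic_kernel(cfg)
    n = len(vel.samples)
    drive = np.zeros(n)
    for k, th in zip(kernels, dirs):
        rad = np.radians(th)
        v = np.maximum(vel.samples @ np.array([np.cos(rad), np.sin(rad)]), 0.0)
        drive += np.correlate(v, k, mode="same") / RATE_HZ  # integral over tau
    return np.maximum(cfg.simple_rate_hz + drive, 1.0)


def gen_session(config: SynthConfig | None = None, seed: int = 0) -> Session:
    """Generate one complete synthetic session. Deterministic in (config, seed)."""
    cfg = SynthConfig() if config is None else config
    mean_pause = cfg.pause_xmin_s * (cfg.pause_alpha - 1.0) / (cfg.pause_alpha - 2.0)
    if cfg.pause_rate_hz * mean_pause >= 1.0:
        raise ValueError("infeasible config: pauses would fill the session")
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_eye, rng_lfp, rng_spk, rng_pause, rng_cx = (
        np.random.default_rng(s) for s in streams
    )

    saccades = _gen_saccades(cfg, rng_eye)
    eye, vel = _eye_from_saccades(cfg, saccades, rng_eye)
    n = len(vel.samples)

    phi = _carrier_phase(cfg, saccades, n, rng_lfp)
    # saccade-evoked slow wave (biphasic, direction-independent, amplitude
    # scaling with saccade size): gives the LFP its eye-motion correlation
    # below the beta/gamma band without touching the carrier phase
    evoked = np.zeros(n)
    if cfg.lfp_evoked_amp > 0:
        sig = cfg.lfp_evoked_sigma_s
        tk = np.arange(-int(4 * sig * RATE_HZ), int(4 * sig * RATE_HZ) + 1) / RATE_HZ
        wave = -tk / sig * np.exp(0.5 - 0.5 * (tk / sig) ** 2)  # unit-peak biphasic
        for s in saccades:
            j = int(round(s.onset * RATE_HZ))
            lo, hi = max(j - len(tk) // 2, 0), min(j + len(tk) // 2 + 1, n)
            seg = wave[lo - (j - len(tk) // 2) : len(tk) - ((j + len(tk) // 2 + 1) - hi)]
            evoked[lo:hi] += cfg.lfp_evoked_amp * (s.amplitude / 10.0) * seg
    lfp = TimeSeries(
        cfg.lfp_osc_amp * np.cos(phi)
        + evoked
        + cfg.lfp_noise_sd * _pink_noise(n, rng_lfp),
        RATE_HZ,
    )
    phase = PhaseSeries(phi, RATE_HZ, 0.0, band=(15.0, 42.0))

    rate_t = _rate_from_velocity(cfg, vel)
    times = _regular_train(cfg, rate_t, rng_spk)
    category = np.full(len(times), "regular", dtype=object)

    # pauses: relocate the initiating spike to the locked phase, carve out the
    # pause, and insert a terminating spike at the second locked phase
    pauses = []
    if cfg.pause_rate_hz > 0 and len(times):
        n_pause = rng_pause.poisson(cfg.pause_rate_hz * cfg.duration_s)
        t_events = np.sort(rng_pause.uniform(1.0, cfg.duration_s - 1.0, n_pause))
        durations = gen_powerlaw_isis(cfg.pause_alpha, cfg.pause_xmin_s, n_pause, rng_pause)
        mu_i = np.radians(cfg.mu_init_deg)
        mu_t = np.radians(cfg.mu_term_deg)
        keep = np.ones(len(times), bool)
        new_spikes, new_cats = [], []
        last_end = -np.inf
        for te, d in zip(t_events, durations):
            if te < last_end + 0.05:
                continue
            tgt_i = rng_pause.vonmises(mu_i, cfg.lock_kappa)
            ji = _next_phase_time(phi, RATE_HZ, int(te * RATE_HZ), tgt_i, cfg.carrier_hz)
            if ji is None:
                continue
            t_init = ji / RATE_HZ
            tgt_t = rng_pause.vonmises(mu_t, cfg.lock_kappa)
            jt = _nearest_phase_time(
                phi, RATE_HZ, int((t_init + d) * RATE_HZ), tgt_t, cfg.carrier_hz
            )
            if jt is None or jt / RATE_HZ <= t_init + cfg.refractory_s:
                continue
            t_term = jt / RATE_HZ
            # carve out base spikes inside [t_init - refractory, t_term + refractory]
            keep &= ~(
                (times > t_init - cfg.refractory_s) & (times < t_term + cfg.refractory_s)
            )
            new_spikes += [t_init, t_term]
            new_cats += ["pause_initiating", "pause_terminating"]
            pauses.append((t_init, t_term))
            last_end = t_term
        times = np.concatenate([times[keep], new_spikes])
        category = np.concatenate([category[keep], new_cats])
        order = np.argsort(times)
        times, category = times[order], category[order]

    kinds = np.full(len(times), SIMPLE, dtype=object)
    # complex spikes: sparse Poisson events, each followed by a short pause
    n_cx = rng_cx.poisson(cfg.complex_rate_hz * cfg.duration_s)
    t_cx = np.sort(rng_cx.uniform(0.0, cfg.duration_s, n_cx))
    for tc in t_cx:
        d = rng_cx.uniform(0.010, 0.030)
        keep = ~((times >= tc - cfg.refractory_s) & (times <= tc + d))
        times, category, kinds = times[keep], category[keep], kinds[keep]
        i = np.searchsorted(times, tc)
        times = np.insert(times, i, tc)
        category = np.insert(category, i, "complex")
        kinds = np.insert(kinds, i, COMPLEX)

    # enforce strict ordering / refractoriness after edits
    keep = np.concatenate([[True], np.diff(times) > 1e-4])
    times, category, kinds = times[keep], category[keep], kinds[keep]

    lags_ms, kernels, dirs = kinematic_kernel(cfg)
    truth = GroundTruth(
        category=category,
        saccades=saccades,
        phase=phase,
        kernel_lags_ms=lags_ms,
        kernels=kernels,
        kernel_directions=dirs,
        pauses=pauses,
    )
    return Session(
        eye=eye,
        velocity=vel,
        lfp=lfp,
        spikes=SpikeTrain(times, kinds),
        truth=truth,
        config=cfg,
        seed=seed,
    )
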