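"""ISI statistics and spike classification.

A Purkinje cell fires simple spikes at 40-80 Hz with striking regularity,
interrupted by occasional long intervals ("pauses"). Per spike, the asymmetry
index AI = (post_ISI - pre_ISI)/(post_ISI + pre_ISI) localizes that
irregularity: AI near +1 marks a pause-initiating spike, near -1 a
pause-terminating one, and CV2 = 2|AI| is the usual local coefficient of
variation. The ISI distribution's long tail is modeled as a power law
P(x) ~ x^-alpha fitted by continuous maximum likelihood with KS-based tail
onset selection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core import COMPLEX, SIMPLE, SpikeTrain

REFRACTORY_S = 0.004


@dataclass
class ISIStats:
    """Per-spike pre/post ISIs (s), AI and CV2; NaN at the train boundaries."""

    pre_isi: np.ndarray
    post_isi: np.ndarray
    ai: np.ndarray
    cv2: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.ai)


@dataclass
class PowerLawFit:
    alpha: float
    xmin: float
    n_tail: int
    loglik_ratio: float  # power law minus exponential; > 0 favors power law
    p_alt: float  # Vuong-style p-value for the comparison
    ks_distance: float


@dataclass
class SpikeClassification:
    """Per-spike category labels and the thresholds that produced them."""

    category: np.ndarray  # 'pause_initiating' | 'pause_terminating' | 'regular' | 'unclassified'
    ai_threshold_init: float
    ai_threshold_term: float
    min_pause_s: float

    def mask(self, cat: str) -> np.ndarray:
        return self.category == cat

    def counts(self) -> dict:
        cats, n = np.unique(self.category, return_counts=True)
        return dict(zip(cats.tolist(), n.tolist()))


def asymmetry_index(train: SpikeTrain) -> ISIStats:
    """Per-spike ISI asymmetry index and CV2 (= 2|AI|)."""
    if len(train) < 3:
        raise ValueError("need at least 3 spikes")
    isis = train.isis
    n = len(train)
    pre = np.full(n, np.nan)
    post = np.full(n, np.nan)
    pre[1:] = isis
    post[:-1] = isis
    ai = (post - pre) / (post + pre)
    return ISIStats(pre_isi=pre, post_isi=post, ai=ai, cv2=2.0 * np.abs(ai))


def local_rates(train: SpikeTrain, n_isis: int = 5) -> np.ndarray:
    """Local firing rate per ISI from the nearest ``n_isis`` ISIs,
    r_k = n / (ISI_{k-2} + ... + ISI_{k+2}); truncated windows at the ends."""
    isis = train.isis
    half = n_isis // 2
    r = np.empty(len(isis))
    for k in range(len(isis)):
        lo, hi = max(0, k - half), min(len(isis), k + half + 1)
        r[k] = (hi - lo) / isis[lo:hi].sum()
    return r


def rate_matched_controls(
    train: SpikeTrain,
    n_controls: int = 200,
    mode: str = "rate_matched",
    seed: int | np.random.Generator = 0,
) -> list[SpikeTrain]:
    """Artificial spike trains matching the local firing rate of ``train``.

    Each control ISI T_k is a shape-2 gamma draw scaled by the local rate r_k,
    with a 4 ms refractory period enforced by resampling. ``mode``:

    - ``rate_matched`` (default): mean 1/r_k, so the control matches the rate.
    - ``literal``: density r_k^2 T exp(-r_k T), mean 2/r_k.
    """
    if len(train) < 7:
        raise ValueError("need at least 7 spikes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = local_rates(train)
    scale = 1.0 / (2.0 * r) if mode == "rate_matched" else 1.0 / r
    if mode not in ("rate_matched", "literal"):
        raise ValueError("mode must be 'rate_matched' or 'literal'")
    out = []
    for _ in range(n_controls):
        T = rng.gamma(2.0, scale)
        bad = T < REFRACTORY_S
        for _ in range(100):
            if not bad.any():
                break
            T[bad] = rng.gamma(2.0, scale[bad])
            bad = T < REFRACTORY_S
        T = np.maximum(T, REFRACTORY_S)
        times = train.times[0] + np.concatenate([[0.0], np.cumsum(T)])
        out.append(SpikeTrain(times))
    return out


def ai_excess_test(
    train: SpikeTrain,
    controls: list[SpikeTrain],
    bin_halfwidth: float = 0.05,
) -> dict:
    """One-sided z-test for an excess of regular spikes (AI ~ 0) over the
    rate-matched controls."""
    if not controls:
        raise ValueError("controls required")

    def frac_near_zero(t: SpikeTrain) -> float:
        ai = asymmetry_index(t).ai
        ai = ai[np.isfinite(ai)]
        return float(np.mean(np.abs(ai) <= bin_halfwidth))

    obs = frac_near_zero(train)
    ctrl = np.array([frac_near_zero(c) for c in controls])
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate controls")
    z = (obs - ctrl.mean()) / sd
    p = float(sstats.norm.sf(z))
    return {"z": float(z), "p": p, "excess_at_zero": obs - float(ctrl.mean())}


def _alpha_mle(x: np.ndarray, xmin: float) -> float:
    return 1.0 + len(x) / np.sum(np.log(x / xmin))


def _ks_tail(x: np.ndarray, xmin: float, alpha: float) -> float:
    xs = np.sort(x)
    cdf_emp = np.arange(1, len(xs) + 1) / len(xs)
    cdf_fit = 1.0 - (xs / xmin) ** (1.0 - alpha)
    return float(np.max(np.abs(cdf_emp - cdf_fit)))


def fit_powerlaw_tail(
    isis: np.ndarray,
    xmin: float | None = None,
    min_tail: int = 50,
    n_xmin_grid: int = 100,
) -> PowerLawFit:
    """Continuous MLE power-law fit to the ISI tail, with KS-minimizing tail
    onset when ``xmin`` is not fixed, and a likelihood-ratio comparison
    against an exponential tail (positive ratio favors the power law)."""
    x = np.asarray(isis, float)
    x = x[x > 0]
    if xmin is None:
        cand = np.quantile(x, np.linspace(0.5, 0.99, n_xmin_grid))
        cand = np.unique(cand)
        best = None
        for xm in cand:
            tail = x[x >= xm]
            if len(tail) < min_tail:
                continue
            a = _alpha_mle(tail, xm)
            ks = _ks_tail(tail, xm, a)
            if best is None or ks < best[2]:
                best = (xm, a, ks)
        if best is None:
            raise ValueError("tail too small")
        xmin, alpha, ks = best
        tail = x[x >= xmin]
    else:
        tail = x[x >= xmin]
        if len(tail) < min_tail:
            raise ValueError("tail too small")
        alpha = _alpha_mle(tail, xmin)
        ks = _ks_tail(tail, xmin, alpha)

    # log-likelihood ratio vs an exponential tail on the same support
    lam = 1.0 / np.mean(tail - xmin)
    ll_pl = np.log((alpha - 1.0) / xmin) - alpha * np.log(tail / xmin)
    ll_ex = np.log(lam) - lam * (tail - xmin)
    d = ll_pl - ll_ex
    R = float(d.sum())
    sd = d.std(ddof=1)
    if sd > 0:
        z = R / (sd * np.sqrt(len(d)))
        p_alt = 2.0 * float(sstats.norm.sf(abs(z)))
    else:
        p_alt = 1.0
    return PowerLawFit(
        alpha=float(alpha),
        xmin=float(xmin),
        n_tail=len(tail),
        loglik_ratio=R,
        p_alt=p_alt,
        ks_distance=ks,
    )


def classify_spikes(
    train: SpikeTrain,
    stats: ISIStats | None = None,
    top_frac: float = 0.15,
    remove_frac: float = 0.25,
    min_pause_factor: float = 1.2,
    remove_on: str = "pause_isi",
) -> SpikeClassification:
    """Partition simple spikes into pause-initiating, pause-terminating and
    regular categories.

    Pause-initiating: the ``top_frac`` of simple spikes with the largest AI,
    minus the ``remove_frac`` of those with the shortest pause (post) ISI,
    then requiring the pause ISI to exceed ``min_pause_factor`` / mean rate.
    Pause-terminating: symmetric, with the smallest AI and the pre ISI.
    Regular: the lowest-CV2 spikes, count matched to the pause groups.
    Complex spikes are never classified.
    """
    simple_mask = train.kinds == SIMPLE
    if int(simple_mask.sum()) < 100:
        raise ValueError("need at least 100 simple spikes")
    sub = train.subset(simple_mask)
    st = asymmetry_index(sub) if stats is None else stats
    valid = st.valid
    idx = np.where(valid)[0]  # indices into sub
    n_valid = len(idx)
    ai = st.ai[idx]
    cv2 = st.cv2[idx]
    post = st.post_isi[idx]
    pre = st.pre_isi[idx]

    mean_rate = sub.mean_rate()
    min_pause = min_pause_factor / mean_rate

    def pick(order_key, pause_isi):
        n_top = int(round(top_frac * n_valid))
        # stable sort: ties broken by spike time (original order)
        top = np.argsort(-order_key, kind="stable")[:n_top]
        n_rm = int(round(remove_frac * n_top))
        if n_rm > 0 and remove_on == "pause_isi":
            keep = top[np.argsort(pause_isi[top], kind="stable")[n_rm:]]
        else:
            keep = top
        return keep[pause_isi[keep] >= min_pause]

    init_sel = pick(ai, post)
    term_sel = pick(-ai, pre)
    n_reg = max(len(init_sel), len(term_sel))
    taken = np.zeros(n_valid, bool)
    taken[init_sel] = True
    taken[term_sel] = True
    free = np.where(~taken)[0]
    reg_sel = free[np.argsort(cv2[free], kind="stable")[:n_reg]]

    cat_sub = np.full(len(sub), "unclassified", dtype=object)
    cat_sub[idx[init_sel]] = "pause_initiating"
    cat_sub[idx[term_sel]] = "pause_terminating"
    cat_sub[idx[reg_sel]] = "regular"

    category = np.full(len(train), "unclassified", dtype=object)
    category[simple_mask] = cat_sub
    ai_init = float(np.min(ai[init_sel])) if len(init_sel) else np.nan
    ai_term = float(np.max(ai[term_sel])) if len(term_sel) else np.nan
    return SpikeClassification(
        category=category,
        ai_threshold_init=ai_init,
        ai_threshold_term=ai_term,
        min_pause_s=min_pause,
    )


def ai_isi_correlation(stats: ISIStats, kind_mask: np.ndarray | None = None) -> float:
    """Pearson correlation between AI and log10(post ISI) on the given spikes."""
    m = stats.valid if kind_mask is None else (stats.valid & kind_mask)
    ai = stats.ai[m]
    isi = stats.post_isi[m]
    if len(ai) < 10:
        raise ValueError("need at least 10 spikes")
    return float(np.corrcoef(ai, np.log10(isi))[0, 1])
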