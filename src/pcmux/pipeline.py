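"""End-to-end per-session analysis and cohort summaries.

``run_session`` chains the full analysis — signal conditioning, CCF/NSR,
spike classification, power-law tail, spike-LFP phase locking, cross-saccade
reliability, and the eye-motion-to-rate LN model — recording stage errors
rather than aborting, so a partial recording still yields a partial report.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from . import lnmodel, phase, preprocess, reliability, spikestats, xcorr
from .core import SIMPLE, EyeTrace, SpikeTrain, TimeSeries

CATEGORIES = ("pause_initiating", "pause_terminating", "regular")


@dataclass
class SessionReport:
    """Per-session results mirroring the per-cell figures of the analysis."""

    fields: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def set(self, key: str, value, source: str) -> None:
        self.fields[key] = value
        self.provenance[key] = source

    def get(self, key: str, default=None):
        return self.fields.get(key, default)


def run_session(
    lfp_raw: TimeSeries,
    eye: EyeTrace,
    spikes: SpikeTrain,
    saccades=None,
    line_freq: float = 50.0,
    M_shift: int = 100,
    n_controls: int = 100,
    seed: int = 0,
    condition: bool = True,
) -> SessionReport:
    """Run the full per-session analysis. ``condition=False`` skips the LFP
    conditioning chain (for already-conditioned input). When ``saccades`` is
    None they are detected from the eye trace."""
    rep = SessionReport()
    simple = spikes.simple()
    if len(simple) < 100:
        raise ValueError("need at least 100 simple spikes")

    def stage(name, fn):
        try:
            fn()
        except Exception as e:  # recorded, downstream fields stay missing
            rep.errors[name] = str(e)

    state: dict = {}

    def s_preprocess():
        lfp = preprocess.condition_lfp(lfp_raw, line_freq) if condition else lfp_raw
        vel = preprocess.compute_eye_velocity(eye)
        speed = preprocess.eye_speed(vel)
        sacc = saccades if saccades is not None else preprocess.detect_saccades(speed, eye)
        state.update(lfp=lfp, vel=vel, speed=speed, saccades=sacc)
        rep.set("n_saccades", len(sacc), "preprocess.detect_saccades")

    def s_xcorr():
        lfp, vel, speed = state["lfp"], state["vel"], state["speed"]
        c_lfp = xcorr.shift_corrected_ccf(lfp, speed, "ccf", M_shift=M_shift)
        c_spk = xcorr.shift_corrected_ccf(speed, simple, "sta", M_shift=M_shift)
        rep.set("ccf_lfp_ev_significant",
                xcorr.ccf_significance(c_lfp)["significant"], "xcorr.ccf_significance")
        rep.set("ccf_spike_ev_significant",
                xcorr.ccf_significance(c_spk)["significant"], "xcorr.ccf_significance")
        cmp_ = xcorr.nsr_compare(simple, lfp, vel, n_controls=n_controls, M_shift=M_shift)
        rep.set("nsr_comparison", cmp_, "xcorr.nsr_compare")
        state["dir_ccf_full"] = xcorr.directional_ccf(simple, vel, M_shift=M_shift)

    def s_spikestats():
        st = spikestats.asymmetry_index(simple)
        cls = spikestats.classify_spikes(simple, st)
        state["stats"], state["classification"] = st, cls
        rep.set("classification_counts", cls.counts(), "spikestats.classify_spikes")
        pl = spikestats.fit_powerlaw_tail(simple.isis)
        rep.set("powerlaw", {"alpha": pl.alpha, "xmin_s": pl.xmin, "n_tail": pl.n_tail,
                             "loglik_ratio": pl.loglik_ratio},
                "spikestats.fit_powerlaw_tail")
        rep.set("ai_isi_r", spikestats.ai_isi_correlation(st),
                "spikestats.ai_isi_correlation")

    def s_phase():
        lfp = state["lfp"]
        bp = phase.bandpass_beta_gamma(lfp)
        ph = phase.instantaneous_phase(bp)
        state["bp"], state["ph"] = bp, ph
        cls = state["classification"]
        all_sta = phase.sta_lfp(lfp, simple, M_shift=M_shift)
        rep.set("h_all", all_sta["h"], "phase.sta_lfp")
        h_rel, ppc_cat, peak = {}, {}, {}
        for cat in CATEGORIES:
            sub = simple.subset(cls.mask(cat)[spikes.kinds == SIMPLE]
                                if len(cls.category) == len(spikes) else cls.mask(cat))
            if len(sub) < 10:
                continue
            r = phase.sta_lfp(lfp, sub, M_shift=M_shift, all_spike_h=all_sta["h"])
            h_rel[cat] = r["h_rel"]
            phases = ph.at_times(sub.times)
            ppc_cat[cat] = phase.ppc(phases)
            peak[cat] = phase.spike_phase_distribution(phases).peak_phase
        rep.set("h_rel", h_rel, "phase.sta_lfp")
        rep.set("ppc", ppc_cat, "phase.ppc")
        rep.set("peak_phase", peak, "phase.spike_phase_distribution")
        rep.set("ppc_by_band", phase.ppc_by_band(lfp, simple), "phase.ppc_by_band")

    def s_reliability():
        ph, sacc = state["ph"], state["saccades"]
        onsets = np.array([s.onset for s in sacc])
        if len(onsets) < 2:
            raise ValueError("too few saccades for reliability")
        res = reliability.r_lfp_significance(ph, onsets, n_controls=n_controls, seed=seed)
        rep.set("r_lfp", res["r_lfp"], "reliability.lfp_phase_reliability")
        rep.set("r_lfp_p", res["p"], "reliability.r_lfp_significance")
        cls = state["classification"]
        r_spike, z_peaks = {}, {}
        for cat in CATEGORIES:
            sub = simple.subset(cls.mask(cat)[spikes.kinds == SIMPLE]
                                if len(cls.category) == len(spikes) else cls.mask(cat))
            if len(sub) < 10:
                continue
            trials = [sub.times[np.abs(sub.times - on) <= 0.3] - on for on in onsets]
            ue = reliability.unitary_events(trials)
            r_spike[cat] = ue["r_spike"]
            z = reliability.peri_saccade_zscore(sub, onsets, n_controls=n_controls,
                                               seed=seed)
            z_peaks[cat] = {"peak_z": z["peak_z"], "peak_time": z["peak_time"],
                            "p": z["p"]}
        rep.set("r_spike", r_spike, "reliability.spike_reliability")
        rep.set("z_peaks", z_peaks, "reliability.peri_saccade_zscore")

    def s_lnmodel():
        vel, cls = state["vel"], state["classification"]
        model = lnmodel.fit_ln_model(vel, simple, M_shift=M_shift)
        rep.set("r2_all", model.r2_linear, "lnmodel.fit_ln_model")
        masks = {}
        cat_arr = cls.category[spikes.kinds == SIMPLE] \
            if len(cls.category) == len(spikes) else cls.category
        for cat in CATEGORIES:
            masks[cat] = cat_arr == cat
        sub = lnmodel.subset_rate_model(simple, masks, vel, M_shift=M_shift)
        rep.set("r2_by_category", {k: v["r2"] for k, v in sub.items()},
                "lnmodel.subset_rate_model")

    stage("preprocess", s_preprocess)
    if "lfp" in state:
        stage("xcorr", s_xcorr)
    stage("spikestats", s_spikestats)
    if "lfp" in state and "classification" in state:
        stage("phase", s_phase)
    if "ph" in state and "saccades" in state:
        stage("reliability", s_reliability)
    if "vel" in state and "classification" in state:
        stage("lnmodel", s_lnmodel)
    return rep


def run_cohort(reports: list[SessionReport]) -> dict:
    """Across-session distributions of the per-cell quantities, with rank-sum
    comparisons between pause and regular categories."""
    if len(reports) < 2:
        raise ValueError("need at least 2 sessions")

    def collect(key, cat):
        vals = []
        for r in reports:
            d = r.get(key) or {}
            v = d.get(cat)
            if v is not None and np.isfinite(v):
                vals.append(v)
        return np.asarray(vals)

    out: dict = {"n_sessions": len(reports)}
    for key in ("ppc", "h_rel", "r_spike", "r2_by_category"):
        per_cat = {c: collect(key, c) for c in CATEGORIES}
        out[key] = {c: {"mean": float(v.mean()) if len(v) else np.nan,
                        "n": len(v)} for c, v in per_cat.items()}
        a, b = per_cat["pause_initiating"], per_cat["regular"]
        if len(a) >= 2 and len(b) >= 2:
            stat, p = sstats.ranksums(a, b)
            out[key]["ranksum_pauseI_vs_regular"] = {"stat": float(stat), "p": float(p)}
    r_lfp = np.array([r.get("r_lfp") for r in reports if r.get("r_lfp") is not None])
    out["r_lfp"] = {"mean": float(r_lfp.mean()) if len(r_lfp) else np.nan,
                    "n": len(r_lfp)}
    return out
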