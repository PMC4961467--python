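"""Spike-LFP phase locking of pause vs regular spikes.

Band-passes the LFP to the beta/gamma band (15-42 Hz), extracts the
instantaneous phase, and compares the pairwise phase consistency (PPC) and
preferred phase of each ground-truth spike category.
"""
import numpy as np

from pcmux.phase import (
    bandpass_beta_gamma,
    circular_mean,
    instantaneous_phase,
    ppc,
    sta_lfp,
)
from pcmux.synthgen import SynthConfig, gen_session

session = gen_session(SynthConfig(duration_s=120.0), seed=7)
simple = session.spikes.simple()
truth = session.truth.category[session.spikes.kinds == "simple"]
phase = instantaneous_phase(bandpass_beta_gamma(session.lfp))

h_all = sta_lfp(session.lfp, simple, M_shift=100)["h"]
print(f"all-spike STA amplitude h_All = {h_all:.3f} (normalized LFP units)")
for cat in ("pause_initiating", "pause_terminating", "regular"):
    sub = simple.subset(truth == cat)
    phases = phase.at_times(sub.times)
    h = sta_lfp(session.lfp, sub, M_shift=100)["h"]
    print(f"  {cat:18s} PPC = {ppc(phases):+.3f}  "
          f"preferred phase = {np.degrees(circular_mean(phases)):6.1f} deg  "
          f"h/h_All = {h / h_all:.2f}")
# pause spikes show high PPC at the programmed phases (48.7 deg for
# initiation, +278.3 deg for termination) and a several-fold larger STA
# amplitude; regular spikes are nearly phase-blind
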