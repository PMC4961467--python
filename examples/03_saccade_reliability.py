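"""Cross-saccade reliability of the LFP phase and of pause-spike timing.

Aligns the beta/gamma LFP phase and the pause-initiating spikes to saccade
onsets, then measures (i) R_LFP, the across-saccade phase coherence, and
(ii) R_spike from unitary-event coincidence counts, plus the peri-saccade
firing z-score peak.
"""
import numpy as np

from pcmux.phase import bandpass_beta_gamma, instantaneous_phase
from pcmux.reliability import (
    align_phase_traces,
    lfp_phase_reliability,
    peri_saccade_zscore,
    unitary_events,
)
from pcmux.synthgen import SynthConfig, gen_session

session = gen_session(SynthConfig(duration_s=120.0), seed=7)
onsets = np.array([s.onset for s in session.truth.saccades])
phase = instantaneous_phase(bandpass_beta_gamma(session.lfp))

traces = align_phase_traces(phase, onsets)
r_lfp, _ = lfp_phase_reliability(traces)
print(f"{len(onsets)} saccades; R_LFP = {r_lfp:.3f}")

simple = session.spikes.simple()
truth = session.truth.category[session.spikes.kinds == "simple"]
pause_i = simple.subset(truth == "pause_initiating")
trials = [pause_i.times[np.abs(pause_i.times - on) <= 0.3] - on for on in onsets]
ue = unitary_events(trials)
print(f"pause-initiating spikes: R_spike = {ue['r_spike']:.3f} "
      f"({int(ue['n_emp'].sum())} coincidences)")

z = peri_saccade_zscore(pause_i, onsets, n_controls=100, seed=0)
print(f"peri-saccade z peak = {z['peak_z']:.1f} at "
      f"{1000 * z['peak_time']:+.0f} ms (p = {z['p']:.3f})")
# the LFP phase resets at saccade onset (R_LFP ~ 0.2 at the default jitter)
# and pause spikes inherit cycle-level timing from the reset carrier, so a
# fraction of their coincidences exceed the rate prediction (R_spike > 0)
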