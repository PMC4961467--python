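# Methods

This note records the models implemented in `pcmux`, the parameters that
matter, the design choices made where the method was genuinely open, and the
limits of what the synthetic-data tests can show.

## Signals and conventions

All times are seconds from session start; angles are degrees
counterclockwise from the positive horizontal. The LFP and eye traces are
uniformly sampled (`TimeSeries`); analysis runs at 1 kHz. Saccade duration
is reported in milliseconds. Band phases are radians in [−π, π) with φ = 0
at local maxima of the band-passed signal ("cosine phase"); the climbing
phase of a cycle is then φ ∈ (−π, 0). The phase origin is a convention —
recovery tests compare estimated against generated phases end-to-end, so
results do not depend on it.

## LFP conditioning and eye kinematics

The slow-LFP chain is: IIR notch at the line frequency (Q = 30), 4th-order
Butterworth low-pass at 42 Hz, cubic resampling to 90 Hz, cubic
interpolation back to 1 kHz. All filters are applied forward–backward
(zero phase): an offline pipeline has no reason to accept group delay, and
the spike–LFP timing analyses downstream depend on it. DC passes unchanged;
residual power above 45 Hz is < 5 % of the passband (tested on white noise).

Eye velocity is the derivative output of a Savitzky–Golay filter, polynomial
order 5, 25 ms window — exact for polynomial trajectories up to the filter
order, which the tests exploit (ramp and quadratic oracles).

Saccade detection uses an iterative adaptive threshold on eye speed:
initialize T = 100 deg/s, recompute T = mean + 6·SD of sub-threshold samples
until the change is < 1 deg/s; events are contiguous supra-threshold runs
extended to the nearest local speed minima, dropped under 10 ms, merged
across gaps under 20 ms. Direction and amplitude come from the net
positional displacement when the position trace is supplied. The published
detector this stands in for was never printed; the scheme and its three
parameters (initial threshold, minimum duration, merge gap) are exposed as
arguments.

## Shift-corrected correlation

CCF_AB(t) = (1/Z) Σ_s x(s+t) y(s) − mean over m = 1..M of the same sum with
y shifted by m·T (T = 1 s, M up to 200). Shifts wrap around the recording,
so one FFT cross-correlation yields the raw term and every control exactly;
the control ensemble supplies both the baseline and its SD. Normalization
`ccf` uses √(Var x · Var y) · L (both signals continuous); `sta` uses
√(Var x) · N_spike with y binned at the sample width, making the result the
shift-corrected spike-triggered average of the SD-normalized signal. In the
circular convention every lag sums L terms, so the (L − |t|) triangular
factor of a linear-sum definition reduces to the constant L; lags used
(≤ 300 ms) are far below L.

Significance over a lag window ([−100, 100] ms by default) uses the
statistic max |value|/control_SD; its null distribution is the same
statistic evaluated on each control CCF, giving an empirical one-sided p
that absorbs the multiplicity of lags. Note the granularity floor: with M
controls the smallest attainable p is 1/(M+1), so testing at the 1 % level
requires M ≥ 100.

Directional CCFs use the rectified projection v_θ = max(0, **v**·**e**_θ)
for θ = 0°, 45°, …, 315°; a direction with no motion yields a flat zero row
by convention. The NSR (trace of the across-angle covariance over the
squared norm of the mean row) quantifies direction tuning. For the NSR
difference test, each control realization adds shift-predictor noise (a
time-shifted control CCF minus the control mean) to the *observed* rows and
recomputes the NSR: this measures the sampling variability of the observed
NSR. Computing NSRs of pure time-shifted data instead divides by a
near-zero mean row and has unbounded variance, leaving the test powerless.

## Spike statistics and classification

AI_i = (post_ISI_i − pre_ISI_i)/(post_ISI_i + pre_ISI_i); CV₂ = 2|AI| holds
identically and is asserted as an invariant. Rate-matched control trains
draw each ISI from a shape-2 gamma scaled to the local rate r_k =
5/(sum of the five surrounding ISIs), with a 4 ms refractory period enforced
by resampling. Two modes exist: `rate_matched` (default, mean 1/r_k) and
`literal` (mean 2/r_k, the historical density r² T e^{−rT}); the default
follows the rate-matching intent, since a mean-2/r control train would fire
at half the reference rate.

The ISI tail is fit by continuous maximum likelihood,
α̂ = 1 + n/Σ ln(x/x_min), with x_min chosen by KS-distance minimization over
a quantile grid when not fixed, and compared against an exponential tail by
a normalized log-likelihood ratio (Vuong-style two-sided p). At least 50
tail samples are required.

Classification: pause-initiating = the top 15 % of AI-defined simple spikes
by AI, minus the 25 % of those with the shortest post-ISI, then requiring
the pause ISI to exceed 1.2/(mean rate); pause-terminating is the mirror
image on the smallest AI and the pre-ISI (the mirror-image removal rule is
an inference from symmetry and is exposed as configuration); regular = the
lowest-CV₂ spikes, count-matched to the larger pause group, drawn from
spikes not already in a pause group. Percentile counts use round(), ties
break by spike time, and complex spikes are never classified. On a 10,000
spike train with distinct AI values this yields exactly
round(0.25·round(0.15·9998)) removals → 1,125 pause-initiating spikes
(≈ 11 % of the train).

## Phase locking

Beta/gamma = 15–42 Hz, 4th-order zero-phase Butterworth (the delta band is a
plain low-pass). PPC is the mean cosine of all pairwise spike-phase
differences, computed in O(n) from the resultant, (|R|² − n)/(n(n−1)), and
checked against the brute-force pair loop; it is translation-invariant on
the circle and unbiased (mean 0 for uniform phases). The printed estimator
sums complex phasors over ordered pairs; its real part is this statistic and
respects the [−1, 1] range. Preferred phases come from a von Mises kernel
density (κ = 10, 1° grid); STA amplitude h is the peak-to-peak value within
±100 ms of a ±150 ms window (the source figures do not state the window; it
is configurable).

## Reliability

R_LFP = time average over [−100, 150] ms of Z(t), the modulus of the
across-saccade mean unit phasor of the beta/gamma phase. Note the
small-sample bias: for N independent uniform phases E[Z] ≈ √(π/4N), and at
true resultant R with N trials E[Z] ≈ √(R² + (1−R²)/N); the acceptance
comparison against the Bessel ratio I₁(κ)/I₀(κ) uses N = 100, where the
bias (≈ +0.01) is inside the stated tolerance.

Unitary events: spike times are discretized at 1 ms; coincidences are spike
pairs across trials with |Δt| ≤ 3 ms whose midpoint falls in the 50 ms
moving window (1 ms steps); the expectation per trial pair is
n_i · n_j · (2δ + bin)/W — the bin term counts the 7 offsets the
discretized |Δt| ≤ 3 ms admits. jp is the Poisson upper tail P(N ≥ n_emp)
at mean n_exp, following the verbal definition of "the same or more
coincidences"; the historical printed sum (which raises n_emp rather than
n_exp to the power r and is not a probability) is retained as mode
`literal` for replication only. R_spike sums n_emp over windows with
jp < 0.05 and divides by the total; overlapping windows enter both sums.
Peri-saccade z-scores smooth the onset-aligned spike probability with a
5 ms Gaussian and standardize against 200 time-shifted controls (an
ISI-shuffling control mode is available); peak significance is the
empirical p of the peak |z| against the controls' own maxima.

## LN inverse model

The motion feature is the shift-corrected STA of the rectified eye velocity
in four directions (0°, 90°, 180°, 270° — the four cardinal rectified
channels span signed horizontal/vertical motion) over ±300 ms. The linear
prediction m(t) = Σ_θ Σ_τ f_θ(τ) v_θ(t+τ) is affinely calibrated to
spikes/s against the σ = 10 ms Gaussian-smoothed observed rate (the
published model appendix is unavailable; calibration-by-least-squares is
the minimal substitute and only sets scale and offset, not shape). The
nonlinearity is the binned conditional mean rate given m (50 bins), made
monotone by isotonic regression, with empty bins interpolated.

Two R² statistics are deliberately distinct. `goodness_of_fit` is the
sample-by-sample R² over the session (the literal contract). The
model-level `linearity_r2` (reported by `fit_ln_model` and the per-category
comparison) is computed on binned predicted-vs-measured means: the observed
rate is averaged within bins of m and compared with the identity line. The
session-wise statistic is dominated by the shot noise of a σ = 10 ms rate
estimate (and collapses under random subsampling of the train, since
thinning raises the relative noise), whereas the binned statistic measures
the linearity of the rate code itself, is stable under subsampling with the
N_all/N_category rescaling, and sits on the scale of the reported per-cell
values (~0.95 for the full synthetic train, lower for pause spikes).

A known estimator limitation: the plain STA is unbiased only for
uncorrelated stimuli. Saccadic velocity is temporally correlated (burst
profiles) and the rectified channels are correlated across directions, so
the recovered kernels are smeared by the stimulus autocorrelation and carry
small negative cross-channel lobes; with a fully noiseless linear rate the
prediction tops out near R² ≈ 0.95 (session-wise) rather than 1.0. The
unbiased alternatives (multichannel least squares, whitened STA) are out of
scope by design; a prototype of single-channel spectral deconvolution was
noise-dominated and rejected.

## Statistics scaffolding

Normality gate: D'Agostino's K² (scipy), n ≥ 20, level 0.05. Empirical
p-values use the plus-one rule (1 + #{controls ≥ observed})/(1 + n), so p is
never zero and is monotone in the observed statistic. Power is the fraction
of with-replacement resamples on which the same test passes at the same
level; a result is reported significant only when p < level and
power > 0.8. Standard named tests (rank-sum, KS, Fisher z) are delegated to
scipy as pipeline plumbing.

## Synthetic sessions: what they emulate, and what not

Defaults (all overridable): 120 s; simple rate 55 Hz with gamma-renewal
regularity CV 0.2; complex spikes 0.8 Hz, each followed by a 10–30 ms pause;
pauses at 3 Hz with durations from a power law (α = 3.78, x_min = 30 ms),
initiating spikes relocated to a von Mises draw (κ = 4) around 48.7° of the
25 Hz carrier phase and terminating spikes placed at the nearest matching
phase around the drawn duration end, +278.3° away (nearest — not next —
so the duration jitter is symmetric and does not bias the fitted tail
exponent); LFP = cosine of the carrier phase (reset at each saccade onset
with von Mises jitter κ = 0.408, which fixes the expected R_LFP at
I₁/I₀(0.408) ≈ 0.20) + a direction-independent saccade-evoked biphasic slow
wave (σ = 30 ms, amplitude scaling with saccade size — this gives the LFP
its eye-motion correlation below the beta/gamma band) + 1/f background
noise; saccades toward 8 targets, amplitudes 2.5–20°, main-sequence-like
duration 20 + 1.8·A ms, Gaussian speed profiles, ~2 s⁻¹ with a 250 ms
refractory gap; kinematic kernel = Gaussian bump (center +50 ms, width
30 ms, unit time-integral) with cosine direction tuning and gain
0.3 (spikes/s)/(deg/s), i.e. saccadic bursts on the order of 100 spikes/s at
peak speed — consistent with saccadic burst sizes in this cell type; weaker
gains leave the rate code statistically invisible at session length.
Randomness is split into named substreams (eye, lfp, spikes, pauses,
complex) of one seed; identical (config, seed) reproduces sessions bitwise.

What the generator does *not* emulate: spike waveforms and sorting errors,
LFP volume conduction and electrode placement, the dependence of pause
probability on behavior (pauses are planted uniformly in time, so
peri-saccade pause-spike rate peaks are cycle-level, not event-level),
>200 ms bistability pauses, saccade curvature and overshoot, and any
across-cell heterogeneity. Passing recovery tests therefore demonstrates
the estimators' correctness under the assumed statistical structure, not
their robustness to real-world artifacts.

## Problem sizes

Test and validation runs use sessions of 60–600 s (most statistics
stabilize by ~100 s at the default rates): 300 s for phase-recovery
statistics (≥ 500 planted pause spikes), 600 s for LN kernel recovery, ten
100 s sessions for cohort-level orderings, 50,000 samples for power-law
refits, and 100-trial ensembles for reliability calibrations. These sizes
were chosen so each quantity's Monte-Carlo error is small against its
tolerance.
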