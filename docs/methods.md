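# Methods

`mobiphys` implements a complete measurement-and-inference chain for a
within/between psychophysiology experiment: participants watch six
one-minute walk-through videos of urban and green environments (green Gr,
indoor/outdoor crowded IC/OC, indoor/outdoor uncrowded IU/OU; the green
space shown twice) while walking or standing on a treadmill, with mobile
EEG, electrodermal activity (EDA) and post-stimulus SAM self-reports
recorded on one clock.  Because no public recording of this paradigm is
available, the package ships a synthetic-session generator with complete
ground truth; every estimator in the pipeline is validated against that
truth.

## Experimental design

A session is a contiguous block timeline: 180 s seated reading baseline,
60 s seated fixation baseline, (walking group only) 180 s walking fixation
baseline, then six trials of [60 s fixation ISI + 64 s video].  Videos
include 2 s fade-in and fade-out; the analysed video window is seconds
2–62 after onset, paired with the 0–60 s window of the preceding fixation.
The video order is the counterbalanced sequence Gr–IC–OU–Gr–OC–IU or its
exact reverse.  Time conventions are half-open intervals `[start, end)` in
seconds; a sample belongs to the window if `floor((t - t0) * rate)` lands
inside it.

## Synthetic data generator

**EEG** (default 27 channels: the 24-electrode mobile 10–20 montage plus
F3, F4 and AFz, which the frontal indices require; 500 Hz): each channel
is a sum of

* 1/f^β background noise (β = 1, σ = 8 µV) — the aperiodic EEG floor;
* white sensor noise (σ = 2 µV) and a 50 Hz mains component (≈1.5 µV,
  random per-channel amplitude/phase), so that the cleaning stages have
  real power to remove;
* per-band narrowband oscillators (theta 4–7.5, alpha 8–12.5, beta
  13–24.5 Hz), built in the frequency domain as band-limited Gaussian
  processes.  Amplitude follows the sinusoid convention: an oscillator of
  amplitude A contributes A²/2 of variance in expectation, with zero
  spectral leakage outside its band.  Condition gains multiply the
  oscillator amplitude inside video blocks (with ramps over the fade
  periods), so a gain g produces a g² power ratio against the preceding
  ISI — the analytic target all index-recovery tests use.
* for the walking group, gait-locked artifact bursts at the 1.85 Hz step
  cadence of 4 km/h treadmill walking (cadence + harmonics + broadband
  transient, Hann-windowed 150 ms, ≈30 µV) during every treadmill block.

Default condition gains mirror the qualitative pattern the paradigm is
built to detect — green raises frontal alpha (1.10), crowding raises
frontal theta (IC 1.10, OC 1.08), green slightly favours right-frontal
alpha (F4 1.05).  The literature does not constrain these effect sizes;
they are free generator parameters, chosen once to be comfortably
detectable at n = 20/group without being unrealistic (≈10–20% band-power
changes).

**EDA** (128 Hz): conductance = tonic + phasic + noise.  The tonic level
is 2 µS plus a walking offset of +0.35 µS (mild physical activity raises
sudomotor tone) and a slow drift (σ = 0.25 µS on a 60 s correlation
timescale — drifts faster than ~tens of seconds would masquerade as
phasic activity, which real tonic EDA does not).  Phasic responses are a
Poisson process (4/min at rest, 5/min uncrowded videos, 8/min crowded;
×1.5 when walking) of Bateman-shaped SCRs `b(t) = exp(-t/τ1) -
exp(-t/τ2)` with τ = (2.0, 0.7) s, normalized to unit maximum so the
event amplitude (log-normal, median 0.3 µS, σ_log 0.5) equals the SCR
peak height.  Measurement noise is 5 nS white.  The generator records
every event, the noiseless trace and the tonic series.

**SAM**: integer 1–9 ratings (arousal 9 = calm, valence 9 = negative) are
latent condition means plus N(0, 1.2) noise, rounded half-up, clamped.
Latent means follow the paradigm's expected ordering (green calmest and
most positive, crowded most arousing and most negative).

One master seed is expanded through `SeedSequence.spawn` into per-stream
substreams (EEG, EDA, SAM, misc), so adding a stream never perturbs the
others and equal seeds give bit-identical sessions.

What the generator does **not** emulate: volume conduction and channel
covariance, eye-blink/EMG sources, nonstationary band power within a
block, SCR shape variability between events, rater idiosyncrasies beyond
Gaussian noise.  Passing tests therefore demonstrate that the estimators
recover the structure the analysis assumes, not that they are robust to
every artifact of real recordings.

## EEG spectral analysis

Power spectra are Welch averaged modified periodograms: 1 s Hann windows,
250 ms overlap, zero-padded to a 0.5 Hz grid, density-scaled so the
integral over frequency equals signal variance.  The 1 s window was
chosen because a shorter (0.5 s) Hann window has a ±4 Hz mainlobe that
pushes ~3% of a 10 Hz sinusoid's power outside the closed 8–12.5 Hz band,
breaking the package's 2% band-power oracle; with 1 s windows the error
is < 0.1%.  Band power is the simple bin-sum × bin width over bins whose
center lies in the closed band interval.

Baseline correction expresses video power as a percentage of the paired
ISI power: `100 + 100·(Pv − Pi)/Pi`.  The value is invariant to common
rescaling and bounded below by 0.  Note one finite-sample property the
tests account for explicitly: the percent value is a ratio estimator, so
its *mean* across trials exceeds the true power ratio by approximately
cv² of the ISI power (≈ +1% at 60 s epochs and 4.5 Hz bands).  Null
centering is therefore checked against `100·(1 + cv²)`, not bare 100; the
log-ratio FAA is free of this bias by symmetry.

Indices per trial: FA = mean corrected alpha over {F3, F4, F7, F8, FP1,
FP2, AFz, Fz}; FMT = mean corrected theta over {Fz, AFz}; TBR = mean
frontal corrected theta / mean frontal corrected beta; FAA = ln(corrected
alpha at F4) − ln(at F3) (right minus left; higher values read as
approach/positive affect).  Corrected values below 10⁻⁶ invalidate a
trial's FAA rather than being clamped.

## EEG quality (SNR)

Cleaning chain: zero-phase 4th-order Butterworth band-pass 1–40 Hz; mains
removal by per-window (4 s) least-squares sine/cosine regression at 50 Hz
(no notch distortion of neighbouring frequencies); artifact suppression
by robust z-scoring of 0.5 s window RMS with spline replacement of
flagged windows.  The suppressor's reference statistics come from the
seated fixation baseline: persistent rhythmic artifacts (gait) dominate a
walking recording's own median/MAD, so self-referenced thresholds would
never flag them.

SNR per channel and segment is `10·log10(Σ clean² / Σ (filtered −
clean)²)` with the band-passed signal as `filtered` and the fully cleaned
signal as `clean`; zero residual maps to +inf, zero clean power to −inf.
Quality scores are the channel-mean SNR of the 60 s sitting baseline
minus each of the six ISIs (positive = ISI noisier than baseline), six
values per participant.

## Electrodermal deconvolution (CDA)

Preprocessing: anti-aliased polyphase resampling to 16 Hz, then a
first-order 5 Hz Butterworth low-pass (zero-phase).  The driver
convention is `sc = conv(driver, kernel)/rate` with a unit-maximum
Bateman kernel, so an impulse of time-integral a µS reproduces an SCR of
peak height a.  Deconvolution is frequency-domain division with Tikhonov
regularization (λ = 10⁻⁸ of the kernel's peak spectral power) on a
constant-extended signal, which keeps onset transients and circular
wrap-around out of the returned segment; `reconvolve` applies the inverse
convention (steady-state history) so noiseless round trips close to
< 1% RMSE.

The tonic driver is a Pchip interpolation through inter-impulse medians
on a 10 s grid (impulse regions = driver > median + 3 robust SD, widened
by 1 s), lightly smoothed; tonic conductance is its re-convolution and
the phasic component the remainder.  SCRs are contiguous suprathreshold
segments of the (0.25 s Gaussian-smoothed, mass-preserving) phasic
driver; an event's amplitude is the driver mass integrated to the next
onset, and nSCR counts events above 0.05 µS (config-exposed).  Trial
measures per window: SCL = mean tonic (µS), ISCR = ∫ phasic driver dt
(µS·s), nSCR; plus video-minus-ISI differences per trial.

Tau optimization is Nelder-Mead on log-taus from the best point of a
coarse lattice (the criterion surface holds spurious local minima).  The
criterion is driver negativity plus an indistinctness term measured as
the failure of a distinct-impulse representation: suprathreshold bursts
collapsed to single impulses at their center of mass, re-convolved, and
scored by the residual against the observed conductance.  Both terms
vanish for a correctly specified kernel on clean data; on sparse,
low-noise records the search recovers (2.0, 0.7) from a (3.75, 1.0)
start essentially exactly.  Under heavy noise or dense overlapping
responses the rise constant τ2 is weakly identified (a known property of
Bateman-kernel fitting at 16 Hz), which is why amplitude-recovery
checks are run with the correctly specified kernel and τ recovery is
demonstrated on sparse event trains.  The default initialization (3.75,
1.0) s is config-exposed.

## Bayesian hierarchical contrasts

For each measure (SAM arousal/valence raw; FA, FMT, TBR, FAA as percent
values, already ISI-normalized; SCL and ISCR as video-minus-ISI
differences) the model is

    y ~ StudentT(ν, μ, σ_group),
    μ = β₀ + β_W·walk + β_c + γ_c·walk + u_participant + w_schedule,

with treatment coding (standing, Gr reference), participant and
counterbalance-schedule random intercepts, a heavy-tailed likelihood
against outliers and a separate residual scale per group.  Priors are
weakly informative: Normal(0, 2.5·sd(y)) on locations (intercept centered
at the sample mean), half-Student-t(3, sd(y)) on all scales, Gamma(2,
0.1) on ν − 2.

Sampling exploits the scale-mixture representation of the Student
likelihood (t_ν = normal with latent Gamma(ν/2, ν/2) precision weights):
each sweep draws the weights exactly, then all location parameters
jointly from their multivariate-normal full conditional (one Cholesky
solve), then the residual scales and ν by collapsed random-walk
Metropolis steps on the log scale using the *marginal* Student likelihood
— collapsing is what makes ν mix (its conditional given the weights is
far narrower than its marginal posterior).  Step sizes adapt toward 44%
acceptance during warmup only.  Defaults are 4 chains × 4000 iterations
(2000 warmup) with convergence declared at split-Rhat < 1.01; simulation
studies and the test suite use the scaled-down 2 × 1000 (500 warmup)
setting, at which a 40-participant fit takes about a second.

EMMs are per-draw cell means of group × condition with random effects at
their zero population mean; the two green presentations enter the model
as two trials of one Gr level, which pools them.  Planned pairwise
contrasts (Gr vs each urban condition; crowded vs uncrowded; outdoor vs
indoor, within group) are summarized by median, SD, equal-tailed 95% CI,
the posterior probability PP of first-minus-second > 0, and evidence
ratios ER01 = PP/(1−PP), ER10 = 1/ER01 ("Inf" when no draw opposes the
direction).  Table flags: bold when PP > 0.85 or < 0.15, star when
PP > 0.95 or < 0.05.  Bayes-factor-style evidence ratios are labelled on
the standard anecdotal/substantial/strong/very strong/decisive bins
(boundaries to the lower bin; values below 1 labelled by the reciprocal's
bin).

Per-participant summary measures (mean SNR difference, raw video-window
SCL/ISCR/nSCR, spatial-presence score) are tested for a directional
walking-group effect with the same robust likelihood in a two-group
location model (no random effects; sampled with an affine-invariant
ensemble, 5 parameters).

## Calibration studies

The inference stage is calibrated on tables drawn from the model's own
data-generating process (2 × 5 design, 20 participants/group, 6 trials
each, Student-t(10) residuals, participant SD 0.5, schedule SD 0.1,
residual SD 1): over 100 replicates with a 1-SD Gr shift injected, the
two-sided star rate on the four within-urban (null) contrasts sits near
the nominal 10%, the 95% CI of the Gr–IC contrast covers the injected
truth at ~95%, and the posterior median recovers it with |median bias| <
0.3 SD.  Signal-level recovery (criteria on FA/FAA/CDA) is exercised
separately through the session generator, so the two stages are validated
independently; problem sizes (100 trials, 100 replicates, scaled-down
sampler) are the package's own defaults for these studies.

## Known limitations

* The artifact suppressor is a deliberately simple robust-z/spline
  cleaner: it needs a clean calibration baseline, and it attenuates
  rather than reconstructs (no subspace methods, no source separation).
* τ2 of the Bateman kernel is weakly identified on dense or noisy
  records; amplitude estimates inherit a scale error when the kernel is
  mis-specified.
* The Gibbs sampler's schedule random intercept has only two levels; its
  scale is barely informed by data and mostly follows its prior, as
  expected.
* XDF import requires the optional `pyxdf` dependency; the native text
  format is the tested interchange path.
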