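# Methods

## The generative model behind the synthetic study

Every downstream stage is validated against data from an explicit
forward model (`orsound.synth`). One session consists of `n_blocks`
blocks (default 28, half low-demand, half high-demand, balanced over
session halves), each a `block_duration_s` soundscape at `audio_fs`
(default 48 kHz; the analysis demos use 8 kHz to keep runtimes in
seconds) with EEG at `eeg_fs` (default 500 Hz; demos use 125–250 Hz).

**Soundscape.** Stationary 1/f-colored noise (the ventilation/machine
floor, RMS 0.05) plus Poisson-scheduled transients (rate 0.5/s): tone
pips with log-uniform frequency 0.5–4 kHz and band-passed noise bursts,
50–150 ms, amplitudes 0.2–0.5, with 5 ms attacks and exponential decays
(machine beeps and instrument clatter start abruptly; this also makes
onset times well defined). The first 500 ms are linearly faded in. Every
transient onset is logged, so onset-detector recall/precision are
measurable.

**Letter stream.** Four letters per block drawn from the 12-letter set
minus the letters memorized in that block, presented as shuffled groups
of four every 3 s with no immediate repetitions. Tokens are brief
formant-like chirps (two damped sinusoids, 10 ms ramps) — only their
timing and energy matter to the pipeline; no speech realism is claimed.

**EEG.** `EEG = Σ_f (kernel_f ⊛ feature_f) ⊗ pattern_f + ERP template at
letter onsets ⊗ pattern_ERP + noise`. Kernels are sums of Gaussians with
N1/P2/N2 morphology (envelope kernel peaking earlier than the onset
kernel, e.g. N1 trough at 80 vs 100 ms); spatial patterns are unit-norm
fronto-central Gaussians on the 24-channel 10–20 montage (Fp1…O2 with
M1/M2). A multiplicative `condition_scale` (default 1.0, i.e. the null
the real study reported) and a linear per-block drift `time_slope`
(default 0.005/block) scale the kernels. Noise is 1/f (exponent 1.0)
shaped white noise from latent sources projected through smooth random
scalp topographies plus a broad common-mode component and a 10%
independent sensor floor — the spatial correlation structure matters:
neighbour-based channel rejection is meaningless on spatially white
noise. `snr_db` sets planted-signal RMS over noise RMS. Optional
artifacts: 50 Hz line noise, frontal blink pulses (squared sinusoids,
300 ms, 80 µV), temporal/mastoid high-frequency muscle bursts, flat or
noisy channels. Letter markers are written 30 ms *before* the true sound
onset, emulating the constant hardware delay the correction stage
removes.

**Behavior.** Workload ratings follow `intercept + β_cond·condition +
participant intercept + noise` clipped to the 0–20 scale, with β values
on the scale of a visual-analog workload questionnaire (effort 3.7,
frustration 2.7, distraction 1.3; SDs 2 and 3). Surgery duration decays
exponentially over blocks (learning); mistakes are Binomial(3, p) with
slowly declining p; tissue damage is Poisson with a log-linear time
trend (−0.02/block); memory responses are simulated item-wise with
load-dependent substitution (8% low, 30% high) and omission ('X', 8%)
probabilities and scored downstream. All draws derive from
`SeedSequence(seed, stream, participant, block)`; identical configs are
bit-identical.

What the generator does *not* emulate: real speech, room acoustics,
non-stationary noise floors, movement artifacts correlated with task
events, ECG, electrode drift. Passing tests therefore demonstrate that
the pipeline recovers what it is designed to recover under its own
assumptions (linear time-invariant responses, stationary noise) — not
that those assumptions hold in an operating room.

## Acoustic features

*Envelope*: squared magnitude of the Hilbert analytic signal, averaged
over consecutive windows of `fs/target_rate` samples, compressed by the
cube root (exponent configurable; 1 disables). A constant-amplitude tone
of amplitude A gives A² per window before compression.

*Wiener denoising*: 1 Hz high-pass, then an STFT (32 ms Hann frames,
8 ms hop) gain `max(0, 1 − PSD_noise/PSD_frame)` with the noise PSD
taken from the first second. The frame PSD is smoothed over 9 frames ×
9 frequency bins before the gain; without smoothing, single-periodogram
chi-square fluctuation leaves ≈45% of a stationary floor's RMS, with it
≈16%. Both smoothing sizes are parameters.

*Onsets*: half-wave-rectified spectral flux on log-compressed STFT
magnitudes (16 ms frames, 4 ms hop), detrended by a 0.5 s running
median, thresholded at 5 robust (MAD) units, peak-picked with a 50 ms
minimum inter-onset interval. Calibrated clicks at 10 dB SNR over a
stationary floor are recovered with recall = precision = 1; slow-attack
events are harder (a known property of flux detectors, reported, not
hidden, by the feature-quality script).

*Marker corrections*: the constant delay shift is exact integer-sample
arithmetic with clamping at the recording end; letter-onset refinement
scans the 5 ms-smoothed short-time energy over a 20 ms window and moves
the marker to the first supra-threshold (10% of window max) point after
which the energy stops rising within a 2.5 ms look-ahead.

## EEG preprocessing

Stage order is fixed and recorded in each recording's history: band-pass
→ restrict to sound (±5 s trimmed, <10 s segments dropped) → channel
rejection → ICA → interpolation → linked-mastoid re-reference. Filters
are MNE Hamming-window FIR with transition bands 0.5 Hz (high-pass) and
7.5 Hz (low-pass); with MNE's automatic length rule these reproduce
orders 3300/220 at 500 Hz and rescale proportionally. Zero phase is
realized as a compensated linear-phase one-pass filter rather than a
forward–backward pass; latencies are unaffected.

*Channel rejection* reconstructs each channel in 5 s windows from its
best-correlated 4 of 8 nearest neighbours (inverse-distance weights),
on a fresh random 60% window subsample per pass; a channel is flagged in
a pass when its reconstruction correlation is below 0.8 in more than
50% of windows, and removed when flagged in ≥50% of 10 passes, worst
first, at most 5. Choosing the reconstruction subset by correlation
makes a good channel robust to broken neighbours while a broken channel
finds no consensus; the pass-level randomness lives in the window
subsample. Known limitation: dense ocular artifacts degrade the frontal
reconstructions and can cause false alarms — blinks belong to the ICA
stage, and the stage order puts channel votes before ICA exactly as in
the underlying protocol, so heavily blink-laden data should rely on the
vote cap.

*Joint-probability screening* estimates per-channel amplitude densities
by histogram (Scott's rule bins), scores each epoch by its negative mean
log-density per channel (local) and summed over channels (global), and
rejects epochs above mean + k·SD on either score (k = 5 for the ICA
copy, 3 for ERPs). Identical epochs (zero spread) reject nothing, with a
warning.

*ICA* is fit on a 1 Hz high-passed copy cut into 1 s epochs and screened
at 5 SD; fastICA is the default (extended infomax is available but an
order of magnitude slower at these sizes with identical downstream
classification on planted artifacts). Components are classified by
heuristics replacing a trained classifier: blink = fronto-polar
dominance (ratio > 1.8) with >50% power below 3 Hz; muscle =
mastoid/temporal-edge dominance with >60% power above 20 Hz; horizontal
eye = opposite-sign lateral-frontal dipole. Flagged components (plus any
manual overrides) are zeroed and the mixing is applied to the original
unfiltered data; bad channels stay untouched. Interpolation is MNE
spherical splines; re-referencing subtracts the M1/M2 mean, which makes
the mastoid average identically zero.

## TRF estimation

EEG is scaled by 0.0313 before fitting (the mTRF convention, making the
λ grid portable). The lag expansion is inclusive with `floor` at the
lower and `ceil` at the upper edge (0–450 ms at 100 Hz = 46 lags). The
ridge penalty is `λ · mean(diag(X'X)) · I` on the mean-centered design,
so the `10⁻⁸…10⁸` grid is dimensionless. Cross-validation partitions
blocks into k contiguous segments (28 blocks, k=10: eight 3-block then
two 2-block segments; remainders go to the earliest segments); per-block
Gram matrices are computed once and train sets are formed by
subtraction, so a held-out segment provably never enters the training
normal equations. λ* maximizes the fold-and-channel mean Pearson r.
Per-block TRFs (−220…500 ms lags) use the participant's modal per-fold
winner (ties toward the larger λ) and are z-scored across (lag, channel,
block) within participant. Prediction accuracy is reported
channel-then-block averaged (the block-then-channel order is also
computed and logged; on balanced synthetic data the two differ only in
the fourth decimal). The common analysis rate is 125 Hz, configurable.

## GED spatial filters

Per response family and component, peak search windows are fixed (ERP
and onset-TRF: N1 80–150, P2 150–250, N2 200–300 ms; envelope-TRF: N1
50–120, P2 120–220, N2 220–320 ms), half-widths ±25 ms (N1) / ±50 ms
(P2/N2), polarity negative/positive/negative. Window and baseline
(−200…0 ms) samples are mean-centered per participant and their
covariances averaged across participants after removing Frobenius-norm
outliers beyond mean + 3 SD (joint exclusion from both sets, single
recomputation). The reference is shrunk toward its mean eigenvalue
(`(1−0.01)·R + 0.01·mean(eig R)·I`) and the symmetric-definite pencil
solved with `scipy.linalg.eigh`; forward models are `S·w` at unit
max-abs. Component 1 is used unless its topography fails a
fronto-central plausibility correlation (threshold 0.5) that component 2
passes; the chosen component's sign is flipped to match the specified
polarity, so eigenvector sign ambiguity never reaches the amplitudes.
Amplitudes are window means of `w'·response` per (participant, block).
Note the window-covariance estimate needs the fine ERP time grid: at
500 Hz the ±25 ms N1 window holds 25 samples, at 125 Hz only 7, which
visibly degrades topography recovery — the validation sims therefore use
the 2 ms grid.

## Statistics

Memory scoring is `1 − d/L` with Levenshtein distance `d` (unit costs,
'X' never matches) and `L` the longer string, clipped to [0, 1].

The three nested fixed-effect structures share a participant random
intercept. The linear model is fitted by profiling the variance ratio
(1-D bounded optimization with an explicit γ=0 boundary check) using
per-group Woodbury identities; REML supplies the reported coefficients,
a matching ML fit the likelihood-ratio tests. Satterthwaite degrees of
freedom follow the standard construction `df = 2f²/(g'H⁻¹g)` with `f`
the coefficient variance, `g` its numeric gradient in (σ²_b, σ²_e) and
`H` the numeric REML Hessian; estimates, SEs, df and p-values reproduce
lme4/lmerTest to the printed precision (tested via Rscript). The Poisson
model adds a participant random intercept integrated by a one-dimensional
Laplace approximation (vectorized Newton mode-finding per group); the
cumulative-logit model uses strictly-increasing-by-construction
thresholds and adaptive Gauss–Hermite quadrature (9 nodes), and with two
categories reproduces a random-intercept logistic regression
(cross-checked against lme4's `glmer`). Model selection is stepwise: 1→2
tested at α=0.05 on ML likelihoods, 2→3 only if time improved the fit.
Wilcoxon signed-rank drops zero differences, reports `W = min(W⁺, W⁻)`,
and uses exact sign-flip enumeration (tie-aware, via half-integer rank
doubling) for n ≤ 12, a continuity- and tie-corrected normal
approximation otherwise. Bonferroni thresholds are α/m, displayed at two
significant digits (0.05/3 → 0.017, 0.05/6 → 0.0083).

## Validation design and problem sizes

The test suite validates each stage against planted ground truth or an
independent oracle (brute-force DP edit distance, sign-flip enumeration,
closed-form ridge, grid-search Rayleigh quotients, statsmodels MixedLM,
lme4/lmerTest/glmer via Rscript). The end-to-end checks use sizes chosen
to finish in minutes on one CPU while keeping effects estimable: TRF
kernel recovery uses 10 participants × 8 blocks × 5 min at 125 Hz and
SNR 0 dB; the feature-ordering study 10 participants × 4 blocks × 60 s
of 8 kHz audio; GED recovery 100 seeds of 8 participants at 500 Hz;
mixed-model calibration 200 recovery simulations and 1000
likelihood-ratio simulations at 22 participants × 28 blocks. Bias in the
recovery simulations is measured against same-data oracle controls
(GLS at the true variance ratio; Poisson GLM and ordinal logit with the
true random intercepts as offsets): the control variate removes
Monte-Carlo data noise, whose floor at 200 simulations (≈7% of the
estimate SD) would otherwise exceed the 5% bias band being checked.

## Known limitations

- The IC classifier is heuristic; it is validated on planted blink,
  muscle and lateral-eye sources, not on real ICA zoo diversity.
- The onset detector underestimates slow-attack events; detection
  latency is biased late by up to half the attack time.
- The channel-rejection stage can false-alarm on data dominated by
  ocular artifacts (see above).
- GED component choice automates what was originally a visual
  plausibility judgement; the `override` argument exists for manual
  decisions.
- Satterthwaite df are implemented for the random-intercept case only.
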