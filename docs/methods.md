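# Methods

This note documents the models, algorithms, numerical choices, and known
limitations behind `betaburst`, in the order the pipeline runs them.

## Synthetic EEG generator

The generator (`betaburst.synthetic`) emulates event-centered sensorimotor
EEG epochs: 3.6 s at 500 Hz, centered on one of four behavioral events
(trial start, first touch, grasp completion, trial end), over two electrode
clusters of four channels each. Each channel trace is the sum of three
components.

**Aperiodic background.** White noise spectrally shaped so its PSD follows
`10^offset · f^-χ` (defaults: offset 0 log10 µV²/Hz at 1 Hz, χ = 1.5 — a
typical scalp-EEG slope). The shaping is exact, so a log-log regression of
the Welch PSD recovers χ; broadband SD with the default settings is ≈3.6 µV.

**Sustained alpha/mu.** A 9.5 Hz sinusoid with random per-epoch phase,
amplitude-modulated by a slow positive envelope (smoothed noise, ~2.5 Hz
bandwidth, mean 1). Amplitude modulation widens the spectral peak enough to
pass the band-retention rule *without* the phase drift that frequency jitter
would introduce — lagged coherence of the synthetic alpha therefore stays
high across lags, as a sustained rhythm's should. The 9.5 Hz default places
the peak under the more permissive (<10 Hz, FWHM ≥ 1 Hz) retention rule, in
the upper mu range.

**Beta bursts.** Burst times follow a thinned Poisson process with a hard
refractory period: candidates at driver rate λ, a candidate within `d`
seconds of the last accepted burst rejected. Inter-burst intervals are then
`d + Exp(λ)`, giving mean rate `λ/(1+λd)` and CV `1/(1+λd)`; the defaults
(λ = 15/7 ≈ 2.14 /s, d = 0.2 s) give an observed ~1.5 bursts/s with CV 0.7,
i.e. timing more regular than Poisson. Rate-profile multipliers (per epoch
phase × cluster × pre/post event) are defined on the *observed* rate and
converted to driver units by inverting `λ_obs = λ/(1+λd)`; a configured 40 %
drop therefore appears as a 40 % drop.

Each burst is `amplitude × (carrier + Σ_k w_k · motif_k) × Gaussian
envelope`, with a negative-centered cosine carrier at the burst's peak
frequency (drawn N(beta_center, 1 Hz)), envelope FWHM drawn in cycles
(N(5, 1), clipped to [2, 9]), and amplitude N(12, 4) µV clipped positive
(age presets shift the band center to 14.5 / 15.25 / 21.5 Hz). Motif
weights `w_k` are zero-mean normal with distinct SDs (0.8 / 1.0 / 1.3):
equal variances would make the PCA rotationally degenerate inside the motif
span and the individual motif axes unidentifiable.

**Motif basis.** Three orthonormal, Gaussian-windowed *harmonic*
perturbations: flank asymmetry at the second harmonic, central-trough
sharpness (second harmonic), and extra peaky deflections (third harmonic).
This choice is deliberate: perturbations at the *fundamental* frequency are
confounded with the pipeline's nuisance directions — a one-sample alignment
shift perturbs the waveform along `sin(2πft)·env`, duration jitter along
`t²·cos(2πft)·env`, frequency jitter along `t·sin(2πft)·env` — and motif
weights placed on those directions are unrecoverable after extraction.
Harmonic motifs are orthogonal to all three nuisances, so their weights
survive the detection → alignment → PCA chain (weight/score correlations
≈ 0.9 on synthetic runs). Waveform-shape dimensions read out of
trough-aligned bursts at the fundamental frequency should generally be
interpreted with this confound in mind.

**Shape-dependent gating.** Optionally, bursts whose motif weight exceeds a
z-threshold are thinned after the centering event of one epoch phase —
emulating selective rate modulation of particular waveform shapes, the
effect the quartile analysis is designed to detect.

What the generator does *not* emulate: eye/muscle artifacts, volume
conduction and channel correlation, non-Gaussian burst envelopes,
non-sinusoidal alpha, ERPs, and inter-participant variability in band
centers. Passing tests on this data demonstrate algorithmic correctness and
statistical calibration, not robustness to real-world artifacts.

## Spectral parameterization and band identification

PSDs use Welch's method via MNE (1 s segments, 50 % overlap, 10×
zero-padding → 0.1 Hz grid). The aperiodic component is a straight line in
log10 power vs log10 frequency over 1–90 Hz, fit by least squares with
three rounds of masking points more than 1.5 residual SDs *above* the fit
(so narrowband peaks cannot drag it up); no knee term. The periodic
spectrum is the log-power residual.

Band identification iterates on the (group-mean) periodic spectrum: fit a
Gaussian at the global maximum — least squares on a window of ±2× the raw
half-max half-width, FWHM taken from the fitted σ — subtract it, and repeat
until the maximum falls below the noise floor (1 SD of the residual over
all frequencies, recomputed each iteration). If a fit fails to reduce the
maximum, the raw peak is subtracted instead so the loop always progresses.
Retention: FWHM ≥ 1 Hz below 10 Hz, ≥ 3 Hz above. The tallest retained peak
in 13–30 Hz is labeled beta; the nearest retained peak below it alpha/mu.

## Lagged coherence and the waveform window

For frequency `f` and lag `l` (cycles), trials are tiled with
50 %-overlapping Hann-tapered segments of width `l/f` seconds; lagged
coherence is `|Σ F(t)·F*(t+l/f)| / √(Σ|F(t)|²·Σ|F(t+l/f)|²)` over all
segment pairs one width apart (trials pooled). Cells whose tiling does not
fit are missing (NaN), excluded from band averages. Maps are normalized by
the per-participant maximum over channels × frequencies × lags.

The waveform-extraction window is the FWHM in lag of the band-averaged
profile. When the profile's maximum sits at the first measured lag (a
decaying profile whose true peak lies below 2 cycles) or never halves, a
Gaussian is fit to the whole profile and its analytic FWHM used, clipped to
[2, 8] cycles and flagged — this is how windows longer than the measured
lag range arise. Cycles convert to ms at the band center frequency,
truncated to integer samples.

## Superlet transform

Morlet wavelets (σ_t = cycles/2πf, support ±3.5 σ) are amplitude-normalized
so a unit sinusoid yields magnitude 1; the TF amplitude at frequency `f` is
the geometric mean of the response magnitudes of wavelets with cycle counts
`4, 8, …, 4·o(f)`, with `o(f)` the rounded linear map 1 Hz→1, 100 Hz→40
(multiplicative adaptive superlet; an additive variant is a switch). All
wavelets share one zero-padded FFT of the signal. A validity mask excludes
samples within half the longest wavelet's support of either edge — for the
beta band of a 3.6 s epoch that leaves roughly ±0.85 s around the centering
event. Consequence worth knowing: the geometric mean *widens* a burst's
apparent TF duration (each wavelet smears the envelope to
√(σ_burst²+σ_wavelet²); the geometric mean of Gaussians averages inverse
variances), so a 5-cycle burst at 21.5 Hz reads as ≈7.9 cycles
(`expected_tf_duration` computes this).

## Burst detection

The aperiodic fit, converted to amplitude (√ of linear power), is
subtracted row-wise from the single-trial TF matrix restricted to the band
± 5 Hz; negatives clip to zero. Then iteratively: find the global maximum
over valid bins; stop when it no longer exceeds mean + 2 SD of the current
residual (recomputed each iteration); otherwise measure the half-max
crossing distance on each side in time and frequency, subtract a two-piece
Gaussian (per-side σ = half-width·2/2.355, evaluated on a ±5σ window), clip
and continue, up to `max_iterations`. Two implementation choices differ
from the plainest reading of the method and matter in practice:

* **Per-side widths instead of a symmetric minimum.** Superlet blobs are
  skewed in frequency; a symmetric-minimum Gaussian leaves 25–50 % shoulder
  residue that re-triggers detection as spurious neighbors. Per-side widths
  remove the shoulders; a 1.75 ratio cap between sides prevents an
  overlapping neighbor from inflating one side and being absorbed.
* **Fragment merging.** A later detection within half the time-FWHM *and*
  the full frequency-FWHM of an earlier one is a fragment of the same blob:
  distinct same-channel bursts are separated in time by the refractory
  period, while Gaussian-removal fragments split along frequency.

Reported amplitude is the aperiodic-subtracted value at the peak *before*
any Gaussian removal; `residual_amplitude` (the residual at the moment of
detection, i.e. the newly explained amplitude) is also stored — the
detector intentionally catalogs events down to the noise floor, and
`residual_amplitude` is the quantity that separates substantive events from
noise-floor peelings in validation and downstream interval statistics.
Burst duration in cycles is FWHM duration (s) × peak frequency (Hz).

## Waveform extraction

The per-participant × condition × epoch-phase ERP is removed; the trace is
band-passed over the burst's detected frequency span (zero-phase Hamming
FIR, ~3 cycles of the low cut); the instantaneous phase comes from the
Hilbert transform. Candidate alignment points are the phase minima
(troughs). Because the TF peak time can err by up to half a period, the
*nearest* trough is ambiguous between the burst's central trough and a
one-period neighbor; among troughs within the 30 ms tolerance the deepest
(most negative band-passed value) is chosen — consecutive troughs are a
full period apart, where the envelope contrast is reliable. No trough in
tolerance, or a window crossing the trial edge, discards the burst. The
raw (unfiltered, ERP-subtracted) window is cut, DC-removed, and
sign-flipped if its central deflection is positive (the EEG sign is
arbitrary up to dipole orientation); a genuinely inverted burst aligns half
a period off with its central deflection still negative.

## Warping and waveform PCA

DTW uses the Rabiner–Juang Type-V local constraint with slope weighting
(c): net moves (1,1), (1,2), (1,3), (2,1), (3,1) — slopes ⅓ to 3 — each
decomposed diagonal-first, each elementary move charged its query-axis
increment times the local |difference|, accumulated cost normalized by the
query length. The weighting is asymmetric in query/reference by
construction. Median waveforms are max-abs normalized before warping; the
alignment path then maps every waveform of the query group onto the
reference length (many-to-one averaged, one-to-many repeated).

PCA (scikit-learn, full SVD) runs on centered, unscaled waveforms —
amplitude is meaningful. Significance per component: each column (time
point) of the waveform matrix is shuffled independently across bursts,
destroying inter-timepoint correlation while keeping marginal amplitude
distributions; the add-one permutation p-value compares each rank's
explained-variance fraction with its shuffled distribution. Note the
add-one estimator's smallest attainable p is 1/(n_perm+1); a warning is
emitted when the requested α is unreachable at the configured permutation
count. Group-vs-global comparisons use absolute correlations between
eigenvectors (and between scores of a common burst set), with per-row
maxima to absorb component reordering and sign flips.

## Rate modulation and interval statistics

Rates: per-participant histograms (25 ms bins; 50 ms for score/quartile
analyses) over trials and channel streams, smoothed with a Gaussian kernel
(σ = 3 or 2 bins, truncated at ±3σ, reflected boundaries), expressed as
`100·(x−baseline)/baseline` with the baseline taken from the 1.5 s before
trial start (the pre-event window of the trial-start epoch), restricted to
the same laterality; score time courses are baseline-*subtracted* instead,
with empty bins filled at the participant baseline (no evidence of
deviation). Zero baselines produce missing values with a warning, never
infinities. Quartiles use linear-interpolation sample quantiles; each
quartile's baseline uses only its own bursts.

Inference: one-sample hat-t across participants (sample variance inflated
by σ=0.001 times the maximum variance over time points), TFCE (start 0,
step 0.01 for rates / 0.2 for scores, E=0.5, H=2, per sign), and
max-statistic sign-flip permutations; p-values use the add-one estimator.
Sign flips leave squared values unchanged, so the permutation null is
computed from flipped means and a fixed sum of squares — identical to
recomputing hat-t per flip, but vectorized.

IBI statistics pool within-stream (participant × trial × phase × channel)
interval differences; CV = SD/mean; surrogates redraw each burst's time
uniformly within its trial, preserving per-stream counts; the reference
bound is the 2.5th percentile of 1000 surrogate CVs. Epoch windows censor
long intervals and bias the pooled CV down by a few hundredths on 3.6 s
epochs; validation of the configured CV uses long (10.8 s) epochs where the
bias is negligible.

## Validation experiments and problem sizes

`betaburst.experiments` fixes the validation conditions. Burst recovery
uses a sparse, high-SNR process (observed ~0.5 /s, 0.3 s refractory,
amplitudes 6× the broadband background SD) over 200 trials so ground-truth
matching is unambiguous; recall/FDR are computed over detections whose
newly explained amplitude exceeds half the expected TF response
(`expected_tf_amplitude`) of the weakest injected burst class, reflecting
the detector's detect-everything design. Motif-gating and hemisphere
experiments run 8 participants × 16 trials on the full 4+4 montage with
detection capped at 60 peeling iterations, 199–200 permutations, α=0.0125
per quartile (the study-scale Bonferroni thresholds are unreachable at
these permutation counts). FWE calibration uses 200 null simulations of 12
participants × 60 time points at 200 permutations. These sizes give stable
statistics in minutes on one CPU.

## Known limitations

* Burst features are biased by the transform: TF durations are
  wavelet-broadened, and frequency spans reflect wavelet bandwidth as much
  as burst content. Comparisons across bands/ages are consistent, absolute
  values are not "true" burst parameters.
* Waveform motifs at the fundamental frequency are partly confounded with
  alignment phase, duration, and frequency jitter (see the motif-basis
  section); the package's synthetic validation therefore uses harmonic
  motifs, and interpretation of fundamental-frequency motifs on real data
  inherits this caveat.
* The detector's noise-floor tail means raw catalogs mix substantive bursts
  with small noise events; analyses that are sensitive to event identity
  (IBI structure, recovery metrics) should use the `residual_amplitude`
  qualification.
* Only 1D (temporal) cluster statistics are provided; no spatial adjacency,
  no two-sample designs.
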