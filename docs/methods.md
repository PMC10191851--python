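# Methods

This note documents the models, estimators, parameter defaults and design
decisions behind `gliocircuit`, and what the synthetic-data generators do
and do not emulate.

## ECoG high-gamma chain

Speech-locked analysis assumes a continuous multichannel recording
(native 1,200 Hz in the intended setting) and a table of vocalization
onsets. Screening precedes referencing: channels whose sample kurtosis
(Pearson convention, Gaussian = 3) exceeds 5.0 are removed first, and the
common average is computed over the retained channels only, so artifact
channels cannot contaminate the reference. Zero-variance channels are
removed with a distinct `degenerate` reason code since kurtosis is
undefined for them. Trials are kept only when the response was correct and
the stimulus-to-response latency did not exceed 2 s (boundary inclusive:
exactly 2 s is kept). Epochs are half-open windows [−2, +2) s around
onset, 4·fs samples, onset at index 2·fs; trials whose window crosses a
recording edge are dropped and logged.

High-gamma power is the squared magnitude of the analytic signal after a
0.1 Hz high-pass and a 70–110 Hz FIR band-pass (Hamming-windowed design,
300 taps + 1). All FIR/IIR stages are applied forward–backward (zero
phase): speech-onset latencies must not be distorted, at the cost of
squaring the magnitude response. "Order 300" refers to the designed taps
before bidirectional application. The squared envelope is the standard
high-gamma power estimator and the only reading of an envelope-power
definition that is nonnegative by construction.

The ERSP variant resamples to 600 Hz, high-passes at 0.1 Hz, notches
60 Hz and every harmonic below the post-resampling Nyquist (Q = 30),
band-passes 70–170 Hz with a ~1 s windowed-sinc kernel, takes the
analytic-signal envelope, smooths with a Gaussian kernel of 100 ms FWHM
(σ ≈ 42.5 ms — we read "100 ms kernel" as the kernel's full width at half
maximum), resamples to 100 Hz, epochs, and z-scores each trial per channel.
Zero-variance trials are flagged and returned as NaN rather than silently
z-scored.

Tumour electrode labelling is purely geometric: a contact is a tumour
contact iff its minimum Euclidean distance to the necrotic-core point set
is ≤ 10 mm (boundary inclusive). Distances are reported per channel so the
caller can audit borderline contacts.

## Decoding

Features are time-binned high-gamma envelope values around onset (default
window [−0.5, +0.5) s, 10 bins; the window is configurable because no
single canonical choice exists). Each leave-one-participant-out fold
standardizes features using training-fold statistics only, then fits an
L2-penalized logistic regression with inverse regularization C = 1
(lbfgs, tolerance 1e-8, deterministic). Accuracy is pooled over held-out
trials; significance is the exact binomial upper tail P(X ≥ k) at chance
0.5 (primary), with the one-sided normal approximation reported alongside.
In the orchestrated pipeline, features are channel-averaged before
binning so participants with different post-screening channel counts share
one feature space.

## Imaginary-coherence connectivity

Cross-spectra are estimated by Welch segmentation (1 s Hann segments, 50%
overlap) on a ≥60 s epoch — at least 20 segments are required. The band
IC of a voxel pair is the |Im C_xy(f)| averaged over alpha-band bins,
*weighted by the cross-power* √(S_xx S_yy): coherency is numerically
undefined at bins carrying no energy, and the weighting removes their
influence while leaving broadband signals effectively uniformly averaged.
The weighting is invariant to per-voxel amplitude rescaling, and the IC
matrix is symmetric with zero diagonal and entries in [0, 1]. Because the
imaginary part of the coherency of any zero-lag real mixture vanishes,
adding a volume-conduction-like mixture voxel leaves existing pairwise IC
unchanged — the property motivating the estimator.

Per-voxel connectivity ("z-connectivity") is Fisher's atanh applied to
each pairwise IC (clipped at 1 − 1e-6 with a warning), averaged over all
other voxels, then standardized to zero mean / unit SD across voxels.
Tertile classification is rank-based with ties broken by voxel id: the top
⌊n/3⌋ voxels are HFC, the bottom ⌊n/3⌋ LFC, the remainder intermediate; a
constant vector yields all-intermediate with a warning. Tertiles default
to all analysed voxels (restricting to tumour voxels is a caller choice).
A tumour is HFC-positive when ≥1 HFC voxel lies inside the
contrast-enhancing mask.

### The contralesional voxel test

The tested null is that the Fisher-transformed IC between index voxel i
and the non-tumour targets equals the contralesional reference
connectivity to the same targets. Four readings are implemented
(`method=` on `contralesional_test`); choosing the default was the one
genuinely open design problem in this package, and we resolved it
empirically on the generator's exchangeable null:

- `welch` / `contra_mean_paired`: reference = mean Fisher IC between all
  contralateral voxels and each target, compared across targets. Targets
  are not independent replicates — estimation noise is shared along a
  voxel's row of the IC matrix, and the contralateral-average reference
  carries a per-dataset offset — so these tests are badly miscalibrated
  (observed false-positive rates ranged 0.0–0.8 under a symmetric null
  depending on the variant). They are retained for comparability.
- `mirror`: reference = the mirror-pair voxel's profile, paired over
  targets. Structural profile differences cancel exactly, but the shared
  row noise remains and the test is anticonservative.
- `mirror_block` (default): the contrast
  mean_j [F(i,j) − F(mirror(i),j)] is recomputed on 12 disjoint time
  blocks of the epoch and tested with a one-sample two-tailed t-test
  across blocks (df = 11). Blocks are (nearly) independent replicates,
  so the statistic is calibrated: measured false-positive rate
  0.03–0.08 per dataset (mean ≈ 0.05) at nominal 5%, with full power to
  detect a 3× coupling boost. Voxels without a mirror pair get NaN.

Mirror pairing reflects the x grid index across the midline; unpaired
voxels are excluded and logged.

## Aperiodic spectra and gamma power

Multitaper spectra use K = 29 Slepian tapers with time–bandwidth
NW = (K + 1)/2 = 15 and eigenvalue weighting; the one-sided density
integrates to the series variance. The aperiodic background is the
knee-parameterized Lorentzian log₁₀ P(f) = b − log₁₀(k + f^χ), the
standard semi-log aperiodic model; b, log₁₀k and χ are fit by bounded
nonlinear least squares (k, χ ≥ 0, multi-start over knee initializations).
Oscillatory peaks only ever add power, so the robust loop estimates the
residual scale from the *below-fit* side only and iteratively masks points
more than 2.5 scales above the fit until the mask stabilizes. On a
noiseless synthetic spectrum the recovery is exact to <1%; with 0.02
log₁₀-unit noise the median exponent error is <0.01.

Gamma power is the mean log₁₀ residual (data − fitted background) over
30–50 Hz. Log-space averaging (rather than linear residual power) keeps
the quantity scale-free: multiplying the raw spectrum by any constant is
absorbed into b and leaves gamma power unchanged, exactly. The per-subject
gamma estimate is regressed on intratumoural HFC node counts by OLS.

## MEA analytics

Noise is estimated as median(|v|)/0.6745 (robust to embedded spikes);
spikes are |v| crossings of 5× that SD on the 200–3,000 Hz band-passed
trace, one event per 1 ms dead time, timestamped at the crossing sample.
Bursts are maximal runs of ≥5 spikes with every ISI ≤ 100 ms (boundary
inclusive). Network bursts merge overlapping single-electrode burst
intervals into candidate windows and emit a window when distinct
participating electrodes reach ⌈0.35 × n_active⌉ and total spikes from
active electrodes inside the window reach 50; this interval-union rule is
our substitution for the proprietary vendor algorithm, keeping its two
published thresholds. wMFR defaults to the mean firing rate over active
electrodes (vendor convention); the literal "well rate × active count"
formula is available via `wmfr_mode="literal"`.

AUNCC bins trains at 5 ms and forms ρ_xy(τ) = C_xy(τ)/√(C_xx(0) C_yy(0))
for |τ| ≤ 100 ms; Cauchy–Schwarz on nonnegative counts bounds every ρ in
[0, 1]. The default area is Σ ρ(τ)²·Δ — the *squared* correlogram area.
This is deliberate: temporal jitter redistributes correlogram mass across
lags without changing its linear sum, so the plain area (available via
`area_mode="linear"`) is provably insensitive to synchrony tightness,
while the L2 area strictly decreases from identical copies through
widening jitter to independence. Bin width and lag window are exposed in
config since no published values exist.

## Statistics

The tissue contrast is a random-intercept mixed model (REML) of
channel-level HGp means on tissue label with participants as random
effects; the Wald F uses 1 numerator df and between-within denominator df
n_obs − n_participants − 1. The fit falls back through optimizers
(bfgs → lbfgs → powell → nm) because near-zero random-effect variance can
make a single method's Hessian singular on small tables. Measured on
simulated tables (14 participants × 40 channels, participant SD 0.5,
residual SD 1), the model recovers a unit tissue effect within ±0.2 in
>90% of seeds and rejects at 3–5% under the null. FDR adjustment is
Benjamini–Hochberg step-up (verified against a literal brute-force
implementation). Extent of resection is (pre − post)/pre × 100 with
post > pre rejected as impossible. Kaplan–Meier medians are the earliest
time survival drops to ≤0.5 (infinite, reported "not reached", when it
never does); the group comparison is a two-tailed log-rank test, and the
reverse-KM median follow-up is available behind a flag.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their spec; random streams are split per
participant / voxel / well with `SeedSequence.spawn`, so increasing one
count never perturbs the others' data.

- **ECoG**: high-gamma "bursts" are raised-cosine-enveloped narrowband
  (70–110 Hz) noise added to Gaussian background — matching the band the
  HGp stage measures without assuming sinusoidal phase locking. The base
  burst RMS is 0.5× the noise SD, chosen so synthetic channels stay
  mesokurtic and survive the kurtosis screen the way real task data
  would; tumour channels multiply the burst by `tumour_amplitude_ratio`
  and high-frequency-word trials add `condition_effect_size` noise-SDs of
  amplitude. Tumour contacts are placed within 10 mm of a core at the
  origin. No speech audio, line noise, or electrode drift is simulated.
- **Voxels**: every voxel carries a share (default 30% of variance) of a
  common narrowband alpha source plus independent noise. Per-voxel phase
  offsets are *balanced* integer multiples of `phase_lag` (default π/4)
  spanning the full alpha cycle, realized as exact fractional delays, and
  mirror twins share an offset. This construction makes the two
  hemispheres statistically exchangeable — the property the calibration
  claims of the voxel test rest on — while keeping pairwise phase
  differences nonzero multiples of `phase_lag` so imaginary coherence is
  positive. Lesion voxels multiply their source amplitude by
  `lesion_coupling_boost`. No beamformer leakage, head model, or spatial
  autocorrelation is simulated, so passing tests show estimator
  correctness under exchangeability, not robustness to source-leakage
  artifacts in real MEG.
- **Rasters**: homogeneous Poisson background per electrode plus
  scheduled network bursts (participating electrodes drawn per burst;
  within-burst spikes at 10 ms base ISI with Gaussian jitter). Voltage
  traces embed a 1 ms biphasic template at `spike_snr`× the unit noise SD
  in Gaussian noise, making the 5-SD threshold analytically checkable.
  No refractory dynamics, bursty single-electrode background, or
  electrode cross-talk.
- **Spectra**: the closed form log₁₀ P = b − log₁₀(k + f^χ) + Gaussian
  peaks + log-noise, tabulated on a 0.25 Hz grid over 1–50 Hz.
- **Cohorts**: exponential event times at the stated group medians with
  independent exponential censoring tuned to the stated expected
  censoring fraction. Note the KM median of an exponential cohort at
  n = 200/group has ~10% relative sampling error, so individual
  realizations scatter around the generator medians accordingly.

## Numerical choices and degenerate inputs

Time is seconds everywhere on disk; indices are 0-based internally and
channel labels 1-based in human-readable reports. Epoch windows are
half-open. IC entries at exactly 1 are clipped to 1 − 1e-6 before atanh
with a warning. Constant vectors: tertile classification returns
all-intermediate; the IC estimator refuses constant voxel series; zero
variance traces yield zero spikes with a warning; zero-variance ERSP
trials are NaN-flagged. Tie-breaks (tertiles) use voxel id so every
output is deterministic. The pipeline report echoes the full effective
configuration, and identical config + seed reproduces every output file
byte for byte.

The orchestrated demo pipeline runs deliberately small problem sizes
(4 participants × 12 channels, 120 voxels, one MEA well, 100 patients per
cohort arm) — large enough to exercise every stage's contracts while
keeping a full run in tens of seconds; all sizes are configurable.

## Known limitations

- The contralesional test's calibration statement is specific to the
  exchangeable synthetic null; on real data, hemispheric asymmetries
  unrelated to tumour biology would inflate rejections under every
  reading.
- The network-burst detector and AUNCC are principled stand-ins for
  proprietary vendor definitions; absolute values are not comparable to
  vendor reports, only within-pipeline contrasts.
- The LME denominator df is a between-within approximation; small-sample
  inference (few participants) is approximate.
- EDF support targets continuous 16-bit recordings with integer sampling
  rates; annotations and discontinuous files are out of scope.
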