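# Methods

## Ocular scoring

The eye aspect ratio of a six-point eye contour (lateral corner p1, medial
corner p4, upper lid p2/p3, lower lid p6/p5) is

    EAR = (‖p2 − p6‖ + ‖p3 − p5‖) / (2 ‖p1 − p4‖),

a dimensionless quantity invariant to translation, rotation and uniform
scaling of the landmarks. Frames with zero eye width are flagged rather
than silently zeroed; flagged or externally masked frames are linearly
interpolated from their neighbours when the gap is at most 0.5 s and left
missing otherwise (the mask file stands in for a manual frame-correction
step). The landmark-error metric is the mean Euclidean pixel distance
between matched predicted and reference landmark sets.

Blink segmentation is deliberately parameter-light: a frame belongs to a
dip when its EAR falls below half of a rolling open-eye baseline (the 95th
percentile of the EAR over a 30 s window, computed per second and
max-pooled); dips are extended to the flanking local maxima (≤ 1 s per
side) and merged when they touch. Per-participant normalization maps the
EAR through the extreme values reached within blinks; values between
blinks can leave [0, 1] and are clamped so the closure threshold stays
well defined. The closure signal is 1 iff the normalized EAR is ≤ 0.8,
boundary inclusive. The threshold is configurable: the printed staging
convention uses 0.8 on the normalized scale even though a literal
"80% closed" reading would suggest 0.2, and we implement the printed
convention as the default rather than guess.

## PERCLOS and the drowsigram

PERCLOS at second t is the mean of the closure signal over the
`N = 60·fps` frames centred on t (indices `t − ⌊N/2⌋ … t + ⌊(N−1)/2⌋`),
stored as a fraction. Seconds whose window is truncated by the recording
edges are marked invalid instead of being computed on partial windows, so
N is constant wherever the index is defined. Staging uses fractional
thresholds with inclusive lower boundaries: awake < 0.08,
likely-drowsy < 0.15, drowsy otherwise; PERCLOS = 1.0 — formally covered
by no branch — is assigned to drowsy. Microsleep is keyed to the closure
signal itself: any maximal run of closed frames strictly longer than 5 s
marks every overlapping second as microsleep, overriding the PERCLOS
class (a run of exactly 5.0 s does not qualify). Raising any closure frame
from open to closed can therefore never lower a second's PERCLOS or move
it to a lower-ranked state, a property the test suite checks.

## Multitaper spectral estimation

Each ROI series (optionally residualized on an intercept plus confounds;
a type-II discrete-cosine basis with `⌊2·n·TR·f_c⌋` columns provides the
0.01 Hz high-pass) is analysed with a DPSS multitaper spectrogram: 60 s
windows stepped by 1 s, per-window linear detrend, K = 4 unit-energy
Slepian tapers at time-half-bandwidth NW = 2.5, zero-padding to NFFT = 64,
uniform (non-adaptive) averaging of the four eigenspectra, one-sided
density normalization (interior bins doubled, divided by the sampling
rate). At TR = 1 s this yields 33 grid frequencies `j/64` in [0, 0.5] Hz;
band j (j ≥ 1) is the half-open interval `]f_{j−1}, f_j]`, six bands lie
at or below 0.1 Hz, and 0.05 Hz falls in band 4, `]0.046875, 0.0625]`,
printed `]0.047, 0.063]` (edges rounded half away from zero). Both the
33-point grid and the 32 inter-bin bands are exposed; band powers are
what the statistics consume.

Columns are timestamped at the window centre on the same grid as PERCLOS,
matched to the drowsigram label at that second, and averaged row-wise per
state; states with no columns are omitted rather than zero-filled, and the
per-state window counts always partition the labelled columns.

Two numerical properties of this configuration are worth knowing. The
resolution bandwidth 2·NW/60 ≈ 0.083 Hz exceeds the 0.0156 Hz bin
spacing, so a sinusoid's spectral peak sits on a near-flat top: the argmax
is bit-reproducible against a direct per-window oracle but can land one
bin off at low frequencies (where the per-window linear detrend and the
conjugate-image cross term tilt the top; the same mechanism mirrors at
Nyquist). Away from those edges the modal peak resolves exactly. This is
a property of the stated estimator, not an implementation artefact.

## Statistics

* **Per-ROI GLM.** psd005 ~ state (categorical), Gaussian-identity by
  default, with the joint state contrast tested against the exact
  F reference — on balanced two-state data this reproduces the pooled
  two-sample t-test to floating point, and the reported Wald χ² is
  F × df. A Gamma-log variant (asymptotic χ²) is available for strict
  positivity, and a within-participant variant adds participant
  indicator covariates to exploit the repeated-measures pairing.
  Observations are participant-state cell means; participants missing a
  state contribute no row (no imputation). Note that when participants
  differ substantially in overall power — which the generator emulates
  and real BOLD data show — the *pooled* GLM is conservative for the
  state effect (the shared participant level inflates the residual but
  not the contrast); detection power at stringent thresholds then comes
  from the within-participant variant, and the type-I calibration of the
  pooled test is verified under its own null model (independent draws).
* **Pairwise post-hocs.** For each ROI and each of the 6 unordered state
  pairs: pooled-variance two-sample t test on participant-level values
  and Cohen's d with the pooled SD, Bonferroni over all emitted
  comparisons (984 at 164 ROIs). Results are antisymmetric under swapping
  the pair. Underpopulated pairs are skipped with a logged reason.
* **PERCLOS–power regression.** psd005 is z-scored within participant
  (removing between-participant power offsets) and pooled; ordinary least
  squares on PERCLOS returns r², slope and p.
* **Network mixed model.** ROI values are averaged into
  (participant, network, state) cells; the model is
  psd005 ~ state * network with a random intercept per participant
  (REML). Term F statistics are Wald χ²/df with a containment-style
  denominator df, `n_cells − rank(X) − (n_participants − 1)`: a proper
  Satterthwaite approximation needs the covariance of the REML variance
  estimates, which the fitting backend does not expose, and at these cell
  counts (≈ 10³) the two differ negligibly. The df method is recorded in
  the result metadata. Post-hoc: 6 state pairs × 7 networks = 42
  comparisons, Bonferroni-corrected.
* **RSQ concordance.** Two-way ANOVA of per-participant state occupancy
  on state × self-report. Occupancies sum to one within participant, so
  the report main effect is structurally null; the informative term is
  the state × report interaction, which the result object surfaces
  (the full table is returned). With one report level the model degrades
  to a one-way ANOVA with a flag.
* Bonferroni thresholds are plain `α/m`; a Shapiro-Wilk normality screen
  is available as a diagnostic, not a gate.

## Synthetic cohorts

The generator defines the study conditions the package is validated
under; defaults describe a 41-participant, 45 min eyes-open recording at
TR = 1 s with a 25 fps eye camera.

* **Vigilance dynamics**: a semi-Markov chain over the four states with
  exponential dwell times (rounded to whole seconds) and configurable
  transition weights; published dwell-time distributions for sleep-onset
  vigilance states are scarce, so dwell means (100, 45, 45, 45 s) and a
  chain-like weight matrix were chosen to give roughly one third of the time awake, about two
  thirds in non-awake states and 15–20% in microsleep, with microsleep
  bouts well under a minute. Microsleep dwells are drawn as 6 s + Exp so
  every bout exceeds the 5 s detection threshold and remains recoverable.
  Sequences start awake.
* **Eyelid traces**: square dips on a noisy open baseline (EAR ≈ 0.32).
  Blinks (10/min outside microsleep, ≈ 0.2 s) plus state-dependent
  partial closures (per-second start probabilities 0.29 and 0.19 and
  durations 0.2 s and 1.5 s in likely-drowsy and drowsy) place the
  60 s closure fraction near the middle of each state's staging band;
  microsleep segments hold the eye closed throughout. Landmark tables put
  the six points on a template eye polygon (width 4 px, vertical pairs at
  EAR·width/2) plus per-frame translation jitter, so the EAR formula
  recovers the trace exactly (≤ 1e−9). No video pixels, head motion or
  lighting effects are simulated; square dips are a simplification of
  real blink kinematics, so the blink detector is additionally exercised
  on triangular dips in the unit tests.
* **BOLD**: per ROI, unit-variance AR(1) noise (ρ = 0.3; white noise
  optional) plus a 0.05 Hz sinusoidal carrier with random phase whose
  amplitude follows the concurrent latent state for ROIs in the
  effect-carrying networks (defaults: visual and somatomotor). A
  lognormal per-participant power scale (SD 0.3 in log units) multiplies
  signal and noise alike, reproducing the strong between-participant,
  within-participant-stable power differences of real BOLD and making
  state contrasts effectively paired.
* **Effect calibration**: requested effects are standardized offsets of
  participant-level band-4 power (Cohen's d units, relative to awake).
  A pilot simulation measures the no-oscillation mean and SD and the
  power added by a unit-amplitude carrier under the configured noise and
  heterogeneity model; offsets are converted to power increments, solved
  against the taper-energy-weighted window-occupancy mixing matrix
  (centre labels = the recovered drowsigram, window occupancy = the
  latent states driving the amplitude), shifted nonnegative — legitimate
  because the mixing matrix is row-stochastic, so a constant shift moves
  every state mean equally and leaves all pairwise contrasts intact —
  and finally rescaled against a closed-loop verification run that
  measures the d actually delivered through the full 60 s windowing and
  drowsigram segregation. The residual cohort-to-cohort spread of the
  realized d is ≈ 0.06–0.08, so recovery experiments average over three
  replicate cohorts.
* **RSQ labels**: ≈ 22% of participants report not having slept; their
  chains get 2.5× longer awake dwells and half-length microsleep dwells,
  making drowsigram occupancy concordant with the self-report by
  construction.
* Everything derives from a single integer seed via spawned generator
  streams; identical configurations reproduce bit for bit.

## Problem sizes and tolerances

Parameter-recovery runs use 40 participants, 45 min at TR = 1 s, a
down-sampled 10 fps camera, and three replicate cohorts; the test suite
uses a reduced 28-ROI atlas and the acceptance script the fuller 164-ROI
atlas (ROI count mainly changes how many effect ROIs the d estimate
averages over). Type-I calibration uses 2000 independent null tables of
40 participants × 4 states, with each cell drawn as a scaled χ²₈ — the
marginal shape of an averaged multitaper band-power estimate — and checks
the empirical α at nominal 0.05. Oracle equivalences (PERCLOS vs a
brute-force windowed mean; the vectorized spectrogram vs a literal
detrend + taper + FFT loop) are asserted at 1e−12 and 1e−10; the GLM vs
t-test identity at 1e−12 on p-values.

## Known limitations

* The generator emulates the statistical structure the analysis assumes
  (state-locked narrowband power, stationary noise, stable participant
  scale); it does not emulate motion artefacts, physiological noise
  spectra, scanner drift beyond AR(1)/optional cosine terms, or EAR
  measurement failure modes, so passing tests certify the pipeline's
  arithmetic and calibration, not robustness to real-data pathologies.
* The pooled per-ROI GLM is conservative under participant power
  heterogeneity (see above); analyses of heterogeneous cohorts should
  prefer the within-participant or mixed variants.
* Near DC and Nyquist the spectrogram's peak location is ambiguous within
  one bin by construction of the stated estimator parameters.
* The mixed model's denominator df is a containment approximation, not
  Satterthwaite.
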