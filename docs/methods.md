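# Methods

This note records the scientific model behind `t1norm`, the default
parameters and why they were chosen, the numerical details of the
solvers, and what the synthetic tests do and do not demonstrate.

## Signal model

The acquisition emulated is a single-shot inversion recovery with a
continuous small-flip FLASH readout: one slice-selective 180° pulse, then
4 s of radial FLASH (TR 4.0 ms, flip α = 6°, 15 spokes merged per frame,
so one frame per 60 ms and 67 frames in total; 220 mm FOV at 1 mm gives a
220×220 matrix). Under continuous readout the longitudinal magnetization
relaxes toward a *reduced* steady state with the apparent rate

    1/T1* = 1/T1 − ln(cos α)/TR,

and the pixel intensity follows the three-parameter model
S(t) = A − B·exp(−t/T1*). The true T1 is recovered by the Look-Locker
correction T1 = T1*(B/A − 1). With the plateau parameterized as
A = M0·T1*/T1 and B = A + η·M0 (η the inversion efficiency, default 1),
the correction inverts the forward model exactly, which the test suite
exploits as a machine-precision round trip. Receive gain and sin α
factors cancel in B/A and are absorbed into M0.

Frame timestamps use the mid-frame convention t_k = (k + ½)·60 ms: each
reconstructed frame aggregates a 60-ms window of spokes, and its centre
minimizes timing bias against the continuous model. The delay between
inversion and the first spoke is taken as zero. Both signed
(real-valued-reconstruction) and magnitude pixel series are supported; in
magnitude mode the sign lost at the inversion is restored by testing
candidate flip indices around the minimum-intensity frame and keeping the
smallest-residual (then smallest-index) candidate. Signed mode is the
default everywhere. Noise is additive Gaussian on signed data and Rician
(magnitude of complex Gaussian) in magnitude mode.

## Synthetic cohort

The generator stands in for a 100-patient pediatric cohort (ages 2 months
to 18 years). Defaults:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 100 | cohort size of the emulated study |
| age range | 0.17–18 y | 2 months to 18 years |
| age sampling | uniform | the emulated cohort's mean age is ≈10 y, which uniform sampling (mean 9.1) matches; a log-uniform option exists for infancy-heavy designs |
| pixel noise | 1% of white-matter M0 | high-SNR regime of the emulated maps |
| background | T1 1000 ms, M0 0.7 | unlabeled brain parenchyma; air outside the head has M0 = 0 |

Each region's ground-truth mean follows T1(x) = a·x^(−n/10) + b. The
phantom is a deliberately schematic ellipse atlas on the acquisition
grid — the analysis needs labeled pixel populations with exactly known
truth, not anatomy. Paired structures get mirrored left/right ellipses;
the brainstem is midline.

Four regions are *anchored*: their offsets b are set by
`calibrate_offset` so that the expected mean over uniform ages 5–18 y
equals published school-age pooled values (frontal white matter 758 ms,
thalamus 1101 ms, putamen 1162 ms, caudate nucleus 1272 ms). The closed
form uses the analytic mean of a·x^r on [5, 18]. The other five regions
have no published pooled anchor; their defaults (occipital white matter
820, globus pallidus 960, dentate nucleus 1030, brainstem 880, bulbus
oculi 4000 ms) are physiologically plausible placeholders — globus
pallidus shortest among deep gray (iron), occipital white matter slightly
above frontal, vitreous body a long-T1 fluid — chosen well-separated so
that distinct structures remain statistically distinguishable, and
flagged `anchored=False`.

Exponents default to n = 8 for white matter, n = 6 for brainstem and
n = 4 for deep gray: the early T1 drop is fastest in maturing white
matter. White-matter amplitudes make T1 at 3 months roughly double the
school-age value. These are generator choices, not estimates of any
patient dataset.

Between-subject dispersion is multiplicative: T1 = curve·(1 + ε),
ε ~ N(0, cv), truncated positive. Per-region cv defaults (white matter
0.046–0.047, deep gray 0.024–0.027, brainstem 0.036, bulbus 0.03) were
derived analytically so that the population R² of the power-law age fit,
Var(signal)/(Var(signal) + cv²·E[T1²]) under uniform age sampling, sits
mid-way in the 0.84–0.94 band that such pediatric normative fits
typically report. A realized 100-subject cohort scatters around that
value with an SD of roughly 0.05–0.10 because a handful of high-leverage
infants dominate both signal and residual variance; median-over-cohorts
statistics are therefore the right way to test the calibration.

## T1 fitting

Per-pixel fits minimize the residual of A − B·exp(−t/T1*) from a
heuristic start (plateau = mean of the last 10% of frames; depth = plateau
minus first frame; T1*₀ = null-crossing time / ln 2, clamped to
[20, 3000] ms). Two solver paths share this start:

* `fit_pixel`: scipy bounded trust-region least squares, analytic
  Jacobian, ftol 1e-10 — the reference path.
* `fit_map`: a vectorized Levenberg–Marquardt written in numpy that
  solves every foreground pixel simultaneously (per-pixel damping,
  cost-decreasing steps only, parameters clipped to A > 0, B ≥ 0,
  T1* ∈ [1, 10⁴] ms). This is what makes a 100-subject × 220×220×67
  pipeline run in about a minute; a test pins it to the scipy path to
  within 1e-4 relative on noisy data.

A pixel converges iff the solver converged, B > A > 0, and the corrected
T1 lies in [50, 6000] ms (configurable physiological window). Pixels
whose plateau magnitude is below 5% of the stack maximum are classified
as air and skipped. Non-converged pixels carry NaN and are excluded from
ROI statistics. Fitting is strictly per pixel — no spatial
regularization.

## ROI statistics and the simulated raters

The automated "largest possible ROI" is the entire labeled region.
Observer variability is injected by perturbing the label map per rater:
each region mask is eroded by 1 px (4-connected) and translated by a
random integer offset up to 1 px. The eroded-and-shifted ROI occasionally
includes a boundary pixel of background tissue; the resulting
partial-volume deviation is ≲0.5% for brain structures but several
percent for the eye, whose 4000-vs-1000 ms boundary contrast is extreme —
which is also why the eye's ICC falls visibly below the brain regions',
mirroring the reported behavior of real raters there.

Pooling is hierarchical — sides averaged within rater, raters within
subject, then the arithmetic mean over subjects in the age window
(default 5–18 y) — making the result invariant to how records are split.

## Normative regression

Five families (linear, logarithmic, square-root, exponential with decay
constant τ, power with r = −n/10) are ordinary least squares on the
transformed covariate. The power exponent is an exhaustive integer grid
n = 1…30 (covering r ∈ [−3, −0.1]); τ uses a 41-point log grid on
0.1–20 y. Ties break to the smaller n or τ; family ties break in the
order power > exponential > logarithmic > square-root > linear. Model
comparison uses adjusted R² (constant responses are assigned 0 rather
than −∞). residual_sd = √(RSS/(n−2)); a Shapiro–Wilk p-value is reported
as a numeric surrogate of a residual quantile plot and gates nothing.
A region whose best family explains less than adjusted R² = 0.2 is
flagged age-independent (the bulbus oculi under defaults).

Percentile bands are *population* bands — prediction ± 1.959964·residual
SD, constant half-width — not standard-error confidence bands. Because
the generator's dispersion is multiplicative, residuals are mildly
heteroscedastic in age and the empirical coverage of these bands sits
just below nominal (≈94.7% analytically for the default regions, vs 95%
for truly homoscedastic data); the tests check coverage to ±2.5
percentage points on a 1000-subject cohort.

## Reliability statistics

* Bland–Altman: bias = mean paired difference; limits = bias ±
  1.959964·sample SD (ddof 1).
* ICC(2,1): two-way random effects, absolute agreement, single measure,
  computed from the mean-square decomposition and cross-checked against
  an independent implementation in the tests. The variant is recorded in
  the result.
* Wilcoxon rank-sum, two-sided: exact enumeration when m + n ≤ 20 with no
  ties, otherwise normal approximation with midranks, tie correction and
  continuity correction. Structure contrasts apply it to subject-level
  means of every pair of the eight brain structures (the eye is analyzed
  for reliability but is not a brain structure), with no multiplicity
  adjustment. Using an unpaired test on within-subject measurements is a
  deliberate fidelity choice to the emulated analysis.

## Problem sizes and determinism

The default end-to-end run (100 subjects × 67×220×220 series, ~23 400
fitted pixels each) completes in roughly 1–2 minutes on one CPU; the test
suite runs it once and otherwise works at single-pixel, single-subject or
ground-truth scale. All randomness flows from one master seed through
`numpy.random.SeedSequence` spawns (subject draw, pixel noise, each
rater), so cohorts, series and measurements are bit-reproducible, and CSV
outputs use fixed float formatting.

## Limitations

* The phantom is geometric: no partial-volume gradients at tissue
  boundaries beyond the rater-simulation effect, no B1 or slice-profile
  errors, no motion (the eye's real-world scatter from involuntary
  movement is only represented indirectly), no CSF compartment.
* Image synthesis happens in the image domain; radial k-space sampling,
  coil sensitivities and nonlinear-inversion reconstruction are out of
  scope, so reconstruction-induced spatial correlations are absent.
* The unanchored regions' growth parameters are placeholders; recovery
  results for them validate the pipeline, not any published value.
* Passing tests show the chain is unbiased and reliable *under the
  generator's assumptions* (mono-exponential recovery, Gaussian noise,
  multiplicative between-subject dispersion); they cannot certify
  accuracy on scanner data.
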