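# Methods

This note documents the models and procedures `hemolag` implements, the
defaults it ships with and why, the numerical choices that required a
decision, and what the synthetic-data tests do and do not demonstrate.

## Lag estimation

The per-voxel hemodynamic shift is estimated against the mean time course
of intact grey matter (grey-matter mask AND NOT lesion).  This reference
embodies the null hypothesis that intact voxels share one hemodynamic
time base; each voxel's deviation from it is the quantity of interest.

The lagged cross-correlation is evaluated on an integer frame grid
`tau ∈ {−W, …, +W}` with `W = 3` frames by default — ±8.4 s at TR 2.8 s,
matching the convention that the physiologically plausible range of
post-stroke lags is roughly ±8 s.  For each shift, the product-sum runs
over the `n_tau = T − |tau|` overlapping frames and is scaled by
`1/(n_tau · sigma_g · sigma_s)`.

Two conventions needed fixing where the formula alone is ambiguous:

- **Demeaning.**  Signals are demeaned globally (full series) before the
  product-sum.  Without centering, non-zero means dominate `C` and the
  `r < 0.1` validity rule is vacuous; centering makes `C` a Pearson-type
  quantity, which is what "not positively correlated" presumes.  Whether
  to demean per overlap window instead is undecidable from the defining
  formula's single mean-free symbols; global demeaning is the simpler
  reading and is what the shift-equivariance tests pin down.
- **Standard deviations** are computed once on the full series (the
  formula's `sigma_g`, `sigma_s` sit outside the tau-sum), not per
  overlap.

The discrete peak is refined by the vertex of the parabola through the
peak and its two neighbours:

    tau_m = tau_p + (Δ/2) · (C[p−1] − C[p+1]) / (C[p−1] − 2·C[p] + C[p+1])

Degenerate cases: a peak at the window edge has no vertex — the voxel is
invalidated (`edge`) rather than clamped, which is conservative; a
zero-curvature triple falls back to the discrete peak; ties between equal
maxima resolve toward the smallest |tau| (biasing toward "no change"),
then toward the negative shift.  Sign convention: positive `tau_m` means
the voxel's content arrives *after* the reference — a lag; negative, a
lead.  This is asserted by the shift-equivariance test (delaying a series
by +k frames raises its estimate by k·TR).

Validity reason codes per voxel: `out-of-mask`, `lesioned`,
`low-correlation` (peak `C < 0.1`), `edge`, `no-variance`.

Accuracy: on noiseless synthetic subjects (24³ grid, lags up to ±2 frames
plus per-patient variation) the worst-case recovery error is ≈ 0.07–0.10 s,
about 3% of a frame — far inside the 0.25·TR acceptance band.  The
residual error comes from parabolic interpolation of a non-parabolic
correlogram and from finite-overlap asymmetry, not from the shift model.

## Preprocessing

Only the temporal steps the lag estimator assumes are implemented; spatial
registration, segmentation, smoothing and lesion delineation are upstream
concerns and their outputs (volumes on a common grid, masks) are inputs.

- **Dual-echo combination**: voxel-wise arithmetic mean of the two echoes.
- **Initial frames**: the first 2 of 130 are discarded (T1 equilibration),
  leaving 128 analysis frames; TR unchanged.
- **Outlier frames**: flagged when the global-mean z-score exceeds ±2.5 or
  any translation axis jumps > 1 mm between consecutive frames.  The
  motion rule is applied to *framewise deltas* of the translation columns;
  an absolute-position reading is also defensible, but deltas are what
  artefact-detection practice flags.  Flagged frames are regressed out via
  per-frame indicator columns, not deleted — deletion would break the
  uniform sampling the lag window requires.
- **Nuisance regression**: per-voxel least squares against mean CSF signal
  (from a user-supplied mask), the Friston 24-parameter motion expansion
  ([p, p², p(t−1), p(t−1)²] of the six rigid-body parameters), and the
  outlier indicators; an intercept is always included.  White-matter and
  global means are deliberately *not* removed: the global/grey mean is the
  reference signal the lag analysis correlates against.
- **Band-pass 0.01–0.08 Hz**: zero-phase FFT mask applied after
  mirror-extending each series (reflection at both ends, 3× length,
  cropped back).  Phase linearity is a correctness requirement here — any
  group delay would bias every lag estimate.  The mirror extension
  suppresses the edge leakage a brick-wall mask exhibits on finite
  non-periodic segments; the residual imperfection is a few percent of
  passband amplitude and a small out-of-band leakage (the white-noise
  test bounds in-band power at ≥ 95% rather than ≥ 99.9%).

## Behavioural factor model

Scores are converted to percentages of the published task maximum, or of
the best score in the group when no maximum exists.  PCA is computed on
the task **correlation** matrix — tasks live on heterogeneous percentage
scales, and the correlation metric (the SPSS default the field uses) stops
high-variance tasks from dominating.  Components with eigenvalue > 1 are
retained (Kaiser criterion) and rotated by varimax with Kaiser row
normalization, implemented as classic pairwise planar rotations — the
closed-form per-pair angle is robust at the symmetric configurations where
gradient-style updates stall.  Rotation is orthogonal and preserves
communalities to 1e−8 (asserted).

Regression-method factor scores `F = Z R⁻¹ Λ` (standardized data `Z`,
correlation matrix `R`, rotated loadings `Λ`; pseudo-inverse when `R` is
singular, e.g. duplicated tasks) are exactly mean-zero, unit-variance and
mutually uncorrelated for PCA components.  Each factor's sign is flipped
so its largest-magnitude loading is positive, and factors are ordered by
explained variance — a reproducible alignment convention.

Patient outliers: any factor score beyond ±3 sample SDs of its column
flags the patient for exclusion from brain–behaviour analyses.  On the
published 35 × 4 score table this flags exactly two patients (the 3.91
fluency and −3.88 semantics entries); the flag set is identical under
either ddof convention and is invariant to affine rescaling of columns.

Minimum sample size for a correlation uses the Fisher-z approximation
`n = ((z_{1−α/2} + z_{power}) / atanh(r))² + 3`, rounded to the nearest
integer: (r = 0.75, α = 0.01 two-sided, power = 0.8) → 15.34 → 15.
Nearest-integer rounding on the two-sided formula is the convention that
reproduces the published 15; a ceiling convention would give 16.  The
Monte Carlo power check at (r = 0.5, α = 0.05) confirms the formula's n
delivers empirical power within ±0.03 of target.

## Voxel-wise correlation mapping

- **Coverage**: voxels damaged in > 20 patients are removed from analysis
  (too few intact observations for a stable estimate).
- **VBCM**: per-voxel partial Pearson correlation of a continuous map with
  the factor score, controlling total lesion volume, computed by the
  first-order closed form; p from `t = r·sqrt(df/(1−r²))` with
  df = n − 3.  The residualization identity is the test oracle
  (agreement to 1e−10).  All patients contribute at every voxel (the
  continuous-signal convention); the coverage mask still applies.  This is
  an interpretation choice — the alternative of masking VBCM by lesion
  would change per-voxel n.
- **Lag–behaviour**: per voxel, the contributing set is patients with a
  valid lag there and not score-flagged; lag values beyond ±3 SD across
  the contributing patients *at that voxel* are dropped; if ≥ 15 remain,
  Pearson r, two-sided p (df = n − 2) and n are recorded, otherwise the
  voxel is invalid (`insufficient-n`).  The ±3 SD exclusion is applied
  per voxel across patients — symmetric with the per-voxel correlation it
  protects; the per-subject-across-voxels alternative is available as
  `lag_outlier_mode="per-subject"`.
- p-values, not r, are thresholded downstream: per-voxel n varies, so a
  single r cutoff would mean different evidence levels at different
  voxels.

## Multiple-comparison control

The Monte Carlo cluster-extent threshold simulates white Gaussian fields
on the analysis mask, smooths to a nominal FWHM (a *user parameter*;
estimating smoothness from residuals is out of scope), standardizes over
the mask, applies the two-tailed voxel-p threshold with positive and
negative clusters labelled separately, and returns the smallest extent k
with `P(max cluster ≥ k) ≤ corrected_p`.  Connectivity defaults to
18-neighbour (faces+edges, the AFNI-family default), with 6 and 26
selectable.  At FWHM 0 the threshold agrees with an independent-voxel
brute-force null within ±1 voxel over 20,000 iterations (asserted).

BH-FDR is the step-up procedure (via statsmodels), equal to its textbook
definition on random vectors and always a superset of Bonferroni at the
same level.  Cluster extraction reports size, volume = size × |det| of
the affine's 3 × 3 block, the member voxels and the |stat|-maximizing peak
in world mm (0-based voxel indices internally; only world coordinates are
reported, avoiding 0/1-based ambiguity).

## Synthetic cohorts

The generator plants exactly the quantities the pipeline estimates:

- a band-limited (0.01–0.08 Hz) unit-variance Gaussian reference signal,
  130 frames at TR 2.8 s;
- per-voxel lags applied as frequency-domain phase shifts — exact
  sub-sample delays for these periodic band-limited signals, avoiding
  interpolation bias at the scale the estimator must resolve;
- grey matter as a centered ball (24³ grid at 3 mm by default — desk
  scale while keeping genuine 3D cluster behaviour), a small central
  CSF compartment, and three ellipsoidal lag territories (+2.8 s, −2.8 s,
  +1.4 s);
- only grey-matter voxels carry the BOLD-like signal; CSF and background
  are pure noise, so the CSF nuisance regressor does not contain the
  reference time course (as in real data, where CSF fluctuations are
  non-neural);
- per-patient ellipsoidal lesions with centers concentrated in one
  sub-volume, emulating a single arterial territory so lesion overlap is
  high enough for the coverage rules to bite; lesioned voxels are pure
  noise;
- behaviour drawn from the published 21-task loading structure via
  `X = F·Λ' + E` with residual variance 1 − communality (66 behavioural
  patients, first 35 imaged);
- couplings: region-0 lag varies with factor 1 at +0.7 s per SD and
  region-1 lag with factor 4 at −0.7 s per SD, plus N(0, 0.7²) s
  per-patient lag jitter, giving a planted lag–behaviour correlation of
  0.7/√(0.7² + 0.7²) ≈ 0.71 — a "strong coupling" comparable to the
  effect sizes such studies report;
- white observation noise of SD 1.0 against a unit-variance signal
  (dual-echo mode: two echoes at SD √2 whose average restores SD 1), and
  motion traces as a slow random walk with occasional supra-threshold
  jumps.

Noise level, lag magnitudes and coupling strengths are free parameters of
the generator — no published values exist for them; the defaults above
were chosen once as plausible for preprocessed rs-fMRI and are the
conditions all statistical tests run under.

**What passing tests show** — that every algorithmic stage is correct
against independent oracles, and that under realistic noise the full
pipeline recovers planted couplings of |r| ≈ 0.7 with the right sign
essentially everywhere.  **What they do not show** — anything about real
vascular territories, HRF shape changes, spatially correlated physiological
noise, registration error, or multi-echo T2* physics: the generator plants
none of these.  Published cohort-specific result maps (cluster locations
and r values) require the original patient data and are not reproduction
targets.

## Determinism and problem sizes

All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning; a fixed seed gives bit-identical cohorts, thresholds and
pipeline outputs.  Default analysis sizes — 24³ voxel grids, 35-patient
imaging cohorts, 100-replicate dimensionality checks, 5,000–20,000
Monte Carlo iterations — were chosen as the package's standard desk-scale
working points; they keep a full run in tens of seconds while leaving the
cluster-threshold and recovery statistics stable to within their stated
tolerances.

## Known limitations

- The lag window (±3 frames) quantizes coarse at TR 2.8 s; parabolic
  refinement recovers sub-frame structure only near the peak.
- Edge-peak voxels are dropped rather than re-estimated with a wider
  window; true lags near ±8.4 s are therefore under-sampled.
- The Monte Carlo null assumes stationary Gaussian smoothness on the
  mask; non-Gaussian spatial autocorrelation (a known cause of inflated
  cluster false positives) is not modelled.
- VBCM includes all patients at every voxel; lesion-masked VBCM would
  give different per-voxel n.
- The mirror-extension band-pass leaks a few percent of power outside the
  nominal band near segment edges.
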