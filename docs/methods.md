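# Methods

## Signal model and assumptions

Each voxel's inversion-recovery magnitude series is modelled as a single
longitudinal ensemble,

    s(TI) = | a + b · exp(−TI / T1) |,

with `a > 0` the fully recovered magnetization amplitude and `b = −(1+η)·a`
the signed inversion amplitude for inversion efficiency `η ∈ (0, 1]`
(default 0.96 — adiabatic inversion is good but imperfect; η shifts the null
point, `TI_null = T1·ln(1+η)`, but cancels from noiseless T1 estimation).
The model assumes full recovery between inversions (TR ≫ T1) and ignores
readout perturbations; a deliberately simple multiplicative apparent-T1 knob
(`read_flip_t1_scale`, default off) stands in for readout-saturation effects
without any quantitative claim.

Fitting assumes a *single* pool. Real white matter is at least
bi-exponential; the two-pool phantom exists precisely to probe what the
mono-exponential pipeline reports when that assumption is violated (see
below).

## Polarity restoration

Magnitude data lose the sign of pre-null samples. With `i*` the index of the
minimum magnitude, the fitter tries flip boundaries `j ∈ {i*−1, i*, i*+1}`
clipped to the valid range, plus `j = −1` (no flip); candidate `j` negates
all samples with index ≤ j. The candidate with the lowest sum of squared
errors wins; ties cannot occur generically and are broken by candidate order
(no-flip first). A configuration switch (`FitConfig.all_boundaries`) widens
the set to every boundary, and `fit_voxel_polarity_restored(check_global=True)`
reports when a brute-force enumeration would have chosen a boundary outside
the default candidate set (a diagnostic; on forward-model data the optimum
boundary is always within ±1 of the magnitude minimum).

## Optimization

Two interchangeable minimizers of the same SSE objective:

* **Per-voxel reference** — direct Nelder–Mead simplex over `(a, b, T1)`,
  initialized at `T1₀ = TI(i*)/ln 2` (null-point heuristic), `a₀ = max s`,
  `b₀ = y₀ − a₀` (signed first sample minus amplitude), with two restarts at
  `T1₀ × {0.5, 2}` on non-convergence; function tolerance `1e-8·(max s)²`,
  parameter tolerance `1e-6·max(a₀, T1₀)`, 2000 iterations.
* **Map engine** — the model is linear in `(a, b)` at fixed T1, so
  `fit_map` uses variable projection: an exact 2×2 least-squares solve on a
  96-point log-spaced T1 grid over [50, 6000] ms, then 48 golden-section
  steps in log T1 (final bracket ~1e-10 relative), fully vectorized across
  voxels and flip candidates. On noiseless forward data it recovers T1 to
  better than 1e-6 relative; a regression test pins its agreement with the
  simplex reference to ~1e-4 on noisy data (both land in the same basin; the
  residual difference is the two stopping rules).

The four-longest-TI mode keeps the four largest TIs, assumes positive
magnitudes, and solves ordinary least squares. The phrase "least-squares
weighting" for this variant is ambiguous in the field; uniform weights are
the default and a signal-proportional weighting is available via
`FitConfig(weights="signal")`.

Validity: fitted voxels are flagged unsuccessful outside T1 ∈ [100, 5000] ms
(excludes CSF-like and failed fits; configurable), for all-zero signal, and
outside the analysis mask. R1 is defined as 1000/T1 (T1 in ms, R1 in 1/s) on
successful voxels and NaN elsewhere.

## Geometry and binning

θ_FB = arccos(|V1·B0|) ∈ [0°, 90°]; voxels whose V1 norm is outside 1±1e-3
(zero vectors outside the brain, badly scaled inputs) are invalid and never
enter profiles. B0 defaults to the grid's third axis (acquisitions without
angulation); any unit vector can be supplied. Grids are assumed
co-registered; shape mismatches raise rather than resample.

Profiles use 9° bins by default — centers 4.5°, 13.5°, …, 85.5°, which makes
the first two centers coincide with the 0°-extrapolation anchors — the bin
width is configurable to any divisor of 90. The bin at 90° is closed so no
voxel is dropped; a test asserts counts are conserved. Means (not medians)
aggregate within bins; SD is the across-voxel sample SD (n ≥ 2). R1 profiles
bin the per-voxel reciprocals; they are *not* reciprocals of T1 bin means,
and a regression test keeps the two distinct.

FA masks use a strict lower and closed upper bound, `fa_low < FA ≤ fa_high`
(so an "FA > 0.5" cutoff excludes exactly 0.5); default band (0.5, 0.8].
Downsampling (for resolution-sensitivity checks) is a non-overlapping block
mean with trailing partial blocks averaged over available voxels and voxel
size scaled by the factor.

## Feature conventions

* **Endpoints.** value(0°) is extrapolated linearly through the first two bin
  centers; value(90°) is by default the last-bin mean, with an optional
  symmetric extrapolation (`extrapolate_high=True`). Δ(0–90) is oriented
  positive in the physiological direction (T1: 90° − 0°; R1: 0° − 90°).
* **Baseline.** The straight line through two anchors: (mean center of
  populated bins in 0–20°, mean of those bins' means) and likewise over
  80–90°. Anchor abscissae at the window's populated-bin mean keep the
  construction reproducible when bins are missing.
* **Hump.** Residual = profile − baseline (T1) or baseline − profile (R1);
  amplitude is the maximum residual over the 20–70° search window
  (configurable), peak angle its bin center, FWHM the distance between the
  two half-amplitude crossings located by linear interpolation between
  adjacent bin centers; a crossing not bracketed inside [0°, 90°] flags the
  FWHM unbounded. All-nonpositive residuals give amplitude 0 with the FWHM
  undefined.
* **Percentages** are relative to the mask-wide mean T1 (or R1), not the
  baseline mean; report rounding is one decimal, half-up.

Across-subject aggregation reports per-field mean, SD and n, plus Welch and
(optionally) paired t statistics between two groups.

## What the phantom emulates — and what it does not

`sample_fiber_field` draws isotropic unit fiber directions (so the θ_FB
density is sin θ and every bin is populated on ≥20³ grids), random antipodal
signs (exercising the folding logic), and two-band uniform FA. The
single-pool truth is `T1(θ) = T1∥ + Δ·θ/90 + A·exp(−4 ln2 (θ−40°)²/FWHM²)`;
a Gaussian hump parameterized directly by FWHM makes width recovery
analytic. Rician noise is the magnitude of the signed signal plus complex
Gaussian noise; default a/σ = 50.

**Features are injected in measurement space.** The two-anchor baseline sits
on the tails of a broad Gaussian: a raw 23.5 ms hump of 34° FWHM measures as
only ~21 ms under the convention (~−10 %), and the last-bin 90° endpoint
under-reads a linear term by ~5 %. Reported feature values in angular-T1
studies are convention-measured quantities, so
`GroundTruthAngularModel.calibrated(delta, hump, fwhm, mean_t1)` solves the
raw model parameters (by fixed-point iteration against a dense sin-weighted
profile oracle) such that the *measured* features of the noiseless ground
truth equal the requested values, and such that the isotropic-orientation
mean T1 equals `mean_t1`. Recovery tests then measure pipeline error (noise,
fitting, binning) rather than the convention's inherent tail truncation. The
raw-parameter constructor remains available.

The two-pool truth mixes a short-T1 compartment (field-dependent:
`SHORT_T1_BY_FIELD` = 120/260/540 ms at 1.5/3/7 T) into the recovery with an
angle-dependent fraction sharing `a` and `b`. Forward analysis of the
magnitude fit shows that a *larger* short fraction speeds the mixed recovery
and shortens the apparent T1; the observed phenomenology — signal humps near
40° in pre-null TI images, an inverted shallow hump at mid TIs, a 40°
apparent-T1 hump that largely vanishes from four-longest-TI fits, and
long-TI T1 ≥ all-TI T1 — therefore corresponds to a short-pool fraction that
*dips* at 40° (negative `fraction_short_hump_amplitude`; the default demo
uses baseline 0.25, dip −0.15). The field is signed, so either construction
is expressible.

Not emulated: k-space/EPI artefacts, B1 inhomogeneity, partial-volume mixing
with GM/CSF, crossing fibers, realistic anatomy, or between-subject
variability. Passing phantom tests therefore demonstrates correctness of the
measurement chain under its stated statistical assumptions, not robustness
to everything real data contain.

## Known limitations

* **Rician near-null bias.** Least squares on magnitude data is biased where
  the recovery crosses zero: the expected magnitude at the null is
  σ·√(π/2), not 0. The bias of the fitted T1 therefore depends on where the
  null falls relative to the TI schedule. At the 7 T defaults (mean T1
  ≈ 911 ms, η = 0.96) the null T1·ln(1.96) ≈ 613 ms sits on the 600 ms
  sample; Monte Carlo at a/σ = 50 shows the T1 bias swinging from −1 ms at
  T1 = 880 ms to +5 ms at T1 = 935 ms, a local slope that *amplifies* the
  recovered angular contrast by roughly 15 % there, while the 1.5 T schedule
  (null ≈ 380 ms, between samples) is nearly unbiased. This is a property of
  the estimator all magnitude-IR pipelines share, not of the implementation
  (the simplex and variable-projection solvers agree to 1e-6); phantom
  recoveries at 7 T-like parameters should be read with this in mind.
* Mono-exponential fitting of genuinely multi-exponential voxels yields an
  apparent T1 whose meaning depends on the TI schedule (the two-pool tests
  quantify exactly this).
* The four-longest-TI fit lacks pre-null and fully recovered samples, so its
  absolute T1 is poorly conditioned; only contrasts between its profiles and
  the all-TI profiles are interpreted.
* No bi-exponential, magnetization-transfer, or B1-corrected modelling; no
  phase-sensitive (complex) IR fitting.

## Problem sizes and runtimes

Default verification runs use 48³ phantoms (~1.1e5 voxels; the full chain
takes ~15 s on one CPU thanks to the vectorized fitter); two-pool property
checks use 24³ noiseless grids. The acceptance script runs one
1.5 T-parameterized and one 7 T-parameterized 48³ phantom at SNR 50 and
reports recovered Δ(0–90), hump amplitudes and FWHM; all randomness derives
from its `--seed` via spawned child seeds (fiber field and noise separately),
making every run bit-reproducible.
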