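# Methods

This note documents the models, estimators and numerical choices behind
each stage of the pipeline, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Synthetic scenes

**Rendering model.** Filaments are straight 2D segments of uniform linear
photon density (`photons_per_um`, expected photons per µm of one filament
per z-section). A segment is splatted onto the pixel grid at five samples
per pixel length, convolved with an isotropic 2D Gaussian PSF
(`psf_sigma_um`, default 0.13 µm), and a uniform background
(`background_photons`/pixel) is added; each pixel of each z-slice is then
Poisson-sampled. This conserves photons: for a noise-free field, the
per-slice total equals `background·n_pixels + photons_per_um·Σ lengths` up
to PSF truncation at the border (filaments are placed inset by 2·psf_sigma,
keeping the loss below 0.1%). Shot noise is the only noise term — camera
read noise and gain are deliberately omitted because every downstream
statistic tested here is photon-limited, and one fewer parameter means one
fewer thing to mis-set.

**z-sections.** The acquisitions being emulated sample a thin z-range
(6×0.25 µm for bundling fields), so all z-sections share the same in-focus
rendering and differ only in their independent shot noise; a 3D PSF would
change nothing visible to the 2D max-projection all analyses start from.

**Field geometry.** Default bundling fields are 65×65 µm² at 0.13 µm/px
(a plausible pixel size for a 100×/1.4 NA confocal; the true magnification
of the source acquisitions is not documented, so the 0.4 intensity
threshold is calibration-dependent and kept configurable). Placement is
uniform random position/orientation with rejection until the segment lies
inside the inset field. `min_separation_um` optionally enforces a minimum
segment-to-segment distance — depolymerization fields default to 1 µm
separation because the emulated preparation is diluted >20-fold before
imaging and crossing filaments cannot be length-measured anyway (they are
flagged and excluded).

**Bundles.** A bundle is `bundle_size` copies of a base segment offset
laterally by at most `bundle_lateral_jitter_um` (default 0.02 µm, far below
the PSF width), so bundle intensity ≈ bundle_size × single-filament
intensity — the physical premise of the bundling assay. `bundle_fraction`
is the fraction of all filaments that are bundle members.

**Spindle simulation.** Each cell's kinetochores sit at
±`plate_separation_um`/2 along the equator normal with Gaussian scatter
(σ_perp across, σ_par along the plate), then the cell is rotated by a
uniform angle and translated. The generative perpendicular distribution is
a symmetric two-point mixture of Gaussians with
SD = √(sep²/4 + σ_perp²) — the closed form used by the recovery tests.

**Flux movies.** The spindle's tubulin signal along its axis is a Gaussian
band (half-width `spindle_sigma_um`) extruded across the short image axis;
poles are fixed in the frame. At t=0 two multiplicative Gaussian bleach
stripes (depth ∈ (0,1], width `bleach_width_um`) are stamped at signed
offsets from the spindle center, one per half-spindle; each stripe center
then translates toward its nearer pole at the ground-truth rate, with
optional exponential recovery of the bleach contrast
(halftime `recovery_halftime_s`). Defaults follow the emulated
acquisition: 5 s frame interval, 13 frames (one minute of anaphase A).

**What the simulator does not emulate** — and hence what passing recovery
tests do *not* demonstrate about real data: dynamic instability and curved
or wavy filaments; out-of-focus light and 3D PSF structure; camera gain,
offset and read noise; kinetochore-fiber mechanics, spindle-pole motion
and whole-spindle elongation during the flux recording; uneven
illumination and photobleaching of the *whole* field (the kymograph stage
compensates per-row median decay, but the generator does not produce it).

## Image processing

Stacks are max-projected over z (standard for sparse fluorescent
structures and monotone in filament presence). Intensities are normalized
by a monotone affine map of the [0.5, 99.9] percentile window onto [0, 1]
with clipping, which makes everything downstream invariant to affine
intensity rescaling. When several images of one experiment are compared,
the normalization bounds are computed once from the pooled pixels of all
images (`pooled_percentile_scale`) so that "relative intensity units" —
and the 0.4 bundling threshold applied to them — mean the same thing in
every image; per-image scaling would silently re-define the threshold per
image and erase the between-condition contrast it exists to measure.

Segmentation is a global threshold (Otsu by default, a fixed value on the
normalized scale as the reproducible alternative) followed by 8-connected
labeling, discarding components under `min_area_px` (default 5). The
cross-condition bundling workflow uses the fixed threshold (0.12 on the
shared scale): per-image Otsu is bistable on strongly bimodal bundled
fields — it can lock onto the filament/bundle boundary instead of the
background/filament boundary, which silently drops all single filaments
from the mask. Coordinates are pixel-centered and 0-based; physical
position = (index + 0.5)·pixel_size.

## Bundling statistic

Each ROI contributes its pixel area at its mean normalized intensity. The
histogram (50 bins over [0, 1], area-weighted, fractions normalized to 1)
is for display; the statistic — the area fraction above the intensity
threshold — is computed from the raw ROIs. The statistic is computed per
image and conditions are compared by Welch t-tests across images, because
replicate counts in this assay are slide images; pooling ROIs across
images would pseudo-replicate. Whether ROI intensities should be
background-subtracted before thresholding is an open question of the
emulated protocol; the normalization's low anchor (0.5th percentile ≈
background) approximates a background subtraction.

## Filament lengths and shrinkage rate

The rate is the two-time-point difference the original assay used, not
per-frame tracking. Two length estimators are implemented:

* **axis** (default): the extent of the ROI's pixels projected on their
  principal axis. For straight filaments its only error is the additive
  blur-driven extension of the mask beyond the true ends — identical at
  both time points when both frames are normalized to one shared scale and
  thresholded identically (the workflow enforces this), so it cancels in
  the difference. Recovery tests show no detectable bias (within 2 SEM
  over 20 seeds at 0.9 µm/min, 50 filaments, shot noise on).
* **skeleton**: morphological-skeleton chain length (1 px orthogonal, √2
  diagonal steps), rescaled by the exact chain-code overestimate factor
  for a digital straight line at the skeleton's end-to-end orientation,
  plus 1 px per free end. Generalizes to gently curved structures but
  retains a few tenths of a percent of quantization bias — measurable in
  the two-time-point difference, which is why it is not the default.

ROIs whose skeleton has more than two endpoints (crossings, aggregates)
are flagged and excluded from rate statistics. Filament identity across
time points is recovered by greedy nearest-midpoint matching (retraction
is symmetric, so midpoints are fixed); filaments present at t₀ but
unmatched at t₁ are censored — counted and excluded, because including
them at length 0 would require knowing *when* they vanished. Estimates are
therefore conditional on survival to t₁; at rates near L/Δt this censors
the fastest-shrinking (shortest) filaments and the population estimate
rises toward the uncensored subpopulation's rate. A population-mean mode
(difference of mean lengths) exists for when identities are unavailable,
valid only without censoring.

## Spindle geometry

The equator is fitted by total least squares — the major principal axis of
the kinetochore covariance through the centroid — because the downstream
quantity is the perpendicular distance; ordinary least squares would make
the metrics depend on the camera axes (an OLS variant exists behind a
flag for comparison). The fit is exact: it agrees with a brute-force
1e-4 rad angle scan on random instances. Direction sign: positive
x-component, or aligned with the pole-to-pole vector when poles are known.

SD is the *population* standard deviation of the signed distances (so a
symmetric pair at ±d has SD exactly d). Because distances are measured
about a fitted two-parameter line, the expected per-cell SD of the two-row
mixture carries the finite-sample factor √((n−2)/n); recovery tests
compare against that corrected closed form. Whether the emulated analysis
averaged per-cell SDs or pooled all cells is ambiguous in the source
protocol; per-cell-then-average is the default, and pooling is available
via `align_cells` (a rigid per-cell transform — distances preserved to
1e-9 µm — mapping centroid to origin and equator to the x-axis).

KW is the 2–98 percentile range of projections on the equator direction
(robust to a single outlier kinetochore, unlike min–max). SW thresholds
the smoothed tubulin projection at half its maximum and measures the mask
extent perpendicular to the pole axis. Poles are supplied or detected as
the two strongest smoothed maxima ≥2 µm apart.

Metaphase selection operationalizes the "two nearly parallel rows
separated by less than ~2 µm" rule: a 1D two-means split of the signed
distances must yield group means closer than 2 µm with each group's spread
smaller than the separation. Lagging scoring: a kinetochore lags if its
distance to the nearer pole strictly exceeds `lag_fraction`·SL
(default 0.2 — this package's operationalization of a qualitative rule;
configurable and reported in output).

## Kymograph and flux

The kymograph samples the movie along a user-supplied line (bilinear
interpolation at 1 px steps, averaged over `width_px`=3 perpendicular
offsets), one row per frame. Mark detection divides each median-normalized
row by its greyscale-closing baseline (structuring element 25 px, wider
than any plausible stripe): the closing fills the bleach dips but
preserves the band profile and the dark margins, so marks are the minima
of a ratio that is ≈1 elsewhere. The matrix is padded with dark columns
before closing — otherwise the margins read as valleys and produce
spurious edge minima. Seeds must dip 3× the row-noise MAD below the
median, else a "no bleach mark" error. Tracking is a windowed argmin
(±3 px around the previous row's position, preventing lock-on to the other
mark) with parabolic sub-pixel refinement clamped to ±½ px; the slope is a
least-absolute-deviation fit (median regression), robust to
recovery-induced contrast loss late in the movie, with per-mark residual
diagnostics. An angle-scan (discrete Radon) estimator over a slope grid is
included as an independent cross-check. Known small bias: the product of
the sloped band profile with the bleach dip shifts the apparent minimum
slightly toward the band peak, growing as the mark moves outward; the
effect is ≲1.5% of the rate at the defaults and is covered by the
recovery tolerances.

## Statistics

Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
freedom, two-sided; SEM error bars; star codes with inclusive thresholds
(* p≤0.05, ** p≤0.01, *** p≤0.001, **** p≤0.0001). Degenerate contract:
two zero-variance samples give t=0, p=1 when equal, |t|=∞, p=0 when not.
No multiple-testing correction is applied (pairwise tests are reported
as-is and the output notes this).

## Problem sizes

Recovery experiments in the tests and the acceptance script use: bundling
9 vs 24 images at the full 65×65 µm² field (monotonicity sweep at
40×40 µm², 10 images per level); depolymerization 50 filaments per movie,
two rendered frames (t = 0 and 400 s), 10–20 seeds; spindle recovery 31
cells × 20 kinetochores; flux 10 seeds per rate at 13 frames. These sizes
give standard errors comfortably inside the tolerances being asserted
while keeping a full run in tens of seconds.
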