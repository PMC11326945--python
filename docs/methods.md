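# Methods

This note records the measurement model behind `stedring`, the defaults and
why they were chosen, what the synthetic scenes do and do not emulate, and
the numerical choices a maintainer would want to know.

## Imaging model and coordinates

Images are 2D grayscale rasters with square pixels; all tables use 0-based
(row, col) coordinates with pixel centers at integer positions, sub-pixel
positions continuous, and physical columns suffixed `_nm`. A point at angle
θ on a ring is `center + r·(cos θ, sin θ)` in (row, col) order. The two
channels must share the grid (congruence is enforced); resampling a
coarser-grid companion channel onto the membrane-channel grid is a
preprocessing concern outside the package.

The point-spread function is modeled as an isotropic Gaussian per channel.
Defaults: 20 nm pixels, 60 nm FWHM for the high-resolution (STED) membrane
channel, 250 nm FWHM for the confocal companion channel. These are plausible
values for the imaging regime the pipeline targets, not measured properties
of any particular microscope; all three are configuration fields.

## Ring fitting

Per seeded center: 360 rays, radial profiles from `r_min_px` (2) to
`r_max_px` (20) in 0.25 px steps by bilinear interpolation; per-ray global
maximum with three-point parabolic refinement. Ray retention compares the
peak against the local background, estimated as median + 1.4826·MAD over an
annulus at 1.2–1.5 `r_max_px`. Because each ray's peak is a maximum over
~70 samples, the retention threshold is median + `retention_k`·spread with
`retention_k` = 5: at the nominal 2 spreads, ~40% of pure-background rays
would pass on Poisson background and empty seeds would yield spurious fits
instead of the intended typed no-signal error.

Outlier exclusion is a single pass: peaks deviating more than
`outlier_fraction` (10%) from the mean distance to the center are dropped,
without recomputing the mean within the pass. The circle is the algebraic
least-squares (Kåsa) fit — exact on noiseless circles, closed-form, and
deterministic; geometric (iterative) refinement is deliberately omitted.
The detect → exclude → fit cycle runs `refit_iterations` (2) times,
re-shooting rays from the refined center, with the radial scan narrowed to
[0.6, 1.6]·r̂ after the first pass so that, in crowded fields, the global
maximum cannot lock onto a neighbouring ring's bright patch.

Two robustness guards handle crowded seeds:

- **Seed anchoring.** Clicked centers are assumed accurate to a few pixels.
  If the fitted center drifts more than `max_center_shift_px` (5) from the
  seed — the signature of a fit walking onto a neighbouring ring — rays are
  re-shot from the seed and inliers selected against the median peak radius
  (robust to ~50% contamination) before refitting; a fit that still drifts
  raises a no-signal error rather than returning a wrong ring.
- **Contact-aware joint refinement** (`refine_ring_fits`, two passes in the
  batch pipeline). Where two membranes lie within `merge_zone_px` (3 px)
  of each other, their blurred signals merge and the crest sits between the
  true circles, biasing single-ring fits outward by ~0.1–0.3 px at the
  contact. Knowing all fitted circles of an image, each ring is re-fitted
  from rays whose crest is outside every neighbour's merge zone.

**Radius debias.** The radial crest of a Gaussian-blurred thin ring of
radius r sits at the ρ solving ρ/r = I₁(ρr/σ²)/I₀(ρr/σ²), inward of r by
≈ σ²/2r — about 0.25 px for a 4 px ring at the default STED blur, which is
the dominant error of the raw crest estimator at small radii. `fit_ring`
therefore measures the Gaussian-equivalent width σ of the angle-averaged
radial profile (half-width at half maximum / 2.355) and inverts the crest
relation by bracketed root finding. The correction uses only observables,
is negligible for large rings or sharp profiles, and is skipped when the
width cannot be bracketed; `FitConfig.debias_radius=False` disables it.

**Small-ring fallback.** If the interpolated intensity at the center
reaches `dip_ratio` (0.7) of the mean retained peak intensity — no clear
central dip, i.e. a filled spot below the resolution limit — the circle is
read off a thresholded segmentation instead: Otsu (or half-maximum)
threshold in a local window, connected component containing or nearest to
the seed, intensity-weighted centroid as center, half the binary-moment
major axis as radius. The window is sized from the median peak radius when
available so that cluster neighbours are not swallowed.

`n_points` reports the retained peaks supporting a radial fit (0 for the
fallback); circumference is 2πr in nm exactly. Both circumference and
`n_points` are reported per ring, since either can serve as the size
readout.

## Profiles and correlation

Intensities are sampled at `n_samples` (360) equally spaced angles on the
fitted circle, aggregated (mean by default) over a symmetric radial band
r̂ ± `band_half_width_px` (2 px) in 0.5 px substeps. The companion channel
uses a band widened by `companion_band_factor` (2) — reflecting its lower
resolution. The band half-width is a free choice; 2 px at 20 nm pixels
covers the membrane crest at the default STED blur, and the band-mean is
insensitive to ±1 px changes on noiseless rings (the profile tests verify
the band mean against dense 2D integration at 1%).

Arc positions are θ·r̂ (nm), uniform per ring; cross-ring analyses use
intensities, never resampled arc grids. Per organelle,
R = Pearson(ma₅(ch1), ma₅(ch2)) with a circular (wrap-around) moving
average; the window (odd, default 5 ≈ 5° at 360 samples) is recorded in the
output. Both channels are smoothed symmetrically. Zero-variance profiles
yield an explicitly flagged undefined R, excluded from condition means with
a logged count — never imputed as 0.

## Contact classification

A profile sample on ring i is **Between** when its boundary point lies
within `gap_nm` of another fitted ring, boundary-to-boundary:
min over j≠i of | ‖p − c_j‖ − r_j | · pixel_size ≤ gap_nm. The 30 nm
default reflects the typical spacing of adjacent peroxisomes at contact
sites. Per ring, class means of the companion intensity are computed (an
empty class is flagged undefined), and per cell the class means are pooled
across rings weighted by sample counts.

The default cell rule classifies a cell *outside* iff pooled Outside mean /
pooled Between mean > 1, with ties conservatively *between* and cells
missing either class (e.g. a single isolated organelle) *indeterminate* and
excluded — with a logged tally — from the condition percentage
100·#outside/(#outside+#between).

**Geometric transfer and the ratiometric rule.** The raw companion ratio is
not an unbiased readout of protein enrichment: at every contact two
membranes superpose (doubling both channels' signal), and the confocal halo
accumulates signal in cluster interiors. On synthetic scenes with *no*
planted enrichment the raw Outside/Between companion ratio measures ≈ 0.55,
and even a threefold planted Outside enrichment stays just below 1 — the
raw rule is a relative, not absolute, readout, which is how it should be
interpreted across conditions. `classify_cell(rule="pooled_ratiometric")`
divides the companion ratio by the membrane-channel ratio computed on the
same arcs; the membrane marker carries no localization signal of its own,
so its ratio isolates the geometric transfer, and the quotient recovers
planted enrichment direction with ~97% per-cell accuracy in the cohort
study. A `brightest_ring` rule (the single ring with the largest class mean
decides the cell) is also provided, since the per-cell definition admits
that reading; none of the three is claimed to replicate any particular
historical script.

## Population statistics

Per-condition summaries report mean ± SD (and per-replicate means) of
circumference, companion intensity, and R, plus the Outside percentage per
replicate. The one-way ANOVA (F = MS_between/MS_within, df (k−1, N−k)) runs
by default on per-ring values pooled across replicates; a replicate-means
mode is available, and the grouping level is recorded in the tests table.
Replicate-level Outside percentages between two named conditions are
compared with a one-tailed paired t-test on d = y − x (df n−1); the tested
direction must be stated in the configuration, never assumed. Identical
paired inputs return t = 0, p = 0.5 (the zero-effect limit); constant
nonzero differences raise a degenerate-data error. No multiple-testing
correction is applied, and the output metadata says so.

## Synthetic scenes: what they emulate, and what not

Per ring, the channel-1 angular truth is baseline 1 plus 2–5 von Mises
bumps (κ = 3, ≈ 35° width, unit peak) scaled by `patch_amplitude` (3) —
smooth periodic patchiness resembling membrane-protein clusters. Channel 2
is α·(normalized ch1) + (1−α)·(independent draw), optionally multiplied by
β over the ring's Outside arcs; α = 1 makes the two truths exactly
proportional. Rings are placed per cell; with `cluster_probability` a new
ring is made exactly tangent (boundary gap 0) to an existing one, matching
the sub-30 nm apposition of organelles at contacts; non-clustered rings
keep ≥ 100 nm clearance so their labels are unambiguous. Cells are spaced
so clusters never touch across cells. Rendering deposits each truth on its
circle (arc-length weighted), convolves with the channel's Gaussian PSF,
scales by `photon_budget`, adds constant background, and applies seeded
Poisson noise. Clicked centers are emulated by jittering true centers by up
to 2 px.

Defaults were fixed once, before the validation studies were frozen: ring
radii 120–300 nm (typical yeast peroxisomes; the contact-cohort study uses
300–500 nm, the size regime of multi-peroxisome methanol-grown cells that
the Between/Outside analysis targets), patch κ = 3 chosen by a design-time
Monte-Carlo of the angular-blur model so that full coupling (α = 1) remains
recoverable (R ≥ 0.9) through the 250 nm confocal blur — a validation
instrument must keep its planted signal recoverable in the noiseless limit,
or it validates nothing.

Not emulated: 3D structure, camera read noise, depletion-beam physics,
drift, bleaching, vesicles/vacuoles, or spectral bleed-through. Passing
tests therefore demonstrate correctness of the estimators under the stated
optical model, not robustness to every artifact of real acquisitions.

## Validation studies (the quantities `scripts/acceptance.py` recomputes)

- **Ring recovery** uses isolated, unpatterned rings so the radial error
  measures the estimator rather than the emission model or contact
  geometry; the noisy variant rescales the photon budget so the noiseless
  foreground peak is 100 counts (peak SNR 10 under Poisson noise).
- **The coupling grid** uses isolated rings: at contacts both channels
  receive the neighbour's blurred signal, which adds a correlation
  component unrelated to the planted coupling.
- **Label agreement** compares Between/Outside labels from fitted circles
  against the true-circle labels on noiseless clustered scenes.
- **The contact cohort** plants per-cell truth symmetrically (β on Outside
  arcs for outside-cells, 1/β for between-cells — a one-sided planting
  could not represent between-cells at all, since the geometric transfer
  already favours Between) and classifies with the ratiometric rule.
- **Statistics oracles**: hand-computable ANOVA/t values, F = t² at k = 2,
  and a 500-replicate null simulation of the type-I error.

Study sizes (100 rings, 200 rings per coupling level, 150 cells, 500 null
replicates) keep each study's sampling error well below its decision
margin while the full script completes in minutes on one CPU.

## Numerical notes and edge cases

- Bilinear interpolation everywhere (profiles, dip test, rendering splats);
  per-ray crest positions pixel-lock by up to ~0.25 px on a unit-pitch
  raster, which averages out over rays — aggregate crest accuracy is
  ~0.05 px and is what the circle fit consumes.
- Kåsa fits solve the normal equations after centering on the centroid;
  collinearity is detected by rank and raises a typed geometry error.
- The moving average is implemented by explicit wrap-padding + convolution,
  so the sequence mean is preserved to machine precision.
- Determinism: every stochastic step (scene draw, Poisson noise, center
  jitter) derives from `rng_seed` through independent seed sequences; the
  same configuration yields byte-identical rasters, truth tables, and
  result CSVs.
- Per-ring failures in the batch pipeline (out-of-bounds seed, no signal,
  degenerate geometry) become failure-coded rows; rows in = rows out.

## Known limitations

- Fitted circles assume circular organelles; strongly elliptical or
  indented membranes bias the radius and the arc positions.
- The Between/Outside raw ratio carries the geometric transfer described
  above; absolute percentages should be compared across conditions or
  corrected with the ratiometric rule, not read as enrichment factors.
- The debias step assumes an approximately Gaussian radial crest; heavily
  overlapping membranes or strongly asymmetric profiles reduce its
  accuracy (it then errs toward the raw crest).
- The companion channel is analyzed on the membrane-channel grid; genuinely
  coarser companion rasters must be resampled upstream.
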