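# Methods

## The assay being quantified

A zebrafish xenograft screen images each larva twice — 72 hpf (before
treatment) and 120 hpf (48 h after) — in two fluorescence channels: an
EGFP-range body channel showing the whole larva and a TRITC-range tumor
channel showing implanted Kusabira-orange-tagged leukemia cells. Each
acquisition is a short z-stack (five slices stepped 40 µm at low
magnification; ten stepped 20 µm at high), because a free-swimming larva
settles at an unpredictable depth. The package turns those stacks into
per-fish numbers (tumor burden, migration, proliferation) and per-group
statistics.

## Geometry and units

Pixels are indexed 0-based with x = column, y = row, origin top-left, and
pixel centres at integer coordinates. All physical quantities are in µm via
`pixel_size_um`, a required calibration with default 3.25 µm/px for the
low-magnification mode; no geometric result depends on its particular
value. µm→px rounding is to the nearest integer with ties toward zero.

## Acquisition model and compositing

**Body detection.** The body mask is the set of pixels above a threshold
(Otsu by default; `k_sigma` = mean + k·SD, k = 3, for low-contrast images)
and the centre of brightness is the intensity-weighted mean position of
masked pixels. A constant image or a mask smaller than `min_area_px`
(default 10 px) flags failure rather than raising, so a well is excluded,
not a run aborted.

**Focus scoring.** Sharpness is the mean squared gradient magnitude
(Tenengrad) with central-difference gradients. It is invariant to constant
offsets, scales as c² under intensity scaling c, and is zero for a constant
image. The composite is, by default, the single slice with the highest
score (ties to the lowest index); `tile` mode assembles 64-px tiles each
from its locally sharpest slice, for specimens thicker than the depth of
field.

**Reliability of slice selection.** On synthetic stacks the body channel's
sharp edges make selection essentially certain (200/200 seeded trials with
shot noise plus read noise at 2% of the body peak). The tumor channel is
intrinsically harder: a smooth Gaussian focus of σ ≈ 10–34 µm changes
almost imperceptibly under one z-step of defocus blur (σ ≈ 2 µm ≈ 0.6 px),
so at read noise comparable to 2% of the tumor peak the score argmax can
land on a slice adjacent to the focal one. This is a discriminability limit
of low-texture scenes near the depth of field, not of the metric (a
Sobel-smoothed variant does not close the gap). It is also inconsequential
downstream: the blur kernels are normalized, so total intensity is
conserved (±0.1%) and the integrated tumor fluorescence of a neighbouring
slice differs from the focal slice by well under 5%.

## Tumor segmentation

Foci are 8-connected components of pixels strictly above the threshold,
discarding components smaller than `min_area_um2` (default 50 µm², a few
cell footprints) as hot pixels. The background level is the median of
sub-threshold pixels — robust to tumor brightness — and is subtracted,
clipped at zero, before any intensity sum. Per-focus readouts: area,
integrated intensity, intensity-weighted centroid, mean member-pixel
distance to the centroid ("average radius"). The main tumor is the focus
with maximal integrated intensity (the implanted mass dominates the
signal); ties resolve to the larger area, then the lowest label. Touching
foci merge — no watershed splitting is attempted (documented limitation).

The pipeline's default tumor threshold is `k_sigma` (k = 3) rather than
Otsu: mean + k·SD is exactly linear in the signal amplitude, so when the
tumor brightens between timepoints the captured fraction of each focus's
Gaussian tail is unchanged and the proliferation ratio is unbiased. Otsu's
histogram split has no such equivariance and introduces a few-percent
timepoint-dependent truncation bias. Otsu remains the default for the
high-contrast body channel.

## Migration rings

Concentric circles of 150, 300 and 450 µm are drawn from the centre of
brightness and non-main foci are counted (with summed areas) in the bins
[0,150), [150,300), [300,450), [450,∞) µm. Bins are half-open and
lower-inclusive — "0–150, 150–300" is ambiguous at the boundary, so a focus
at exactly 150 µm falls in the second bin. A focus is assigned by its
centroid alone and never split across rings. The ring origin is the *main
tumor's* centroid by default — the rings measure distance from the
implanted mass — with the whole-channel centre of brightness available via
the `center_um` argument, since the assay description does not fix the
choice.

## Proliferation and quality gates

Per fish, proliferation = I(120)/I(72) of integrated tumor fluorescence,
paired by well. Fish with a 72-hpf signal below `min_baseline_frac`
(default 1%) of the plate-median baseline are excluded with reason
`baseline_below_minimum`: the bench protocol selects "cancer-positive fish
with similar tumor mass" by eye, and this gate is the automated stand-in.
Fish flagged `no_tumor`, `dead` or `unreadable_image` at either timepoint
are excluded from ratios but kept in the bookkeeping; every exclusion is
logged with its reason. Cohort success/survival rates are plain
percentages of the injected count.

## Toxicity brackets and statistics

LD50 is reported as a *bracket* between tested concentrations — matching
how such screens report toxicity (">10 µM", "0.5 µM∼1 µM") — never
interpolated. The bracket is taken at the first downward crossing of 50%
survival; a row whose survival recovers at a higher dose triggers a
warning. The working concentration is the highest tested dose at which
every compound shows exactly 100% survival.

Two-group comparisons use the classic pooled-variance Student t
(n₁ + n₂ − 2 df). Multi-group comparisons use one-way ANOVA followed by
Dunnett's two-sided many-to-one test against the designated control;
adjusted p-values come from the equicorrelated multivariate-t distribution
of max |tᵢ| (scipy's implementation, with the quasi-random CDF integration
seeded for reproducibility), are floored at the raw per-comparison p, and
are starred at 0.05 (*) and 0.01 (**). The family-wise type-I error of
this procedure is verified by simulation in the test suite (2000 null
plates of 4 groups × 10 fish). The control group is designated explicitly
(layout `role` column or an explicit argument) and never inferred from
group names.

## Synthetic data: what it emulates, and what it does not

The generator renders what the downstream code must be able to measure,
with every quantity on record:

- **Body**: an intensity ellipse (semi-axes ≈ 0.28 × field width,
  0.10 × field height, intensity 1000) with a linearly tapered tail —
  enough structure for centroid and masking tests; no anatomical realism.
  The truth `body_center_um` is the centroid of the rendered ideal body
  image, since the tail skews it tailward of the ellipse centre.
- **Tumor foci**: isotropic Gaussian profiles; "radius" is the half-width
  at half maximum, so analytic totals (2πσ²·peak) exist. Defaults: one
  main focus near the yolk position (radius 40 µm, peak 3000, each
  jittered ±10%) plus 0–5 migration foci (radius 8–16 µm, peak
  1200 ± 20%) at exactly specified distances, angles biased toward the
  tail. No published intensity calibration exists for the implanted
  100–200 cells, so these scales are free synthetic parameters.
- **Acquisition**: 256 × 256 px at 3.25 µm/px, five slices stepped 40 µm,
  middle slice in focus; defocus blur is a normalized Gaussian of
  σ = `blur_per_um` × |i − focus| × z-step (default 0.05 µm/µm,
  i.e. σ = 2 µm one step off focus — the geometric blur of an NA ≈ 0.1
  objective); background offset 100; Poisson shot noise and Gaussian read
  noise (SD 2), both optional so exact oracles exist. Images are written
  as 16-bit multi-page TIFF; a growth factor multiplies tumor intensities
  at the second timepoint.
- **Determinism**: all randomness flows from `numpy` SeedSequences keyed
  on (scene seed, channel, timepoint, slice); identical seeds give
  byte-identical TIFFs.

Not emulated: optics-accurate PSFs, intra-focus cell texture, vessel
(fli1:EGFP) anatomy, larva motion, anesthesia artifacts, or well-to-well
illumination drift. Passing tests therefore demonstrate the correctness of
the measurement chain under controlled imaging physics, not robustness to
every failure mode of live-larva microscopy; in particular real composites
can contain texture-driven focus cues and segmentation challenges (touching
foci, autofluorescent gut) the synthetic scenes do not pose.

## Problem sizes used in validation

Oracle-equivalence checks run on 100 random 64 × 64 blob images plus the
fixed reference scene; growth-factor recovery uses plates of 2 groups × 10
fish at default noise (mean per-group ratio within 5% of truth) and
2 groups × 5 fish noise-free (ring counts exact); the Dunnett calibration
uses 2000 simulated null plates. A full 20-well plate generates in ~3 s
and analyzes in ~0.5 s on one core, so the whole suite stays comfortably
interactive.

## Known limitations

- Touching foci merge; migration counts undercount when a focus abuts the
  main mass (mitigated in the generator by a ≥100 µm placement margin).
- Integrated intensity is threshold-truncated: the Gaussian tail below
  threshold is not counted. Ratios are unaffected (the truncation is
  timepoint-equivariant under `k_sigma`), but absolute intensities are
  ~25% below the analytic whole-plane totals at default settings.
- The LD50 bracket carries no uncertainty; with n = 10 fish per condition
  a survival row is effectively all-or-none, which is why bracketing, not
  curve fitting, is the appropriate summary.
- Tile-mode compositing scores edge tiles smaller than 3 px by variance
  rather than Tenengrad.
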