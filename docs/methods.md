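# Methods

## Scope and approach

The package quantifies five assay families on single-plane grayscale
micrographs of *C. elegans* sperm and whole animals: in-vitro sperm
activation (Pronase/monensin), JC-1 mitochondrial membrane potential (MMP)
and morphology, fluorescent redox probes, whole-animal transcriptional
reporters, and in-vivo uterine sperm motility. The measurement conventions
follow ImageJ's particle analysis, which the original workflows were built
on, so numbers are comparable with that ecosystem.

No raw imaging data are public for these assays, so validation rests on a
synthetic generator whose ground truth is known exactly. The generator is
first-class, tested code: its contracts (stratified counts, determinism,
truth/render consistency) are part of the test suite.

## Shape metrics

For each labelled object:

* **area** — pixel count (µm² when a pixel size is supplied);
* **perimeter** — Crofton-weighted boundary length (`perimeter_crofton`,
  4 directions). Circularity is sensitive to the perimeter estimator; this
  one is fixed and documented rather than configurable.
* **circularity** — `4π·area / perimeter²`, capped at 1.0 because
  rasterization can push small round objects slightly above 1.
* **solidity** — area over convex-hull area. The hull area is counted in
  *pixels covered by the hull polygon* using Pick's theorem
  (`A_hull = A_polygon + B/2 + 1`, boundary lattice points `B` summed as
  `gcd(|Δr|, |Δc|)` per hull edge). With this convention a convex digital
  shape scores exactly 1.0; naive polygon areas would penalise
  rasterization by 2–6% on cell-sized objects, swamping the biological
  signal.
* **aspect ratio** — major/minor axis of the second-moment-fitted ellipse
  (≥ 1, degenerate minor axes report 1).
* **Feret's diameter** — the maximum caliper distance, computed as the
  largest pairwise distance among convex-hull vertices of the boundary
  pixel centres; identical to brute-force all-pairs over the boundary, but
  cheap. A single pixel reports 1 px.

Single-pixel and collinear degenerate objects take explicit fallbacks —
no division by zero anywhere in the metric engine.

## Activation classification

The original assays scored activation classes by eye. Here a deterministic
decision tree stands in, applied in order: vacuolated (interior intensity
dip ≥ 0.30 of the interior median) → abnormal; moment-ellipse aspect ratio
≥ 1.50 → spermatozoon (full pseudopod); round and ≥ 572 px → abnormal
(swollen); solidity deficit that a disk(3) opening removes (gain ≥ 0.04
with an opened solidity ≥ 0.94) → abnormal (spiked, too thin to be a
pseudopod); aspect ratio ≥ 1.15 → small protrusion; otherwise spermatid.

Thresholds were calibrated once on noiseless synthetic fields with equal
class counts so that ≥ 95% of ground-truth classes are recovered (in
practice recovery is 100% at the default noise level), and they are
user-overridable (`ActivationRules`). Two auxiliary features feed the tree
beyond the four standard metrics: solidity after a morphological opening
(separates thin spikes from wide pseudopods) and the interior intensity
dip (vacuole detector). These are the package's explicit, auditable
replacement for the manual call; `rule_scores` records every branch input
per cell.

## Segmentation

*Activation fields* (bright cells, dim background): Otsu threshold, fill
holes, a 1-px opening (removes single-pixel rim artifacts that would bite
into solidity), size filter (default 120 px, well under a cell), connected
components. Watershed is off by default here — dissected spermatids are
sparse, and a distance-transform split would sever pseudopods from cell
bodies.

*JC-1 cells* ("generous" green mask): scaled-Otsu threshold
(factor 0.6 — the original "generous" setting is unstated; 0.6 captures
whole dim spermatid bodies on the synthetic fields), size filter
(default 50 px), fill holes, two rounds of 3×3 dilate/erode, then a
distance-transform watershed (seeds ≥ 14 px apart) to separate touching
spermatids.

*Redox cells*: Triangle threshold, fill holes, watershed, size filter,
replacement of each object by its moment-fitted ellipse, and a second
watershed to separate ellipses that merged; final labels are
ellipse-shaped. A constant image raises "no threshold found".

Watershed never creates foreground (labels ⊆ input mask) and uses
4-connected boundary lines.

## JC-1 mitochondrial pipelines

Preprocessing is rolling-ball background subtraction (radius 25 px)
followed by CLAHE (64-px tiles, clip 0.01, output rescaled to the input
range); the original macro's values for these are unstated, so the
defaults are documented choices. Detection negates a Gaussian-smoothed
Laplacian (σ = 1 px; bright blobs give positive response), thresholds it
with IsoData (iterative intermeans, 256 bins), and keeps components of
≥ 7 px — the stated debris cutoff, applied exactly.

Two numerical choices matter on sparse fields and are therefore explicit:

* the IsoData histogram is formed over response values above a robust
  noise floor (median + 3 scaled MADs). Without the floor, the
  empty-background mode dominates the histogram and the intermeans fixed
  point lands inside the noise. The cut itself is still the intermeans
  fixed point.
* each detected component is trimmed to the half-max footprint of the
  *unequalized* channel (the response footprint is systematically wider
  along a blob's major axis than its minor axis, which would inflate
  aspect ratios by ~35%; CLAHE flattens blob tops, so the half-max must
  come from the raw channel). The trim is bounded to the component plus a
  1-px margin, so neighbouring structures are never absorbed. This
  refinement can be disabled (`MitoParams.refine_halfmax`).

Counting reduces each detected mitochondrion to one representative point —
its internal intensity maximum, with plateau/near-equal maxima merged by a
prominence tolerance (default 10% of the object's dynamic range) — and
counts points per cell label; boundary points fall back to the
mitochondrion's majority-overlap cell, and points outside every cell are
reported under key 0, so counts always sum to the number of detections.
The per-cell red:green ratio is the ratio of channel totals under the cell
mask; a zero green total flags the ratio undefined (nan), never infinity.
No per-cell background correction is applied to the totals by default
(whether the original totals were background-corrected is unstated).

## Reporters and motility

Adjusted reporter intensity is animal mean minus the average of all
background readings (negative values are returned but flagged); relative
intensity divides by the pooled control-group mean, making the control
mean exactly 1 and the measure invariant to global intensity scaling.
Animal ROIs come from a manual polygon (CSV of vertices) or an automatic
Otsu + largest-component mask; provenance is recorded per measurement.

The uterus axis is the straight vulva→spermatheca segment. Sperm are
projected onto it; zones are thirds with half-open boundaries
([0,1/3), [1/3,2/3), [2/3,1]) — a sperm at exactly 1/3 is zone 2 — and
out-of-range projections are clamped with a warning. Track speed is total
path length over elapsed time (tracking convention); net displacement over
time is available separately as a progressivity metric. Per-arm velocity
averages zone-2 track speeds; an arm without qualifying tracks reports a
missing value, never zero. The default frame interval is 30 s.

## Synthetic generator

All randomness flows from one seeded `numpy` generator; identical
config + seed yields byte-identical images. Cells are placed on a
jittered grid sized by the largest cell extent, so fields are overlap-free
except for an explicitly configured fraction of touching pairs (placed at
tangency to exercise the watershed).

*Activation fields.* Class counts are exact largest-remainder roundings of
mixture × n — never binomial draws — so fraction-recovery tests isolate
classifier error from sampling error; per-cell geometry stays random.
Default geometry: cell radius 12 ± 0.5 px (tight size control, matching
the absence of a size phenotype between genotypes; absolute size in µm is
not pinned by the source assays, so pixel radii are plausible
placeholders), pseudopod 0.8× diameter long and 0.35× wide (tapered),
small protrusion 0.35×/0.45×, spike 0.6×/0.20×, swollen morph at 1.5×
area, vacuole at 0.35× radius with a 70% intensity dip. Amplitude
120 ± 8 over background 8 with a ±4 linear gradient, optics blur σ = 1 px,
Gaussian read noise σ = 2 (Poisson optional). The three Pronase presets
encode the published activation mixtures: wild-type 9/4/85/2 (only the
85% activated figure is published; the split of the remaining 15% is this
package's choice), mutant 63/9/23/5, AKA36 62/12/21/5 percent over
(spermatid, small protrusion, spermatozoon, abnormal).

*JC-1 fields.* Mitochondria are anisotropic Gaussian blobs placed with a
minimum-separation retry so they render as discrete organelles. High-MMP
mitochondria fluoresce red at a fixed multiple (8×) of their green
amplitude — emulating aggregate emission tracking monomer loading — so red
blobs are uniformly detectable; the drawn per-cell red:green ratio
(LogNormal, mean 2.0) is realised by diluting the diffuse green cell-body
amplitude, and the recorded `true_ratio` is exact for the noiseless
render. Low-MMP (green-dominant) mitochondria contribute no red signal.
The wild-type preset uses elongation 1.2 ± 0.15, σ 0.15 ratio spread and
10% low-MMP mitochondria; the mutant preset larger cells (24 px) with
elongation 3.0 ± 0.4, thicker blobs, σ 0.45 spread at the same mean and
30% low-MMP — encoding the published contrasts (larger/longer/more
elongated/less circular mitochondria, wider ratio spread at an unchanged
mean, excess green-channel mitochondria). In dense mutant cells elongated
blobs can overlap and detect as fused clusters; that is the hyperfusion
phenotype rather than an artifact, and the per-object fidelity tests use
sparse configurations where every blob is resolvable.

*Reporter animals* render a tapered sinusoidal worm at an absolute mean
intensity (50 × brightness factor) over background 10; edges are sharp, so
a zero-noise render recovers the configured means exactly under the truth
mask. *Uterus time-lapses* move bright puncta along straight lines at
drawn speeds (0.15 ± 0.04 px/s, 30 s frames by default), so true per-track
speed equals the draw exactly; placement along the axis follows a Beta
distribution (wild-type biased spermathecal, mutant vulval).

What the generator does **not** emulate: optical PSF structure beyond
Gaussian blur, depth/defocus, autofluorescence texture, debris, curved
uterine geometry, or cell motion during acquisition. Passing tests
therefore demonstrate that the pipelines are correct implementations of
the stated procedures and recover known truth under idealised imaging —
not that they are robust to every artifact of real micrographs.

## Problem sizes and determinism

The bundled suites run activation fields of 200 cells at 1280², JC-1
fields of 25 cells at 640–704², and time-lapses of ~10 frames at 256×512 —
sizes chosen so a full validation pass completes in well under a minute
per assay on one CPU while keeping ≥ 180 sperm per activation field, the
scale of the source assays. The acceptance script reuses the presets
unchanged at n = 200. Every driver echoes its full effective configuration
(defaults merged with overrides) into a YAML-formatted run log, and a
fixed seed reproduces any run bit-for-bit.

## Known limitations

* The "generous" Otsu factor can admit background on pathological
  two-level histograms where Otsu's criterion is nearly flat; realistic
  noisy backgrounds do not trigger this.
* Measured per-cell ratio spread exceeds the generative spread because the
  green mask extent co-varies with the body amplitude; comparisons between
  presets (the supported use) are unaffected.
* The activation decision tree is calibrated on synthetic geometry, not on
  expert labels; on real data its thresholds should be re-calibrated
  against a manually scored subset (all thresholds are config-exposed).
* Only straight uterine axes are modelled by the generator, although the
  zone module accepts any pair of landmark points.
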