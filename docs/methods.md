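# Methods

This note documents the models, estimators and design choices in katquant:
what each stage computes, the assumptions behind it, what the synthetic-data
generators emulate, and where the methods have known limitations.

## Conventions

Angles are in degrees, measured counterclockwise from the +x (column) axis
with the image y axis pointing down; orientations are axial (modulo 180,
reported in [0, 180)). Lengths are µm, leaf dimensions mm (converted
internally), times in the units stated per field (severing durations in
minutes with event times in seconds; division time-lapses in minutes).
No p-value is reported as exactly 0; underflow floors at 1e-300.

## Microtubule array metrics

**Anisotropy and orientation.** Per-pixel intensity gradients are taken by
centered differences; the local fibril direction is orthogonal to the
gradient. The unit nematic tensors n = uuᵀ of those directions are averaged
without weighting over ROI pixels whose gradient magnitude exceeds 1e-12
(pure-background pixels in noise-free images are thereby excluded; in noisy
images every pixel contributes, which dilutes anisotropy toward 0 — the
familiar behaviour of fibril-tensor tools on low-SNR data). Because the
averaged tensor has unit trace, anisotropy = λ₁ − λ₂ ∈ [0, 1] and the
principal angle is the leading eigenvector's orientation,
θ = ½·atan2(2n₁₂, n₁₁ − n₂₂). The angle to the growth axis is the acute
difference in [0, 90]. A flat ROI returns anisotropy 0 with the angle
flagged undefined.

**Density.** The IsoData ("default") threshold is computed on the whole
image and the foreground area fraction measured within the ROI; density is
reported as 1 − that fraction, exactly as the upstream workflow defines it.
If the threshold selects filaments as foreground this is the *background*
fraction; the complement is always available as 1 − density. We keep the
printed definition rather than silently inverting it.

**Bleach correction** rescales every frame to the first frame's mean
(simple ratio). It is exact for pure multiplicative decay and idempotent.

**Severing frequency** is count / (cell area × duration) in
events · µm⁻² · min⁻¹ (the units are a package choice; upstream practice
states only "per area over time"). Events are manual annotations; automated
severing detection is out of scope. Against homogeneous Poisson streams the
estimator is unbiased (mean relative error ≪ 1% over 200 replicates at ~200
expected events).

## Leaf morphometry

Cell length and width come from the minimum-area bounding rectangle of the
outline — rotation-invariant and matching manual long/short-axis practice —
with elongation ratio length/width ≥ 1.

The whole-leaf cell count is extrapolated from base, middle and tip region
samples, each region weighted as exactly one third of the leaf area even
though real blades taper:

    Total ≈ Σ_r (A/3) · [PC_r + 4·SC_r] / [Σ PCA_r + Σ SCA_r]

with PC/SC the sampled pavement-cell and stomatal-complex counts, PCA/SCA
their areas, and each stomatal complex counting as 4 cells (2 guard + 2
subsidiary). The estimator is exact (to float precision) when the samples
tile the leaf, and unbiased under uniform subsampling; with 5% of cells
sampled per region its spread is dominated by resampling of the stomatal
composition (SD ≈ 1% at ~2000 sampled cells per region).

**Leaf projections** answer "what would the wild-type leaf look like with
mutant cell properties": mode 1 rescales the wild-type leaf by mutant mean
cell length and width (cells along each axis = leaf length / mean cell
length etc., real-valued, not rounded); mode 2 = wild-type cell number ×
mutant mean cell area; mode 3 = mutant cell number × wild-type mean cell
area (laid out in the wild-type aspect ratio); mode 4 = mutant number ×
mutant area. Modes 2 and 4 define only an area. All four return the
wild-type area when mutant statistics equal wild-type ones, and mode 4 =
mode 2 × (count ratio) identically. Whether mutant statistics pool regions
or match region-by-region, and per-leaf vs per-genotype averaging, are left
to the caller — both orderings are expressible.

**Elongation rate** is the OLS slope of length on time over the supplied
window; callers trim to the linear phase (no automatic phase detection).

## DNA-content cytometry

Integrated density (sum of pixel intensities over a segmented nucleus) is
proportional to DNA content at fixed gain, but gain varies per image.
Normalization therefore divides each measurement by its image's modal
density — the 2N peak, located as the maximum of a Gaussian KDE with
Silverman bandwidth on a 512-point grid — and scales the mode to 100. The
KDE peak is used instead of a histogram argmax because the latter depends
on bin width. Images with fewer than 20 nuclei are normalized but flagged
unreliable. Normalization is exactly invariant to per-image gain.

Phases are binned on the normalized scale: 2N = [60, 140] and
4N = [160, 210] closed (boundary values assign deterministically), S the
open interval between, everything else unclassified. Fractions are reported
over the full population (unclassified included in the denominator), with
classified-only denominators also available. Plain bin counting is used; no
curve fitting is applied to the histogram shape.

**Known bias.** Bracket binning undercounts S: an S-phase nucleus with DNA
content uniform between 1× and 2× falls inside the 2N bracket ~40% of the
time and inside the 4N bracket ~40% of the time, so only ~20% of true
S-phase nuclei land between the brackets; likewise multiplicative noise
(CV 8%) pushes ~27% of true 4N nuclei above the asymmetric 210 cutoff.
The test suite quantifies both effects against the analytic pushforward of
the generator model; comparisons between genotypes remain valid because the
bias applies to both.

Label-mask measurements use per-label intensity sums, pixel-count areas,
intensity-weighted centroids, and a perimeter from Moore-neighbour tracing
of the 8-connected boundary (axial steps 1, diagonal steps √2), which keeps
circularity 4πA/P² near 1 for rendered disks. Circularity is capped at 1.

## Division geometry

PPB categories (normal, four-sided, three-sided, split, uneven, one-sided,
misoriented) are input annotations — they were scored by eye, and a
rule-based image classifier would overreach. Each category is tested as a
2×2 table (category vs rest, by genotype) with the two-sided Fisher's exact
test; the family of 7 tests uses the Bonferroni threshold 0.05/7 ≈ 0.007.

Nuclear offset = distance between nucleus and cell centroids, normalized by
the **full** long-axis length (not the half-length), ×100. Axis position
projects the nucleus onto the long axis with 0% at the end opposite the
dominant microtubule accumulation and 100% at the accumulation (50 =
mid-cell); this orientation convention makes offset direction comparable
across cells.

Stage durations use inclusive frame counting (k frames in a stage → k ×
interval, default 10 min): metaphase from the first PPB-free frame through
the last pre-telophase frame, telophase from the first phragmoplast frame
through disassembly. Phragmoplast expansion is the OLS slope of length vs
time over telophase frames.

## Statistics core

The two-sided Fisher p-value sums hypergeometric probabilities of all
tables with the observed margins that are no more probable than the
observed table, within relative tolerance 1e-7 — the convention of
mainstream implementations, delegated to scipy and verified in the test
suite against exhaustive enumeration for all small tables. Chi-square
independence is the Pearson statistic without continuity correction. The
Wilcoxon rank-sum test uses exact enumeration when both groups have ≤ 25
observations and no ties, otherwise the normal approximation with
tie-corrected variance and continuity correction. Bonferroni adjustment
reports min(1, m·p) with significance at raw p < α/m.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) via numpy's
`default_rng`; identical calls give byte-identical outputs, and every
categorical generator has a quota mode (largest-remainder rounding of
probabilities × n) so printed tallies reproduce verbatim.

* **Epidermis mosaics** tile a rectangular leaf, split lengthwise into
  three equal regions, with a jittered rectangular grid (grid lines
  perturbed with relative SD 0.15 and rescaled so each region tiles
  exactly — making the count extrapolation exact on full samples). Default
  cell dimensions (base 60×18, middle 100×20, tip 80×20 µm; stomatal
  fraction 0.25) are typical of an expanded maize blade. The mosaic does
  not emulate lobed pavement-cell outlines, blade taper, or stomatal-row
  patterning, so passing tests validate the estimator arithmetic, not
  segmentation of real micrographs.
* **Filament images** draw line segments with axial von Mises orientations
  (sampled on the doubled circle and halved; κ = 0 isotropic, large κ
  parallel) and a smooth Gaussian cross-section (the analytic profile
  avoids rasterization staircase that would bias the tensor), plus Gaussian
  read noise (SD 0.02 of filament amplitude by default). The ideal
  "parallel stripes" scenario is the noise-free large-κ limit. No PSF or
  photobleaching is modelled.
* **Severing streams** are homogeneous Poisson in area × time with uniform
  event times and positions.
* **Nuclear populations** draw per-nucleus phase from (f₂N, f_S, f₄N) with
  the remainder an out-of-range tail (multiplier 2.2–4, emulating
  aggregates); density = gain × µ × m × (1 + ε) with m = 1 (2N), 2 (4N),
  uniform(1, 2) (S) and ε ~ Normal(0, CV) truncated at −0.9 (densities are
  positive; the default CV 0.08 matches tight staining). Geometry is
  disk-consistent. Default per-image gains (0.8, 1.0, 1.5) emulate
  session-to-session staining/acquisition drift.
* **Division records** draw categories multinomially (or by quota) and
  displace the nucleus toward the dominant accumulation side by a
  category-dependent mean fraction of the long axis (normal 0, three-sided
  0.05, uneven 0.10, misoriented 0.10, one-sided 0.15; SD 0.03), on a
  30 × 12 µm rectangular cell with the long axis along +x.

## Problem sizes and numerical choices

Analyses and the acceptance script run at the study's tallies (161/182 PPB
cells; ~3076 and ~4124 nuclei over 3 images per genotype) and at synthetic
sizes chosen to make estimator spread small relative to the tolerances
checked: 18 × 6 mm mosaics (~130k cells) for subsampled count extrapolation,
256² filament images with 150–200 filaments, 200 Poisson replicates at ~200
expected events. The tie-break for the KDE mode is the first grid argmax;
quota rounding uses largest remainders; degenerate inputs (flat images,
all-zero tables, zero-variance groups) raise typed errors or return flagged
values as documented per function.

## Limitations

* No segmentation: nuclei arrive as label masks or tables, severing events
  and PPB categories as annotations.
* The bracket S-phase estimator is biased low by construction (quantified
  above); it is retained because it is the method being modelled.
* The region-weighting of the cell-count formula assumes equal-area thirds.
* The 3-sided PPB row of the shipped reference tally is excluded from
  printed-value checks: exact enumeration of that 2×2 table gives p ≈ 0.067,
  inconsistent with the accompanying published annotation (0.7); both
  values lead to the same call at the 0.007 threshold.
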