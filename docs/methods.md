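# Methods

## The measurement problem

Stem-cell colonies grown on a dish are roughly disk-shaped monolayers a few
cell diameters across (the analyses here target colonies of about 80–100 µm
diameter). Immunofluorescence staining of such colonies often shows *radial*
heterogeneity: a marker can be enriched at the colony periphery or at its
centre. `colonyprofiler` quantifies that heterogeneity from multi-channel,
multi-plane image stacks by (1) defining one colony footprint per colony on a
reference channel, (2) partitioning the footprint into concentric sections by
distance from the periphery, (3) measuring per-section mean intensities
relative to the whole-colony mean on selected z-planes, and (4) testing
section and treatment differences with a normality-gated decision tree. A
companion module handles relative expression from qPCR cycle thresholds.

## Colony footprint

Segmentation runs on the reference-marker channel only: Gaussian smoothing
(`smoothing_sigma`, default 1 µm), a threshold, hole filling, and rejection of
objects smaller than a 20 µm-diameter disk (debris floor; the choice is ours —
anything much smaller than one cell cannot be a colony). The default threshold
is Otsu's method on the smoothed plane because it is reproducible and
scriptable; a fixed intensity value can be supplied instead, and it must lie
within the intensity range of the plane. Each connected component becomes one
colony mask carrying its threshold and source plane, so downstream records can
assert that every channel of a colony was measured over identical pixels.

Two conventions are deliberate:

* **One boundary per colony.** The footprint is segmented once, on the middle
  selected plane (the 50 %-depth plane), and reused for all analysed planes.
  Colonies at these depths are approximately prismatic; a per-plane
  re-segmentation mode exists behind `segment_per_plane` for cases where that
  assumption fails.
* **Border exclusion.** A mask touching the image border has a censored
  distance-to-background, which would corrupt the ring geometry; such colonies
  are dropped by default (`exclude_border`).

An advisory diameter window (default 80–100 µm, inclusive bounds, computed as
the equivalent-disk diameter `2·sqrt(area/π)·pixel_size`) selects colonies of
the intended size class; it can be disabled.

## Ring partition and relative intensities

Every colony pixel is assigned its Euclidean distance `d` (µm) to the nearest
background pixel via an exact distance transform. Euclidean distance is the
only rotation-invariant reading of "so many µm inwards from the periphery".
With ring widths `(w1, w2)` (default 15 µm each, roughly one cell):

* outer: `0 < d ≤ w1`
* middle: `w1 < d ≤ w1 + w2`
* inner: `d > w1 + w2`

Intervals are half-open toward the interior so each pixel gets exactly one
label; a colony thinner than `w1` is entirely outer (recorded, not an error).

Per plane and channel, the arithmetic mean of raw intensities is taken over
each section and over the whole mask, and each section mean is divided by the
whole-colony mean. This *relative* mean is the unit of all downstream
analysis: it is invariant to per-plane illumination or staining scale, and by
construction the area-weighted average of the three relative means is exactly
1 (asserted to 1e-9 in tests). Empty sections and zero total means yield NaN
plus a flag — never a silent zero.

Planes are selected at fractional depths of the stack (default 0.30 / 0.50 /
0.70): index `round(f · n_planes)`, rounding half away from zero, clamped to
`[1, n_planes]`, duplicates dropped. A 100-plane stack yields planes 30, 50
and 70; a single-plane image yields plane 1. Fractions address plane *index*,
not physical depth, matching the worked 100-plane example; pooling across the
selected planes is an unweighted mean of relative means (no weighting rule is
defensible without knowing per-plane reliability). Per-plane normalization
before pooling is the default; normalizing against a pooled total is possible
behind a flag but couples planes that plane modulation would otherwise cancel
out of.

## Statistical decision tree

All families share one gate: Shapiro–Wilk per group; if any group rejects at
alpha (default 0.05), the nonparametric branch is taken. Brown–Forsythe
(median-centred Levene) is computed and reported alongside. Groups too small
to test (n < 3) or with zero spread are flagged untestable.

| family | parametric branch | nonparametric branch |
|---|---|---|
| sections within a treatment | one-way ANOVA + Tukey HSD (all pairs) | Kruskal–Wallis + Dunn (all pairs) |
| treatments vs vehicle | one-way ANOVA + Dunnett (control = vehicle) | Kruskal–Wallis + Dunn (vehicle contrasts only) |
| blocked designs | randomized-block ANOVA + uncorrected Fisher's LSD on preselected pairs | — |
| paired expression | ratio paired t (one-sample t on log ratios) | Wilcoxon matched-pairs signed-rank |

Details and choices:

* **Dunn's test** is implemented directly (tie-corrected rank z-tests,
  two-sided normal p-values). By default no additional family-wise correction
  is applied to Dunn p-values, matching common practice in the GUI packages
  this decision tree mirrors; a Bonferroni option exists.
* **Dunnett** never reports treatment-vs-treatment pairs; **Tukey** reports
  all pairs; **LSD** tests only the pairs passed in (all pairs if omitted),
  uncorrected, using the ANOVA residual mean square and degrees of freedom.
* **Blocked ANOVA**: the biological replicate enters as an additive block
  factor. The one-way design fits `response ~ condition + block`; the two-way
  design fits two crossed factors with interaction plus the block, and its
  omnibus is the joint test of all cell-mean differences. A perfectly
  additive table makes the condition F a 0/0; that degenerate case is
  resolved to F = 0, p = 1 (no condition effect) rather than NaN.
* **Zero variance** anywhere short-circuits to a flagged no-test result;
  identical paired samples report p = 1 by convention.
* **Observational unit**: `aggregation_mode` chooses whether colonies
  (technical replicates, the default) or per-biological-replicate means enter
  the tests; both are first-class because summary figures in this field are
  frequently presented at both units.

Type-I error of every family under its null (normal data, n = 12 per group,
alpha = 0.05) is held within 0.05 ± 0.02 over 1000 simulations in the
acceptance suite.

## qPCR quantification

ΔCt subtracts the arithmetic mean of the reference-gene Cts (default UBC,
GAPDH, TBP) from each target Ct — on the quantity scale this is normalization
by the geometric mean of reference quantities, and the two routes agree to
1e-12 in tests. Technical replicates are averaged on the Ct scale first.
ΔΔCt pairs treated and vehicle samples by biological replicate; the fold
change is `E^-ΔΔCt` with amplification efficiency `E` fixed at 2 (an
efficiency parameter exists but no deviation from 2 is asserted anywhere).
Single-reference normalization is the degenerate case of the same formula.
Two identities are property-tested: adding a constant to every Ct of a sample
leaves ΔCt unchanged, and relabelling which group is "vehicle" inverts every
fold change exactly. An optional pre-filter drops targets whose mean Ct
exceeds a configurable cut-off (default 38 cycles) before normalization.

## Synthetic data generator

The generator is the oracle surface for everything above. It renders
disk-shaped colonies (default radius 45 µm in a 256×256 px field at
0.5 µm/px, i.e. a 90 µm colony inside the target size window) with a radial
profile parameterized by the *distance from the colony boundary* — the same
coordinate the ring partition uses, which is what makes the carried
ground-truth section means exact rather than approximate. Profiles: uniform;
exponential peripheral-high (`base·(1+(c−1)e^{−d/λ})`, periphery/centre
contrast `c`, decay length λ default 15 µm); the mirrored central-high; and a
linear ramp. The nuclear and reference channels are rendered as the colony
footprint at constant intensity — the analysis never uses nuclear positions,
though the rendering of a flat DAPI-like channel keeps the channel-role
plumbing honest.

Noise follows the standard fluorescence-camera model: Poisson on scaled
photon counts, then additive Gaussian read noise, clipped at zero (the clip
is negligible whenever the mean exceeds ~3 SD, which all tested conditions
satisfy inside the colony). Per-plane multiplicative modulation emulates
depth-dependent attenuation and cancels exactly in relative means. An
optional mean-one log-normal speckle term stands in for cell-to-cell texture;
no particular amplitude is asserted because real within-colony texture is
uncharacterized here. The "SNR 5" condition used in recovery tests means
Gaussian SD = base intensity / 5 (20 at base 100) with shot noise off.

What the generator does **not** emulate: optical point-spread blur and
deconvolution artifacts, irregular (non-elliptical) colony outlines, nuclear
substructure, and channel bleed-through. Passing tests therefore demonstrate
correctness of the measurement geometry and statistics under the stated image
model, not robustness to every property of real micrographs.

The Ct-table generator draws per-gene base Cts (uniform 20–30 cycles),
per-sample loading shifts (SD 0.3 cycles, cancelled exactly by reference
normalization), subtracts `log2(fold change)` for treated samples, and adds
independent Gaussian Ct noise per technical replicate, so the expected ΔΔCt
equals `−log2(fold change)` by construction.

## Problem sizes in the test and acceptance suites

Simulation scales were chosen to make the checks statistically meaningful at
desk scale: the direction-recovery check uses 12 colonies per group (within
the 9–15 technical-replicate range typical of such experiments) over 100
seeded end-to-end runs; type-I error uses 1000 replicates per family at
n = 12; ddCt recovery uses 6 replicate pairs over 20 seeds; the ring-label
oracle uses 100 random masks up to 64×64 px, where the all-pairs brute-force
scan is exact and affordable.

## Known limitations

* Segmentation assumes colonies are brighter than background on the reference
  channel and separable by a single global threshold per field; touching
  colonies are not split.
* The ring geometry is 2-D per plane; no volumetric distance transform.
* Thresholding the smoothed reference can shift the boundary by a sub-pixel
  ring relative to the true footprint; with default smoothing this perturbs
  relative means by well under 1 % for 90 µm colonies, and disappears as
  pixel size shrinks.
* The decision tree intentionally reproduces a pragmatic lab workflow; it is
  not a recommendation of, e.g., uncorrected LSD or uncorrected Dunn tests
  for confirmatory analysis.
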