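# Methods

This note documents the models, conventions and numerical choices
behind `phosphoprofiler`, and what the synthetic-data tests do and do
not demonstrate about real membranes.

## Membrane model and layouts

A membrane is a grid of antibody spots; every analyte is spotted in
duplicate, and each membrane carries three positive-reference duplicate
pairs (constant-intensity controls used for between-membrane
normalization) and one PBS-only negative-control duplicate pair. The
built-in RTK layout has 49 target analytes (pan-phospho-tyrosine
readout, so no per-analyte site annotation) and the MAPK layout 26
targets with site-specific detection, 9 of them MAP kinases proper.

The physical coordinate maps of the commercial membranes are
proprietary, so the built-in layouts place duplicate pairs on a regular
synthetic grid (pitch 40 px, spot radius 13 px, margin 40 px; version
string `builtin-grid-1.0`). Only analyte identity enters the downstream
mathematics — physical position matters solely for rendering and
quantifying synthetic images — so the grid is a repo convention, not a
claim about the kits. Coordinates are 0-based pixel centers with y
increasing downward. Custom layouts load from JSON/YAML and are
validated structurally (duplicate names, spot counts, reference/negative
cardinality, non-overlap); registration onto an image is an affine
scale + offset that fails, rather than clips, when a spot would leave
the frame.

## Densitometry

The spot statistic is the **integrated density**: the exact sum of the
values of pixels whose centers lie inside the spot disc. This
convention is deliberately simple enough to check against a brute-force
loop over every pixel, which the test suite does exactly (integer
images, 100 random image/disc pairs).

Background is a single global per-pixel level, by default the mean
pixel value over the negative-control spot discs (`negative_spots`),
alternatively the median over four corner windows (`corner_patches`).
Whether the original workflow used a global or spot-local background is
not specified by the upstream software conventions, so both options are
exposed. Per spot, `net = max(0, raw − background × n_pixels)`; the
unfloored value is kept as `signal_density` because the
negative-control activation scheme needs it (see below). Duplicates are
averaged arithmetically. Floored spots are flagged; a saturated-pixel
fraction above 5% raises a QC warning, not an error, since film
saturation is common.

Two important interactions, both verified by tests:

* adding a constant to every pixel is absorbed by the background
  estimate and leaves signals unchanged (flat backgrounds);
* with a background *gradient*, a global background misestimates
  spot-local levels; the simulator's default gradient is 0 and the
  round-trip fidelity checks use gradient 0 so the comparison is exact.

## Profile views

For one sample, the averaged net densities over **target analytes
only** (controls excluded, switchable) are reported on four scales:
absolute; percent of maximum (top analyte exactly 100 — computed as
`(v / max) * 100` so the maximum is floating-point-exact); percent of
total (sums to 100 within 1e-9); and reference-normalized, where the
denominator is the mean over the three positive-reference averaged nets
(mean chosen for robustness to one weak corner; no aggregation rule is
prescribed by the kits). All views are monotone transforms of the
absolute profile (Spearman ρ = 1, property-tested), and reference
normalization is exactly invariant to a global exposure factor. Top-k
ranking sorts by descending absolute density with ties broken by layout
order (stable mergesort).

## Activation calling

* **mean + SD scheme**: statistics are `log2(net + pseudocount)` over
  target analytes (pseudocount 1 density unit, configurable; controls
  excluded since the bright references would inflate both moments);
  threshold = mean + sample SD (ddof = 1). Worked reference: log2
  values (1, 1, 1, 1, 8) give mean 2.4, SD 3.1305, threshold 5.5305,
  activating only the 8.
* **3× negative control scheme**: threshold = 3 × the highest
  negative-control spot signal; an analyte is active when its averaged
  *unfloored* signal exceeds it. Two consequences drive defaults
  elsewhere: (a) the comparison uses pre-floor signals so the threshold
  stays meaningful when background subtraction would zero weak spots;
  (b) when the negative spots are the cut-off basis they cannot also
  serve as the background estimate — with both roles the negative
  signals are ~0 by construction and the threshold collapses to pixel
  noise. The specificity analyses therefore quantify with
  `corner_patches` background.
* **Ordinal grading** of %max into poorly / lower extent / moderately /
  strongly activated at cuts (10, 50, 80): 10 and 50 are anchored in
  reported concordance behaviour of these arrays (very weak IHC below
  ~10 %max, strong/medium above ~50 %max); 80 is a repo convention
  splitting moderate from strong. Values equal to a cut fall in the
  upper bin.

No multiple-testing correction is applied to per-analyte calls; the
schemes are per-membrane screens, not inference, and are documented as
such.

## IHC concordance

Array %max values are compared with ordinal immunoreactivity (IR)
scores (0..3 for –/+/++/+++) per analyte over paired samples: a 4×4
cross-table of grade bins vs IR (and vs the staining-distribution score
DIST, which is tabulated but not part of the headline statistic), the
exact-agreement fraction, and Kendall τ-b between the continuous %max
and IR. The permutation p-value is exhaustive over all n! orderings for
n ≤ 10 (comparing τ numerators, since the τ-b denominator is
permutation-invariant; processed in chunks), and a seeded 20,000-draw
Monte-Carlo beyond. Constant IR or constant %max makes τ undefined and
is reported as such. Sample mismatches raise, listing the offending ids.

## Serial comparison

Serial profiles of one patient (same array type, strictly increasing
timepoints) are compared on the reference-normalized view by default so
exposure differences between membranes cancel. Per-interval log2 fold
changes are defined only where both values are positive. An analyte is
flagged **diminished** when every interval decreases and the cumulative
log2 change is ≤ −1 (configurable) — the signature of an inhibitor
suppressing its target.

## Cohort preprocessing and clustering

Pipeline: `log2(v + 1)` → per-sample median centering ("normalization";
removes loading/exposure differences between samples) → per-analyte
z-score across samples, ddof = 1 ("scaling"; matches the −3..3 heatmap
display convention). Analytes with zero variance (relative tolerance
1e-12 against floating-point round-off) are dropped with a warning.
Clipping to [−3, 3] happens only at heatmap export, never before
clustering.

The significance filter is a per-analyte Welch t-test on the logged
values between exactly two diagnostic groups (≥2 samples each),
unadjusted p < 0.05 — deliberately liberal, matching common practice
with these arrays, and flagged as such. "Supervised" means the group
labels drive this filter; the clustering itself is unsupervised on the
filtered matrix. When fewer than two analytes pass, the pipeline
clusters the full matrix and still reports the p-values (or raises,
with `require_filtered=True`).

Both axes are clustered agglomeratively with **Ward linkage over
correlation distances** (1 − Pearson r, in [0, 2]; constant vectors are
rejected by name). The agglomeration is implemented natively:
Lance–Williams recursion on squared dissimilarities with merge heights
on the distance scale (the `ward.D2` convention — a singleton pair
merges at its input distance), and a documented, platform-deterministic
tie rule: among minimal-distance pairs, merge the lexicographically
smallest cluster-id pair. Tests verify (a) exact merge-sequence and
height agreement with an exhaustive oracle that recomputes every
inter-cluster Ward distance from the original matrix via the centroid
closed form, and (b) height agreement with scipy's independent Ward
implementation. Merge-height monotonicity is asserted on every run.
Cutting into k clusters removes the k−1 tallest merges (equivalently,
keeps the first n−k merges); cluster ids are ordered by each cluster's
smallest member label, so assignments are stable under row reordering.
Dendrograms export to Newick (branch length = parent height − child
height) and nested JSON.

## Synthetic data: what it emulates, and what it does not

Defaults emulate a small two-group pediatric-tumour comparison: n = 12
samples in groups of 5 ("NB") and 7 ("CNS"), with 6 group-specific
analytes per group shifted by 3 log2 units — after p < 0.05 filtering
this typically leaves ~12 differential RTKs, the scale of cohort the
method is used on in practice. Latent levels are lognormal
(`log2 level ~ N(8, 1)` in arbitrary density units): phosphorylation
signals are multiplicative and strictly positive, and no distributional
form is prescribed upstream, so lognormal is the standard modelling
choice. Measured cohort values multiply the truth by
`2**N(0, 0.25)`; duplicate spots jitter with a unit-mean lognormal
factor at CV 0.05 (densitometry noise scales with signal).

Rendering: each spot deposits `level × gain × n_pixels` spread over its
disc (uniform by default; truncated-Gaussian with equal integral
optional), on a background plane (level 500, optional linear tilt),
plus additive pixel noise (SD 5), quantized to 8/16-bit with clipping
and a saturation flag (error if clipping is disabled). Positive
references render at 4096 and the PBS negatives at a small nonspecific
residual of 30 — real film negatives are never perfectly blank, and a
perfectly blank negative would make any negative-control-based cut-off
degenerate. The zero-noise fidelity checks use gain 8 and blank
negatives so that 16-bit quantization (±0.5 counts/pixel) is negligible
relative to signal; at gain 1 the integer rounding alone can reach ~1%
relative error for the dimmest analytes.

Not modelled: film response curves and chemiluminescence kinetics,
optical point-spread functions, spot-shape irregularities, dust and
local artifacts, or spatially structured (non-planar) background.
Passing the round-trip and recovery tests therefore demonstrates that
the *pipeline's* arithmetic is faithful and that planted effects of the
stated size are recoverable under well-behaved noise — not that the
method is robust to every artifact of real film.

IHC scores are simulated by binning true levels at three cut points
with optional ±1-level misclassification, giving a monotone truth-score
link whose strength decreases with the misclassification probability.

## Problem sizes and determinism

All generators are deterministic under their seed (verified
bit-identically). The test suite and `scripts/acceptance.py` use: 100
random image/disc pairs for the densitometry oracle; 1,000 random
profiles for the normalization algebra; 100 seeded membranes for
cut-off specificity; 100 seeded cohorts each for effect and null
clustering conditions; 100 random ≤6-row matrices for the agglomeration
oracle. These sizes give stable Monte-Carlo estimates (binomial SE
arguments in the tests) while the whole suite runs in seconds.

## Known limitations

* The supervised filter introduces selection circularity: at null
  effect, chance-significant analytes separate the groups by
  construction, so clustering *after* filtering shows inflated
  label agreement (mean ARI ≈ 0.25 here). Generator-null checks
  therefore cluster unfiltered; on real data, the filtered heatmap's
  visual group separation should not be read as evidence by itself.
* Unadjusted p-values in the filter; with 49 analytes, ~2–3 pass at
  α = 0.05 under the null.
* Global (not spot-local) background; gradients bias dim spots.
* The mean + SD scheme is distribution-sensitive: a membrane with many
  strong analytes raises its own threshold (translation invariance in
  log space holds, but scale effects do not cancel).
* Cross-array harmonization (RTK vs MAPK membranes on one scale) is out
  of scope; profiles are compared only within an array type.
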