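# Methods

## Problem

In a grafted vineyard, the root system (rootstock), irrigation history,
sampling year, vineyard position (block) and leaf developmental stage all
leave small imprints on the shoot phenotype. `vineleaf` quantifies two such
phenotypes — leaf outline shape and leaf elemental composition — and
attributes their variance to these design factors. The experiment structure
it targets is a 288-vine factorial: four root treatments (ungrafted, 1103P,
3309C, SO4) x three irrigation regimes (none, partial, full) assigned by
vineyard row, nine rows in three blocks, eight vine replicates, two sampling
years, four mid-shoot leaves per vine for shape and three developmental leaf
positions (old/mid/young) per vine for ionomics.

## Contour preparation

Leaf masks are contoured by marching squares at iso-level 0.5 on the
zero-padded binary grid. The longest closed contour is kept (holes and
smaller components are discarded with a warning). A light periodic Gaussian
smoothing along arc length (sigma 0.5 px, configurable) removes the pixel
staircase: without it, the staircase inflates perimeters by ~5% and biases
circularity; at 0.5 px the perimeter of a 50 px-radius disk is recovered
within 2% while a 3x3-pixel object still keeps ~87% of its area. Contours
are then resampled to `n_points` (default 1000) vertices equally spaced by
arc length, centered on the point centroid and scaled so the maximum
centroid-to-vertex radius is 1. Everything downstream sees only this
normalized cloud, so results are invariant to scanner placement, rotation
and resolution.

## Shape descriptors

Computed on the polygon (not pixel counts): area by the shoelace formula,
perimeter as summed segment lengths, ellipse axes from the polygon's exact
second central moments (Green's theorem), convex hull via Qhull. Circularity
uses the ImageJ definition 4*pi*A/P^2, clipped at 1 (a `include_pi=False`
switch yields the plain 4*A/P^2 ratio for comparison with sources that print
the formula without pi). Roundness is 4*A/(pi*major^2), which equals
1/aspect-ratio exactly on ellipses — this identity is enforced as a property
test rather than used as the formula. Descriptors are averaged per
(vine, year) before modeling.

## Topological featurization

Per normalized contour:

1. **Density.** For every vertex, the unnormalized Gaussian-kernel average
   density (1/n) * sum_q exp(-|p-q|^2 / (2 h^2)), default bandwidth
   h = 0.05 in normalized-radius units. The 1/(2 pi h^2) constant is omitted
   deliberately: curves are swept on a per-leaf max-normalized scale, so
   constant factors cancel.
2. **Annuli.** 16 concentric rings with centers (i - 1/2)/16 and Gaussian
   radial width sigma = half the ring spacing — a smooth bump rather than a
   hard indicator, so counts do not jump discontinuously when a vertex
   crosses a ring border. Per ring, the filtration value is the radial
   weight times the density. Vertices whose filtered value falls below
   1e-8 x the leaf's peak density are outside the ring's support; the floor
   is relative to the leaf (not the ring) so rings far from any contour mass
   have genuinely empty support.
3. **ECC sweep.** 100 threshold levels equally spaced from 1 down to 0 on
   the ring's max-normalized filtration scale. At each level the number of
   connected components of the super-level set is recorded: vertices with
   value >= level, joined when within a connectivity radius
   eps = 2.5 x the contour's median nearest-neighbor spacing (adjacent
   contour points always connect; distant lobes do not). Implemented
   incrementally — vertices inserted in descending value order into a
   union-find structure, edges activated when both endpoints are present —
   so one O(n alpha) pass yields the whole curve. Only component counts
   (0-dimensional homology of the point graph) are tracked; no cycles.
4. **Vector.** The 16 curves concatenate to a 1600-entry integer vector per
   leaf; vectors are averaged per (vine, year) and decomposed by full-SVD
   PCA (first 20 components kept by default, signs canonicalized so each
   component's largest-magnitude loading is positive).

The incremental sweep is verified exactly against a per-threshold
from-scratch recount (scipy's connected components on the rebuilt graph) on
random clouds, and the full featurization is exactly integer-identical under
rigid motions and uniform scaling of the input.

Tunables (`TDAConfig`): `n_rings` (16), `n_thresholds` (100), `bandwidth`
(0.05), `connectivity_eps_factor` (2.5), `n_points` (1000),
`n_components` (20). The bandwidth, threshold count and connectivity rule
are genuinely open choices — the upstream literature delegates them to
companion software — so they are explicit configuration, and the per-ring
max-normalization (rather than a global per-leaf scale) is likewise a
flagged dialect option of this implementation.

## Variance partitioning

Ordinary least squares with ordered categorical terms, treatment-coded
against the alphabetically first level. Sums of squares are sequential
(Type I): each term's SS is the drop in residual SS when its columns enter
after all preceding terms, the decomposition R's `anova(lm(...))` reports.
Order matters on unbalanced data, so the order is part of the model
definition and is recorded in every output: descriptors and PCs use (block,
year, rootstock, irrigation, rootstock:irrigation); elements use (block,
irrigation, leaf position, irrigation:leaf, rootstock, rootstock:irrigation,
rootstock:leaf, year). Percent variance explained is 100 * SS_term /
SS_total with SS_total the total SS about the mean, so shares of all terms
plus the residual sum to 100. F statistics use the full-model residual mean
square; p-values are raw (no multiple-testing correction — reports filter at
p < 0.05 and say so). Rank-deficient terms keep df = 0 with undefined F.
The implementation is nested least squares via numpy; it is cross-checked in
the tests against both an explicit nested-projection oracle and statsmodels'
Type I `anova_lm`.

## Ionomics QC

Within each (element, year) stratum, values outside
[Q1 - 5*IQR, Q3 + 5*IQR] are removed, with quantiles by linear interpolation
(R type 7, the default of the toolchain this mirrors; the convention is
configurable since it is not uniquely determined). The fence width k = 5 is
deliberately wide: it keeps log-scale biological spread (~0.3 log units
here) and removes only instrument-scale artifacts. Filtering is idempotent
and invariant to unit rescaling. Concentrations are modeled on the raw
scale by default (a log option exists but is off).

## Synthetic vineyard

The generator is a stand-in shape family, not a botanical model; its role is
to give every pipeline stage inputs with known ground truth. Leaves are
polar curves r(theta) = R * (1 - d*|cos(L*theta/2)|^p + s*cos(m*theta)) with
L = 5 lobes, shape exponent p = 2, serration frequency m = 40, y-stretch e
(elongation), and radial Gaussian noise (sd 0.01 R). Baselines: d = 0.30,
s = 0.10, e = 1.0. Injected effects act on generator parameters so the whole
image -> feature -> ANOVA chain is exercised: year shifts elongation
(+0.08 in 2016), the rootstock x irrigation cell shifts lobe depth through a
fixed binary pattern scaled by 0.10 (the pattern has a nonzero pure
interaction component, so the sequential interaction term carries signal
after the main effects), block drifts base radius (+0.05/+0.10). Vine- and
leaf-level noise on lobe depth are each sd 0.02, leaf serration noise
sd 0.01.

Ion concentrations are log-normal around realistic leaf-tissue baselines for
17 elements, residual sd 0.3 log units, with leaf-position gradients
(Ca/Mn/Al up with leaf age, K/Rb down; +/-0.35–0.5 log units), rootstock
shifts (Ni highest on SO4 at +0.45, a graded Mo series), and
rootstock-by-irrigation patterns on Mo/P/Sr/Rb (amplitude 0.3–0.4). One
percent of rows are multiplied by 1000 to plant detectable outliers for the
QC stage. All randomness derives from a single seed through fixed per-stage
child streams; outputs are byte-identical across runs.

What the generator does *not* emulate: petioles, vein structure, asymmetric
lobing, leaf damage, spatial autocorrelation beyond the categorical block,
element–element covariance, and instrument drift. Passing tests therefore
demonstrate that the pipeline recovers known effects injected through this
shape family — not that it would measure any particular field dataset with
the same percentages. A real study at ~2,300 scanned leaves, with biological
rather than generated variation, will give smaller and differently
apportioned variance shares than the synthetic runs do; the block radius
drift in particular is invisible to the morphometric chain because the
features are size-normalized by construction.

## Problem sizes in tests and the acceptance script

The packaged simulations keep the study's structure (288 vines, full
factorial) but reduce per-leaf resolution where the full default would be
wasteful for the property being checked: contour resolution 120–300 points
and 20–50 thresholds for end-to-end runs, 200 points / 50 thresholds and
one year x two leaves per vine for the interaction-power replicates, 10–20
seeds for power/calibration rates, 50–100 seeds for recovery means. These
sizes were chosen once as sufficient for the assertions made (exact oracles
do not depend on resolution; rate estimates carry binomial bands sized to
their seed counts).

## Numerical notes and edge cases

- Degenerate inputs raise typed errors: empty masks, all-coincident points,
  collinear contours (ellipse fit), constant responses, constant feature
  matrices, saturated models (zero residual df).
- Ties in filtration values are handled by the threshold grid: a level
  includes every vertex with value >= level, so tied vertices enter
  together regardless of sort order.
- A ring with empty support contributes an all-zero curve (not an error).
- Self-intersecting polygons get a warning; area remains |shoelace|.
- PCA component signs are canonicalized for reproducible score files;
  explained-variance shares are of total variance, so the kept-20 shares sum
  to less than 100 on full-rank data.
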