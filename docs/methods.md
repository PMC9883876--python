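# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
validation scenes do and do not establish about real data.

## Data model and distance conventions

All statistics operate on a `CategoricalPointPattern`: N labelled points
with planar coordinates plus a study region of known area A.  Coordinates
are assumed projected (metre-like); geographic input is projected on read by
a local equirectangular projection about the data centroid
(x = R·cos φ₀·Δλ, y = R·Δφ, R = 6 371 008.8 m).  Over a city-scale extent
(≲ 100 km) the scale distortion of this projection is far below 1%, which is
negligible against the Monte-Carlo noise of the tests; users with a
preferred projected CRS can simply supply planar coordinates.

Distances are Euclidean throughout.  Network (road) distance is a known
limitation: travel behaviour follows transport cost, not straight lines, so
all colocation findings describe geometric, not functional, proximity.

**Ties.**  Exact distance ties are never broken.  A k-nearest-neighbour
query returns every point tied at the k-th distance, and each tied
neighbour carries equal weight 1/nnᵢ in the global quotient.  Ties are
detected with a relative tolerance of 1e−9 (absolute 1e−12 to cover exact
zero), which is ~10⁶ machine epsilons — wide enough to catch ties produced
by symmetric constructions, and effectively measure-zero for continuous
random coordinates.  Coincident points (distance 0 between distinct ids)
are legal: co-addressed facilities occur in real POI data, and such a point
is always the other's first neighbour.

## Clark–Evans index

NNI = mean nearest-neighbour distance / (0.5√(A/n)), computed within the
selected category (the study area is always the full pattern's A).  The
Z-test uses the classical Clark–Evans standard error 0.26136/√(n²/A); the
index equation alone does not determine a test, and this SE is its
universally used companion — it reproduces the conventional decision rule
"clustered at the 1% level when Z < −2.58" (Φ⁻¹(0.005) ≈ −2.576).
P-values are reported two-sided at full precision; the one-sided clustered
classification is exposed separately as `NNIResult.clustered`.

**No edge correction** is applied, matching the plain form of the index.
Boundary points have artificially distant neighbours (their search disc is
truncated by nothing, but the CSR expectation assumes an unbounded
process), which biases NNI slightly *upward*: for n = 1000 in the unit
square the Donnelly-style perimeter term predicts a mean of ≈ 1.013 rather
than 1, and the measured calibration value matches this.  The ±0.03
calibration band around 1 absorbs the bias at that problem size; at much
smaller n (≲ 100) the bias is proportionally larger and users should
interpret NNI near 1 cautiously.

## Global colocation quotient

GCLQ_{A→B} = (N_{A→B}/N_A) / (N_B′/(N−1)) with the tie-weighted count
N_{A→B} defined over each A point's k nearest neighbours.  The (N−1)
denominator reflects that a point cannot be its own neighbour.  For the
same-category quotient A→A the reference count is N_A − 1 for the same
reason; this keeps the expectation at 1 under random labelling for the
diagonal too.  The quotient is bounded below by 0 (no B neighbours at all)
and above by (N−1)/N_B′ (every neighbour is B).

**Significance** is a random-labelling permutation test: locations — and
hence every neighbour set and weight — stay fixed; the label vector is
permuted, preserving all category counts.  This conditions on the point
locations and tests purely the association between labels, which is the
colocation question (a CSR re-simulation would confound label association
with each category's own clustering).  P-values use the (r+1)/(M+1) rank
rule; the two-sided default doubles the smaller tail and caps at 1.
Permuted-value comparisons use a 1e−12 slack so ties between observed and
permuted values count towards the tail (conservative).  The default is
1000 permutations (p-value floor 1/1001 ≈ 0.001); the test machinery
requires at least 99.

**Bandwidth sweep.**  The quotient is computed for k = 1..k_max with the
first-order neighbour as the starting point.  As the selection rule is
genuinely open — practitioners typically "compare the results" — the
package uses a documented, overridable default: the smallest k whose
permutation p ≤ 0.05.  The full sweep is always returned so any other rule
can be applied.  In the pairwise matrix, a pair with no significant k is
reported at k = 1 and flagged unselected.

**Stars.**  One shared formatter: *** p ≤ 0.01, ** p ≤ 0.05, * p ≤ 0.10.
The 10% tier exists because published colocation tables use a bare *
without defining its level; mapping it to 0.10 is the conventional reading
and is clearly separated from the 5%/1% tiers used for decisions.

## Local colocation quotient

LCLQ_{Aᵢ→B} divides the Gaussian-kernel-weighted share of B among the
focal's neighbours by N_B′/(N−1).  Two typesetting/reading ambiguities in
the literature are resolved as follows, both forced by the requirement that
the statistic have expectation 1 under random labelling:

* the denominator is N_B/(N−1), not N_B·(N−1) — the latter is
  dimensionally inconsistent with an expectation of 1;
* f_ij means "point j is of type B", not "j is the single nearest
  neighbour" — the weighted sum runs over the whole neighbour set.

**Neighbour universe.**  By default the sum is truncated to the k nearest
neighbours (ties included), with the adaptive bandwidth d_ib equal to the
k-th neighbour distance.  With a Gaussian kernel the omitted far points
carry weight < exp(−½) of the boundary neighbour, so truncated and
full-sum versions differ little; both are available
(`BandwidthSpec(truncated=False)`) for sensitivity checks, as is a flat
kernel.  A degenerate bandwidth (all k nearest neighbours coincident with
the focal) raises an error directing the caller to increase k.

**Per-point Monte-Carlo.**  Each iteration draws one global permutation of
the label vector (counts preserved, locations fixed) and re-evaluates every
focal point against it; each focal's p-value ranks its observed value in
its own permuted distribution by (r+1)/(M+1).  Sharing permutations across
focal points is the standard implementation (per-focal independent streams
would change nothing in distribution, only cost).  The focal's own label
never enters its value since j ≠ i.  P-values are one-sided high by
default because the mapped quantity is colocation (LCLQ > 1); the map
filter keeps p < 0.05 and value > 1.

The per-point test is intrinsically low-powered at small k: with k
neighbours the share takes ~k+1 values and only near-pure-B neighbourhoods
can reach p < 0.05 when B is common.  This is a property of the statistic,
not the implementation — global association should be read from the GCLQ,
local maps from the LCLQ.

## Kernel density surfaces

Density-of-points convention: density(x) = Σᵢ K_h(x−xᵢ) with an isotropic
Gaussian kernel, so the surface integrates to the category count where the
grid covers the kernel mass.  Published density maps rarely state kernel,
bandwidth or cell size, so the surfaces are qualitative; the defaults are
reproducible ones — Silverman's rule h = σ̄·n^(−1/6) (σ̄ the RMS marginal
sd) and cell size = extent/256 — and both are overridable.  When the
pattern carries an explicit region the grid covers exactly its bounding
box (mass near the boundary is lost by construction, as in any
fixed-window density map); without a region the grid auto-pads by 5h so
mass is conserved to well under 1%.

## Synthetic scenes and what they show

Generators: CSR (uniform), Thomas clusters (uniform parents, Gaussian
offspring of sd σ, offspring resampled — not clipped — into the region to
preserve isotropy away from edges), planted attraction (points displaced
from a base category), planted inhibition (uniform with a hard exclusion
radius around a base category, by capped rejection sampling).  All
generators condition on exact counts so fixtures can match published
category totals exactly (e.g. the six-category medical inventory of
2383/1548/391/737/297/45 = 5401 points used as the scale reference).  One
master seed per scene is split into per-category substreams
(`numpy.random.SeedSequence.spawn`), so scenes are bit-reproducible and
adding a category never perturbs earlier ones.

The six-category default scene (`medical_scene_config`) mirrors the broad
features of an urban medical-resource inventory: all categories clustered,
clustering strength decreasing from pharmacies to top-tier hospitals
(σ from 0.020 to 0.045 on a unit square with correspondingly fewer
parents), and the small top-tier category planted attracted to general
hospitals.  The σ and parent counts are scene-design choices on the unit
square, not estimates of any real city's parameters.

What passing on these scenes shows: the statistics recover planted
attraction/inhibition directions with calibrated type-I error, and their
null expectations are correct.  What it does not show: behaviour under the
features of real POI data that the generators omit — inhomogeneous
background intensity driven by population or road networks, category
counts correlated through shared covariates rather than direct attraction,
and positional noise from geocoding.  Apparent colocation in real data can
always be confounded by shared drivers; the quotients measure association,
not mechanism.

## Problem sizes and numerical choices

Validation studies run at deliberately modest sizes chosen to make the
Monte-Carlo error small relative to each tolerance: 200 scenes × 1000
points for the CSR/NNI calibration (±0.03 band), 100 label draws × 250
focals for the LCLQ null (±0.05), 100 seeds × 199 permutations for the
power/size studies (≥ 90% power, size within [0.02, 0.09]).  Oracle
equivalence against exhaustive brute force is asserted for scenes up to
N = 200 at 1e−10 relative tolerance.

Degenerate inputs: patterns require N ≥ 1 and area > 0; NNI requires n ≥ 2
in the selected category; quotients require both categories present (and
≥ 2 points for a same-category quotient); the pairwise matrix skips
categories with fewer than 2 points with a warning.  Containment of points
in the region is warn-by-default and strict-by-flag, since crawled POI data
are noisy.
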