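# Methods

This note records the models behind `nichecmp`, the defaults and the
reasoning for them, what the synthetic generator does and does not emulate,
and the numerical conventions that make runs reproducible.

## The comparative design

The package implements the standard two-pronged test of climatic niche
conservatism for species occupying disjoint ranges:

1. **Environmental-space comparison.** Niches are compared not in geography
   but in a low-dimensional environmental space, with occurrence densities
   corrected for how common each environment is in each species' accessible
   background. This separates "the species sit in different climates" from
   "the species' regions offer different climates".
2. **Reciprocal model projection.** A distribution model calibrated on one
   species is projected across the other's region. Conserved niches
   cross-predict; diverged niches do not.

Both prongs run end-to-end on synthetic landscapes, which is how the test
suite exercises them.

## PCA-env and occupancy surfaces

The PCA is computed on the correlation matrix of the calibration background
(every layer standardized by its background mean and ddof-1 standard
deviation). Two distinct calibrations are used, matching their two uses:
for distribution-model layers the background is the whole study grid; for a
pairwise niche comparison it is the union of the two species' backgrounds,
so both species are scored in one common space. Components are selected as
the smallest k whose cumulative variance fraction reaches a target (default
0.97). Component signs are fixed by making each component's
largest-magnitude loading positive, so repeated fits are bit-identical.

Occurrence-cell and background-cell scores on axes 1–2 are smoothed onto an
R×R grid (default R = 100) with a Gaussian product kernel. The bandwidth per
axis follows Silverman's rule for two dimensions, h = σ·n^(−1/6), unless
overridden; if all points coincide on an axis the rule degenerates to zero
and the code raises with guidance to set a floor bandwidth rather than
guessing one. Axis bounds are the min/max of background scores expanded 5 %
per side (shared between the two species of a comparison). Occupancy is
z = o/e on the availability support — cells where e ≥ 10⁻⁶ × max(e) — and
exactly zero elsewhere, renormalized to sum to one. R, the bandwidth, the
bound expansion and the availability floor are all configuration-exposed;
none of them is identifiable from published analyses, so they are declared
defaults, not recovered values.

The product kernel is separable, so each surface is assembled as an outer
product of per-axis kernel matrices (O(n·R) exponentials rather than
O(n·R²)). This is what keeps 100-simulation calibration experiments with 99
permutations each in the tens of seconds.

## Overlap tests

Schoener's D = 1 − ½ Σ|z₁ − z₂| on cell-aligned surfaces. Inputs must each
sum to 1 within 10⁻⁶; misalignment and unnormalized surfaces are errors, not
warnings.

**Equivalency.** Each rep pools the two occurrence sets and re-assigns
records to two pseudo-sets of the original sizes; each pseudo-set is
rebuilt against its own species' background (re-assignment changes the
occurrences, not the availability). One refinement matters: observed
occurrence sets hold *unique* cells, so the re-assignment preserves that
structure — a cell recorded for both species contributes one copy to each
pseudo-set and only singleton records are shuffled. Without the constraint,
a shared cell can land twice in one pseudo-set, doubling its kernel mass, a
configuration the observed data can never produce; the test then becomes
strongly conservative under a shared niche (measured: 0 rejections in 100
null simulations at α = 0.05). With the constraint the measured type-I rate
is 0.05.

**Similarity.** Each rep translates the randomized species' observed
occupancy surface so that its centroid lands on a uniformly drawn cell of
that species' availability support, zeroes mass falling off-grid or off
support, renormalizes, and records D against the fixed species' surface.
Both directions (1→2, 2→1) are produced by exchanging roles. Translation of
the whole surface (rather than re-sampling points) keeps the niche's shape
and asks only whether its *position* in available environmental space is
special.

p-values use the add-one convention p = (count + 1)/(reps + 1) under a
stated one-tailed alternative; both tails are always computable from the
stored null distributions. With the default 100 reps the attainable p-values
are 1/101, 2/101, … — hence the recurring 0.0594 for "5 of 100 nulls beyond
the observed". A p-value of exactly zero is impossible by construction.

## Presence-only models and evaluation

**Envelope score** (quantitative BIOCLIM): per-layer interval at the
symmetric training percentile (default 0 = min–max); suitability is the
fraction of layers inside their interval, so values lie on the ladder
{0, 1/k, …, 1} and training presences score 1 under min–max bounds. Note the
intrinsic ceiling: a fresh presence falls outside the training min–max on
any one layer with probability ≈ 2/(n+1), so envelope sensitivity at the top
threshold is ≈ (1 − 2/(n+1))^k even for a perfectly sampled niche.

**Mahalanobis distance**: training centroid and ddof-1 sample covariance;
suitability is the χ²(k) survival function of the squared distance — 1 at
the centroid, strictly decreasing along any ray, invariant under affine
transformations applied consistently to training and prediction data. When
there are no more presences than layers, a ridge of 10⁻⁶ × mean diagonal is
added and the model flagged as regularized; a constant training layer is a
degenerate input and raises.

**Evaluation.** Ten random 70 %/30 % train/test splits (train size =
round(0.7·n)); per split, pseudo-absences are drawn 1:1 with test presences,
uniformly from the background excluding all presence cells — 1:1 keeps
sensitivity and specificity on equal footing inside TSS. The threshold
scans the union of observed scores and picks the one minimizing
|sensitivity − specificity| (equalizing omission and commission error
rates), ties broken by larger sensitivity + specificity, then by the
smallest threshold; a cell is predicted present iff score ≥ threshold. The
Youden-style alternative (maximize sensitivity + specificity first) is one
line of configuration away but not the default. Consensus averages the
binary replicates with TSS strictly above 0.4; an empty consensus is an
explicit error, never a silent all-zero map. Cross-region prediction is the
fraction of the other species' occurrence cells where the consensus
fraction is at least 0.5.

The acceptance cutoff 0.4 sits below the conventional "acceptable" band of
0.5; both numbers circulate in the evaluation literature and the shipped
default deliberately follows the permissive one, with the cutoff exposed in
configuration.

## Survey gaps

Consensus maps are downscaled by nearest-neighbour block replication
(factor f replicates each coarse cell into an f×f block) onto the remnant
raster. Remnant patches are connected components (default 8-connectivity —
a diagonal gap of one ~4 km cell should not split a forest remnant; 4 is
available). Priority cells satisfy: consensus ≥ 0.5, patch area ≥ 16 km²,
and no known occurrence in the fine cell (exclusion is toggleable; excluded
by default because the goal is *new* records). The minimum-area criterion
operates per patch; setting `min_patch_km2` at or below one cell's area
reproduces the per-cell reading of the criterion.

## The synthetic generator

What it emulates: several spatially smooth environmental layers with
controllable pairwise correlation (the strong collinearity that motivates
the PCA step), built as a latitudinal trend plus Gaussian-filtered noise,
whitened and remixed so the realized correlation matches the target almost
exactly; two disjoint east/west biomes; species with multivariate-Gaussian
(unimodal) niches in raw environmental units; occurrence sampling without
replacement with probability proportional to suitability, records snapped
to cell centers and unique per cell; an optional sampling-bias weight
raster (off by default); and a patchy fine remnant mask thresholded from a
smoothed field at the quantile matching the requested coverage.

Three scenario classes fix the comparative design: `divergent_allopatric`
(disjoint ranges, centroids 3.0 Mahalanobis units apart under the shared
niche covariance, placed symmetrically about the background mean along the
background's leading environmental axis so both stay inside available
environments), `conserved_allopatric` (disjoint ranges, identical niche),
and `sympatric_shared` (one range and one niche, mask duplicated).

Scenario defaults and why: 48×48 cells, 5 layers, inter-layer correlation
0.6, 50 occurrences per species (the ≥ 20-unique-records floor is
enforced). Noise correlation length (smoothness 0.15, i.e. filter σ ≈ 1.8
cells) is kept well below the biome width so the two biomes offer
statistically comparable environments — the premise under which a conserved
niche is reciprocally predictable at all; with long-wavelength noise the
biomes' availabilities drift apart and even an identical niche stops
cross-predicting, which would conflate landscape artefacts with niche
divergence. Niche breadth 0.35 × background sd per layer makes the species
a habitat specialist occupying a modest slice of environmental space.

What it does **not** emulate: coordinate error and georeferencing noise,
taxonomic misidentification, spatially autocorrelated survey effort
(beyond the optional bias raster), niche multimodality, dispersal
limitation within a biome, and temporal climate change. Passing tests
therefore demonstrate the statistical machinery under clean assumptions,
not robustness to messy real occurrence data.

## Reproducibility and numerics

Every stochastic routine takes a seed; nested stages derive child seeds via
`numpy` seed sequences, and the full pipeline writes a manifest with a
parameter hash (output paths excluded) and sha256 digests of every output —
re-running a config reproduces the digests bit-for-bit. No timestamps enter
outputs. Degenerate inputs (zero-variance layers, singular covariances,
coincident kernel points, empty consensus, too-small supports) raise typed
errors early rather than propagating NaNs.

Problem sizes in the shipped tests were chosen to make the statistical
checks sharp yet quick: calibration uses 100 simulations × 99 permutations
at n = 50 on 48×48 grids; pattern-recovery and reciprocal-projection
contrasts use 50 matched-seed pairs; the separable-species skill check uses
a 96×96 landscape with 80 records and a 0.08-sd niche (sharp separation
needs a landscape large enough that weighted sampling without replacement
does not spill into marginal cells). The full suite runs in well under a
minute.

## Known limitations

- Only two of the four classic algorithms are built in; maximum-entropy and
  rule-set learners attach via the plug-in protocol but are not
  re-implemented.
- Geographic handling is lattice-based in degrees: no projections, no
  resampling; all layers must share one grid. Patch areas use a fixed
  km²-per-cell factor rather than latitude-dependent cell areas.
- The similarity test translates surfaces on the environmental-space grid;
  mass clipped at the grid edge is renormalized, which slightly favours
  central placements on very tight supports.
- Equivalency and similarity nulls are Monte-Carlo; with 100 reps the
  smallest attainable p is ≈ 0.0099, so "highly significant" cannot be
  resolved below that granularity.
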