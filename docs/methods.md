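# Methods

This note documents the models, estimators and numerical choices behind
`specmode`, and what the synthetic-data generator does and does not
emulate.

## Projection and range estimation

Localities (decimal-degree lon/lat) are projected onto a single
equirectangular plane anchored at the data centroid:
x = R·cos(lat₀)·(lon−lon₀)·π/180, y = R·(lat−lat₀)·π/180 with R = 6371 km.
For study extents of a few hundred km the metric distortion is well below
the 5–10 km georeferencing error typical of map-derived localities, which
is why a planar frame (rather than geodesic-exact areas) is appropriate;
`reference_latitude` can be fixed explicitly when several datasets must
share a frame. The optional per-locality precision radius is carried
through but never used to inflate hulls — imprecise points enter as-is,
matching how map-digitized localities are normally handled.

Each species' range is the convex hull of its projected localities,
computed by Andrew's monotone chain with the exact-on-doubles orientation
predicate; collinear boundary points are dropped, vertices are CCW, and the
area comes from the shoelace formula. Fewer than 3 non-collinear points
give a *degenerate* range (area 0) rather than an error or an arbitrary
buffer.

Overlap between two non-degenerate ranges is intersection area (via
shapely's exact convex clipping) divided by the smaller area. Degenerate
cases use locality membership: a degenerate range against a polygon scores
the fraction of its localities inside-or-on the polygon; two degenerate
ranges score 1 only if some locality pair coincides within 10⁻⁶ km. The
result is clamped to [0,1] and the argument order is canonicalized so
O(a,b) and O(b,a) are bit-identical.

## Nested overlap on the dated tree

Node ages are taken from root-to-tip path lengths assuming an ultrametric
tree; non-ultrametric input is accepted with a warning, using max tip depth
minus node depth. Polytomies are resolved arbitrarily into a caterpillar of
zero-length edges (logged), since the nested-average recursion is defined
for binary nodes. When a tree carries multiple accessions per species it is
trimmed to one tip per species (first alphabetically if no metadata says
otherwise); because conspecific accessions are expected to be monophyletic,
the choice does not affect between-species structure.

The nested overlap at a node with daughters L, R is O(L,R) with
O(X,Y) = (O(X₁,Y)+O(X₂,Y))/2 when X = (X₁,X₂), and M[x,y] for tip pairs.
This equals Σ wₓw_y M[x,y] over cross-clade tip pairs with weights halving
at each internal node passed — both forms are implemented (recursion with
memoisation in the package, weight enumeration as the independent oracle in
the tests) and agree to 10⁻¹² on thousands of random trees. The per-node
table is reported with a *descriptive* OLS of overlap on age; no
Monte-Carlo null is attached to the regression, because with one tree and
nested values the regression is exploratory, not inferential — inference
happens at the clade-contrast stage.

## Morphometrics

Measurements are analysed on the raw mm scale; the Mahalanobis metric
itself supplies the standardization (whitening by the pooled within-species
covariance), so a prior log transform is unnecessary for the distances and
is deliberately not applied. Species with a single specimen contribute a
mean but no covariance; the pooled estimator Σ(nᵢ−1)Sᵢ/(N−k) runs over
species with nᵢ ≥ 2. Distances are computed by Cholesky whitening
(no explicit inverse) and reported as D², with D as a secondary output
column; D² is the scale on which values of order 100–900 indicate strong
differentiation for 4 traits and ~20 specimens per species. A pooled
condition number above 10¹² raises an explicit singularity error advising
trait removal or regularization — never a silent pseudo-inverse.

The DFA solves the symmetric-definite generalized eigenproblem
B v = λ W v (scipy `eigh`), with B the nᵢ-weighted between-group scatter of
species means, giving axes with unit pooled within-group score variance;
squared centroid distances over the full canonical basis equal D² (tested
to 10⁻⁸ relative). Both specimen-level (default) and species-mean-level
inputs are supported, since either convention appears in practice; the
weighted/unweighted B is the only difference.

## Clade contrasts and the permutation null

Within-clade pairwise values are compared with the pooled-variance Student
t, df = n₁+n₂−2 *pairs* (15 + 6 − 2 = 19 at the 6-vs-4 design). Pairs
sharing a species are not independent, so the parametric p is a
convention, not a guarantee; the permutation null addresses this by
reshuffling clade labels across **species** and rebuilding all within-clade
pair values per draw. The empirical p is (1+exceedances)/(1+N), two-sided
on |t|; N defaults to 9,999 and the seed is recorded in the output.
Permuted labelings whose t is undefined (zero pooled variance) count as
exceedances — conservative. With 10 species and groups of 6/4 there are
only C(10,6) = 210 distinct labelings, so the attainable p floor is ~1/210
regardless of N; this is a property of the design, not of the test.
Calibration: under an exchangeable null the type-I error at α = 0.05 sits
inside the exact binomial 99% interval over 500 replicates (tested).

The contrast always uses *all* C(n,2) within-clade pairs and reports
df = n₁+n₂−2 computed from those counts. Published analyses of this kind
sometimes report fewer comparisons (e.g. after excluding selected pairs)
or df values that do not match any obvious pair count; this implementation
makes no such exclusions, so its df can differ from such reports even on
identical data. The deterministic pair order (species sorted, combinations
order) makes the extracted value lists reproducible.

## Synthetic generator: what it emulates, and what not

Defaults encode the emulated study design: clades of 6 and 4 species
(hence 15/6 within-clade pairs and df 19), birth rate 1/Ma, a
300 × 200 km root range, equal-area vicariant splits (`split_fraction`
0.5), dispersal 10 km/√Ma per coordinate, 20 localities per species with
5 km Gaussian map-precision noise (matching ~5–10 km georeferencing
accuracy), 20 specimens per species, 10% measurement CV, Brownian log-trait
rate 0.02/Ma with cross-trait correlation 0.5, and a sympatric divergence
boost κ = 3 (units of one-Ma BM standard deviation, applied as opposite
shifts on one random trait axis to the two daughters). Trait evolution on
the log scale guarantees positive mm measurements; lognormal specimen noise
is mean-preserving.

Choices worth stating: the root range is split vicariantly between the two
clades, so clades start in separate sectors (as in escarpment systems where
subclades occupy different range axes); dispersal is pure translation — the
simplest displacement creating secondary contact or withdrawal without
shape change; the root age is the larger clade's crown age plus one
expected two-lineage waiting time 1/(2λ).

The generator does **not** emulate: range shape change or fragmentation
after birth (only translation), spatially explicit landscapes or barriers,
extinction, trait-range co-evolution, phylogenetic signal in sampling
effort, or sequence evolution. Passing tests therefore show the estimators
recover the planted regime contrast under these idealized conditions; they
do not show robustness to range-shape dynamics or sampling biases present
in real herbarium data.

## Alignment statistics

Parsimony-informative columns require ≥2 resolved states (A/C/G/T) each in
≥2 sequences; gaps, `?` and IUPAC ambiguity codes are treated as missing —
deterministic and conservative. Tools that resolve ambiguities as
polymorphic states can count slightly more informative sites; reports flag
the convention so small discrepancies against such tools are traceable.
NEXUS support covers the plain DATA/CHARACTERS-MATRIX dialect (interleaved
or sequential); assumptions/charset blocks are ignored with a warning.

## Problem sizes and determinism

All stochastic components draw from a single `numpy.random.Generator`
seeded from the config or CLI `--seed`; datasets, CSVs and permutation p
values are bit-reproducible. The replicate counts used by the verification
suite — 100 datasets for regime recovery, 500 replicates for null
calibration, 1,000 random trees for the recursion/closed-form identity,
50 geometry instances at 10⁵ Monte-Carlo samples — were chosen so the full
pipeline remains a desk-scale computation (under a minute for the test
suite's heaviest file) while keeping Monte-Carlo standard errors far below
the effect sizes being checked.

## Known limitations

Convex hulls ignore range discontinuities (a crescent-shaped range can
manufacture overlap); overlap proportions use the smaller range as
denominator, so a tiny embedded range scores 1 regardless of the larger
species' extent; the pooled-covariance Mahalanobis assumes a shared
within-species covariance, only approximately true under multiplicative
noise; and the clade contrast treats pairwise values as the analysis units,
with the species-label permutation as the principled guard against their
non-independence.
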