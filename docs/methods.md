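# Methods

## Voxel networks

A root system enters the pipeline as occupied integer lattice points
(vertex-only PLY, an x,y,z CSV table, or a dense binary tensor). Coordinates
are quantized by dividing by the voxel spacing and rounding to nearest (ties
to even); the method operates on whatever voxel set is supplied — surface
voxels and filled volumes are both valid, and no infilling or skeletonization
is performed. The graph connects every voxel pair at Chebyshev distance 1
(26-connectivity) with Euclidean edge length (1, √2 or √3 × spacing), so path
lengths approximate true curved root length. Convention: the lattice is
0-based, the depth axis is z increasing downward, and the "top plane" is the
minimal z among root voxels.

Inputs with several connected components are reduced to the largest (ties go
to the component containing the lexicographically smallest voxel) with a
warning rather than an error, since the analysis assumes a single connected
root. `cycle_rank` (|E| − |V| + #components) is the tree-ness diagnostic:
imaging artifacts such as touching branches produce cycles, which H0
persistence tolerates but which break the tip-count interpretation below.

## Filtration and barcodes

The geodesic function is a multi-source Dijkstra from the top-plane vertex
set (configurable); the depth function is (z − min z) × spacing. Each edge
takes the minimum of its endpoint values, so an edge enters the superlevel
subgraph {f ≥ t} exactly when its lower endpoint does.

The H0 barcode is computed by processing vertices in decreasing function
value with a union–find structure. Design choices, where the sweep narrative
leaves room:

- **Births at exact values.** A component is born at the exact function value
  of its maximal vertex, not at the discretized sweep level; the integer
  `step` parameter only describes sweep granularity, and barcodes are
  step-independent for any step at most the smallest positive value gap.
- **Elder rule and ties.** At a merge the component with the smaller birth
  (the shorter bar at that moment) dies at the entering vertex's value. Equal
  births are resolved toward the component whose birth vertex has the
  smaller index; any consistent rule yields bottleneck-identical barcodes,
  which the tests assert by relabeling vertices.
- **Zero-persistence pairs are dropped.** A vertex absorbed into a component
  at its own level is never a visible component at any threshold and is not
  recorded.
- **The essential bar dies at 0.** The surviving component's death is
  recorded as 0 (the function minimum on a connected network), so every bar
  is a finite diagram point and bottleneck computations need no
  essential-class special-casing.

On a tree whose tips are strict local maxima of the geodesic function, the
bar count equals the tip count and each non-essential bar spans a branch from
its tip to its merge junction. Note the merge junction of a branch need not
be its own insertion point: a lateral that reaches a larger geodesic value
than the primary axis survives the merge, and the axis-side component dies
instead. The tests therefore compare bar lengths to branch lengths only under
generator settings where no lateral outlives the primary axis.

## Bottleneck distance

The bottleneck distance is the minimum over partial matchings of the maximum
L∞ pair cost, with unmatched points paying their diagonal cost
|birth − death|/2. Because any optimal cost is attained at one of the
finitely many candidate values (all point-to-point L∞ costs plus all diagonal
costs), the implementation binary-searches that candidate set, testing each
threshold by a maximum bipartite matching on the standard augmented graph
(each diagram extended by one diagonal slot per point of the other). The
result is exact, and the test suite verifies it against an exhaustive
matching oracle on small diagrams. Repeated diagram points are distinct
matchable copies.

Two barcodes per root combine as √(d_geo² + d_depth²), which is again a
metric; population matrices are computed entrywise in geodesic-only or
combined mode.

## Trait vectors

Classical (Torgerson) MDS double-centres −½ J D² J, eigendecomposes, and
keeps coordinates for eigenvalues above 1e−9 × the largest (bottleneck
matrices are non-Euclidean, so negative eigenvalues are expected and
discarded). PCA is by SVD of the column-centred (optionally standardized)
matrix. Both fix axis signs deterministically — the largest-magnitude loading
(or score, for MDS) of each axis is made positive — so reruns are
reproducible; PCA of the MDS scores returns the same scores and adds variance
fractions, which drive component retention.

Component retention uses the smallest k whose cumulative variance fraction
reaches the cutoff: 80 % for G_PCs and GH_PCs, 95 % for PDD_PCs (the density
vectors concentrate variance in very few directions, so an 80 % cutoff would
retain almost nothing), 90 % for mPCs. All cutoffs live in configuration.

The diagram KDE places a unit-mass isotropic bivariate normal (bandwidth 20
length units) at every geodesic diagram point and averages, so diagrams of
different sizes give comparable densities rather than counts. The evaluation
grid spans [−20, 2000] on both axes inclusive at spacing 20 — "resolution 20"
is read as grid spacing equal to the bandwidth, giving 102 nodes per axis and
vectors of length 10404. Flattening is row-major with the birth axis fastest.
Points outside the bounds are kept (with a warning) since their kernels still
contribute mass inside. Bandwidth, bounds and spacing are fixed across a
population and configurable.

## Trait selection and genetics statistics

VIF_j = 1/(1 − R_j²) regresses trait j on all others with an intercept, via
least squares; exact collinearity reports +inf, and constant columns are an
error naming the column. Pruning removes the single worst trait per round
(ties: the later column) and recomputes until all VIF pass the threshold,
logging every removal. The regressions require more samples than traits; the
pipeline enforces this before pruning by dropping trailing (lowest-variance)
principal components, largest trait family first, until at most
n_samples − 5 columns remain — at desk-scale population sizes the retained
PH components can otherwise approach the sample count.

The threshold itself comes from the sweep rule: prune at an increasing grid
of thresholds (default 2 to 50 in steps of 0.5), record surviving trait
counts, fit y = a·ln(x − b) + c by nonlinear least squares (initialized from
the data range, with b constrained below min x), and take the slope-1 point
x = a + b as the "high" threshold — beyond it a unit of extra collinearity
buys less than one trait. The "median" threshold is exactly half the high
one; the rounded value 8 used in the original analysis is surfaced as
metadata, not applied.

Heritability uses one-way method-of-moments variance components: Vr is the
within-genotype mean square; Vg is (between MS − within MS)/ñ with ñ the
standard unbalanced-design effective replicate number
(N − Σnᵢ²/N)/(k − 1), floored at 0; nrep is the mean replicate count; H² =
Vg/(Vg + Vr/nrep). The method-of-moments estimator needs nothing beyond the
two mean squares, is exactly testable, and coincides with REML for balanced
interior solutions. In the recovery simulations the drawn genotype and
residual effects are normalized so the realized variance components equal
their nominal values exactly; this conditions the check on the simulated
truth and isolates estimator error from sampling of the truth, whose
between-genotype mean square otherwise dominates the spread of H².

Allele effect size divides the model estimate by the mean trait value of
major-allele carriers, preserving sign (positive = the major allele
increases the trait). Co-localization merges trait-associated SNPs within
the window (default 1 Mb) transitively per chromosome — three SNPs at 0,
0.9 Mb and 1.8 Mb chain into one locus — and reports loci plus Venn counts
per trait-group combination; fixed genomic bins were the rejected
alternative since pairwise proximity matches "window" semantics and has no
bin-boundary artifacts.

## Synthetic roots

The generator is a stochastic geometric model, not a biological growth
model: a primary axis grows one voxel per step in z with optional sideways
jitter (tortuosity), and laterals emerge at sampled insertion depths with
soil angles measured from the horizontal plane. Counts are Poisson (a fixed
count is available as a degenerate distribution, useful when a test wants
angle or length to be the only varying factor), lengths are truncated
normal, azimuths align with the insertion side plus jitter.

Under 26-connectivity a branch cannot attach to a straight voxel column with
a single adjacency — any voxel touching a column voxel also touches one of
its column neighbours, creating a 3-cycle. The generator therefore bends the
primary axis sideways by one voxel at each insertion point; the corner is
the one local configuration admitting a single-adjacency attachment voxel.
Branches are rasterized as digital lines whose dominant axis advances every
step (hence simple arcs), corner attachment voxels are reserved so earlier
laterals cannot crowd later insertions, and any lateral whose path would
come within one voxel of the existing root is resampled (up to 60 attempts,
then a generation error suggests a sparser spec; population generation
retries with a fresh derived seed). Every emitted root is one connected
component with cycle rank 0 and carries ground truth: tip count, per-branch
rasterized length, insertion depth, and soil angle.

Default spec (primary 80 voxels, Poisson mean 6 laterals of ~25 ± 6 voxels,
insertions over 5–85 % of the axis, 45° ± 15° angles, tortuosity 0.1)
produces roots of roughly 150–350 voxels — the scale at which every pipeline
stage runs in milliseconds while still exercising realistic branching
variety. What the generator does not emulate: gel optics, imaging noise,
reconstruction artifacts, root thickness (branches are one voxel wide),
higher-order laterals, and root growth over time. Passing tests therefore
demonstrate correctness of the topological computations and statistics on
clean tree-structured inputs, not robustness to segmentation noise — the
`perturb_voxels` helper (random boundary additions and leaf deletions) plus
the bottleneck stability bound cover small geometric noise, nothing more.

## Pipeline

`run_pipeline` executes voxels → barcodes → distance matrices → PH traits →
merge with user-supplied univariate traits → VIF pruning → mPCs →
heritability (simulate mode, where genotype replicate structure is known) →
manifest, writing each stage as CSV/JSON with 12-significant-digit floats.
In simulate mode genotypes differ in lateral count, length and angle
(genotype-indexed RNG) while replicates differ by per-sample seeds. Stage
failures are re-raised with the stage name after writing a FAILED marker;
identical configurations and seeds reproduce bundles byte for byte. The CLI
(`rootph simulate/extract/barcode/distances/traits/select/stats/run`) is a
thin wrapper over these library calls.

## Problem sizes used in the test suite

Synthetic populations in the tests use 100 roots of ~150–350 voxels for the
persistence-vs-component-counting and tip-count checks, 200 random diagram
pairs (≤ 6 points) for the exhaustive bottleneck oracle, 50 function
perturbations for the stability bound, 50 seeds × 200 genotypes × 3
replicates for heritability recovery, and n = 20 populations for end-to-end
determinism — sizes chosen so each property is exercised over meaningful
variation while the whole suite stays fast enough to run on every change.

## Known limitations

- H1 and higher homology are out of scope (roots are assumed loop-free;
  loops that survive cleaning only affect the tip-count reading, not H0
  correctness).
- Bottleneck pairwise matrices are O(n²) in population size with an
  O(k²·√k·log k) matching per pair; fine for hundreds of samples, slow for
  tens of thousands.
- The "resolution 20" reading (grid spacing, not node count) and the
  inclusive bounds are documented conventions; altering them changes PDD_PC
  values but not the qualitative analysis.
- The association scan itself (multi-locus mixed models) is deliberately
  external: the pipeline exports trait tables and consumes estimate tables.
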