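# Methods

This note documents the statistical procedures `tumorgeo` implements, the
generative model behind its synthetic patients, the numerical choices
that affect results, and what the validation suite does and does not
establish.

## Data model

A patient is a set of n ≥ 2 *sectors* — bulk samples with 2-D coordinates
in millimetres on one tumor slice — with any of: a binary sectors ×
variants mutation presence matrix (or a VAF matrix to be thresholded), a
genes × sectors normalized expression matrix, a sectors × clones
proportion matrix (rows sum to 1), and copy-number segment tables.
Pairwise dissimilarities are held in `skbio.DistanceMatrix` (symmetric,
hollow; the triangle inequality is *not* assumed — 1 − Spearman can
violate it), trees in `skbio.TreeNode`.

### Presence calls from VAFs

`binarize_and_filter(v, present_threshold=0, min_max_vaf=0.05)` drops any
variant whose maximum VAF across sectors is ≤ `min_max_vaf` (a variant
never clearly observed anywhere is treated as a false positive) and marks
presence where VAF > `present_threshold`. Missing VAFs (zero sequencing
depth) count as 0, except that a variant missing in *every* sector is
dropped. The synthetic-data analyses raise the presence threshold to 0.05
(`tumorgeo.studies.CALLING_VAF_FLOOR`): at ~100× depth a realistic caller
needs several supporting reads, so presence at ≥ ~10% cell fraction is
the detection floor being emulated.

## Distances and isolation by distance

- genetic, `hamming`: |A Δ B|, the number of variants in exactly one of
  the two sectors' mutation sets.
- genetic, `branch_proportion`: |A Δ B| / |A ∪ B| (Jaccard distance; the
  proportion of non-shared "branch" mutations among all mutations in the
  two samples), defined as 0 for two empty sets.
- transcriptomic: genes ranked by median absolute deviation across
  sectors, top `n_top` (default 3000, all genes if fewer) retained, then
  1 − Spearman ρ per sector pair. Average ranks for ties; MAD ties at the
  cutoff break by gene id so selection is deterministic. An explicit
  `gene_subset` bypasses MAD ranking (purity-correlated or CNA-free gene
  lists). A zero-variance profile after subsetting is an error naming the
  sector.
- clonal: Euclidean distance between clone-proportion vectors; range
  [0, √2].

`ibd_fit` regresses one distance on another over the n(n−1)/2 unordered
pairs by ordinary least squares. Pairs share sectors, so the OLS p-value
is anti-conservative; it is reported anyway because it is the
field-standard summary, and a one-sided Mantel permutation test
(scikit-bio, label permutation, seeded) is offered as the defensible
alternative. A constant response or predictor is reported as slope 0,
r = 0 with a `degenerate` flag rather than an error.

## Local Geary's C

C_i = (2n² / Σ_{i≠j} D²_ij) · Σ_{j≠i} w_ij D²_ij, with w_ij the inverse
physical distance. Both sums run over *ordered* pairs; since D_ii = 0 the
inclusion of i = j is immaterial, and the unordered reading differs only
by a factor absorbed by the leading 2 — the ordered-pair reading is
implemented. Co-located sectors make w undefined and raise an error.
With w in 1/mm, C is unit-dependent; the permutation p-value is the
unit-free quantity (verified by a unit-rescaling invariance test). The
test permutes genetic identities over fixed positions; for each position
i, p_i = (1 + #{C_i^perm < C_i^obs}) / (B + 1). Small p therefore marks
neighborhoods with unusually *similar* genetics — strong local
autocorrelation. The add-one correction keeps p > 0 (standard permutation
practice); the plain proportion is available via `add_one=False`. If all
genetic distances are zero every C_i is reported as 0 with a degenerate
flag.

## Spatial blocks

1. Build the sector tree: Fitch parsimony on binary presence (below), or
   NJ on any distance matrix.
2. For each k in 2–5, enumerate **all** partitions of the leaves into k
   connected components obtainable by deleting k−1 tree edges
   (edge-subset enumeration with bitmask leaf sets; components containing
   no leaf are skipped; duplicate partitions deduplicated). Cutting is
   edge-based on the unrooted topology, so rooting is irrelevant here.
3. Score each partition with the distance-based CH index
   (SS_within = Σ_k Σ_{i<j∈k} d(i,j)/n_k; SS_between = Σ_{i<j} d(i,j)/N −
   SS_within; CH = SS_between(N−K) / (SS_within(K−1))), using the tree's
   patristic distances by default. This is deliberately the *mean-sum-of-
   distances* form, not the classical variance-based CH. SS_within = 0
   yields +inf (a perfect partition of identical points).
4. Report, per k, the best partition and CH; choose the k with maximal
   CH. Ties break to the smaller k, then to the lexicographically
   smallest partition, making the result invariant to sector input order.

`block_contiguity` summarizes spatial coherence as the fraction of
sectors whose nearest spatial neighbor shares their block.

### Parsimony search

Binary characters are Fitch-scored with bitmask state sets vectorized
across variants. Search: exhaustive enumeration of all unrooted binary
topologies for ≤ 8 leaves (`auto`), otherwise steepest-descent
nearest-neighbor-interchange hill climbing started from the NJ tree on
Hamming distances plus 16 seeded random-topology restarts (single-start
NNI gets trapped in local optima on noisy binary data; restarts are the
standard cure and restore exactness on every small instance we can check
exhaustively). Deterministic given input order and seed. Branch lengths
are per-edge change counts from one most-parsimonious reconstruction
(top-down traceback keeping the parent state when compatible; the counts
sum to the parsimony score). All-identical sectors yield a flagged star
tree. NJ is scikit-bio's; its negative branch lengths are clamped to
zero (without redistributing the deficit to the sibling edge).

## Regional diversity θ_R

Grid with 2-mm step covering the sector bounding box padded by the
neighborhood radius, anchored at (min_x − r, min_y − r), row-major. The
neighborhood is a circle whose *diameter* is the median pairwise sector
distance (radius = median/2) unless given. θ_R at a grid point is the
mean branch-proportion distance over all pairs of sectors whose centers
lie within the radius; fewer than two sectors → NaN. θ_R is invariant
under rigid motions of the coordinate frame (the grid is anchored to the
translated bounding box).

## Neutrality tests

Sackin index S = Σ_leaves depth(leaf) in edges, on the rooted tree
(outgroup/normal leaf excluded first — the question concerns tumor-sector
asymmetry). The null is the pure Yule process conditioned only on the
leaf count: repeatedly split a uniformly chosen leaf. Only leaf depths
matter for S, so the null simulation tracks the depth multiset (splitting
a depth-d leaf adds d + 2 to S), vectorized across replicates; this is
why 10⁶ null trees cost seconds. p = (1 + #{S_null ≥ S_obs}) / (n_sim+1),
one-sided toward imbalance because the scientific alternative is clonal
asymmetry under selection (a two-sided reading can be had by doubling).
Multifurcations are resolved uniformly at random (seeded) and flagged.
No closed-form normalization is used — the Monte-Carlo p replaces it.

Clonal asymmetry: exact two-sided binomial test of the derived-block
sector count against 0.5. GII: fraction of `genome_length` covered by
segments with |log₂(CN/2)| > 0.2; CN = 0 is aberrant (the ratio
diverges); uncovered bases count as normal; invariant to segment
subdivision.

## The synthetic tumor generator

The generator is the package's study system: it must *exhibit* the
spatial phenomena the pipeline detects, with known ground truth.

Growth is a 2-D Eden model on a square lattice (default 128², stopping at
a quarter of the lattice ≈ 4,096 cells): one founder cell at the center;
at each step a cell with ≥ 1 empty 4-neighbor divides into a random empty
neighbor. Restricted mixing makes lineages spatially coherent — the
mechanism behind isolation by distance. One lattice cell stands for a
coherent tissue patch (~10⁵ real cells), 0.3 mm across, so a full-grown
blob is ~2 cm in diameter.

Mutations: the founder carries 200 clonal (truncal) mutations — sequenced
tumors are truncal-dominated, since most detectable mutations predate the
imaged expansion — and each division adds Poisson(0.2) new detectable
mutations. (An early uniform-rate regime without a truncal load made
branch-proportion distances saturate near 1, erasing the θ_R interface
ridge; the truncal anchor is what keeps within-block dissimilarities
meaningfully below between-block ones, as in real data.) Genotypes are
stored as a parent-pointer tree with ancestry closure.

Driver subclone: at population size `driver_time` (150 in the canonical
two-block scenario) one daughter founds a derived clone with division
weight `driver_advantage` (2.0) and a punctuated burst of Poisson(100)
extra clonal mutations — derived tumor subtypes carry markedly elevated
genomic instability, and without such a burst a late clone is genetically
nested inside the regional lineage structure and no tree cut can isolate
it. Because a rim-born lineage is often engulfed (or sweeps), two-block
runs condition on coexistence: the growth is resampled from the seeded
stream until the final driver fraction lies in [0.2, 0.8]. This mirrors
studying patients in whom two subtypes demonstrably coexist.

Sampling: circular sectors (radius 1.5 mm) on a honeycomb grid (pitch
4 mm), retained only when cells fill ≥ 85% of the sector area — tissue
punches come from inside the tumor; rim-clipped sectors would contain
mostly non-tumor material, and their noisier profiles fabricate spatial
signal in null data. Bulk sequencing: diploid heterozygous variants, so a
variant at cell fraction f has expected VAF f/2 × purity; observed VAF is
Binomial(Poisson(depth), f/2·purity)/depth with zero-depth cells missing.
Clone proportions are exact cell counts. Expression: per-clone centroids
(log-normal baseline; derived clones shift a fraction of genes by
± effect size), sector profile = proportion-weighted centroid mix +
Gaussian noise, clipped at 0.

The `mixed` negative control keeps the growth law but chooses dividing
cells uniformly among *all* cells, places daughters at random frontier
sites, and finally shuffles all cell positions. The full shuffle matters:
without it a radial age gradient (late = peripheral = more mutations)
leaks positive IBD correlation into the "unstructured" control.

### What the simulations do not capture

3-D growth, cell death and migration, deme structure, copy-number
evolution, purity/ploidy confounding of VAFs (purity is a clean scalar
here), microenvironment, and any transcriptional program beyond
clone-linked shifts. Passing the recovery studies shows the pipeline
detects the *kinds* of structure these mechanisms produce at realistic
scale — not that real tumors satisfy the model.

## Validation suite and problem sizes

The acceptance studies use, per run: exact worked examples (CH = 19 on
the two-pairs instance; √2, 2.0, 0.5 closed forms); 50 random instances
each for the Geary double-loop oracle (n ≤ 12) and parsimony exhaustive
oracle (≤ 6 leaves, 20 characters); NJ additivity on a random 8-leaf
additive matrix (≤ 1e-9); Geary p uniformity over 200 unstructured
replicates at B = 199 (pooled KS); Sackin type-I error over 1000 Yule
trees (n = 20, n_sim = 999; nominal 5%, accepted band 3–7%); and 100/100
(IBD boundary/mixed), 20 (block recovery, ARI ≥ 0.9 against
driver-invasion ground truth), 20 (θ_R ridge) simulated patients. These
sizes keep the full suite under ~2 minutes on one CPU while leaving the
binomial noise on the reported rates small relative to the accepted
bands.

## Known limitations

- Plain OLS over pairwise distances remains the headline IBD fit for
  comparability; use the Mantel p for inference.
- The CH scan is exhaustive over tree cuts and is exponential in k; for
  n ≲ 30 sectors and k ≤ 5 it is interactive, beyond that it is not.
- NNI + restarts is a heuristic above 8 leaves; the score is a certified
  minimum only where exhaustive search ran.
- The Yule null conditions on leaf count only; sector sampling effort is
  not modeled in the null.
- Geary's C values are reported in the units implied by 1/mm weights;
  compare p-values, not raw C, across patients.
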