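# Methods

This note documents the statistical procedures implemented in `deepcomm`,
the conventions adopted where the standard descriptions leave choices open,
and what the synthetic-data scenarios do and do not emulate.

## Community tables and normalisation

A community table is a site × taxon matrix of nonnegative integer read
counts. All comparative statistics operate on raw counts at a caller-chosen
taxonomic rank (genus throughout the analysis drivers); phylum-level views
optionally split Proteobacteria into its classes, the usual convention when
that phylum dominates.

**Subsampled relative abundance.** Unequal sequencing depth is handled by
subsampling every site, without replacement, to a common depth of
⌊0.85 × min_j N_j⌋ and averaging the resulting proportion matrices over
1,000 iterations. Flooring guarantees the depth is attainable by every
site; the 85 % fraction and iteration count are the procedure's standard
operating point and are parameters. Each iteration's random stream is
derived deterministically from (seed, iteration), so results are
reproducible and the loop could be parallelised without changing output.

**Site metadata.** Coordinates are parsed from degrees–minutes–seconds text
(both unicode prime/double-prime and ASCII quotes; hemisphere from the
column label or a suffix; south and west negative). Measurements printed as
ranges (temperature `63-67`, pH `8.3-8.94`) are stored as intervals and
collapsed to midpoints wherever a scalar is needed. Censored cells are
interpreted conservatively: `n.a.` and `<d.l.` become missing; one-sided
bounds (`>1862`, `<1e-4`) contribute their bound value and are flagged, so
downstream users can exclude them. This keeps the environmental matrix as
complete as the printed tables allow while recording where values are only
bounds.

## Alpha diversity

Shannon entropy is computed in bits (base 2), matching the evenness
definition J = H′/log₂ G_obs; the base is a parameter. Chao1 uses
G_obs + F₁²/(2F₂) and falls back to the bias-corrected
G_obs + F₁(F₁−1)/2 when no doubletons are observed — the unguarded form
divides by zero on real data. The standard error uses the classical
variance formulas for both branches (the `±` printed alongside richness
estimates is interpreted as a standard error); with no singletons the
estimator degenerates to G_obs and the se is reported as 0. Singleton taxa
are included by default, with a `drop_singletons` switch for the
sensitivity analysis. Rarefaction curves are Monte-Carlo means of
without-replacement subsamples (multivariate hypergeometric draws); the
analytic expectation G − Σ_i C(N−n_i, d)/C(N, d) is used as the test
oracle.

## Beta diversity

The Sørensen index 2c/(a+b) is presence/absence only and therefore depth
sensitive. The Morisita overlap C_λ is the primary between-site metric
because it is approximately invariant to sample size — the property that
matters when one habitat was sequenced two orders of magnitude deeper than
the other; the test suite checks that rarefying one of a pair of large
communities to a quarter of its depth moves C_λ by less than 0.05.

Morisita is computed on raw integer counts, exactly as the λ_j terms
n(n−1)/N(N−1) require, not on rarefied or relative abundances. The
classical form can exceed 1 for small, highly concentrated samples; the
dissimilarity 1 − C_λ is clamped at 0 with a warning so the matrix remains
a valid clustering input. Each sample needs N ≥ 2, and a pair in which both
samples are all singletons (λ₁ + λ₂ = 0) is undefined and rejected.

**Clustering.** Dendrograms use average linkage (UPGMA) by default —
standard for community dissimilarity matrices — with single and complete
linkage available. Agglomeration is deterministic: among pairs tied at the
minimum distance, the pair with the lowest cluster creation indices merges
first. Distances between merged clusters follow the Lance–Williams
recurrences; a from-scratch O(n³) re-derivation (recomputing every
cross-cluster mean from the original matrix) serves as the test oracle,
and scipy's implementation is cross-checked on tie-free random matrices.
Newick export places each node at half its merge distance (ultrametric
heights), so leaf-to-root path lengths equal half the largest merge.

## Geography and environment

Great-circle distances use the haversine formula on a sphere of radius
6371.0 km (mean Earth radius). The one distance used as a reference value
(two boreholes ~4 km apart) is insensitive to the radius convention at
nearest-km rounding.

The bioenv search standardises each environmental variable to mean 0 and
unit sample standard deviation (ddof = 1), builds the Euclidean distance
matrix of every nonempty variable subset, and Pearson-correlates its
strictly-upper triangle with the community dissimilarity's. The strict
upper triangle avoids double-counting symmetric pairs and the zero
diagonal; a `full_matrix` switch reproduces spreadsheet-style whole-matrix
correlation for comparison. Squared Euclidean distances are additive over
variables, so the search precomputes one squared-difference vector per
variable and assembles each subset by summation; results are identical to
the naive per-subset computation (tested). Subsets are enumerated by size
then lexicographically, and PCC ties resolve toward the smaller subset —
determinism plus parsimony. An exhaustive search over k variables evaluates
2ᵏ−1 subsets and is guarded at k = 20 by default.

Depth estimation assumes conductive warming of gravity-circulated meteoric
water: depth = (T_water − T_surface)/gradient with T_surface = 20 °C and a
regional gradient bracket of 20–30 °C km⁻¹ by default. Temperature ranges
use their midpoint; outputs are metres rounded to the nearest metre. One
published spring row is internally inconsistent with its own formula by a
few metres (printed 830 vs computed 833); the fixture transcribes the
printed value, and computations always derive depths from temperature.

## Correlation screening

Pairwise Pearson r between every pair of columns (phylum relative
abundances and environmental variables), with two-sided p-values from the
exact t distribution on n−2 degrees of freedom. Missing values are handled
pairwise-complete; pairs with fewer than three complete rows or a
zero-variance column are excluded with a warning. Multiple-testing
adjustment defaults to Benjamini–Hochberg — deterministic and well defined
at the small pair counts involved; a Storey-style q-value with a fixed-λ
grid π₀ estimate (median over λ ∈ {0.05…0.5}, no spline) is available. A
pair is significant only when p < 0.05 **and** q < 0.05. On pure-noise
screens this dual filter flags anything at all in well under 7 % of
families (tested over 500 replicates).

## Sequence operations

**Distances.** Aligned-sequence distances follow the eachgap/countend=F
convention: leading and trailing gap runs in either sequence (alignment
overhangs) are excluded; inside the comparable span, a gap opposite a base
counts as one difference, gap-opposite-gap columns are dropped from both
numerator and denominator, and the distance is differences divided by
compared columns. A pair with no comparable columns is undefined.

**Dereplication** merges exact duplicates (full mode) or also any sequence
that is an exact prefix of a longer retained sequence (prefix mode),
summing abundances; candidates are processed longest-first and fold into
the earliest retained match. **Preclustering** is the abundance-greedy
("pseudo-single-linkage") denoising pass: records in descending abundance
order merge into the first retained record within `max_diffs` columns.
This is deliberately not true single linkage — a chain A–B–C can leave C
unmerged — and the tests document that behaviour.

**OTUs** come from average-linkage clustering of the full distance matrix
cut at 0.03 (≈97 % identity); cluster representatives are the most
abundant members (ties by id). Cross-site shared OTUs follow a
representative-reclustering procedure: reduce each site's OTUs to their
representatives, pool, dereplicate (keeping provenance), recluster at
0.0049, and map clusters to site sets. Representatives must share a common
alignment; reconciling alignment columns across independently aligned
sites is out of scope and treated as a precondition.

**Read mapping** is an exhaustive ungapped scan reporting every (query,
reference, offset, strand) placement within the mismatch budget (0 or 2 in
the analyses). Both strands are searched by default. At amplicon scale the
brute-force scan is exact by construction and fast enough; it is also its
own clearest specification, tested against an independently written
sliding-window oracle.

## Oligotyping

Column entropies are Shannon entropies in bits of the abundance-weighted
symbol distribution; the gap counts as a fifth symbol by default (indel
columns are real signal in alignments; a switch excludes them). Random
sequencing error produces entropies near or below 0.2 bits, which is the
threshold-mode selection floor; top-c mode takes the c highest-entropy
positions (ties toward the lower index). Decomposition keys each read by
its residues at the component positions, aggregates abundance per key, and
moves keys below the minimum substantive abundance M = 20 to a `filtered`
bin rather than discarding them, so total abundance is conserved and the
noise load is inspectable. A single supervised pass is implemented — no
iterative refinement rounds.

## Synthetic-data scenarios

The generators exist because the original per-read amplicon data are not
public; they emulate the *structure* of the two habitats, not any specific
dataset.

- **Subsurface-like preset**: 7 sites, 900 taxa with a 220-taxon core
  present in every site, lognormal global abundance weights (σ = 1.6)
  with mild per-site noise (σ = 0.35), per-site reads 14,000–23,500, and
  site-private taxa kept in the abundance tail (weight scale 0.1). This
  yields pairwise shared-genus counts ≥ 220 and Morisita dissimilarities
  of roughly 0.01–0.4 — deeply sequenced, strongly overlapping communities.
- **Spring-like preset**: 6 sites, 300 taxa, a single-core, 40 % of a
  shared pool drawn independently per site, an independently chosen
  dominant taxon per site (weight × 40), reads 120–800. This produces one
  runaway genus per site, many singletons, and Morisita dissimilarities
  mostly in 0.45–1.0.

Counts are multinomial over the site's weights after seeding every core
taxon with one read (so the configured core is genuinely universal); row
totals equal the drawn depths exactly, and all generators are
bit-reproducible from their seed. The lognormal rank-abundance model
reproduces dominance plus a long rare tail but none of the phylogenetic,
chimeric, or primer-bias structure of real amplicon data — so passing
tests demonstrate the statistics behave as specified, not that any
biological conclusion transfers.

Environmental scenarios plant variables along a principal-coordinate
embedding of a given dissimilarity matrix, rotated so planted columns have
equal variance. The rotation matters: the best-subset search standardises
variables independently, and only with equal-variance planted columns is
that standardisation a similarity transform of the planted distance
structure. Decoys are iid standard normal. Read-set generation draws reads
from equal-length haplotypes with iid substitution errors at non-gap
positions (alignment length 61 by convention of the V6 region analysed).

## Problem sizes and determinism

Unit and property tests run on small objects (≤ 10-sequence alignments,
≤ 7-site tables) with explicit seeds; the heavier checks use 100–500
replicates and 200 random clustering instances, chosen so the full suite
completes in well under a minute per module. All random draws go through
`numpy.random.default_rng` with seeds derived from explicit inputs; nothing
depends on global RNG state.

## Known limitations

- Taxonomic annotation, chimera detection, reference-based alignment, and
  phylogenetic (UniFrac-style) comparisons are out of scope; annotations
  and alignments are inputs.
- Morisita clamping discards the magnitude of small-sample overshoot
  (C_λ > 1 becomes dissimilarity 0); the unclamped C_λ is always reported
  alongside.
- The Storey π₀ estimator is a simple grid median, adequate for small test
  families but cruder than spline-based estimators.
- Censored environmental bounds enter scaled analyses at their bound
  value; with many censored cells the Euclidean distances would understate
  true differences.
- The shared-OTU procedure assumes representatives remain aligned across
  sites; it does not re-align.
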