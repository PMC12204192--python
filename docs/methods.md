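# Methods

This note documents the models and procedures implemented in `seqspace`,
the parameters that matter, what the synthetic fixtures do and do not
emulate, and the numerical choices made where the design was open.

## Homology networks and streaming components

**Edge semantics.** Hits are ingested from 12-column BLAST/MMSeqs tabular
files (bitscore from column 12, E-value from column 11; extra columns
ignored). Normalization removes self-hits, drops hits with E-value ≥ 1e-3
(the conventional significance filter), and merges reciprocal hits for the
same unordered pair keeping the **maximum** bitscore. Max (rather than mean
or min) preserves the "any connection above the cut-off" semantics of
component clustering: if either direction of a search deems two sequences
homologous at a score, the edge survives at that score. Bitscore, not
E-value, is the canonical homology metric: E-values saturate at the
reporting floor of search tools and are dataset-size dependent, whereas
bitscores keep scaling with alignment quality.

**Thresholding.** An edge survives at cut-off *c* iff bitscore ≥ *c*
(inclusive, so printed integer cut-offs keep their ties). Cut-offs are
chosen from empirical percentiles (default 10/25/50/75/90) of the bitscore
distribution, estimated from a single-pass reservoir sample of up to 10⁶
scores so the edge file never needs to fit in memory. Quantiles use linear
interpolation between order statistics (the "type 7" rule) and are rounded
half-up to integers; any standard quantile estimator shifts thresholds by
at most ~1 bit at these sample sizes. Duplicate thresholds collapse with a
warning.

**Streaming components.** Connected components at each cut-off are computed
by streaming the edge file in chunks. Each chunk builds a local
disjoint-set forest (union-by-size, path compression); local clusters are
merged into a global forest by unioning their members. Union is associative
and commutative, so the partition is provably independent of chunk size and
chunk order (chunks could be processed concurrently), and peak memory is
O(nodes + chunk_edges). The multi-cutoff variant keeps one forest per
cut-off and applies each edge to every cut-off at or below its bitscore;
nesting of the resulting partitions is automatic because higher cut-offs
see a subset of the edges. Cluster labels are canonicalized to the
lexicographically smallest member id, making outputs byte-stable across
runs and chunkings. Singletons (sequences with no surviving edge) are kept
as clusters of size 1 so the id universe is conserved across levels.

## Embedding clustering

**Vectors.** Per-residue language-model states enter through an adapter
(id → L×d matrix) or as precomputed pooled vectors; mean-pooling over the
sequence dimension yields one fixed-length vector per sequence, and PCA
reduces to 30 dimensions by default (deterministic sign convention: the
largest-magnitude loading of each component is positive). No GPU or model
weights are required by the package; vectors are stored as a float32 binary
table with a JSON provenance sidecar. PCA is fit on whatever matrix is
provided; the fit set is recorded in provenance.

**Hierarchy-consistent bisecting K-means.** Naive bisecting K-means re-run
at each K produces partitions that do not nest across K. Instead the
divisive split tree is retained: starting from one cluster holding all
sequences, the leaf with the largest SSE (sum of squared Euclidean
distances to the leaf centroid) is repeatedly split by 2-means until K_max
leaves exist. Each split runs seeded k-means++ with 10 restarts, tolerance
1e-6, max 300 iterations (conventional values); per-split seeds derive from
the master seed so the whole tree is reproducible, and SSE ties break
toward the leaf with the smallest member index. The branch length from
parent to child is SSE(parent) − SSE(child) ≥ 0. The K_max leaves then
become items of a single-linkage agglomeration whose item distance is the
branch-length path between leaves in the split tree — the natural
tree-induced metric, chosen where the conversion rule was ambiguous — and
any K ≤ K_max is obtained by maxclust flattening of that one merge
structure. Because all cuts are height thresholds of one monotone tree,
flatten(k₂) provably refines flatten(k₁) for k₁ < k₂, and flatten(K_max)
reproduces the bisecting leaves exactly. Leaves containing only duplicated
points are split by index halves (2-means is undefined there).

**Agglomerative clustering.** WPGMA ("weighted") linkage over cosine
distances (1 − cosine similarity), per-item semantics. The full pairwise
distance matrix is required, so inputs beyond 50,000 items raise a memory
budget error advising redundancy reduction (e.g. clustering to 70%-identity
representatives) first; representative labels are projected back to all
members afterwards. Merge heights are passed through a running max before
flattening: maxclust needs monotone heights and cosine/WPGMA can produce
inversions. The linkage is also emitted as a rooted binary tree with branch
lengths equal to merge-height differences, round-trippable through Newick
(scikit-bio).

**Tree summarization.** A merge tree is collapsed to k clades dendrogram
style: starting from the root clade, the clade with the tallest subtree is
repeatedly split into its children (ties break by smallest contained leaf
name). Each clade becomes one leaf whose branch length is its incoming
branch plus the longest root-to-leaf path inside the clade, so collapsed
branch lengths report the farthest member; every clade's subtree remains
retrievable for higher-resolution views.

## Agreement

ARI and AMI (arithmetic-mean entropy normalization, the common default; the
normalization convention was otherwise unspecified) are computed by
scikit-learn after aligning the two partitions on a shared, sorted id
universe; mismatched universes are an error, not a silent intersection. The
sweep evaluates the full grid of level pairs between two hierarchies. Both
scores are label- and order-invariant; 1 means identical partitions, ≈0
independent ones.

## Layout

Each cluster is a circle of radius sqrt(size), so area ∝ membership exactly
within every sibling group. Sibling groups are packed by a bespoke
deterministic relaxation rather than a rigid-body physics engine — the
contract (no overlap, compact, deterministic) is what matters: circles
initialize on a seeded sunflower spiral, then alternate (a) pairwise
push-apart of overlapping circles by half the overlap each along the center
line (coincident centers separate along a deterministic per-pair angle) and
(b) centripetal contraction toward the area-weighted centroid; a final
resolution loop runs until the deepest overlap is below 1e-3 × the smallest
sibling radius (the internal convergence target is a quarter of that, since
a resolution pass reports pre-move overlap). Packed children are translated
so their area-weighted centroid coincides with the parent center and
uniformly rescaled by the largest s ≤ 1 placing every child within 0.95 of
the parent radius (both constants are package choices; the uniform rescale
preserves within-group proportionality, and s is recorded per group in the
layout file). Filtering keeps clusters above a minimum size or containing
nominated sequences, plus all their ancestors. Per-group seeds derive from
(master seed, level, parent id) via CRC-32, so layouts are byte-identical
across reruns. Overlap resolution uses a k-d tree for candidate pairs, so
cost scales near-linearly with circle count rather than edge count.

## Representatives

**Profile route.** Cluster members are aligned (mafft for unequal lengths;
equal-length clusters are treated as already aligned), a profile is built
from the MSA, every member is scored against it, and the best scorer wins
(ties toward the smaller id; singletons represent themselves at score 0).
Two engines exist and are never mixed in one report: HMMER3 via pyhmmer,
and a pure per-column log-odds profile (match columns = columns with < 50%
gaps; Laplace pseudocount 1 against a uniform 1/20 background — standard
defaults) that keeps the selection logic testable and usable without the
HMMER machinery.

**Vector route.** The member nearest (Euclidean) to the arithmetic mean of
the cluster's vectors; ties toward the smaller id.

**Evaluation.** Global percent identity is Needleman–Wunsch with BLOSUM62,
affine gaps (open 11, extend 1), identity = identical columns / alignment
length including terminal gap columns × 100 — the convention affects
absolute values, not orderings, and is fixed package-wide. Three metrics
per cluster: `delta_id` (median %ID of members to the representative minus
the median %ID of seeded random member pairs, capped at 10,000 pairs since
full pairwise identity is quadratic), `rank` (percentile rank of the
representative's median %ID among all members' median %IDs; 1 = most
central), and `length_delta` (representative length minus median member
length). Cluster-level properties (size, within/between %ID medians over
seeded pair subsamples, genus diversity) consider clusters of ≥ 5 members.

## Even phylogenetic sampling

The sampler walks a cut-off ladder (default base 150, step 10, max 400).
Neighborhoods whose size falls in the window (default 100–1,000 sequences)
contribute one representative chosen by the configured method;
neighborhoods above the window are re-clustered at the next cut-off and
their children visited; neighborhoods below the window are skipped.
Neighborhoods still oversized at the maximum cut-off contribute one
representative flagged `unresolved_at_max_cutoff` — dropping them would
leave visible sequence space unsampled, contradicting the point of even
coverage. Representatives whose lengths fall outside the length window
(default 100–300 aa) are excluded and logged. Optional anchors restrict the
walk to neighborhoods containing an anchor at a coarse anchor cut-off
(default 102). Clusters are visited in canonical sorted order, so output is
deterministic and no cluster ever contributes more than one representative.
Coverage comparison reports the fraction of one sample whose clusters
contain no member of another sample.

## Synthetic worlds

`make_world` plants a two-level hierarchy: each superfamily ancestor (a
uniform-random amino-acid sequence, length drawn per superfamily from
120–240 aa) spawns family centers by point substitution at rate 0.30, and
members derive from their center at rate 0.05 — families tight, superfamilies
loose. Pairwise edges carry bitscores drawn from two bands: within-family
N(250, 10²) on all pairs, cross-family-within-superfamily N(120, 10²) on a
sparse 10% of pairs, and no cross-superfamily edges (emulating the E-value
filter of a real search). Band draws are truncated at three standard
deviations and at zero, so the separability precondition guarantees exact
recovery of the planted partition at any threshold between the bands.
Embedding fixtures are hierarchical Gaussians whose three scales
(superfamily separation 100, family separation 10, member noise 1, all in
expected-pairwise-distance units) make `sep_fam / noise_sd` a direct
separation-to-noise ratio; at ratio 10 the planted families are exactly
recoverable, which is the regime the recovery tests assert. Genus labels
are drawn per family from a small pool. Bitscores are drawn, not computed
from alignments, for speed and controllability.

What the fixtures do **not** emulate: indels (members differ only by
substitution, so alignments are trivial), realistic bitscore–identity
coupling, overlapping score bands, and — important for interpreting the
representative metrics — any correlation between embedding noise and
within-family mutational distance. Synthetic vectors carry family
structure, not intra-family identity structure, so vector-representative
identity metrics (delta_id, rank) on fixtures hover near chance within a
family, whereas profile-based representatives track identity directly.
Passing tests therefore demonstrate the mechanics and invariants of every
method at desk scale, not field performance on real superfamilies, whose
headline statistics depend on UniProt-scale datasets and real language-model
inference.

## Problem sizes

Tests and the acceptance script run on planted worlds of ~270–800
sequences, random graphs up to 10⁴ nodes / 10⁵ edges, and layouts of 10³
clusters — sizes chosen so the full suite completes in well under a minute
per module while still exercising every scaling mechanism (streaming,
chunk merging, k-d-tree packing). The streaming and packing paths are the
same code that handles the hundreds-of-thousands-of-sequences regime.

## Known limitations

* The chunk-merging components algorithm is sensitive to single spurious
  linkages (one edge joins two otherwise separate clusters), inherent to
  connected-components clustering; community detection is out of scope.
* WPGMA requires the full distance matrix; beyond the 50,000-item budget the
  caller must reduce redundancy first.
* The fallback profile scorer is a position-specific scoring model, not a
  full plan7 HMM (no insert/delete states or E-values); its scores are not
  comparable to HMMER bitscores.
* The even sampler assumes the hierarchy is computable at every ladder
  cut-off; with anchors, the anchor level must be coarser than the base
  cut-off.
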