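# Methods

This note records the model implemented by `protofam`, the numerical and
design choices made where the protocol left room, and what the synthetic
benchmarks do and do not demonstrate.

## Similarity substrate

The clustering operates on a symmetric matrix of pairwise E-values over a
proteome, capped at 100: any pair less significant than the cap, and any
pair never scored, reads as 100.  The diagonal is pinned to a floor of
1e-180 (a stand-in for "identical" that keeps log-space work finite).
Aligner E-values are directed; when a score table contains both directions
of a pair we keep the minimum (most significant) of the two.  This is a
choice, not a property of the protocol: it is conservative (merges are
driven by the better of the two alignments) and deterministic.

Fragment records are dropped before scoring.  Fragment status is read from
an explicit `fragment=1` key on the FASTA header rather than free-text
description matching, because free-text flags are ambiguous across sources.

The built-in surrogate scorer maps the k-mer Jaccard index J of two
sequences to `clamp(10^(2 − s·J), 1e-180, 100)` with k = 3 and s = 40.
These values put unrelated random sequences at or near the cap (random
protein-length sequences share few 3-mers, J ≈ 0.01, E ≈ 40) and
near-identical sequences far below any plausible eligibility threshold
(J = 1 gives 1e-38).  The scorer is symmetric, deterministic, monotone in
J, and pluggable — tables from a real aligner can be ingested instead.

## Hierarchy construction

Average-linkage agglomeration: `linkage(A,B)` is the arithmetic mean of
all inter-cluster pairwise E-values.  The implementation maintains pairwise
*sums* and updates them additively on each merge
(`S(A∪B, C) = S(A,C) + S(B,C)`), which is the Lance–Williams mean update in
exact form; each linkage equals the direct mean over member pairs up to
summation order.  Ties on the lowest linkage are broken on the
lexicographically smallest (min node id, max node id) pair, making trees
bit-reproducible; the test suite checks the full merge log against a direct
O(n³) re-scan, including tie-rich matrices whose sums are exact in double
precision.  Merging runs to a single root by default; a `merge_cutoff`
below the cap stops merging early and leaves a forest.

**ProtoLevel.** Only the endpoints of the depth coordinate are fixed by the
protocol (0 = singletons, 100 = final merge); between them we use
`PL = 100 · birth_step / n_merges`, which is monotone along every
leaf-to-root path and linear in merge time.

**LifeTime.** Defined here as an integer count of merge steps between a
cluster's creation and its absorption; surviving roots die notionally one
step after the final merge.  Whether the original system measured stability
in merge steps or in PL units is not documented; steps were chosen because
they are exact integers and independent of tree size normalization.

**Stable clusters.** Nodes with LT ≥ `lt_min` (default 10).  Singleton
leaves are excluded by default: a "cluster" is something the agglomeration
created, which also matches the protocol's description of the LT = 0 set as
having about as many clusters as proteins (the internal nodes of a binary
tree).  Long-lived leaves can be admitted with `include_singletons=True`.
Without this exclusion, mapping degenerates whenever a query is also a tree
member (its own leaf is always the minimal eligible cluster).

## Mapping

A query's eligibility score for a stable cluster is the mean capped
E-value between the query and the cluster's members; the cluster is
eligible when the score is below `tau_map`.  The default `tau_map = 1.0` is
permissive while excluding cap-level noise: a cluster whose members average
E ≥ 1 against the query carries no real signal.  Among eligible clusters
the minimal-sized one wins (ties: lower score, then lower node id),
following the protocol's wording; best-score-first ordering is available
via `prefer="score"`.  The mapped cluster is lifted to its highest ancestor
at PL ≤ `pl_root` (default 70).  A mapped cluster that itself sits above
the cutoff is reported as EXCLUDED — deliberately distinct from UNMAPPED,
since the two failure modes (too deep in the hierarchy vs. no eligible
cluster) are reported separately in the protocol.

Queries never modify the frozen hierarchy.  Both workflows are supported:
re-using the original all-vs-all matrix for member self-mapping, and
scoring external queries against the tree proteome with any symmetric
scorer.

## Annotation inference

The Correspondence Score of a term in a cluster is implemented as the
intersection-over-union of the cluster's member set and the term's carrier
set within the analysis universe.  The original system's "union" is not
precisely scoped in the available description (cluster ∪ carriers vs. all
carriers in the subtree); the standard IoU reading was chosen and the
carrier set can be restricted by the caller if the other scoping is wanted.
Specificity is cluster purity — the fraction of members carrying the term —
matching the protocol's use of the two as independent measures.

The specificity filter (≥ 0.2) is applied to every candidate term *before*
CS ranking, not only to the winner, so a low-purity term can never win a
source on CS alone.  Blacklist matching is a case-insensitive substring
test on the term label (default: "complete proteome", "taxonomy",
"hypothetical protein") applied both at load and at selection.  Ties on CS
break on larger intersection, then lexicographic term id.  Clusters of
fewer than 5 proteins are never named.

A protein inherits the per-source ProtoName terms of its mapped cluster and
of every ancestor up to and including its ProRoot, deduplicated by
(source, term id).  Unmapped and depth-excluded proteins receive nothing
and carry a status flag.

## Paralog statistics

Guide trees are built with UPGMA under the same deterministic lowest-id
tie-break as the main hierarchy (scipy's linkage does not expose a
tie-break, and determinism here is load-bearing for reproducible scores).
In sequence mode the distance matrix defaults to 1 − k-mer Jaccard; any
user matrix can be supplied.  Trees are scored as rooted: the "set of all
subtrees" in the tree-score definition is read as the set of rooted clades
(a node with all its descendants), under which the minimum is achieved at
the LCA of the species' leaves.  The alternative connected-subgraph reading
degenerates to TS ≡ 1 and is rejected; an exhaustive-enumeration oracle in
the tests confirms the LCA shortcut on every random tree it sees.  The
guide tree for a mapped cluster spans the cluster's proteins plus the
queries mapped onto it, so the species of interest is present by
construction.

Taxonomy Balance is kept as an exact integer fraction so the inversion
identity `TB(a,b) · TB(b,a) = 1` holds exactly rather than to rounding.
The amplification ratio (proteins under a root / distinct stable clusters
holding them) is reported rounded half-up to two decimals, the precision of
the published table it mirrors.  TS histograms use paralog-count strata
(2, 3–9, ≥ 10), bins of width 0.1, and a high-divergence cutoff of
TS < 0.2; TB extremes are ≥ 10 and ≤ 0.1.  All of these are exposed as
configuration.

## Synthetic data: what it emulates and what it does not

The generator plants protein families with within-family E-values far
below the cap (log10 range −60..−20 by default) and cap-level values
between families and around orphans; per-family species occupancy
(default three species at probabilities 1.0/0.6/0.6) exercises the
cross-species partitions; one planted term per family at a controllable
purity exercises annotation transfer; and planted clade/intermixed guide
trees exercise the tree score.

Within a family, E-values follow a star-like divergence model rather than
independent per-pair draws: each family occupies one log10 band, each
member carries a divergence rank, and a pair's E-value is set by the more
divergent member (an ultrametric matrix, as produced by a founder gene with
successively diverging duplicates).  Families therefore agglomerate as
chains — founder pair first, then one member per step — so intermediate
sub-family clusters die after exactly one step while completed families
persist through the entire cap-level merge phase.  This keeps "stable
cluster" aligned with "planted family", which is the property the recovery
benchmarks need.  With independent per-pair draws, family assembly
interleaves globally and arbitrary sub-family clusters become stable; that
regime can be explored by supplying a custom matrix, but it is not the
benchmark condition.  The default of 24 families (sizes 4–20, 2% orphans)
gives every completed family a LifeTime comfortably above the pruning
threshold of 10 (the youngest family survives roughly
(families + orphans)/2 cap-level merges).

Two small-tree effects are worth keeping in mind when reading benchmark
results.  First, on a tree of a few hundred proteins the within-family
merge phase spans ~90% of all merges, so families completed late are born
above PL 70 and their proteins are depth-excluded exactly as the protocol
excludes deep mappings; recovery statements therefore apply to the
annotatable (non-excluded) proteins, and the excluded ones are verified to
be flagged and term-free.  Second, the global root and some cap-level
superclusters always have LT ≥ 10, so the stable *set* is necessarily a
superset of the planted families; recovery is asserted on the partition
induced by mapping (superclusters fail eligibility because their mean
E-values are dominated by cap-level pairs), which recovers the planted
partition at adjusted Rand index 1.0.

What passing these benchmarks does *not* show: real proteomes have
overlapping domain architectures, fragmentary gene models, and families
without clean E-value separation; the generator has none of these (no
indels, no substitution-rate matrices, no inter-family similarity
gradients).  The benchmarks validate the machinery — linkage maintenance,
pruning, eligibility, score algebra — not the biological error rate of
annotation transfer at scale.

## Problem sizes and numerics

Default benchmark sizes are a few hundred proteins per dataset (24
families × ~12 members), where a full clustering takes well under a second;
the implementation is quadratic in memory and is intended for desk-scale
analyses up to roughly 10⁴ proteins, not for database-scale runs.  Linkage
comparisons use exact ordering on accumulated double-precision sums; the
tie-break makes every ordering decision deterministic.  Degenerate inputs
are defined errors: empty proteomes after fragment filtering, non-symmetric
matrices, clusters without the species of interest, taxonomy balance with
an absent species (UNDEFINED), and amplification ratios over zero stable
clusters.
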