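# Methods

## The network model

A regulatory network here is a typed graph over three node roles — TF,
miRNA, gene — where a node may carry both the TF and gene roles (a TF is
itself encoded by a gene and can appear as a regulatory target); the miRNA
role is exclusive.  Edges belong to one of six relation types: four
directed (TF→miRNA activation, miRNA⊣gene repression, TF→gene regulation,
miRNA⊣TF repression) and two undirected (gene–gene interaction,
miRNA–miRNA interaction).  Undirected edges are stored with
lexicographically ordered endpoints, so re-listing an interaction in the
opposite orientation collapses to one edge.  Self-loops and duplicate
(source, target, relation) triples are rejected; endpoint roles must match
the relation type, and violating rows in input tables are skipped and
reported rather than aborting a load.

The miRNA–miRNA layer need not be supplied: it can be derived from the
miRNA⊣gene layer by the shared-target rule, connecting every miRNA pair
with at least `min_shared` (default 2) common target genes.  The derivation
is order-invariant and monotone in the threshold.

## Motif census and canonical labels

All connected induced subgraphs of size k ∈ {3, 4, 5} are enumerated
exactly once with ESU-style extension over the symmetrized connectivity
graph (each directed edge contributes adjacency both ways, matching how
motif-detection tools treat mixed graphs).  Each induced subgraph is
assigned to a colored-isomorphism class: node colors are full role sets
(so a dual-role TF&gene node is a distinct color from TF or gene — the
coloring of dual-role nodes is a genuine modelling choice, and the full
role set preserves the most information), edge colors are the six relation
types, and a node pair may carry several relations simultaneously.  The
class label is the lexicographic minimum over all k! node permutations of
a serialized (colors, typed adjacency) tuple; with k ≤ 5 this exact
minimization is cheap, and repeated patterns hit a memoization cache.  The
label string is self-describing and can be parsed back into the pattern it
names, which is how the composite-FFL test below inspects classes.

A subset-enumeration census (`brute_force_census`, guard-railed to ≤ 30
nodes) is kept as an independent oracle; the test suite checks exact
agreement of labels and counts on randomized networks for all three sizes.

## Null model and significance

Replicate networks are produced by endpoint-switch randomization *within*
each relation type: two same-type directed edges (a→b, c→d) become (a→d,
c→b); two same-type undirected edges swap one endpoint each in a random
matching.  Proposals creating self-loops or duplicates are rejected and do
not consume the exchange budget of 3 successful swaps per edge per relation
(a retry cap of 100× the budget prevents livelock on rigid relations; a
relation with fewer than two edges is left unchanged).  This preserves
per-relation edge counts, role assignments and every node's per-relation
in-, out- and undirected degree — the invariant is asserted in the tests
via an exact per-node fingerprint.

Each class is scored against `n_random` replicates with
Z = (N_real − mean)/sd on raw counts (sample sd, n−1 denominator) and an
empirical p, the fraction of replicates whose count reaches the real count;
classes absent from a replicate count 0, and a reported p of 0 means
"< 1/n_random".  When sd = 0 and the real count equals the null mean, Z is
0; when sd = 0 and the real count differs (a class never produced by the
null), Z is reported as a ±inf sentinel with a warning — the empirical p
then carries the evidence.  The JSON report serializes the sentinel as the
string "inf" to stay within strict JSON.  A concentration-based Z
(frequencies instead of counts) was considered and deliberately not made
the default: counts are exactly testable and the two orderings agree on
networks of fixed size.

## Composite-FFL definitions and the CFMSN

A 3-node class qualifies as a composite FFL when its role multiset is
exactly {1 TF, 1 miRNA, 1 gene} and the pattern contains TF→miRNA,
miRNA⊣TF, TF→gene and miRNA⊣gene between those slots — mutual TF/miRNA
regulation plus a co-regulated target.  The 4-node definition adds one gene
(role multiset {1, 1, 2}) and requires a gene–gene edge plus an embedded
3-node core; the 5-node definition further adds one miRNA ({1, 2, 2}) and
a miRNA–miRNA edge.  This is the minimal reading: the added gene need only
be connected through the gene–gene interaction.  A `strict=True` mode
additionally requires every gene slot to be a common target of the TF and
a core miRNA (the stronger "common target" reading); both are exposed
because the two readings genuinely differ and the minimal one subsumes the
strict one.  A dual-role TF&gene node may fill either a TF or a gene slot,
but one node fills only one slot.

Selection takes, per size, the classes passing Z > 2 and p < 0.05 that
qualify as composite FFLs and picks the highest-Z class, breaking ties by
lower p and then lexicographic label for reproducibility.  All instances of
the three winners are merged into the CFMSN — node set and induced edges
are subsets of the parent network by construction, and every stored
instance re-classifies to its winning label.

## Topology

Node metrics are computed on the undirected simple projection (relation
colors ignored, parallel relations counted once): degree, clustering
coefficient 2·triangles/(deg·(deg−1)), neighborhood connectivity (mean
neighbor degree), and the topological coefficient — for a node n with ≥ 2
neighbors, the mean over partners m sharing at least one neighbor of
(|shared neighbors| + [m adjacent to n])/deg(n), else 0.  Clustering and
neighbor degree are delegated to networkx; the topological coefficient is
implemented directly.  The degree-distribution fit is an ordinary
least-squares line on (log degree, log raw frequency) over degrees with
positive frequency — the network-viewer convention, chosen for
comparability with how such fits are usually reported, not a
maximum-likelihood tail estimate.  Degree-0 nodes and empty bins are
excluded (log undefined).

## Expression validation

Differential expression uses Welch's unequal-variance t-test on log2-scale
values, logFC as the difference of group means, BH FDR reported alongside,
and the flag p < 0.05 ∧ |logFC| > 1 on the *raw* p (the FDR column is
informational; moderated-t variants would need probe-level data and are
out of scope).  A feature constant in both groups gets p = 1 (no
evidence); a deterministic shift with zero variance gets p = 0.  Pair
correlation uses Pearson r on shared samples (≥ 3 required) with the
t-distribution p on n−2 degrees of freedom and the joint flag
|r| > 0.5 ∧ p < 0.05; pairs spanning two matrices are matched by sample
name or an explicit alignment map, and constant vectors are flagged
not-significant with a reason rather than erroring.

## Drug association

The curation screen is a conjunction of seven boolean flags (approved,
marketed, APRD-numbered; not carcinogenic, illegal, mixture-only, or
vaginally administered).  Association between a miRNA's target set (K
genes) and a drug's target set (N genes, drugs with < 2 targets excluded)
in a universe of M genes uses the cumulative hypergeometric distribution
computed by exact integer arithmetic (one correctly rounded float division
at the end; the test suite checks agreement with a rational-arithmetic
oracle to 1e−12 for all M ≤ 60).  The lower cumulative F(x) *decreases*
with stronger overlap, so the over-representation score is the upper tail
P(X ≥ x) = 1 − F(x−1), computed by direct summation; `tail="lower"`
evaluates F(x) itself for completeness.  The universe M defaults to 20 000
protein-coding genes and is configurable; when an explicit universe set is
given, both target sets are intersected with it before counting.  The same
machinery drives a generic gene-set enrichment over GMT files with BH FDR.

## Synthetic data: what it emulates and what it does not

`generate_background_network` draws each relation's edges without
replacement from the feasible role-consistent pairs, either uniformly or
by preferential attachment (endpoint probability ∝ 1 + current degree),
the latter producing the right-skewed, approximately power-law degree
distributions typical of regulatory networks.  The global-scale default
(16 TFs, 76 miRNAs, 156 genes; per-relation edge counts
60/276/47/39/222/194) mirrors the composition of the merged network the
pipeline is designed for.  `plant_composite_ffls` inserts node-disjoint
composite-FFL instances, preferring node tuples with no pre-existing
internal edges so the planted class is unambiguous and ground-truth counts
exact.  Expression profiles are baseline + group shift + Gaussian noise,
with designated pairs drawn from a bivariate normal at the target
correlation (each feature in at most one pair — a normality and
independence structure chosen for tractability); drug fixtures draw target
sets uniformly and flags as independent Bernoullis.

None of this reproduces real data's correlated noise, batch structure,
probe-level artifacts, or literature-curation biases.  Passing tests
therefore demonstrate that the *algorithms* are correct and calibrated
(planted signals recovered, null rates controlled), not that any
biological conclusion transfers.

## Problem sizes and numerical choices

- Motif-stage scenario: 68-node background (8 TFs / 20 miRNAs / 40 genes,
  ~185 edges) with 6/4/3 planted composite FFLs of sizes 3/4/5; replicate
  counts 200/100/30 for k = 3/4/5, scaled to the census cost, which grows
  steeply with k (the 5-node census of this network classifies ~40 000
  subgraphs).  At 30 replicates, rare 5-node classes never occur under the
  null and carry the Z = inf sentinel.
- Null calibration uses a denser 32-node background in which reciprocal
  TF–miRNA regulation is common enough that the composite-FFL class occurs
  with nonzero count variance; 50 analyses at 40 replicates each.
- All randomness flows from one global seed through named substreams
  (`substream_seed`), so components can be regenerated independently and
  identical configurations yield byte-identical pipeline reports; replicate
  pools are sorted before switching so results do not depend on hash
  randomization.
- Degenerate inputs: empty networks census to empty results; a relation
  with < 2 edges is returned unchanged by the randomizer; constant
  expression vectors and zero-variance groups follow the conventions above;
  hypergeometric parameters are validated (K, N ≤ M) and out-of-support
  terms are zero.

## Known limitations

- The exact-minimization canonical form is specific to k ≤ 5; larger motifs
  would need a real canonical-labeling backend.
- The census is exact, not sampled; on networks much denser than the study
  scales the 5-node stage becomes the bottleneck.
- Expression validation assumes log2-scale input and performs no
  normalization or probe mapping.
- The hypergeometric model treats gene sets as unstructured; dependence
  between miRNA targets and drug targets (e.g. pathway co-membership) is
  not modelled.
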