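# Methods

## Detection model

A gene tree is handled unrooted throughout. A *focal subtree* is a maximal
set of leaves, all belonging to the focal kingdom, separated from the rest
of the tree by a single (stem) edge; maximality is computed by orienting
the tree from an arbitrary nonfocal leaf and taking the highest all-focal
nodes. A single tree can contain several focal subtrees; they are disjoint
by construction. Working unrooted avoids automatic gene-tree rooting,
which is a known source of spurious incongruence.

### Neighbor clades and the stem walk

The donor context of a focal subtree is summarized by its two nearest
neighbor clades N1 and N2, collected by a deterministic walk that starts
across the stem edge and, at each branching, takes the side clade with the
fewer unmasked leaves as the next neighbor (ties broken by the smallest
leaf label) while continuing into the larger side. Leaves belonging to
*other* candidate focal subtrees in the same tree are masked during the
walk, so that independent transfers do not contaminate each other's donor
context; a side clade emptied by masking is skipped and the walk
continues. The walk records the support of every edge it defines or
crosses; requiring all of them to pass the threshold is the conservative
reading of "well-supported".

Two neighbor clades, not one, are required because a sister clade alone
cannot distinguish *nesting* inside a donor clade (transfer) from *sister
placement* next to it (compatible with vertical descent): only when the
first two clades along the walk share a donor-side ancestry is the focal
subtree truly inside foreign territory. This two-deep criterion is the
weakest one that makes the three-way classification below well-defined
and verifiable against the enumeration oracle.

### Classification under a polytomous taxonomy

Let X be the LCA, in the reference taxonomy, of all N1 ∪ N2 leaf taxa.

* **supported** — X is disjoint from the focal lineage (neither ancestor
  nor descendant of the focal clade) and the stem plus neighbor-defining
  edges all have support ≥ `min_support`. Disjointness in the polytomous
  tree implies disjointness under *every* binarization, because resolving
  polytomies can only push an LCA deeper, never above X.
* **congruent** — X is a strict ancestor of the focal clade and at least
  one neighbor leaf lies inside the child of X on the path toward the
  focal clade. Any resolved LCA must then still span that child, hence
  remain an ancestor of the focal lineage in every binarization: vertical
  descent survives all resolutions.
* **weak** — everything else, with a recorded reason. The interesting case
  is `resolvable_polytomy`: X is an ancestor of the focal clade but no
  neighbor leaf sits in the child toward it, which happens exactly when X
  is a polytomy whose resolutions disagree — some group the neighbor
  lineages away from the focal lineage (transfer-like), others do not.
  The remaining reasons are bookkeeping: `low_support`,
  `no_second_neighbor` (the tree, after masking, has fewer than two
  nonempty neighbor clades), and `neighbor_contains_focal` (only
  reachable when masking is disabled).

The equivalence of this polynomial test with exhaustively enumerating all
binarizations is the package's central correctness claim; it is asserted
on hundreds of random fixtures in the test suite and the acceptance
script, with the enumeration (`(2m−3)!!` resolutions per degree-*m*
polytomy) restricted to the taxa present in each fixture.

Donor = LCA of the N1 taxa; it generalizes rather than errs (it can only
be an ancestor of the true donor when sampling is sparse). Acceptor = LCA
of the call's target-proteome taxa in the species tree; this approximates
the transfer depth, biased recent by losses and sparse sampling, ancient
by within-kingdom re-transfer.

## Contamination filter

Contigs are the unit of evidence: a contig is kept at stage 1 iff at
least one of its genes has a homolog in another target proteome (own
proteome excluded), and at stage 2 — applied sequentially to stage-1
survivors — iff at least one gene has a focal-kingdom top hit. Genes with
no hits contribute to neither criterion; a top-hit score tie between
focal and nonfocal counts as focal, since the filter's job is removing
clear contaminants and the downstream phylogenetic test supplies
stringency. Identity- or GC-based screens are deliberately absent: contig
context is the evidence that distinguishes an integrated xenolog from a
co-assembled organism.

## Reconciliation

Each supported subtree, rooted at the stem-edge endpoint inside the focal
clade (the acceptor node), is embedded in the binary species tree by the
classical LCA mapping: M(leaf) = its species, M(u) = lca(M(children)).
A node is a duplication iff its image equals a child's image; losses
accumulate per gene edge as the species-path length between images minus
one, plus one if the parent is a duplication. This is the parsimony
duplication count (verified against a brute-force minimum over all valid
embeddings on small instances). Species-tree polytomies are resolved
deterministically (sorted left-comb) with a warning, since any resolution
can inflate the counts at those nodes.

## Size laws

Geometric pmf convention: `p(1−p)^(k−1)` on k ≥ 1, so the parameter is a
success probability and the untruncated ML estimate is 1/mean. The
truncated fit renormalizes the pmf on a window (default 1–12) and solves
the score equation numerically (bounded scalar minimization of the
negative log-likelihood). The Yule–Simon pmf is `α·B(k, α+1)`; α is
tested at fixed values (1 for subtree sizes, 2 for duplication counts)
rather than estimated when reproducing the two-law contrast, because the
scientific question is whether a fixed heavy-tail law fits, not which α
does; a numeric ML estimator is nevertheless provided.

χ² goodness-of-fit pools adjacent support values from the low end until
each bin's expected count reaches 5 (remainder merged into the last bin),
and df = bins − 1 − ddof with ddof = 1 when the tested parameter was
estimated from the same sample. The empirical-background mode rescales a
background histogram to the observed total and uses ddof = 0.

The permutation Spearman test reports
`p = (1 + #{|ρ*| ≥ |ρ|}) / (1 + n_perm)` (two-sided, default n_perm =
10⁵, vectorized); the smallest achievable p is 1/(n_perm+1), so extreme
claims are floors. Intronization: β̂ = Σxy/Σx² with the usual t statistic
on n−1 residual df; units are introns per substitution per site.

## Synthetic data: what it emulates and what it does not

The generator produces the exact input formats the pipeline consumes,
fully determined by one seed. The demo taxonomy has the structural
features that drive the classifier: a root polytomy of kingdoms, an
unresolved eukaryote radiation (so ambiguous placements exist), a
resolved opisthokont clade above the focal kingdom (so congruent
placements exist), bacterial phyla as donors, and a binary species tree
of 15 target fungi in three phyla.

Planted transfers nest a focal clade two branchings deep in one donor
phylum (`supported`), between two eukaryote lineages that are separate
children of the radiation (`ambiguous` — weak by construction under the
all-binarizations rule), or beside a metazoan inside the resolved
opisthokont ancestor (`congruent`). Subtree sizes are drawn from the
generative model under study: Geometric(p = 0.47) for neutral
birth–death, Yule–Simon(α = 1) for preferential attachment, matching the
parameter values the two laws take in the motivating data set; sizes are
capped at 40 leaves for tractability. Branch lengths are Exponential
(mean 0.3 substitutions/site); supports are drawn uniformly above a
floor of 0.97, with an optional fraction of trees given a weak stem to
exercise the support gate. Contaminant contigs carry no vertical
evidence; stage-2-only contigs carry a homolog but no focal top hit —
both recovered exactly by construction, which is what the filter's
recall/precision 1.0 statement means (and all it means).

What the simulation does **not** emulate: sequence-level evolution (no
alignments, no substitution-model misspecification), gene-tree estimation
error, long-branch attraction, incomplete lineage sorting, rate
variation, or partially contaminated contigs. Passing on synthetic data
therefore demonstrates the correctness of the combinatorial and
statistical machinery under its stated model, not robustness of upstream
tree inference.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `min_support` | 0.95 | normalized support | conservative gate on the three defining edges; 0–100 scales auto-detected and divided by 100 |
| `max_focal_fraction` | 0.5 | fraction | the plain reading of a "predominantly nonfocal" cluster |
| `max_len` | 2000 | aa | screens out multidomain/ORF-chimera candidates |
| hit thresholds | 1e-5 / 0.5 | e-value / query coverage | standard permissive first-stage homology |
| size window | 1–12 | subtree size | the range where both candidate laws put enough mass to bin at expected ≥ 5 |
| domain thresholds | 0.2 / 0.5 | fraction of sequences | loss requires ≥20% presence in *both* neighbor clades; representative requires ≥50% in the subtree and ≥20% in at least one neighbor |
| localization quorum | 0.75 | fraction of labeled targets | a subtree is "consistent" when one label covers three quarters of its target proteins; ties are inconsistent |

## Problem sizes used by the automated checks

The acceptance script runs 500 oracle-equivalence fixtures (restricted
taxonomies capped at 2,000 binarizations each), 200 planted supported
trees, 100 ambiguous trees, 1,000 contigs, 200 replicates of the n = 226
heavy-tail contrast, 40 reconciliation instances of up to 10 leaves, and
an 800-point intronization simulation — sizes chosen so every check
exercises the asymptotics it claims while the whole script completes in
seconds.

## Known limitations

* Transfers *within* the focal kingdom are invisible by design: the
  classifier conditions on an all-focal subtree with nonfocal neighbors.
* Clustering reconstructs homology groups as connected components of
  passing hits — permissive by intention; no Markov clustering.
* Domain gains/losses are binary per protein at clan level; copy-number
  changes and per-residue conflicting signals are out of scope.
* The neighbor-clade walk is a reconstruction of an algorithm whose
  original specification is not public; it is validated against its own
  enumeration oracle, not against the original implementation.
* Taxonomy corrections (merged or renamed taxa) are the caller's
  responsibility via an edited input table; only scientific names from
  the names file are attached.
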