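# Methods

## Overview

`oncopath` scores every directed edge of an integrated gene-interaction
network with an *oncogenic potential* (OP) in [0, 1] and then uses those
scores as edge weights to extract, for a chosen source/target gene pair, the
signaling subnetwork spanned by the highest-scoring paths.  The premise is
topological: genes involved in cancer signaling occupy distinctive positions
in the interactome, so an edge's propensity to transmit oncogenic signal can
be predicted from the network centralities of its two endpoints alone.

## The integrated network

Three typed edge classes are merged over a shared integer gene-id namespace
(Entrez-style):

- **physical** protein–protein interactions, undirected in the source data
  and expanded into both directed edges (a physical contact transmits signal
  either way);
- **regulatory** transcription-factor → target edges, inherently directed;
- **metabolic** enzyme → enzyme edges derived from a reaction table: E1→E2
  whenever a reaction catalysed by E1 produces a metabolite consumed by a
  reaction catalysed by E2, with reversible reactions playing both roles.
  Ubiquitous *currency metabolites* are excluded, either as an explicit list
  (default: ADP, ATP, H+, H2O, NADP+, NADPH, Pi, PPi) or as the top-m
  most-connected metabolites of the table (m = 8 by default).

An ordered pair may carry up to three typed parallel edges.  They are stored
distinctly, so per-type edge counts are additive, but all centrality and
path computations run on the collapsed simple digraph, and all typed
variants of an ordered pair share one OP (the features depend only on the
endpoints).  Self-interactions are dropped throughout: a loop at one node
has no signal-flow meaning here.

## Centrality features

Per gene, on the collapsed digraph: degree k (in + out), clustering
coefficient C on the undirected projection (C = 2e/(n(n−1)), 0 when n < 2),
unnormalized directed betweenness B = Σ σ_st(i)/σ_st, and closeness along
outgoing edges Cl = (r/S)·(r/(N−1)) with r the number of reachable nodes and
S the sum of their distances.

Two conventions are fixed here because more than one defensible choice
exists.  Clustering is computed undirected (the measure's classical
definition; directed variants disagree with each other and gain nothing for
a feature that trees will threshold).  The closeness scaling by r/(N−1)
keeps values of partially-reaching nodes comparable across components and
bounded in [0, 1]; without it, a node reaching only one near neighbor would
out-score a hub reaching the whole network.  Betweenness is left
unnormalized: any monotone rescaling is equivalent for tree learners, so
the raw pair-fraction sum is kept for transparency.

## Training and the shuffled-label control

An edge's feature vector is the concatenation (k, C, B, Cl)-of-source ++
(k, C, B, Cl)-of-target — 8 features.  This edge-level assembly is the
minimal construction that makes edges classifiable from gene-level
centralities, and it is order-sensitive on purpose: direction matters.

Balanced *normal* datasets each contain the full positive set (known
oncogenic interactions; 265 by default) plus an equal-size uniform sample,
without replacement per dataset and independent across datasets, of the
remaining network edges as negatives.  Negatives are a contaminated
background — some unlabeled edges may truly be oncogenic — which bounds the
achievable precision; the balanced design keeps chance level at 0.5.
*Shuffled* datasets are copies with the label column uniformly permuted:
models trained on them calibrate chance, and any gap between normal and
shuffled performance measures genuine signal rather than overfitting.

The base learner is a C4.5-style decision tree (entropy splits, minimum
leaf size 2) with Laplace-smoothed leaf probabilities p = (n_pos+1)/(n+2);
bagging fits one tree per bootstrap replicate (20 by default) and averages
leaf probabilities.  The scikit-learn tree provides the splitter; the
bagging wrapper and Laplace smoothing are implemented here because the
stock bagging ensemble exposes no smoothed probabilities.

Evaluation is stratified 10-fold cross-validation of the bagged ensemble:
per fold, recall and precision at the 0.5 score threshold and a rank-based
AUC (the Mann–Whitney statistic on held-out scores, ties counted half);
fold values are averaged per model and medians are reported across models.
Precision of a fold with no positive calls is reported as 0, the
conservative convention.  Normal and shuffled groups are compared per
measure with a two-sided Mann–Whitney U test at significance threshold
0.005; the test is distribution-free, which matters for bounded, skewed CV
metrics.  Ensemble-level evaluation (10 fold values per model) is used
rather than per-bag evaluation; the two differ only in the granularity of
the averaging.

## OP assignment and enrichment

All models trained on normal datasets are merged into a vote ensemble whose
output is the arithmetic mean of member outputs — with equal bag sizes this
equals the mean over every constituent tree (asserted numerically in the
tests).  That mean is the edge's OP.  Over-representation of a designated
edge set among edges with OP above a threshold (default 0.7) is assessed
with an upper-tail hypergeometric test.

## Path enumeration (REA)

OP is converted to cost by c = 1 − OP, so path weight W = n − C equals the
summed OP of the path's n edges and maximizing ΣOP is minimizing cost at
fixed length.  The K cheapest directed paths between the pair are
enumerated with the recursive enumeration algorithm: one backward Dijkstra
pass gives every node its optimal suffix path to the target; the k-th path
at a node is popped from a lazily refilled per-node candidate heap (when
the (k−1)-th path continues via neighbor u's j-th suffix, the one new
candidate is u's (j+1)-th suffix, computed on demand).  Paths are walks —
they may revisit nodes — which is the algorithm's native semantics; an
optional `simple_only` filter drops node-repeating walks before subnetwork
construction, and an optional `max_hops` guard caps walk length for graphs
with zero-cost cycles (OP = 1 cycles), where equal-cost walks of every
length exist.

Determinism: paths are totally ordered by (cost, edge count, node
sequence).  The order is prefix-monotone — prepending an edge preserves
it — which is the property REA's correctness argument needs, and unlike a
pure lexicographic rule it remains a well-founded order in the presence of
zero-cost cycles.  The implementation is validated against an independent
uniform-cost search over walk space on hundreds of random instances, with
edge costs drawn from a dyadic grid so that float sums are exact and even
tie order must match.

The published K ladder (41 values, 100 … 3 000 000) is the default and is
fully configurable; desk-scale graphs need only its lower rungs.  Because
enumeration order is deterministic, one run at the ladder's maximum yields
every smaller K group as a prefix, and the extraction routine exploits
this instead of re-running the enumerator per rung.

## Subnetwork construction and selection

Per K group: weights W = n − C are min–max normalized,
W_norm = (W − W_min)/(W_max − W_min).  When all weights coincide the
formula is undefined; every path is then assigned W_norm = 1, the only rule
that keeps all 20 thresholds meaningful.  Twenty candidates are built for
θ = 0, 0.05, …, 0.95, candidate θ merging the edges of all paths with
W_norm ≥ θ (candidate edge sets are therefore nested in θ).  The candidate
with the highest average clustering coefficient — mean over the candidate's
own nodes of undirected local clustering, nodes with fewer than two
neighbors contributing 0 — is the per-K winner; ties prefer fewer edges,
then larger θ, i.e. the most specific subnetwork.  The candidate's own
node set is the only defensible universe for the average; averaging over
all network nodes would reward nothing but size.  The final subnetwork for
the pair is the per-K winner with the highest average clustering
coefficient (same tie rule, then the smaller K).  No deduplication of
walks with identical edge sets is performed before normalization.

Clustering rewards locally dense path bundles: many high-weight paths that
share genes and interconnect indicate a coherent signaling module rather
than a loose collection of detours.

## Evaluation against linear pathways

A reference linear pathway (an ordered gene cascade, 3–8 edges typical) is
scored by its *success rate*: the fraction of its consecutive directed
edges present in the extracted subnetwork, matched as directed pairs
ignoring interaction type.  Aggregates: fractions of pairs at success 1.0
and ≥ 0.5, and Kendall tau-b correlations (tie-corrected, as both success
rates and sizes tie heavily) of success against pathway size and against
the subnetwork:pathway size ratio.

## Synthetic data

The generator grows a Barabási–Albert skeleton (m = 3 attachments) and
types each link by a 70/20/10 physical/regulatory/metabolic mixture,
echoing the dominance of physical interactions in the real composite
network; physical links become both directed edges, others one random
orientation.  The bidirectional majority keeps ≥ 90% of ordered pairs in
the giant component mutually reachable.  Positives (265 by default) are
drawn from edges whose endpoints both lie in the top-decile **degree**
stratum, a deliberate simplification of a general high-centrality stratum:
degree is itself a feature and strongly correlated with betweenness in
preferential-attachment graphs, so the planted signal is learnable by
construction, and `centrality_shift = 0` gives the uniform null case.
Backbones are explicit directed chains inserted between two genes and
returned as reference pathways; tests raise their OP (0.95 by default)
against a low-OP background to check exact recovery.

What the generator does not emulate: assortativity and motif structure of
curated interactomes, database-specific noise, confidence scores, and any
non-centrality signal distinguishing oncogenic edges.  Passing tests
therefore demonstrate that the machinery recovers a planted centrality
signal and planted path structure — not that centralities suffice for real
oncogenic interactions, which is an empirical claim about real data.

## Problem sizes and numerical choices

The bundled benchmark (`oncopath.benchmark.run_benchmark`, also driven by
`scripts/acceptance.py`) runs the evaluation study at desk scale: 2000
genes, 265 positives, 50 normal datasets × 4 shuffles (200 shuffled
models), 20 bags, 10 folds — sizes chosen so the full study runs in a few
minutes on one core while keeping ≥ 50 models per group for stable
medians.  All randomness flows from one master seed through named SHA-256
substreams (`derive_seed`), so every stage is independently reproducible;
seeds stay below 2^31.  Float equality in the REA suffix-tree construction
uses exact comparison, which is correct for the Dijkstra-derived optimum
and affects only tie-breaking among costs equal to rounding error.

## Known limitations

- Headline performance on the real integrated human interactome (median
  recall/precision/AUC of the original study) is not reproducible without
  the third-party database downloads; the package reproduces the method and
  its chance-level and planted-signal behavior.
- The bagged-tree learner is C4.5-*style*, not a bit-exact reimplementation
  of any particular legacy tree package (no subtree-raising pruning).
- REA enumerates walks; on graphs with many near-zero costs the number of
  short cheap walks grows quickly, and `max_hops` may be needed at extreme
  K.
- SBML/BioPAX parsing and live database access are out of scope; inputs are
  plain TSV edge lists and the bespoke reaction-table format.
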