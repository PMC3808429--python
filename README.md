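# oncopath

Oncogenic-potential edge scoring and signaling-subnetwork extraction on
integrated gene-interaction networks.

## The problem

A cancer cell arises when multiple signaling interactions are disturbed at
once, so the interesting object is not a single gene but the *subnetwork*
that carries an oncogenic signal from a trigger gene (say, a mutated
kinase) to a target gene (say, a cell-cycle regulator).  Databases record
hundreds of thousands of physical, regulatory and metabolic interactions,
but only a few hundred are annotated as oncogenic.  `oncopath` is for
systems biologists who want to (1) score *every* directed edge of an
integrated interactome by its propensity to transmit oncogenic signal and
(2) extract, for any gene pair of interest, the signaling subnetwork formed
by the highest-scoring paths between them.

## The method

**Scoring.**  Each edge is represented by the network centralities of its
two endpoints — degree k, clustering coefficient C, betweenness B and
closeness Cl, giving an 8-vector (k, C, B, Cl)ₛ ++ (k, C, B, Cl)ₜ.  Many
balanced training sets are built, each containing all known oncogenic
interactions plus an equal-size random sample of other edges; a bagged
ensemble of C4.5-style decision trees (20 bootstrap replicates each) is
trained per set, and all models are merged into a vote ensemble whose
averaged probability is the edge's *oncogenic potential* OP ∈ [0, 1].
Label-shuffled copies of every training set calibrate chance: models
trained on permuted labels must score at recall ≈ precision ≈ AUC ≈ 0.5 in
10-fold cross-validation, and a Mann–Whitney test (p < 0.005) confirms the
real models sit significantly above them.

**Extraction.**  OP becomes an edge cost c = 1 − OP, and the K cheapest
directed paths between the pair are enumerated with the recursive
enumeration algorithm (REA).  Each path of n edges gets weight W = n − C =
Σ OP, min–max normalized within the K group; 20 candidate subnetworks merge
the paths with normalized weight ≥ θ for θ = 0, 0.05, …, 0.95, and the
candidate with the highest average clustering coefficient wins.  Repeating
over a ladder of K values and keeping the best per-K winner yields the
final subnetwork.  Extracted subnetworks are evaluated against reference
linear pathways by the fraction of pathway edges they contain.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

Everything below runs on a seeded synthetic network (no downloads); the
generator plants a positive edge set with a centrality shift and a
high-score backbone chain so each stage has known ground truth.

```python
import oncopath as op

cfg = op.SynthConfig(n_genes=500, n_positives=60, seed=42)
net = op.generate_network(cfg)
cent = op.centrality_table(net)
positives = op.plant_positive_edges(net, cfg)

datasets = op.sample_normal_datasets(net, cent, positives, n_datasets=10,
                                     seed=op.derive_seed(0, "negatives"))
models, reports, shuffled = [], [], []
for i, ds in enumerate(datasets):
    models.append(op.train_bagged_trees(ds, n_bags=20, seed=op.derive_seed(0, f"bag/{i}")))
    reports.append(op.cross_validate(ds, 10, 20, seed=op.derive_seed(0, f"cv/{i}")))
    for j, sh in enumerate(op.shuffle_labels(ds, 2, seed=op.derive_seed(0, f"shuffle/{i}"))):
        shuffled.append(op.cross_validate(sh, 10, 20, seed=op.derive_seed(0, f"cv/{i}/{j}")))
cmp = op.compare_normal_vs_shuffled(reports, shuffled)

scored = op.assign_scores(net, cent, op.combine_models(models))
enr = op.enrichment_test(scored, set(positives), threshold=0.7)

olp = op.plant_backbone(net, 7, 480, 4, seed=1)
boosted = op.ScoredNetwork(net, op.boost_backbone_scores(scored.op, olp, 0.95))
res = op.extract_signaling_subnetwork(boosted, 7, 480, k_ladder=[100, 200, 500, 1000])
```

Output:

```
normal medians:   {'recall': 1.0, 'precision': 0.936, 'auc': 0.945}
shuffled medians: {'recall': 0.492, 'precision': 0.488, 'auc': 0.482}
p-values:         {'recall': '9.69e-06', 'precision': '1.20e-05', 'auc': '1.20e-05'}
enrichment: 60/223 high-OP edges are known positives (population 60/2519), p = 2.136e-67
extracted subnetwork for 7 -> 480: K=500, theta=0.45, 482 paths, 156 edges, avg_cc=0.352
backbone recovery: 1.00
```

Reading this: models trained on true labels recover the planted signal
(median AUC 0.945) while label-shuffled controls sit at chance (≈ 0.49),
and the gap is significant on all three measures.  The known positives
concentrate heavily among edges with OP > 0.7 (hypergeometric
p ≈ 10⁻⁶⁷).  For the pair 7 → 480, the threshold sweep selects the
K = 500, θ = 0.45 candidate — 156 edges merged from 482 high-weight
paths — and it contains all four edges of the planted backbone chain
(recovery 1.00).

The same flow is available from the shell:

```sh
oncopath simulate --out data/
oncopath build-network --regulatory data/network.tsv --out net.graphml
oncopath centralities --net net.graphml --out cent.tsv
oncopath train --net net.graphml --centralities cent.tsv \
    --positives data/positives.tsv --n-datasets 50 --seed 1 --out models/
oncopath score --net net.graphml --centralities cent.tsv --models models/ --out wnet.graphml
oncopath extract --wnet wnet.graphml --source 7 --target 480 \
    --k-ladder 100,200,500,1000 --out subnet.sif
oncopath run --config run.yaml   # the whole pipeline, with a manifest
```

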