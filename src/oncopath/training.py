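"""Balanced edge datasets and bagged decision-tree models.

An interaction is represented by the 8-vector obtained by concatenating the
four centralities of its source gene with those of its target gene, in the
fixed order (degree, clustering, betweenness, closeness).  Training data are
balanced: every dataset contains the full positive set (known oncogenic
interactions) plus an equal-size random sample of the remaining network
edges as negatives.  Label-shuffled copies of these datasets serve as a
control: any apparent skill of a model trained on permuted labels is
overfitting, so the shuffled models calibrate chance level.

The base learner is a C4.5-style decision tree (entropy split criterion,
minimum leaf size 2) with Laplace-smoothed class probabilities at the
leaves; bagging trains one tree per bootstrap replicate and averages the
leaf probabilities, giving a score in [0, 1].

All randomness (negative sampling, label shuffling, bootstrap, fold
assignment) flows from explicit integer seeds; helper :func:`derive_seed`
produces named substreams from a master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .network import InteractionNetwork

FEATURE_NAMES = tuple(
    f"{col}_{end}"
    for end in ("source", "target")
    for col in ("degree", "clustering", "betweenness", "closeness")
)

Edge = tuple[int, int]


def derive_seed(master: int, label: str) -> int:
    """Deterministic named substream seed (< 2**31) from a master seed."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_edge_features(
    cent: pd.DataFrame, edges: list[Edge]
) -> np.ndarray:
    """8-feature matrix, one row per edge in input order.

    Raises ``KeyError`` naming the gene when an endpoint is missing from the
    centrality table.
    """
    for s, t in edges:
        for gene in (s, t):
            if gene not in cent.index:
                raise KeyError(f"gene {gene} missing from centrality table")
    cols = ["degree", "clustering", "betweenness", "closeness"]
    src = cent.loc[[s for s, _ in edges], cols].to_numpy(dtype=float)
    tgt = cent.loc[[t for _, t in edges], cols].to_numpy(dtype=float)
    x = np.hstack([src, tgt])
    if not np.isfinite(x).all():
        raise ValueError("non-finite centrality feature")
    return x


@dataclass
class LabeledEdgeDataset:
    """Balanced edge dataset with oncogenic (1) / non-oncogenic (0) labels."""

    edges: list[Edge]
    X: np.ndarray
    y: np.ndarray
    kind: str  # "normal" or "shuffled"
    seed: int

    def __post_init__(self) -> None:
        n_pos = int(self.y.sum())
        if 2 * n_pos != len(self.y):
            raise ValueError("dataset is not balanced")

    def __len__(self) -> int:
        return len(self.y)


def sample_normal_datasets(
    net: InteractionNetwork,
    cent: pd.DataFrame,
    positives: list[Edge],
    n_datasets: int,
    seed: int,
) -> list[LabeledEdgeDataset]:
    """Positives plus per-dataset uniform negative samples, all balanced.

    Each dataset reuses the full positive set and draws, without replacement
    within the dataset and independently across datasets, an equal number of
    non-positive network edges as negatives.
    """
    if not positives:
        raise ValueError("need at least one positive edge")
    pos_set = set(positives)
    pool = sorted(net.simple_edges() - pos_set)
    if len(pool) < len(positives):
        raise ValueError(
            f"only {len(pool)} non-positive edges available for "
            f"{len(positives)} negatives"
        )
    x_pos = build_edge_features(cent, positives)
    rng = np.random.default_rng(seed)
    datasets = []
    for i in range(n_datasets):
        idx = rng.choice(len(pool), size=len(positives), replace=False)
        negatives = [pool[j] for j in idx]
        x_neg = build_edge_features(cent, negatives)
        datasets.append(
            LabeledEdgeDataset(
                edges=list(positives) + negatives,
                X=np.vstack([x_pos, x_neg]),
                y=np.concatenate(
                    [np.ones(len(positives), int), np.zeros(len(negatives), int)]
                ),
                kind="normal",
                seed=seed,
            )
        )
    return datasets


def shuffle_labels(
    ds: LabeledEdgeDataset, n_shuffles: int, seed: int
) -> list[LabeledEdgeDataset]:
    """Label-permuted control copies; features untouched, label multiset kept."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(ds))
        out.append(
            LabeledEdgeDataset(
                edges=list(ds.edges),
                X=ds.X,
                y=ds.y[perm],
                kind="shuffled",
                seed=seed,
            )
        )
    return out


class BaggedTreeModel:
    """Bagging over C4.5-style trees with Laplace-smoothed leaves.

    ``n_bags`` bootstrap replicates (with replacement, same size as the
    training set) each fit one entropy-criterion decision tree; the model's
    output for an edge is the mean over trees of the Laplace-smoothed
    positive-class probability of the leaf the edge falls into:
    p = (n_pos + 1) / (n + 2).
    """

    def __init__(self, n_bags: int = 20, seed: int = 0) -> None:
        self.n_bags = n_bags
        self.seed = seed
        self._trees: list[DecisionTreeClassifier] = []
        self._leaf_probs: list[dict[int, float]] = []
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTreeModel":
        if len(np.unique(y)) < 2:
            raise ValueError("training data contain a single class")
        rng = np.random.default_rng(self.seed)
        n = len(y)
        self._trees, self._leaf_probs = [], []
        self.n_features_ = X.shape[1]
        for b in range(self.n_bags):
            idx = rng.integers(0, n, size=n)
            xb, yb = X[idx], y[idx]
            tree = DecisionTreeClassifier(
                criterion="entropy",
                min_samples_leaf=2,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(xb, yb)
            leaves = tree.apply(xb)
            probs: dict[int, float] = {}
            for leaf in np.unique(leaves):
                mask = leaves == leaf
                probs[int(leaf)] = (yb[mask].sum() + 1.0) / (mask.sum() + 2.0)
            self._trees.append(tree)
            self._leaf_probs.append(probs)
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if not self._trees:
            raise RuntimeError("model is not fitted")
        acc = np.zeros(len(X))
        for tree, probs in zip(self._trees, self._leaf_probs):
            leaves = tree.apply(X)
            acc += np.array([probs[int(leaf)] for leaf in leaves])
        return acc / len(self._trees)

    def tree_probas(self, X: np.ndarray) -> np.ndarray:
        """Per-tree positive-class probabilities, shape (n_trees, n_rows)."""
        return np.vstack(
            [
                np.array([probs[int(leaf)] for leaf in tree.apply(X)])
                for tree, probs in zip(self._trees, self._leaf_probs)
            ]
        )


def train_bagged_trees(
    ds: LabeledEdgeDataset, n_bags: int = 20, seed: int = 0
) -> BaggedTreeModel:
    return BaggedTreeModel(n_bags=n_bags, seed=seed).fit(ds.X, ds.y)


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-based AUC: P(score of a random positive > random negative).

    Equivalent to the Mann–Whitney U statistic divided by n_pos * n_neg,
    with ties counted half.
    """
    if len(scores_pos) == 0 or len(scores_neg) == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([scores_pos, scores_neg]))
    n_pos = len(scores_pos)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * len(scores_neg)))


@dataclass
class FoldCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        # no positive calls at all: report 0, the conservative convention
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0


@dataclass
class PerformanceReport:
    """Fold-averaged cross-validation metrics for one model."""

    recall: float
    precision: float
    auc: float
    folds: list[FoldCounts] = field(default_factory=list)


def cross_validate(
    ds: LabeledEdgeDataset,
    k_folds: int = 10,
    n_bags: int = 20,
    seed: int = 0,
    threshold: float = 0.5,
) -> PerformanceReport:
    """Stratified k-fold CV of the bagged ensemble.

    Per fold, a fresh bagged model is trained on the remaining folds and
    scored on the held-out fold; recall and precision use the 0.5 score
    threshold and AUC is rank-based.  Fold metrics are averaged.
    """
    if len(ds) < k_folds:
        raise ValueError("fewer rows than folds")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
    recalls, precisions, aucs, folds = [], [], [], []
    for f, (train_idx, test_idx) in enumerate(skf.split(ds.X, ds.y)):
        model = BaggedTreeModel(n_bags=n_bags, seed=seed + f + 1)
        model.fit(ds.X[train_idx], ds.y[train_idx])
        scores = model.predict_proba_pos(ds.X[test_idx])
        y = ds.y[test_idx]
        pred = scores >= threshold
        fc = FoldCounts(
            tp=int((pred & (y == 1)).sum()),
            fp=int((pred & (y == 0)).sum()),
            fn=int((~pred & (y == 1)).sum()),
            tn=int((~pred & (y == 0)).sum()),
        )
        folds.append(fc)
        recalls.append(fc.recall)
        precisions.append(fc.precision)
        aucs.append(rank_auc(scores[y == 1], scores[y == 0]))
    return PerformanceReport(
        recall=float(np.mean(recalls)),
        precision=float(np.mean(precisions)),
        auc=float(np.nanmean(aucs)),
        folds=folds,
    )


@dataclass
class ComparisonReport:
    """Normal-vs-shuffled Mann–Whitney comparison per performance measure."""

    medians_normal: dict[str, float]
    medians_shuffled: dict[str, float]
    p_values: dict[str, float]
    significant: dict[str, bool]
    alpha: float


def compare_normal_vs_shuffled(
    normal_reports: list[PerformanceReport],
    shuffled_reports: list[PerformanceReport],
    alpha: float = 0.005,
) -> ComparisonReport:
    """Two-sided Mann–Whitney U test per measure, plus group medians.

    The test is distribution-free, which matters here because CV metric
    distributions over models are bounded and typically skewed.
    """
    if not normal_reports or not shuffled_reports:
        raise ValueError("both report groups must be non-empty")
    med_n, med_s, pvals, sig = {}, {}, {}, {}
    for measure in ("recall", "precision", "auc"):
        a = np.array([getattr(r, measure) for r in normal_reports])
        b = np.array([getattr(r, measure) for r in shuffled_reports])
        med_n[measure] = float(np.median(a))
        med_s[measure] = float(np.median(b))
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        pvals[measure] = p
        sig[measure] = p < alpha
    return ComparisonReport(med_n, med_s, pvals, sig, alpha)
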