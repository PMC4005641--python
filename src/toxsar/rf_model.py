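"""Bagged classification forest with out-of-bag evaluation and
permutation importance.

The classifier is a random forest in the Breiman sense: ``n_tree``
CART trees (Gini impurity, unlimited depth, minimum node size 1), each
fit on a bootstrap resample of the sequences, each split considering
``m_try`` randomly chosen descriptors.  Following the classification
convention of the original Fortran/R implementation used for this kind
of screen, ``m_try`` defaults to floor(p/3) of the p screened motifs
(the sqrt(p) rule is available as an option).

Evaluation is out-of-bag (OOB): each sequence is scored by majority
vote of only those trees whose bootstrap did not contain it, giving an
internal estimate of generalization without a held-out set.  Variable
importance is mean decrease accuracy (MDA): for each tree, the drop in
its OOB accuracy after permuting one feature's OOB values, averaged
over trees.

The bagging bookkeeping (per-tree in-bag/out-of-bag membership, OOB
vote tallies, per-tree MDA permutation) is implemented here on top of
individual scikit-learn decision trees, because per-sequence OOB votes
and per-tree OOB permutation are required outputs of the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor, sqrt
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .kmer_features import FeatureMatrix

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ForestConfig:
    """Training configuration.

    n_tree : number of bootstrap trees (default 1000).
    m_try_rule : "p_over_3" (default), "sqrt_p", or "explicit".
    m_try : used only with m_try_rule="explicit".
    vote_threshold : predicted toxic iff toxic vote fraction exceeds
        this strictly; an exact tie therefore resolves to non-toxic.
    """

    n_tree: int = 1000
    m_try_rule: str = "p_over_3"
    m_try: Optional[int] = None
    seed: int = 0
    vote_threshold: float = 0.5

    def resolve_m_try(self, p: int) -> int:
        if self.m_try_rule == "p_over_3":
            m = max(1, floor(p / 3))
        elif self.m_try_rule == "sqrt_p":
            m = max(1, floor(sqrt(p)))
        elif self.m_try_rule == "explicit":
            if self.m_try is None:
                raise ValueError("m_try_rule='explicit' requires m_try")
            m = int(self.m_try)
        else:
            raise ValueError(f"unknown m_try_rule {self.m_try_rule!r}")
        if not 1 <= m <= p:
            raise ValueError(f"m_try={m} out of range for p={p} features")
        return m


@dataclass(frozen=True)
class Confusion:
    """Binary confusion counts with toxic as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


@dataclass
class ForestResult:
    """A trained forest plus its OOB evaluation and importances."""

    motifs: tuple[str, ...]
    row_ids: tuple[str, ...]
    y: np.ndarray                     # training labels, True = toxic
    oob_vote_fraction: np.ndarray     # toxic vote fraction among OOB trees
    oob_tree_count: np.ndarray        # trees for which each row was OOB
    oob_predictions: np.ndarray       # bool
    confusion: Confusion
    importance: Optional[np.ndarray]         # mean decrease accuracy per motif
    importance_scaled: Optional[np.ndarray]  # MDA / (per-tree SD / sqrt(T))
    importance_rank: Optional[np.ndarray]    # 1 = most important (by raw MDA)
    config: ForestConfig
    m_try: int
    trees: list[DecisionTreeClassifier] = field(repr=False, default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float:
        return self.confusion.specificity

    def importance_table(self) -> pd.DataFrame:
        if self.importance is None:
            raise ValueError("forest was trained with compute_importance=False")
        order = np.argsort(self.importance_rank)
        return pd.DataFrame(
            {
                "motif": [self.motifs[i] for i in order],
                "mean_decrease_accuracy": self.importance[order],
                "mean_decrease_accuracy_scaled": self.importance_scaled[order],
                "rank": self.importance_rank[order],
            }
        )


def _prepare_xy(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    labeled = fm.labeled()
    X = np.ascontiguousarray(labeled.X, dtype=np.float32)
    y = labeled.labels_array()
    return X, y, labeled.row_ids


def train_forest(
    feature_matrix: FeatureMatrix,
    config: ForestConfig = ForestConfig(),
    compute_importance: bool = True,
) -> ForestResult:
    """Fit the bagged forest and evaluate it out-of-bag.

    The feature matrix should already be restricted to the screened
    motifs (see :func:`toxsar.kmer_features.FeatureMatrix.subset_motifs`).
    Reproducible: the same seed, data and configuration give identical
    OOB votes, confusion counts and importances.

    ``compute_importance=False`` skips the per-tree permutation pass
    (the expensive part when p is large); importances come back None.
    The bootstrap draws are unaffected, so OOB predictions are
    identical either way.
    """
    X, y, row_ids = _prepare_xy(feature_matrix)
    n, p = X.shape
    if p == 0:
        raise ValueError("no features left after screening; cannot train")
    if n == 0 or y.all() or not y.any():
        raise ValueError("training requires labeled sequences of both classes")
    m_try = config.resolve_m_try(p)
    # separate streams so skipping the importance pass leaves the
    # bootstrap draws (hence OOB predictions) bitwise unchanged
    ss_boot, ss_perm = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(ss_boot)
    rng_perm = np.random.default_rng(ss_perm)

    trees: list[DecisionTreeClassifier] = []
    votes_toxic = np.zeros(n, dtype=np.int64)
    votes_total = np.zeros(n, dtype=np.int64)
    importance_sum = np.zeros(p, dtype=np.float64)
    importance_sumsq = np.zeros(p, dtype=np.float64)
    importance_trees = 0

    for _ in range(config.n_tree):
        boot = rng.integers(0, n, size=n)
        inbag = np.zeros(n, dtype=bool)
        inbag[boot] = True
        oob = ~inbag
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=m_try,
            min_samples_leaf=1,
            random_state=int(rng.integers(0, _SEED_MOD)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)

        if oob.any():
            Xo = np.ascontiguousarray(X[oob])
            yo = y[oob]
            pred = tree.predict(Xo, check_input=False).astype(bool)
            votes_toxic[oob] += pred
            votes_total[oob] += 1

            if compute_importance:
                # mean decrease accuracy: permute one OOB column at a time
                base_acc = float(np.mean(pred == yo))
                n_oob = Xo.shape[0]
                for j in range(p):
                    perm = rng_perm.permutation(n_oob)
                    saved = Xo[:, j].copy()
                    Xo[:, j] = saved[perm]
                    pred_j = tree.predict(Xo, check_input=False).astype(bool)
                    Xo[:, j] = saved
                    drop = base_acc - float(np.mean(pred_j == yo))
                    importance_sum[j] += drop
                    importance_sumsq[j] += drop * drop
                importance_trees += 1

    if not votes_total.any():
        raise ValueError("no tree had out-of-bag sequences; increase n_tree")
    if compute_importance:
        T = importance_trees
        importance = importance_sum / T
        # scaled variant (z-score over trees), the display convention of
        # the classic randomForest importance output; 0 where the
        # per-tree drops never vary (e.g. constant features)
        if T > 1:
            var = np.maximum(importance_sumsq / T - importance**2, 0.0) * T / (T - 1)
            sd = np.sqrt(var)
        else:
            sd = np.zeros(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            importance_scaled = np.where(sd > 0, importance / (sd / np.sqrt(T)), 0.0)
        # rank 1 = largest raw MDA; ties broken by catalogue position
        order = np.argsort(-importance, kind="stable")
        importance_rank = np.empty(p, dtype=np.int64)
        importance_rank[order] = np.arange(1, p + 1)
    else:
        importance = importance_scaled = importance_rank = None

    no_oob = votes_total == 0
    if no_oob.any():
        warnings.warn(
            f"{int(no_oob.sum())} sequences were in-bag for every tree and have "
            "no OOB prediction; treated as predicted non-toxic",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        frac = np.where(votes_total > 0, votes_toxic / np.maximum(votes_total, 1), np.nan)
    oob_pred = (votes_total > 0) & (np.nan_to_num(frac) > config.vote_threshold)

    tp = int(np.sum(oob_pred & y))
    fn = int(np.sum(~oob_pred & y))
    tn = int(np.sum(~oob_pred & ~y))
    fp = int(np.sum(oob_pred & ~y))

    return ForestResult(
        motifs=feature_matrix.index.motifs,
        row_ids=row_ids,
        y=y,
        oob_vote_fraction=frac,
        oob_tree_count=votes_total,
        oob_predictions=oob_pred,
        confusion=Confusion(tp=tp, fn=fn, tn=tn, fp=fp),
        importance=importance,
        importance_scaled=importance_scaled,
        importance_rank=importance_rank,
        config=config,
        m_try=m_try,
        trees=trees,
    )


def importance_ranking(result: ForestResult) -> pd.DataFrame:
    """Motifs ordered by mean decrease accuracy, most important first."""
    return result.importance_table()


def predict(result: ForestResult, feature_matrix: FeatureMatrix) -> pd.DataFrame:
    """Score new sequences with the full forest (all-tree majority vote).

    The feature matrix columns must match the training motif set
    exactly; a mismatch raises with the missing/extra motif names.
    Returns a frame with the toxic vote fraction and the thresholded
    label per row.
    """
    if feature_matrix.index.motifs != result.motifs:
        missing = set(result.motifs) - set(feature_matrix.index.motifs)
        extra = set(feature_matrix.index.motifs) - set(result.motifs)
        raise ValueError(
            "feature columns do not match the training motif set: "
            f"missing={sorted(missing)}, extra={sorted(extra)}"
        )
    X = np.ascontiguousarray(feature_matrix.X, dtype=np.float32)
    votes = np.zeros(X.shape[0], dtype=np.float64)
    for tree in result.trees:
        votes += tree.predict(X, check_input=False).astype(np.float64)
    frac = votes / len(result.trees)
    return pd.DataFrame(
        {
            "id": list(feature_matrix.row_ids),
            "vote_fraction_toxic": frac,
            "predicted_toxic": frac > result.config.vote_threshold,
        }
    )


def forest_summary(result: ForestResult) -> dict:
    """Plain-dict summary (confusion, per-class metrics, configuration)."""
    c = result.confusion
    return {
        "n_tree": result.config.n_tree,
        "m_try": result.m_try,
        "seed": result.config.seed,
        "tp": c.tp,
        "fn": c.fn,
        "tn": c.tn,
        "fp": c.fp,
        "sensitivity": c.sensitivity,
        "specificity": c.specificity,
        "balanced_accuracy": c.balanced_accuracy,
    }
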