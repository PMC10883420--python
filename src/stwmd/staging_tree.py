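"""CART staging trees on per-class PC1 features.

Trees are binary CART classifiers (Gini impurity, minimum leaf size 2) whose
growth is followed by complexity-parameter pruning: every split whose
training misclassification-risk improvement falls below ``cp`` times the
root risk is removed together with its subtree (``cp`` = 0.05 by default,
the rpart convention for classification trees).  A tree's identity for
stability counting is its *signature* — the sorted multiset of split
features — since across subsamples the informative question is which gene
classes the tree uses, not the exact numeric thresholds or the left/right
order of tied splits.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError


def _as_features(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]




@dataclass
class TreeModel:
    """A grown-then-pruned CART tree.

    The underlying classifier is grown with Gini impurity; ``collapsed``
    marks internal nodes that risk-based pruning turned into leaves, so all
    predictions and the signature are taken from the pruned structure.
    """

    classifier: DecisionTreeClassifier
    feature_names: list[str]
    classes: list[str]
    cp: float
    collapsed: frozenset[int]
    signature: tuple[str, ...]
    training_accuracy: float = float("nan")

    @property
    def n_splits(self) -> int:
        return len(self.signature)

    def _is_leaf(self, i: int) -> bool:
        return i in self.collapsed or self.classifier.tree_.children_left[i] == -1

    def _leaf_of(self, x: np.ndarray) -> int:
        tree = self.classifier.tree_
        i = 0
        while not self._is_leaf(i):
            if x[tree.feature[i]] <= tree.threshold[i]:
                i = tree.children_left[i]
            else:
                i = tree.children_right[i]
        return i

    def predict_proba(self, X) -> np.ndarray:
        """Leaf class proportions of the pruned tree."""
        arr, _ = _as_features(X)
        tree = self.classifier.tree_
        out = np.empty((arr.shape[0], len(self.classes)))
        for row, x in enumerate(arr):
            counts = tree.value[self._leaf_of(x)][0]
            out[row] = counts / counts.sum()
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(proba, axis=1)]

    def to_dict(self) -> dict:
        """JSON-serializable nested structure of the pruned tree."""
        tree = self.classifier.tree_

        def node(i: int) -> dict:
            if self._is_leaf(i):
                counts = tree.value[i][0]
                stage = self.classes[int(np.argmax(counts))]
                return {"leaf": stage, "n": int(tree.n_node_samples[i])}
            return {
                "feature": self.feature_names[tree.feature[i]],
                "threshold": float(tree.threshold[i]),
                "n": int(tree.n_node_samples[i]),
                "left": node(tree.children_left[i]),
                "right": node(tree.children_right[i]),
            }

        return {
            "cp": self.cp,
            "signature": list(self.signature),
            "training_accuracy": self.training_accuracy,
            "tree": node(0),
        }


@dataclass
class CVReport:
    folds: int
    repeats: int
    per_repeat_accuracy: list[float]
    mean_accuracy: float
    auc: dict[str, float]  # one-vs-rest AUC per stage
    macro_auc: float
    roc_points: dict[str, tuple[list[float], list[float]]] = field(default_factory=dict)


@dataclass
class StabilityReport:
    runs: int
    fraction: float
    counts: dict[tuple[str, ...], int]  # signature -> occurrences
    modal_signature: tuple[str, ...]
    modal_count: int

    def feature_occurrences(self, feature: str) -> int:
        """Number of runs whose fitted tree used ``feature`` in any split."""
        return sum(c for sig, c in self.counts.items() if feature in sig)

    def containing(self, features: Sequence[str]) -> int:
        """Number of runs whose signature contains *all* of ``features``."""
        req = set(features)
        return sum(c for sig, c in self.counts.items() if req <= set(sig))


def _prune_by_risk(clf: DecisionTreeClassifier, cp: float) -> frozenset[int]:
    """Per-split pruning on the misclassification-risk scale.

    Walking from the root, a split survives only if it lowers the training
    misclassification risk by at least ``cp * R(root)``; otherwise the whole
    subtree below it is discarded.  This is the classification convention of
    a complexity parameter: with cp = 0.05 a chance-level split cannot pay
    for itself and the tree collapses to the majority class.
    """
    tree = clf.tree_
    n_total = tree.n_node_samples[0]
    counts = tree.value * tree.weighted_n_node_samples[:, None, None]

    def node_risk(i: int) -> float:
        c = counts[i][0]
        return float(c.sum() - c.max()) / n_total

    root_risk = node_risk(0)
    budget = cp * root_risk if root_risk > 0 else 0.0
    collapsed: set[int] = set()

    def walk(i: int) -> None:
        left, right = tree.children_left[i], tree.children_right[i]
        if left == -1:
            return
        improvement = node_risk(i) - node_risk(left) - node_risk(right)
        if improvement < budget - 1e-12:
            collapsed.add(i)
            return
        walk(left)
        walk(right)

    walk(0)
    return frozenset(collapsed)


def _signature(model_tree, names: list[str], collapsed: frozenset[int]) -> tuple[str, ...]:
    """Canonical signature: the sorted multiset of the pruned tree's split features."""
    out: list[str] = []

    def walk(i: int) -> None:
        if i in collapsed or model_tree.children_left[i] == -1:
            return
        out.append(names[model_tree.feature[i]])
        walk(model_tree.children_left[i])
        walk(model_tree.children_right[i])

    walk(0)
    return tuple(sorted(out))


def fit_cart(
    X,
    labels: Sequence[str],
    cp: float = 0.05,
    *,
    min_leaf: int = 2,
    seed: int = 0,
) -> TreeModel:
    """Grow and prune a CART staging tree.

    The tree is grown with Gini impurity (minimum leaf size 2) and then
    pruned top-down: any split whose training misclassification-risk
    improvement falls below ``cp`` times the root risk is collapsed together
    with its subtree.
    """
    arr, names = _as_features(X)
    y = np.asarray([str(v) for v in labels])
    if len(np.unique(y)) < 2:
        raise ConfigurationError("staging tree requires at least two stages")
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError("tree features must be finite")
    clf = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_leaf,
        random_state=seed,
    ).fit(arr, y)
    collapsed = _prune_by_risk(clf, cp)
    model = TreeModel(
        classifier=clf,
        feature_names=names,
        classes=[str(c) for c in clf.classes_],
        cp=cp,
        collapsed=collapsed,
        signature=_signature(clf.tree_, names, collapsed),
    )
    model.training_accuracy = float(accuracy_score(y, model.predict(arr)))
    return model


def repeated_cv(
    X,
    labels: Sequence[str],
    *,
    folds: int = 5,
    repeats: int = 20,
    cp: float = 0.05,
    seed: int = 0,
    min_leaf: int = 2,
) -> CVReport:
    """Repeated stratified k-fold cross-validation with one-vs-rest ROC.

    Folds are re-drawn every repeat from a seeded generator, so the same
    seed reproduces the report exactly.  Held-out scores (leaf class
    proportions) are pooled over all folds and repeats for the ROC curves.
    """
    arr, names = _as_features(X)
    y = np.asarray([str(v) for v in labels])
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < folds]
    if small.size:
        raise ConfigurationError(
            f"stage(s) {list(small)} have fewer samples than folds={folds}"
        )
    rng = np.random.default_rng(seed)
    per_repeat = []
    pooled_scores = []
    pooled_truth = []
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        accs = []
        for train, test in skf.split(arr, y):
            model = fit_cart(
                pd.DataFrame(arr[train], columns=names),
                y[train],
                cp,
                min_leaf=min_leaf,
                seed=int(rng.integers(2**31)),
            )
            pred = model.predict(arr[test])
            accs.append(accuracy_score(y[test], pred))
            proba = model.predict_proba(arr[test])
            # align to the global class list (a fold can miss a class only if
            # stratification failed, which the contract above prevents)
            aligned = np.zeros((len(test), len(classes)))
            for j, c in enumerate(model.classes):
                aligned[:, list(classes).index(c)] = proba[:, j]
            pooled_scores.append(aligned)
            pooled_truth.append(y[test])
        per_repeat.append(float(np.mean(accs)))

    scores = np.vstack(pooled_scores)
    truth = np.concatenate(pooled_truth)
    auc: dict[str, float] = {}
    roc_points: dict[str, tuple[list[float], list[float]]] = {}
    for j, c in enumerate(classes):
        binary = (truth == c).astype(int)
        if binary.min() == binary.max():
            continue
        auc[str(c)] = float(roc_auc_score(binary, scores[:, j]))
        fpr, tpr, _ = roc_curve(binary, scores[:, j])
        roc_points[str(c)] = (fpr.tolist(), tpr.tolist())
    macro = float(np.mean(list(auc.values()))) if auc else float("nan")
    return CVReport(
        folds=folds,
        repeats=repeats,
        per_repeat_accuracy=per_repeat,
        mean_accuracy=float(np.mean(per_repeat)),
        auc=auc,
        macro_auc=macro,
        roc_points=roc_points,
    )


@dataclass
class PairwiseTree:
    pair: tuple[str, str]
    model: TreeModel
    cv: CVReport | None


def pairwise_trees(
    X,
    labels: Sequence[str],
    *,
    cp: float = 0.05,
    seed: int = 0,
    folds: int = 5,
    repeats: int = 20,
    with_cv: bool = True,
) -> list[PairwiseTree]:
    """One staging tree (plus CV) per unordered stage pair."""
    arr, names = _as_features(X)
    y = np.asarray([str(v) for v in labels])
    stages = list(dict.fromkeys(y))
    out = []
    for a, b in combinations(stages, 2):
        mask = np.isin(y, [a, b])
        if len(np.unique(y[mask])) < 2:
            warnings.warn(f"stage pair ({a}, {b}) absent from data; skipped")
            continue
        sub = pd.DataFrame(arr[mask], columns=names)
        model = fit_cart(sub, y[mask], cp, seed=seed)
        cv = None
        if with_cv:
            cv = repeated_cv(
                sub, y[mask], folds=folds, repeats=repeats, cp=cp, seed=seed
            )
        out.append(PairwiseTree(pair=(a, b), model=model, cv=cv))
    return out


def stability_analysis(
    X,
    labels: Sequence[str],
    *,
    runs: int = 100,
    fraction: float = 0.8,
    cp: float = 0.05,
    seed: int = 0,
) -> StabilityReport:
    """Signature recurrence over repeated stratified subsample refits.

    Each run refits the tree on a stratified ``fraction`` subsample and
    records the split-feature signature; the report maps signatures to
    occurrence counts (thresholds are deliberately ignored — across
    subsamples they jitter while the feature identity is the finding).
    """
    arr, names = _as_features(X)
    y = np.asarray([str(v) for v in labels])
    classes = np.unique(y)
    takes = {}
    for c in classes:
        n_c = int((y == c).sum())
        n_take = int(round(fraction * n_c))
        if n_take < 1:
            raise ConfigurationError(
                f"fraction {fraction} empties stage {c!r} ({n_c} samples)"
            )
        takes[c] = n_take
    rng = np.random.default_rng(seed)
    counter: Counter[tuple[str, ...]] = Counter()
    for _ in range(runs):
        idx = np.concatenate(
            [
                rng.choice(np.nonzero(y == c)[0], size=takes[c], replace=False)
                for c in classes
            ]
        )
        model = fit_cart(
            pd.DataFrame(arr[idx], columns=names),
            y[idx],
            cp,
            seed=int(rng.integers(2**31)),
        )
        counter[model.signature] += 1
    modal, modal_count = counter.most_common(1)[0]
    return StabilityReport(
        runs=runs,
        fraction=fraction,
        counts=dict(counter),
        modal_signature=modal,
        modal_count=modal_count,
    )
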