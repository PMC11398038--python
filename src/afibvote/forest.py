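"""Bagged decision-tree ensemble with explicit out-of-bag bookkeeping.

The voting stage and the permutation-importance ranking both need to know,
for every tree, exactly which training rows were in its bootstrap sample.
Bootstrapping, vote aggregation, tie-breaking and OOB error live here; the
per-tree axis-aligned learner is a standard CART tree (Gini impurity,
sqrt(p) candidate features per split, grown to purity).

The continuous ensemble output is the per-class fraction of hard tree
votes; majority-vote ties break toward non-AFib, then noise, then AFib,
i.e. toward the fewest false AFib alarms.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .records import TIE_PRIORITY

DEFAULT_N_TREES = 500


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def _data_digest(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.asarray(y).astype(str).tobytes())
    return h.hexdigest()[:16]


def _tie_rank(classes: np.ndarray,
              priority: tuple[str, ...] = TIE_PRIORITY) -> np.ndarray:
    """Lower rank wins ties; unknown labels fall back to lexical order."""
    ranks = []
    extra = sorted(str(c) for c in classes if str(c) not in priority)
    for c in classes:
        c = str(c)
        ranks.append(priority.index(c) if c in priority
                     else len(priority) + extra.index(c))
    return np.asarray(ranks)


@dataclass
class TreeEnsemble:
    """A fitted bagged forest plus its bootstrap/OOB membership."""

    trees: list[DecisionTreeClassifier]
    oob_mask: np.ndarray                 # (n_trees, n_train) True where OOB
    classes_: np.ndarray
    feature_names: list[str]
    seed: int
    n_train: int
    data_digest: str
    hyperparams: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": self.seed,
            "n_train": self.n_train,
            "classes": [str(c) for c in self.classes_],
            "feature_names": self.feature_names,
            "data_digest": self.data_digest,
            "hyperparams": self.hyperparams,
        }
        (path / "ensemble.json").write_text(json.dumps(meta, indent=2))
        joblib.dump({"trees": self.trees, "oob_mask": self.oob_mask},
                    path / "trees.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "TreeEnsemble":
        path = Path(path)
        meta = json.loads((path / "ensemble.json").read_text())
        blob = joblib.load(path / "trees.joblib")
        return cls(trees=blob["trees"], oob_mask=blob["oob_mask"],
                   classes_=np.asarray(meta["classes"]),
                   feature_names=list(meta["feature_names"]),
                   seed=int(meta["seed"]), n_train=int(meta["n_train"]),
                   data_digest=meta["data_digest"],
                   hyperparams=meta["hyperparams"])

    # -- internals ---------------------------------------------------------
    def _check_columns(self, names: list[str]) -> None:
        if names != self.feature_names:
            raise ValueError(
                f"feature columns {names} do not match training columns "
                f"{self.feature_names}"
            )

    def _check_training_data(self, X: np.ndarray, y: np.ndarray) -> None:
        if X.shape[0] != self.n_train or _data_digest(X, y) != self.data_digest:
            raise ValueError(
                "OOB computations require the exact training data the "
                "ensemble was fitted on (row order included)"
            )

    def _vote_counts(self, X: np.ndarray,
                     tree_subset: np.ndarray | None = None) -> np.ndarray:
        class_index = {c: i for i, c in enumerate(self.classes_)}
        counts = np.zeros((X.shape[0], self.classes_.size))
        trees = (self.trees if tree_subset is None
                 else [self.trees[i] for i in np.flatnonzero(tree_subset)])
        for tree in trees:
            pred = tree.predict(X)
            for i, c in enumerate(pred):
                counts[i, class_index[c]] += 1
        return counts

    def _majority(self, counts: np.ndarray) -> np.ndarray:
        # primary key: votes; equal-vote ties resolved by lower tie rank
        ranks = _tie_rank(self.classes_)
        key = counts * (ranks.max() + 1) - ranks[None, :]
        return self.classes_[np.argmax(key, axis=1)]


def fit_forest(X, y, n_trees: int = DEFAULT_N_TREES, seed: int = 0,
               *, min_samples_leaf: int = 1,
               max_features: str | int | float = "sqrt") -> TreeEnsemble:
    """Fit ``n_trees`` CART trees on bootstrap resamples of (X, y).

    Every bootstrap draws n rows with replacement; rows left out of a
    tree's sample are recorded as that tree's out-of-bag set.  Fully
    deterministic for a fixed seed.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    if Xm.shape[0] == 0 or Xm.shape[1] == 0:
        raise ValueError("empty training matrix")
    if Xm.shape[0] != y.size:
        raise ValueError("X and y must have the same number of rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels must contain at least 2 classes")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")

    n = Xm.shape[0]
    rng = np.random.default_rng(seed)
    trees: list[DecisionTreeClassifier] = []
    oob_mask = np.zeros((n_trees, n), dtype=bool)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob_mask[t] = ~np.isin(np.arange(n), idx)
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(Xm[idx], y[idx])
        trees.append(tree)

    covered = oob_mask.any(axis=0)
    if n_trees < 50 or not covered.all():
        warnings.warn(
            f"n_trees={n_trees}: {int((~covered).sum())} training rows are "
            "in-bag for every tree; OOB estimates exclude such rows",
            stacklevel=2,
        )
    return TreeEnsemble(
        trees=trees, oob_mask=oob_mask, classes_=classes,
        feature_names=names, seed=seed, n_train=n,
        data_digest=_data_digest(Xm, y),
        hyperparams={"n_trees": n_trees, "min_samples_leaf": min_samples_leaf,
                     "max_features": str(max_features), "criterion": "gini"},
    )


def forest_scores(ens: TreeEnsemble, X) -> pd.DataFrame:
    """Per-row class vote-fractions (columns ordered as ``ens.classes_``).

    The AFib column is the continuous score used for ROC analysis.
    """
    Xm, names = _as_matrix(X)
    ens._check_columns(names)
    counts = ens._vote_counts(Xm)
    frac = counts / ens.n_trees
    return pd.DataFrame(frac, columns=[str(c) for c in ens.classes_])


def forest_predict(ens: TreeEnsemble, X) -> np.ndarray:
    """Hard majority-vote labels with the documented tie-break."""
    Xm, names = _as_matrix(X)
    ens._check_columns(names)
    return ens._majority(ens._vote_counts(Xm))


def oob_error(ens: TreeEnsemble, X, y) -> float:
    """Out-of-bag misclassification rate on the training data.

    Each row is predicted by majority vote among only the trees for which
    it was out-of-bag; rows in-bag everywhere are excluded from the
    denominator.
    """
    Xm, names = _as_matrix(X)
    ens._check_columns(names)
    y = np.asarray(y)
    ens._check_training_data(Xm, y)
    class_index = {c: i for i, c in enumerate(ens.classes_)}
    counts = np.zeros((ens.n_train, ens.classes_.size))
    for t, tree in enumerate(ens.trees):
        rows = np.flatnonzero(ens.oob_mask[t])
        if rows.size == 0:
            continue
        pred = tree.predict(Xm[rows])
        for r, c in zip(rows, pred):
            counts[r, class_index[c]] += 1
    covered = counts.sum(axis=1) > 0
    pred_labels = ens._majority(counts[covered])
    return float(np.mean(pred_labels != y[covered]))


def per_tree_oob_errors(ens: TreeEnsemble, X, y) -> np.ndarray:
    """Each tree's error on its own OOB rows (NaN if a tree has none)."""
    Xm, names = _as_matrix(X)
    ens._check_columns(names)
    y = np.asarray(y)
    ens._check_training_data(Xm, y)
    errs = np.full(ens.n_trees, np.nan)
    for t, tree in enumerate(ens.trees):
        rows = np.flatnonzero(ens.oob_mask[t])
        if rows.size:
            errs[t] = np.mean(tree.predict(Xm[rows]) != y[rows])
    return errs
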