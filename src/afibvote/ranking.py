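"""Permutation-based out-of-bag feature importance and top-k selection.

For every candidate feature (a base detector's output column or a scalar
feature) and every tree, the feature's values are shuffled within that
tree's out-of-bag rows and the increase in the tree's OOB error is
recorded.  The importance is the mean increase across trees and repeats;
an uninformative feature's importance converges to zero, while a feature
the trees rely on produces a large error increase when destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import TreeEnsemble, _as_matrix, per_tree_oob_errors


@dataclass
class RankingResult:
    """Per-feature OOB-error increases and the induced rank order."""

    feature_names: list[str]
    importances: np.ndarray      # mean OOB-error increase per feature
    standard_errors: np.ndarray  # across-tree SE of the per-tree increases
    ranks: np.ndarray            # 1 = most important
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "importance": self.importances,
            "se": self.standard_errors,
            "rank": self.ranks,
        }).sort_values("rank").reset_index(drop=True)


def permutation_importance(
    ens: TreeEnsemble, X, y, n_repeats: int = 5, seed: int = 0
) -> RankingResult:
    """OOB permutation importance of every column of the training matrix.

    Shuffles are seeded independently per (feature, tree, repeat), so the
    full ranking is reproducible.  A constant column has importance exactly
    zero since permutation cannot change it.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    Xm, names = _as_matrix(X)
    ens._check_columns(names)
    y = np.asarray(y)
    baseline = per_tree_oob_errors(ens, X, y)

    p = Xm.shape[1]
    tree_rows = [np.flatnonzero(ens.oob_mask[t]) for t in range(ens.n_trees)]
    # per-tree mean increase over repeats; NaN for trees without OOB rows
    increases = np.full((p, ens.n_trees), np.nan)
    for j in range(p):
        col = Xm[:, j]
        for t, tree in enumerate(ens.trees):
            rows = tree_rows[t]
            if rows.size == 0:
                continue
            X_oob = Xm[rows]
            y_oob = y[rows]
            if np.all(col[rows] == col[rows[0]]):
                increases[j, t] = 0.0  # constant within OOB: permutation is a no-op
                continue
            acc = 0.0
            for r in range(n_repeats):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, j, t, r])
                )
                X_perm = X_oob.copy()
                X_perm[:, j] = X_oob[rng.permutation(rows.size), j]
                err = np.mean(tree.predict(X_perm) != y_oob)
                acc += err - baseline[t]
            increases[j, t] = acc / n_repeats

    valid = ~np.isnan(increases)
    importances = np.array([increases[j, valid[j]].mean() for j in range(p)])
    ses = np.array([
        (increases[j, valid[j]].std(ddof=1) / np.sqrt(valid[j].sum())
         if valid[j].sum() > 1 else 0.0)
        for j in range(p)
    ])
    # rank 1 = highest importance; ties broken by smaller column index
    order = np.lexsort((np.arange(p), -importances))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return RankingResult(feature_names=names, importances=importances,
                         standard_errors=ses, ranks=ranks,
                         n_repeats=n_repeats)


def select_top_k(result: RankingResult, k: int) -> list[str]:
    """The ``k`` most important features, in decreasing importance.

    Ties break toward the smaller original column index.
    """
    p = len(result.feature_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    order = np.lexsort((np.arange(p), -result.importances))
    return [result.feature_names[i] for i in order[:k]]
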