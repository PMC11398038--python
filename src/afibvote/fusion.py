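"""The voting algorithm: a 3-class forest fused over selected base detectors.

The fusion model is a 500-tree bagged forest trained on the AFib scores of
the selected base detectors, classifying each record as AFib, non-AFib or
noise by majority vote among the trees.  For deployment the 3-class output
is reduced to a binary AFib decision: the continuous AFib score is the
AFib vote-fraction, and a record is called positive when the score is
greater than or equal to the model threshold (the boundary case counts as
positive, fixed for bit-exact reproducibility).

The threshold is either a uniform 0.5 or a per-dataset operating point:
a seeded stratified subsample of the target dataset is scored, its ROC
computed, and the threshold maximising Youden's J (sensitivity +
specificity - 1) chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .forest import (
    DEFAULT_N_TREES,
    TreeEnsemble,
    fit_forest,
    forest_predict,
    forest_scores,
)
from .records import CLASSES

THRESHOLD_MODES = ("fixed_half", "roc_subsample")


@dataclass
class VotingModel:
    """A fitted fusion forest plus its binary operating point."""

    ensemble: TreeEnsemble
    selected_features: tuple[str, ...]
    threshold: float = 0.5
    threshold_mode: str = "fixed_half"

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise ValueError("selected_features must be non-empty")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def fit_voting_model(
    X_selected: pd.DataFrame,
    y_3class,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> VotingModel:
    """Train the 3-class voting forest on selected base-detector outputs."""
    y = np.asarray(y_3class)
    missing = set(CLASSES) - set(y)
    if missing:
        raise ValueError(f"classes absent from training labels: {sorted(missing)}")
    ens = fit_forest(X_selected, y, n_trees=n_trees, seed=seed)
    return VotingModel(ensemble=ens,
                       selected_features=tuple(X_selected.columns))


def predict(model: VotingModel, X_selected: pd.DataFrame) -> pd.DataFrame:
    """Per-record 3-class label, binary AFib call, and continuous score.

    ``afib_score`` is the AFib vote-fraction; ``binary`` is True when the
    score reaches the model threshold; ``class3`` is the tie-broken
    majority-vote label.
    """
    scores = forest_scores(model.ensemble, X_selected)
    afib = scores["AFib"].to_numpy()
    return pd.DataFrame({
        "class3": forest_predict(model.ensemble, X_selected),
        "binary": afib >= model.threshold,
        "afib_score": afib,
    })


def choose_threshold(
    scores,
    y_binary,
    strategy: str = "roc_subsample",
    calib_fraction: float = 0.2,
    seed: int = 0,
) -> float:
    """Operating-point selection for the binary reduction.

    ``fixed_half`` returns the uniform 0.5.  ``roc_subsample`` draws a
    seeded stratified subsample of ``calib_fraction`` of the records,
    computes its ROC, and returns the score threshold maximising Youden's
    J; the returned value is clipped to [0, 1] so the >= decision rule
    stays well-defined.
    """
    if strategy not in THRESHOLD_MODES:
        raise ValueError(f"strategy must be one of {THRESHOLD_MODES}")
    if strategy == "fixed_half":
        return 0.5
    if not 0.0 < calib_fraction <= 1.0:
        raise ValueError("calib_fraction must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_binary)
    if y.dtype.kind not in "bi":
        y = y == "AFib"
    y = y.astype(bool)

    if calib_fraction < 1.0:
        rng = np.random.default_rng(seed)
        idx_parts = []
        for cls in (True, False):
            rows = np.flatnonzero(y == cls)
            take = max(int(round(calib_fraction * rows.size)), 1)
            idx_parts.append(rng.choice(rows, size=take, replace=False))
        idx = np.sort(np.concatenate(idx_parts))
    else:
        idx = np.arange(y.size)
    ys, ss = y[idx], scores[idx]
    if ys.min() == ys.max():
        raise ValueError("calibration subsample lacks one of the classes")
    fpr, tpr, thr = skm.roc_curve(ys.astype(int), ss)
    best = int(np.argmax(tpr - fpr))
    return float(np.clip(thr[best], 0.0, 1.0))


def set_operating_point(
    model: VotingModel,
    X_selected: pd.DataFrame,
    y_binary,
    strategy: str = "roc_subsample",
    calib_fraction: float = 0.2,
    seed: int = 0,
) -> VotingModel:
    """Return a copy of the model with its threshold set on target data."""
    scores = forest_scores(model.ensemble, X_selected)["AFib"].to_numpy()
    thr = choose_threshold(scores, y_binary, strategy=strategy,
                           calib_fraction=calib_fraction, seed=seed)
    return VotingModel(ensemble=model.ensemble,
                       selected_features=model.selected_features,
                       threshold=thr, threshold_mode=strategy)
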