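"""Evaluation mathematics: standard per-dataset metrics, ROC/PR curves,
cross-validation, the composite error-variability indices, and the
large-scale screening PPV calculation.

Conventions
-----------
* AFib is the positive class; non-AFib and noise together form the
  negative class.
* The class-specific F1 scores are harmonic means: F1+ of (PPV,
  sensitivity) and F1- of (NPV, specificity); the average F1 is their
  arithmetic mean.
* A metric whose denominator is zero is *undefined* (``None``), never
  silently zero.
* Across N datasets with per-dataset metric values P_i, the efficacy
  index is ``E = mean(P_i)``, the variability index ``V`` is the sample
  standard deviation (divisor N-1), and the composite error-variability
  index combines the error index (1-E) with V either as the convex
  combination ``C = a*(1-E) + (1-a)*V`` or with unit weights
  ``C = (1-E) + V``.  Published comparison tables use the unit-weights
  form on unrounded per-dataset values; both are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import KFold, StratifiedKFold


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Confusion matrices and standard metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with AFib as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        """Counts from boolean (or AFib-labelled) truth/prediction vectors."""
        t = _as_positive_indicator(y_true)
        p = _as_positive_indicator(y_pred)
        return cls(
            tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)),
        )


def _as_positive_indicator(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "bi":
        return arr.astype(bool)
    return arr == "AFib"


@dataclass(frozen=True)
class MetricSet:
    """Per-dataset standard metrics; ``None`` marks an undefined entry."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1_pos: float | None
    f1_neg: float | None
    f1_avg: float | None
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "f1_pos": self.f1_pos,
            "f1_neg": self.f1_neg, "f1_avg": self.f1_avg, "auc": self.auc,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _harmonic(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return 2 * a * b / (a + b) if (a + b) > 0 else None


def standard_metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV and the three F1 scores."""
    sen = _ratio(cm.tp, cm.tp + cm.fn)
    spe = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    f1_pos = _harmonic(ppv, sen)
    f1_neg = _harmonic(npv, spe)
    f1_avg = (0.5 * (f1_pos + f1_neg)
              if f1_pos is not None and f1_neg is not None else None)
    return MetricSet(sensitivity=sen, specificity=spe, ppv=ppv, npv=npv,
                     f1_pos=f1_pos, f1_neg=f1_neg, f1_avg=f1_avg, auc=auc)


# --------------------------------------------------------------------------
# ROC / PR curves
# --------------------------------------------------------------------------

def roc_pr_curves(scores, y_binary) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """ROC points, precision-recall points, and trapezoidal ROC AUC."""
    y = _as_positive_indicator(y_binary).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute curves")
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, roc_thr = skm.roc_curve(y, scores)
    prec, rec, pr_thr = skm.precision_recall_curve(y, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr})
    pr = pd.DataFrame({"recall": rec, "precision": prec})
    return roc, pr, float(skm.auc(fpr, tpr))


# --------------------------------------------------------------------------
# Composite error-variability indices
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSeries:
    """One metric's per-dataset values P_i across N datasets."""

    values: tuple[float, ...]
    dataset_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 1:
            raise ValueError("a metric series needs at least one value")
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ValueError("metric series must not contain undefined entries")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("metric values must lie in [0, 1]")
        if self.dataset_names and len(self.dataset_names) != len(vals):
            raise ValueError("dataset_names must match values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CompositeIndex:
    """(efficacy, variability, composite) for one metric across datasets."""

    ep: float
    vp: float
    cp: float
    alpha: float
    mode: str

    def rounded(self, ndigits: int = 3) -> tuple[float, float, float]:
        return (round_half_away(self.ep, ndigits),
                round_half_away(self.vp, ndigits),
                round_half_away(self.cp, ndigits))


def composite_indices(series: MetricSeries, alpha: float = 0.5,
                      mode: str = "unit_weights") -> CompositeIndex:
    """Efficacy, variability and composite error-variability indices.

    ``mode="convex"`` computes ``C = alpha*(1-E) + (1-alpha)*V``;
    ``mode="unit_weights"`` computes ``C = (1-E) + V`` (twice the convex
    value at alpha = 0.5), which is the form the published comparison
    tables print.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if mode not in {"convex", "unit_weights"}:
        raise ValueError("mode must be 'convex' or 'unit_weights'")
    vals = np.asarray(series.values)
    ep = float(vals.mean())
    if series.n < 2:
        warnings.warn("variability index of a single dataset is 0",
                      stacklevel=2)
        vp = 0.0
    else:
        vp = float(vals.std(ddof=1))
    if mode == "convex":
        cp = alpha * (1.0 - ep) + (1.0 - alpha) * vp
    else:
        cp = (1.0 - ep) + vp
    return CompositeIndex(ep=ep, vp=vp, cp=cp, alpha=alpha, mode=mode)


def weighted_composite_indices(series: MetricSeries,
                               sizes: Sequence[int],
                               alpha: float = 0.5,
                               mode: str = "unit_weights") -> CompositeIndex:
    """Dataset-size-weighted variant of the efficacy/variability indices."""
    w = np.asarray(sizes, dtype=float)
    if w.size != series.n or np.any(w <= 0):
        raise ValueError("need one positive size per dataset")
    w = w / w.sum()
    vals = np.asarray(series.values)
    ep = float(np.sum(w * vals))
    if series.n < 2:
        vp = 0.0
    else:
        # unbiased weighted sd (frequency weights normalised)
        var = float(np.sum(w * (vals - ep) ** 2) / (1.0 - np.sum(w**2)))
        vp = float(np.sqrt(var))
    cp = (alpha * (1.0 - ep) + (1.0 - alpha) * vp if mode == "convex"
          else (1.0 - ep) + vp)
    return CompositeIndex(ep=ep, vp=vp, cp=cp, alpha=alpha, mode=mode)


# --------------------------------------------------------------------------
# Screening scenario
# --------------------------------------------------------------------------

def screening_ppv(n_weekly: int, prevalence: float, sensitivity: float,
                  specificity: float) -> float:
    """Expected PPV (percent) of population-scale weekly ECG screening.

    With ``n_weekly`` recordings at the given AFib prevalence, the expected
    true positives are ``n*prev*sen`` and false positives
    ``n*(1-prev)*(1-spe)``; the returned value is ``100*tp/(tp+fp)``.
    """
    if n_weekly <= 0:
        raise ValueError("n_weekly must be positive")
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    tp = n_weekly * prevalence * sensitivity
    fp = n_weekly * (1.0 - prevalence) * (1.0 - specificity)
    if tp + fp == 0:
        raise ValueError("no positive predictions: PPV undefined")
    return 100.0 * tp / (tp + fp)


# --------------------------------------------------------------------------
# k-fold cross-validation
# --------------------------------------------------------------------------

def kfold_cv(X, y, k: int = 10, seed: int = 0, n_trees: int = 500,
             threshold: float = 0.5) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the voting forest.

    Trains the ensemble on k-1 folds and evaluates binary AFib metrics on
    the held-out fold.  Stratification uses the 3-class labels when every
    class has at least ``k`` members, otherwise the binary reduction.
    Returns a tidy frame of per-fold metrics plus ``mean`` and ``std``
    summary rows (sample standard deviation over folds; undefined fold
    entries are excluded).
    """
    from .forest import fit_forest, forest_scores  # local import avoids cycle

    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    n = y.size
    pos = _as_positive_indicator(y)
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    if min(np.bincount(pd.factorize(y)[0])) >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(Xdf, y)
    elif int(pos.sum()) >= k and int((~pos).sum()) >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(Xdf, pos.astype(int))
    elif k == n:
        # leave-one-out: stratification is vacuous, folds are single rows
        warnings.warn("k == n: falling back to unstratified leave-one-out",
                      stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(Xdf)
    else:
        raise ValueError("a class is too rare to stratify into k folds")
    rows = []
    for fold, (tr, te) in enumerate(splits):
        ens = fit_forest(Xdf.iloc[tr], y[tr], n_trees=n_trees,
                         seed=seed + fold)
        scores = forest_scores(ens, Xdf.iloc[te])
        afib = (scores["AFib"].to_numpy() if "AFib" in scores.columns
                else scores.iloc[:, 0].to_numpy())
        pred = afib >= threshold
        cm = ConfusionMatrix.from_predictions(pos[te], pred)
        auc = None
        if pos[te].min() != pos[te].max():
            auc = roc_pr_curves(afib, pos[te])[2]
        ms = standard_metrics(cm, auc=auc)
        rows.append({"fold": fold, **ms.as_dict()})
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c != "fold"]
    df[metric_cols] = df[metric_cols].astype(float)  # None -> NaN
    summary = pd.DataFrame([
        {"fold": "mean", **{c: df[c].mean(skipna=True) for c in metric_cols}},
        {"fold": "std", **{c: df[c].std(ddof=1, skipna=True)
                           for c in metric_cols}},
    ])
    return pd.concat([df, summary], ignore_index=True)
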