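"""End-to-end experiment runner for the cross-dataset evaluation protocol.

Pipeline: generate the synthetic cohorts -> calibrate the base detectors on
the training cohort -> build detector matrices -> rank detector outputs by
OOB permutation importance and select the top k -> train the voting forest
-> evaluate the fusion and every base detector on each test cohort ->
aggregate the composite error-variability indices across test cohorts.

Every stage takes an explicit seed from the config, logs it, and is
reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import fusion as fusion_mod
from .detectors import (
    DEFAULT_DETECTORS,
    DetectorCalibration,
    build_detector_matrix,
    calibrate_detectors,
)
from .forest import DEFAULT_N_TREES, fit_forest
from .metrics import (
    ConfusionMatrix,
    MetricSeries,
    composite_indices,
    roc_pr_curves,
    standard_metrics,
)
from .ranking import permutation_importance, select_top_k
from .records import DetectorMatrix, LabeledDataset
from .synthetic import DEFAULT_CLASS_MIXES, generate_dataset

logger = logging.getLogger("afibvote")

STANDARD_METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1_avg")


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic cohort."""

    name: str
    n: int
    class_mix: Mapping[str, float]
    difficulty: str
    seed: int


@dataclass
class ExperimentConfig:
    """Full recipe for one cross-dataset evaluation run."""

    train: DatasetSpec
    tests: list[DatasetSpec]
    detectors: tuple[str, ...] = DEFAULT_DETECTORS
    top_k: int = len(DEFAULT_DETECTORS)
    n_trees: int = DEFAULT_N_TREES
    ranking_repeats: int = 5
    threshold_strategy: str = "roc_subsample"
    calib_fraction: float = 0.2
    alpha: float = 0.5
    composite_mode: str = "unit_weights"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tests:
            raise ValueError("need at least one test dataset")
        if not 1 <= self.top_k <= len(self.detectors):
            raise ValueError("top_k out of range")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["train"]["class_mix"] = dict(d["train"]["class_mix"])
        for t in d["tests"]:
            t["class_mix"] = dict(t["class_mix"])
        d["detectors"] = list(self.detectors)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        d["train"] = DatasetSpec(**d["train"])
        d["tests"] = [DatasetSpec(**t) for t in d["tests"]]
        if "detectors" in d:
            d["detectors"] = tuple(d["detectors"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_config(seed: int = 0, n_train: int = 900,
                   n_test: int = 600) -> ExperimentConfig:
    """The default four-cohort benchmark: one training cohort and three
    shifted test cohorts with the published AFib prevalences."""
    roles = ["train_like", "apple_like", "ds2_like", "ds3_like"]
    specs = [
        DatasetSpec(name=role, n=(n_train if role == "train_like" else n_test),
                    class_mix=DEFAULT_CLASS_MIXES[role], difficulty=role,
                    seed=seed * 1000 + i)
        for i, role in enumerate(roles)
    ]
    return ExperimentConfig(train=specs[0], tests=specs[1:], seed=seed)


# --------------------------------------------------------------------------
# Report container
# --------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Structured, fully seed-traceable output of one experiment run."""

    config: ExperimentConfig
    calibration: DetectorCalibration
    ranking: pd.DataFrame
    selected_features: list[str]
    thresholds: dict[str, dict[str, float]]   # dataset -> algorithm -> thr
    per_dataset: pd.DataFrame                 # dataset x algorithm metrics
    composite: pd.DataFrame                   # algorithm x metric E/V/C
    curves: dict[str, dict[str, pd.DataFrame]]  # dataset -> {roc, pr}

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "config.yaml")
        self.calibration.to_json(outdir / "calibration.json")
        self.ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
        self.per_dataset.to_csv(outdir / "per_dataset_metrics.tsv",
                                sep="\t", index=False)
        self.composite.to_csv(outdir / "composite_indices.tsv",
                              sep="\t", index=False)
        for ds, cs in self.curves.items():
            for kind, df in cs.items():
                df.to_csv(outdir / f"curve_{kind}_{ds}.csv", index=False)
        summary = {
            "selected_features": self.selected_features,
            "thresholds": self.thresholds,
            "per_dataset": json.loads(
                self.per_dataset.to_json(orient="records")),
            "composite": json.loads(
                self.composite.to_json(orient="records")),
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2))
        return outdir


# --------------------------------------------------------------------------
# Runner
# --------------------------------------------------------------------------

def _evaluate_scores(scores: np.ndarray, labels: np.ndarray,
                     threshold: float) -> dict[str, float | None]:
    pos = labels == "AFib"
    pred = scores >= threshold
    cm = ConfusionMatrix.from_predictions(pos, pred)
    auc = None
    if pos.any() and (~pos).any():
        auc = roc_pr_curves(scores, pos)[2]
    return standard_metrics(cm, auc=auc).as_dict()


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full generate/calibrate/rank/train/evaluate pipeline."""
    logger.info("experiment seed=%d detectors=%s n_trees=%d",
                config.seed, config.detectors, config.n_trees)

    # 1. cohorts
    datasets: dict[str, LabeledDataset] = {}
    for spec in [config.train, *config.tests]:
        ds = generate_dataset(spec.n, spec.class_mix, spec.difficulty,
                              spec.seed, name=spec.name)
        datasets[spec.name] = ds
        logger.info("generated %s: n=%d seed=%d prevalence=%s",
                    spec.name, spec.n, spec.seed,
                    {k: round(v, 4) for k, v in ds.prevalence.items()})

    # 2. detector calibration on the training cohort
    cal = calibrate_detectors(datasets[config.train.name], seed=config.seed)
    logger.info("calibrated detectors seed=%d noise_threshold=%.4f",
                config.seed, cal.noise_threshold)

    # 3. detector matrices
    matrices: dict[str, DetectorMatrix] = {
        name: build_detector_matrix(ds, cal, config.detectors)
        for name, ds in datasets.items()
    }

    # 4. ranking on the training matrix; the ranking forest uses mildly
    # regularized trees (min leaf 5) because permutation importance under
    # fully grown trees gives irrelevant features a small positive bias
    train_mat = matrices[config.train.name]
    rank_forest = fit_forest(train_mat.features, train_mat.labels,
                             n_trees=config.n_trees, seed=config.seed,
                             min_samples_leaf=5)
    ranking = permutation_importance(rank_forest, train_mat.features,
                                     train_mat.labels,
                                     n_repeats=config.ranking_repeats,
                                     seed=config.seed)
    selected = select_top_k(ranking, config.top_k)
    logger.info("ranking digest=%s selected=%s",
                rank_forest.data_digest, selected)

    # 5. voting model
    model = fusion_mod.fit_voting_model(
        train_mat.features[selected], train_mat.labels,
        n_trees=config.n_trees, seed=config.seed,
    )

    # 6-7. per-dataset evaluation of fusion + each base detector
    rows, thresholds, curves = [], {}, {}
    for spec in config.tests:
        ds_name = spec.name
        mat = matrices[ds_name]
        labels = mat.labels
        pos = labels == "AFib"
        algo_scores: dict[str, np.ndarray] = {
            "voting": fusion_mod.forest_scores(
                model.ensemble, mat.features[selected])["AFib"].to_numpy(),
        }
        for det in config.detectors:
            algo_scores[det] = mat.features[det].to_numpy()

        thresholds[ds_name] = {}
        for algo, scores in algo_scores.items():
            thr = fusion_mod.choose_threshold(
                scores, pos, strategy=config.threshold_strategy,
                calib_fraction=config.calib_fraction, seed=spec.seed + 1,
            )
            thresholds[ds_name][algo] = thr
            rows.append({"dataset": ds_name, "algorithm": algo,
                         "threshold": thr,
                         **_evaluate_scores(scores, labels, thr)})
        roc, pr, _ = roc_pr_curves(algo_scores["voting"], pos)
        curves[ds_name] = {"roc": roc, "pr": pr}
        logger.info("evaluated %s: thresholds=%s", ds_name,
                    {k: round(v, 4) for k, v in thresholds[ds_name].items()})

    per_dataset = pd.DataFrame(rows)

    # 8. composite indices across test cohorts
    comp_rows = []
    for algo in ["voting", *config.detectors]:
        sub = per_dataset[per_dataset["algorithm"] == algo]
        for metric in STANDARD_METRIC_NAMES:
            vals = sub[metric].tolist()
            if any(v is None or (isinstance(v, float) and np.isnan(v))
                   for v in vals):
                comp_rows.append({"algorithm": algo, "metric": metric,
                                  "ep": None, "vp": None, "cp": None})
                continue
            ci = composite_indices(
                MetricSeries(values=tuple(vals),
                             dataset_names=tuple(sub["dataset"])),
                alpha=config.alpha, mode=config.composite_mode,
            )
            comp_rows.append({"algorithm": algo, "metric": metric,
                              "ep": ci.ep, "vp": ci.vp, "cp": ci.cp})
    composite = pd.DataFrame(comp_rows)

    return ExperimentReport(
        config=config, calibration=cal, ranking=ranking.to_frame(),
        selected_features=selected, thresholds=thresholds,
        per_dataset=per_dataset, composite=composite, curves=curves,
    )
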