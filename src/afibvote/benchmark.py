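"""Published benchmark fixture: confusion matrices and printed metrics.

The cross-device evaluation of the voting algorithm against the
proprietary Apple and Kardia detectors was reported on three test cohorts
(an Apple Watch cohort and two AliveCor hand-held cohorts) as vectorized
binary confusion matrices, alongside the 3-decimal standard metrics and
the voting algorithm's efficacy / variability / composite
error-variability indices.  Those published counts and values are
embedded here so the package's evaluation mathematics can be checked
against them cell by cell: every printed metric must be recomputable from
the raw counts alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import (
    CompositeIndex,
    ConfusionMatrix,
    MetricSeries,
    composite_indices,
    round_half_away,
    screening_ppv,
    standard_metrics,
)

#: (dataset, algorithm) -> binary confusion counts, AFib positive.
REFERENCE_CONFUSION: dict[tuple[str, str], ConfusionMatrix] = {
    ("Apple Watch DS", "Apple"): ConfusionMatrix(tp=168, tn=2239, fp=18, fn=68),
    ("Apple Watch DS", "Voting"): ConfusionMatrix(tp=212, tn=2247, fp=10, fn=24),
    ("AliveCor DS2", "Kardia"): ConfusionMatrix(tp=762, tn=3629, fp=269, fn=16),
    ("AliveCor DS2", "Voting"): ConfusionMatrix(tp=700, tn=3805, fp=93, fn=78),
    ("AliveCor DS3", "Kardia"): ConfusionMatrix(tp=419, tn=4044, fp=78, fn=30),
    ("AliveCor DS3", "Voting"): ConfusionMatrix(tp=386, tn=4290, fp=37, fn=66),
}

#: Expected record totals per test dataset.
REFERENCE_TOTALS: dict[str, int] = {
    "Apple Watch DS": 2493,
    "AliveCor DS2": 4676,
    "AliveCor DS3": 4779,
}

#: Published 3-decimal standard metrics for the same (dataset, algorithm) rows.
REFERENCE_STANDARD: dict[tuple[str, str], dict[str, float]] = {
    ("Apple Watch DS", "Apple"): dict(sensitivity=0.712, specificity=0.992,
                                      ppv=0.903, npv=0.971, f1_avg=0.889),
    ("Apple Watch DS", "Voting"): dict(sensitivity=0.898, specificity=0.996,
                                       ppv=0.955, npv=0.989, f1_avg=0.959),
    ("AliveCor DS2", "Kardia"): dict(sensitivity=0.979, specificity=0.931,
                                     ppv=0.739, npv=0.996, f1_avg=0.902),
    ("AliveCor DS2", "Voting"): dict(sensitivity=0.900, specificity=0.976,
                                     ppv=0.883, npv=0.980, f1_avg=0.935),
    ("AliveCor DS3", "Kardia"): dict(sensitivity=0.933, specificity=0.981,
                                     ppv=0.843, npv=0.992, f1_avg=0.936),
    ("AliveCor DS3", "Voting"): dict(sensitivity=0.854, specificity=0.991,
                                     ppv=0.913, npv=0.985, f1_avg=0.935),
}

#: Published voting-row efficacy / variability / composite values per metric
#: (unit-weights composite on unrounded per-dataset values).
REFERENCE_COMPOSITE_VOTING: dict[str, dict[str, float]] = {
    "f1_avg": dict(ep=0.943, vp=0.014, cp=0.071),
    "sensitivity": dict(ep=0.884, vp=0.026, cp=0.142),
    "specificity": dict(ep=0.988, vp=0.010, cp=0.023),
    "ppv": dict(ep=0.917, vp=0.036, cp=0.119),
    "npv": dict(ep=0.985, vp=0.005, cp=0.020),
}

#: Cells of the published tables that are internally inconsistent with the
#: published confusion counts themselves (recomputation cannot reproduce
#: them under any rounding convention consistent with the other cells):
#: * the Kardia counts on AliveCor DS3 sum to 4571, not the stated cohort
#:   total of 4779 (208 records unaccounted for);
#: * that same row's printed NPV (0.992) recomputes to 4044/4074 = 0.993;
#: * the voting PPV composite index prints 0.119, which matches combining
#:   the already-rounded E and V (0.083 + 0.036); the unrounded values
#:   give 0.1196 -> 0.120, while every other composite cell matches the
#:   unrounded convention.
KNOWN_DISCREPANT_CELLS: frozenset[tuple[str, str, str]] = frozenset({
    ("AliveCor DS3", "Kardia", "npv"),
    ("all test datasets", "Voting", "ppv.cp"),
})
KNOWN_TOTAL_SHORTFALLS: dict[tuple[str, str], int] = {
    ("AliveCor DS3", "Kardia"): 4571,
}

#: Constants of the published million-recording weekly screening example:
#: 15% AFib prevalence, near-perfect sensitivity, 10% specificity loss.
SCREENING_SCENARIO = dict(n_weekly=1_000_000, prevalence=0.15,
                          sensitivity=1.0, specificity=0.90)
#: PPV (percent) the example reports, to the printed precision ("~64%").
SCREENING_EXPECTED_PPV = 63.8

TEST_DATASETS = ("Apple Watch DS", "AliveCor DS2", "AliveCor DS3")
STANDARD_METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1_avg")


@dataclass(frozen=True)
class ReferenceFixture:
    """The embedded benchmark counts, validated against the cohort totals."""

    confusion: dict[tuple[str, str], ConfusionMatrix]
    totals: dict[str, int]

    def __post_init__(self) -> None:
        for (dataset, algorithm), cm in self.confusion.items():
            expected = KNOWN_TOTAL_SHORTFALLS.get(
                (dataset, algorithm), self.totals[dataset])
            if cm.total != expected:
                raise ValueError(
                    f"{dataset}/{algorithm}: counts total {cm.total}, "
                    f"expected {expected}"
                )


def load_reference_fixture() -> ReferenceFixture:
    return ReferenceFixture(confusion=dict(REFERENCE_CONFUSION),
                            totals=dict(REFERENCE_TOTALS))


def voting_metric_series(metric: str,
                         fixture: ReferenceFixture | None = None) -> MetricSeries:
    """Unrounded per-dataset values of one metric for the voting algorithm."""
    fixture = fixture or load_reference_fixture()
    vals, names = [], []
    for ds in TEST_DATASETS:
        ms = standard_metrics(fixture.confusion[(ds, "Voting")])
        vals.append(ms.as_dict()[metric])
        names.append(ds)
    return MetricSeries(values=tuple(vals), dataset_names=tuple(names))


def voting_composite(metric: str, mode: str = "unit_weights",
                     alpha: float = 0.5,
                     fixture: ReferenceFixture | None = None) -> CompositeIndex:
    """Composite error-variability index of the voting algorithm's metric."""
    return composite_indices(voting_metric_series(metric, fixture),
                             alpha=alpha, mode=mode)


def reproduce_reference_tables(
    fixture: ReferenceFixture | None = None,
) -> pd.DataFrame:
    """Recompute every published cell from the raw confusion counts.

    Returns a tidy frame with one row per checked cell (standard metrics
    for all six dataset/algorithm rows, composite indices for the voting
    rows, and the screening-scenario PPV), comparing the recomputed
    3-decimal value with the printed one.
    """
    fixture = fixture or load_reference_fixture()
    rows = []
    for (dataset, algorithm), cm in fixture.confusion.items():
        ms = standard_metrics(cm).as_dict()
        for metric in STANDARD_METRIC_NAMES:
            computed = round_half_away(ms[metric])
            printed = REFERENCE_STANDARD[(dataset, algorithm)][metric]
            rows.append({
                "table": "standard", "dataset": dataset,
                "algorithm": algorithm, "metric": metric,
                "computed": computed, "printed": printed,
                "match": computed == printed,
                "known_discrepancy": (dataset, algorithm, metric)
                in KNOWN_DISCREPANT_CELLS,
            })
    for metric, printed_evc in REFERENCE_COMPOSITE_VOTING.items():
        ci = voting_composite(metric, mode="unit_weights", fixture=fixture)
        for name, computed in zip(("ep", "vp", "cp"), ci.rounded()):
            rows.append({
                "table": "composite", "dataset": "all test datasets",
                "algorithm": "Voting", "metric": f"{metric}.{name}",
                "computed": computed, "printed": printed_evc[name],
                "match": computed == printed_evc[name],
                "known_discrepancy":
                    ("all test datasets", "Voting", f"{metric}.{name}")
                    in KNOWN_DISCREPANT_CELLS,
            })
    ppv = round_half_away(screening_ppv(**SCREENING_SCENARIO), 1)
    rows.append({
        "table": "screening", "dataset": "weekly screening",
        "algorithm": "-", "metric": "ppv_percent",
        "computed": ppv, "printed": SCREENING_EXPECTED_PPV,
        "match": ppv == SCREENING_EXPECTED_PPV,
        "known_discrepancy": False,
    })
    return pd.DataFrame(rows)
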