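"""Core domain containers shared across the pipeline.

The unit conventions used throughout the package:

* ECG amplitudes are millivolts, sampled at ``fs`` Hz (default 300).
* R-peak times are seconds from record start; RR intervals are milliseconds.
* Rhythm labels are the three-way scheme ``{"AFib", "non-AFib", "noise"}``;
  the binary reduction treats AFib as positive and everything else negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical 3-class label set, in the order used for posterior vectors.
CLASSES: tuple[str, str, str] = ("AFib", "non-AFib", "noise")

#: Majority-vote tie-break preference: fewest false AFib alarms first.
TIE_PRIORITY: tuple[str, str, str] = ("non-AFib", "noise", "AFib")


class InsufficientDataError(ValueError):
    """Raised when a statistic is requested from too few beats."""


@dataclass(frozen=True)
class RhythmParams:
    """Beat-timing model for one rhythm class.

    Parameters
    ----------
    rhythm_class:
        One of ``sinus, afib, bigeminy, aflutter_like, tachy, brady``.
    mean_heart_rate:
        Mean ventricular rate in beats/min.
    rr_cv:
        Target coefficient of variation of the RR intervals.
    serial_corr:
        Lag-1 autocorrelation of the RR sequence, in [-1, 1].  AFib is
        modelled with ~0 serial correlation ("irregularly irregular"),
        sinus rhythm with positive correlation from autonomic drift.
    respiratory_mod_depth:
        Respiratory sinus arrhythmia depth as a fraction of the mean RR.
    respiratory_rate:
        Respiration frequency in Hz.
    ectopic_rate:
        Per-beat probability of a premature (ectopic) beat followed by a
        compensatory pause; applies to the AR(1) rhythms and models the
        isolated PAC/PVC activity that makes real non-AFib records hard.
    """

    rhythm_class: str
    mean_heart_rate: float
    rr_cv: float
    serial_corr: float = 0.0
    respiratory_mod_depth: float = 0.0
    respiratory_rate: float = 0.25
    ectopic_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.rhythm_class not in RHYTHM_CLASSES:
            raise ValueError(
                f"unknown rhythm_class {self.rhythm_class!r}; "
                f"expected one of {sorted(RHYTHM_CLASSES)}"
            )
        if not 20.0 <= self.mean_heart_rate <= 300.0:
            raise ValueError("mean_heart_rate must lie in [20, 300] bpm")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        if not -1.0 <= self.serial_corr <= 1.0:
            raise ValueError("serial_corr must lie in [-1, 1]")
        if not 0.0 <= self.ectopic_rate <= 0.5:
            raise ValueError("ectopic_rate must lie in [0, 0.5]")

    @property
    def mean_rr_ms(self) -> float:
        return 60_000.0 / self.mean_heart_rate


RHYTHM_CLASSES = frozenset(
    {"sinus", "afib", "bigeminy", "aflutter_like", "tachy", "brady"}
)


@dataclass(frozen=True)
class RRSeries:
    """R-peak times (s, strictly increasing) and RR intervals (ms)."""

    peak_times: np.ndarray
    rr_ms: np.ndarray

    @classmethod
    def from_peak_times(cls, peak_times: Sequence[float]) -> "RRSeries":
        t = np.asarray(peak_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("peak times must be strictly increasing")
        return cls(peak_times=t, rr_ms=np.diff(t) * 1000.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "peak_times", t)
        object.__setattr__(self, "rr_ms", rr)
        if rr.size != max(t.size - 1, 0):
            raise ValueError("rr_ms must have one entry per successive peak pair")
        if rr.size and np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def n_beats(self) -> int:
        return int(self.peak_times.size)

    def __len__(self) -> int:
        return self.n_beats


@dataclass(frozen=True)
class ECGRecord:
    """A single-lead (Lead I) ECG strip with its rhythm annotation."""

    record_id: str
    samples: np.ndarray
    fs: float = 300.0
    duration_s: float = 30.0
    label: str = "non-AFib"
    source_tag: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        expected = int(round(self.fs * self.duration_s))
        if s.size != expected:
            raise ValueError(
                f"record {self.record_id!r}: expected {expected} samples "
                f"({self.fs} Hz x {self.duration_s} s), got {s.size}"
            )
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class LabeledDataset:
    """A named collection of labelled records, e.g. one emulated device cohort."""

    records: list[ECGRecord]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset must contain at least one record")

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def prevalence(self) -> dict[str, float]:
        labels = self.labels
        n = labels.size
        prev = {c: float(np.sum(labels == c)) / n for c in CLASSES}
        assert abs(sum(prev.values()) - 1.0) < 1e-9
        return prev

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class DetectorMatrix:
    """Per-record candidate features: one column per base detector or scalar.

    ``features`` holds one row per record; columns named in
    ``posterior_columns`` are AFib posteriors and must lie in [0, 1].
    """

    features: pd.DataFrame
    labels: np.ndarray
    posterior_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.features) != self.labels.size:
            raise ValueError("features and labels must have one row per record")
        if self.features.isna().any().any():
            raise ValueError("detector matrix must not contain missing entries")
        for col in self.posterior_columns:
            vals = self.features[col].to_numpy()
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"posterior column {col!r} must lie in [0, 1]")

    @property
    def column_names(self) -> list[str]:
        return list(self.features.columns)

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class DetectorOutput:
    """One base detector's 3-class posterior for one record."""

    detector_name: str
    posterior: tuple[float, float, float]  # (AFib, non-AFib, noise)

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.posterior)
        object.__setattr__(self, "posterior", p)
        if any(v < 0 for v in p):
            raise ValueError("posterior components must be non-negative")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("posterior must sum to 1")

    @property
    def afib_score(self) -> float:
        return self.posterior[0]
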