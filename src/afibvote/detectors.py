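"""Pool of classical base AFib detectors built on RR-interval irregularity.

The evaluation framework treats base algorithms as black boxes that map a
30-s record to a 3-class posterior over (AFib, non-AFib, noise).  The six
detectors here are classical irregularity statistics from the heart-rate
variability literature — normalised RMSSD, delta-RR Shannon entropy, sample
entropy, turning-point ratio, a CV/MAD spread statistic, and a pure
signal-quality gate — each wrapped in a calibrated logistic that converts
the raw statistic into an AFib probability, with a shared soft noise gate
driven by a spectral signal-quality score.

An uncalibrated detector refuses to run: calibration (fit on a labelled
training set) is an explicit artifact, serialisable to JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression

from .records import (
    DetectorMatrix,
    DetectorOutput,
    ECGRecord,
    InsufficientDataError,
    LabeledDataset,
    RRSeries,
)

# ΔRR histogram: 16 fixed-width bins spanning ±600 ms
_ENTROPY_BINS = np.linspace(-600.0, 600.0, 17)
# sample entropy parameters: template length m=1, tolerance r=30 ms
_SAMPEN_M = 1
_SAMPEN_R_MS = 30.0
#: Minimum beats required before RR statistics are defined.
MIN_BEATS = 5
#: Refractory period enforced between accepted R peaks, seconds.
REFRACTORY_S = 0.2


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

def detect_r_peaks(
    record: ECGRecord,
    *,
    band_hz: tuple[float, float] = (5.0, 18.0),
    integration_window_s: float = 0.150,
    threshold_fraction: float = 0.35,
) -> RRSeries:
    """Locate R peaks with an energy-based detector.

    Band-pass filter, differentiate, square, integrate over a 150-ms moving
    window, then accept peaks of the integrated energy above a fraction of
    its robust (98th-percentile) level, at least 200 ms apart.  All
    thresholds are relative to the signal's own scale, so peak times are
    invariant under amplitude rescaling.  Noise records legitimately yield
    few or no accepted peaks.
    """
    if record.duration_s < 2.0:
        raise ValueError("record must contain at least 2 s of signal")
    fs = record.fs
    nyq = fs / 2.0
    b, a = sps.butter(2, [band_hz[0] / nyq, band_hz[1] / nyq], btype="band")
    filtered = sps.filtfilt(b, a, record.samples)
    energy = np.convolve(
        np.gradient(filtered) ** 2,
        np.ones(max(int(integration_window_s * fs), 1)),
        mode="same",
    )
    scale = np.percentile(energy, 98)
    if scale <= 0:
        return RRSeries.from_peak_times([])
    peaks, _ = sps.find_peaks(
        energy, height=threshold_fraction * scale,
        distance=max(int(REFRACTORY_S * fs), 1),
    )
    if peaks.size == 0:
        return RRSeries.from_peak_times([])
    # refine each candidate to the local maximum of the band-passed signal
    half = int(0.10 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, filtered.size)
        refined.append(lo + int(np.argmax(filtered[lo:hi])))
    refined = np.unique(refined)
    # re-enforce refractory after refinement
    accepted: list[int] = []
    for p in refined:
        if not accepted or (p - accepted[-1]) / fs >= REFRACTORY_S:
            accepted.append(int(p))
    return RRSeries.from_peak_times(np.asarray(accepted) / fs)


# --------------------------------------------------------------------------
# RR-interval irregularity features
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RRFeatureVector:
    """Irregularity statistics of one RR series (all dimensionless)."""

    rmssd_norm: float
    delta_rr_entropy: float
    sample_entropy: float
    turning_point_ratio: float
    rr_cv: float
    rr_mad_norm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rmssd_norm": self.rmssd_norm,
            "delta_rr_entropy": self.delta_rr_entropy,
            "sample_entropy": self.sample_entropy,
            "turning_point_ratio": self.turning_point_ratio,
            "rr_cv": self.rr_cv,
            "rr_mad_norm": self.rr_mad_norm,
        }


def _shannon_entropy_bits(drr: np.ndarray) -> float:
    clipped = np.clip(drr, _ENTROPY_BINS[0], _ENTROPY_BINS[-1] - 1e-9)
    counts, _ = np.histogram(clipped, bins=_ENTROPY_BINS)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _sample_entropy(x: np.ndarray, m: int = _SAMPEN_M,
                    r: float = _SAMPEN_R_MS) -> float:
    """SampEn(m, r) with Chebyshev distance on the raw (ms) series.

    Degenerate cases are kept finite: with no template matches at length m
    the series carries no detectable structure and 0 is returned; with no
    matches at length m+1 the standard upper bound log(B) is returned.
    """
    n = x.size
    if n <= m + 1:
        raise InsufficientDataError("sample entropy needs more than m+1 beats")

    def _count(mm: int) -> int:
        # n - m templates at both lengths, so A/B is a conditional probability
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        iu = np.triu_indices(templ.shape[0], k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = _count(m)
    a = _count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float(math.log(b))
    return float(-math.log(a / b))


def compute_rr_features(rr: RRSeries) -> RRFeatureVector:
    """All six irregularity statistics; raises on fewer than 5 beats."""
    if rr.n_beats < MIN_BEATS:
        raise InsufficientDataError(
            f"need >= {MIN_BEATS} beats, got {rr.n_beats}"
        )
    x = rr.rr_ms
    drr = np.diff(x)
    mean_rr = float(np.mean(x))
    rmssd = math.sqrt(float(np.mean(drr**2)))
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    # turning points: interior samples that are strict local extrema
    interior = x[1:-1]
    tp = np.sum((interior > x[:-2]) & (interior > x[2:])
                | (interior < x[:-2]) & (interior < x[2:]))
    tpr = float(tp) / max(x.size - 2, 1)
    return RRFeatureVector(
        rmssd_norm=rmssd / mean_rr,
        delta_rr_entropy=_shannon_entropy_bits(drr),
        sample_entropy=_sample_entropy(x),
        turning_point_ratio=tpr,
        rr_cv=float(np.std(x, ddof=1)) / mean_rr,
        rr_mad_norm=mad / med if med > 0 else 0.0,
    )


def compute_signal_quality(record: ECGRecord) -> float:
    """Spectral concentration score in [0, 1].

    Fraction of (mean-removed) signal power inside the 1-40 Hz band where
    ECG content lives.  Broadband noise spreads power up to the Nyquist
    frequency and baseline wander concentrates it below 1 Hz, so the score
    decreases monotonically with either contamination.  Deterministic.
    """
    x = record.samples - np.mean(record.samples)
    freqs, psd = sps.welch(x, fs=record.fs,
                           nperseg=min(1024, x.size))
    total = float(np.trapezoid(psd, freqs))
    if total <= 0:
        return 0.0
    band = (freqs >= 1.0) & (freqs <= 40.0)
    return float(np.trapezoid(psd[band], freqs[band]) / total)


# --------------------------------------------------------------------------
# Detector registry and calibration
# --------------------------------------------------------------------------

def _stat_from_features(name: str) -> Callable[[RRFeatureVector, float], float]:
    def getter(f: RRFeatureVector, quality: float) -> float:
        return f.as_dict()[name]
    return getter


#: Registry: detector name -> raw statistic from (features, quality score).
DETECTOR_REGISTRY: dict[str, Callable[[RRFeatureVector, float], float]] = {
    "rmssd": _stat_from_features("rmssd_norm"),
    "drr_entropy": _stat_from_features("delta_rr_entropy"),
    "sampen": _stat_from_features("sample_entropy"),
    "turning_point": _stat_from_features("turning_point_ratio"),
    "cv_mad": lambda f, q: 0.5 * (f.rr_cv + f.rr_mad_norm),
    "quality_gate": lambda f, q: q,
}

DEFAULT_DETECTORS: tuple[str, ...] = tuple(DETECTOR_REGISTRY)


@dataclass
class DetectorCalibration:
    """Per-detector logistic maps plus the shared noise gate.

    ``logistic[name] = (slope, intercept)`` maps the raw statistic to an
    AFib-vs-non-AFib probability; ``noise_threshold`` is the quality-score
    cut separating noise from readable records, applied with a logistic
    soft edge of width ``noise_softness``.
    """

    logistic: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_threshold: float = 0.3
    noise_softness: float = 0.05

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "logistic": {k: list(v) for k, v in self.logistic.items()},
            "noise_threshold": self.noise_threshold,
            "noise_softness": self.noise_softness,
        }, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "DetectorCalibration":
        if isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc
                                     and doc.endswith(".json")):
            doc = Path(doc).read_text()
        data = json.loads(doc)
        return cls(
            logistic={k: (float(v[0]), float(v[1]))
                      for k, v in data["logistic"].items()},
            noise_threshold=float(data["noise_threshold"]),
            noise_softness=float(data["noise_softness"]),
        )


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _record_statistics(record: ECGRecord) -> tuple[dict[str, float] | None, float]:
    """Raw statistic per detector (None when too few beats) and quality."""
    quality = compute_signal_quality(record)
    rr = detect_r_peaks(record)
    if rr.n_beats < MIN_BEATS:
        return None, quality
    feats = compute_rr_features(rr)
    return {name: fn(feats, quality)
            for name, fn in DETECTOR_REGISTRY.items()}, quality


def run_base_detector(
    name: str,
    record: ECGRecord,
    cal: DetectorCalibration,
    *,
    _stats: tuple[dict[str, float] | None, float] | None = None,
) -> DetectorOutput:
    """Evaluate one calibrated base detector on one record.

    The noise posterior comes from the quality gate's soft threshold; the
    remaining mass splits between AFib and non-AFib via the detector's
    calibrated logistic.  A record with too few detectable beats gets the
    degenerate posterior (0, 0, 1).
    """
    if name not in DETECTOR_REGISTRY:
        raise KeyError(f"unknown detector {name!r}; "
                       f"registered: {sorted(DETECTOR_REGISTRY)}")
    if cal is None or name not in cal.logistic:
        raise RuntimeError(f"detector {name!r} is not calibrated")
    stats, quality = _stats if _stats is not None else _record_statistics(record)
    if stats is None:
        return DetectorOutput(detector_name=name, posterior=(0.0, 0.0, 1.0))
    p_noise = _sigmoid((cal.noise_threshold - quality) / cal.noise_softness)
    slope, intercept = cal.logistic[name]
    p_afib = _sigmoid(slope * stats[name] + intercept)
    readable = 1.0 - p_noise
    return DetectorOutput(
        detector_name=name,
        posterior=(readable * p_afib, readable * (1.0 - p_afib), p_noise),
    )


def calibrate_detectors(train: LabeledDataset, seed: int = 0) -> DetectorCalibration:
    """Fit every registered detector's logistic and the noise gate.

    The AFib-vs-non-AFib logistic for each detector is fitted on its raw
    statistic over the readable training records (noise-labelled records and
    records with too few beats are excluded); the noise threshold is placed
    where the quality score best separates noise from non-noise records
    (maximum balanced accuracy, midpoint between adjacent scores).
    """
    labels = train.labels
    present = set(labels)
    if not {"AFib", "non-AFib"} <= present:
        raise ValueError("training set must contain AFib and non-AFib records")

    stat_rows: list[dict[str, float]] = []
    stat_labels: list[str] = []
    qualities: list[float] = []
    for rec in train:
        stats, quality = _record_statistics(rec)
        qualities.append(quality)
        if stats is not None and rec.label != "noise":
            stat_rows.append(stats)
            stat_labels.append(rec.label)

    y = (np.asarray(stat_labels) == "AFib").astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("AFib-vs-non-AFib calibration needs both classes")
    cal = DetectorCalibration()
    for name in DETECTOR_REGISTRY:
        x = np.array([row[name] for row in stat_rows]).reshape(-1, 1)
        lr = LogisticRegression(random_state=seed)
        lr.fit(x, y)
        cal.logistic[name] = (float(lr.coef_[0, 0]), float(lr.intercept_[0]))

    q = np.asarray(qualities)
    is_noise = labels == "noise"
    if is_noise.any() and (~is_noise).any():
        order = np.argsort(q, kind="stable")
        qs, ns = q[order], is_noise[order]
        candidates = (qs[1:] + qs[:-1]) / 2.0
        best_thr, best_bacc = float(np.median(q)), -1.0
        for thr in np.unique(candidates):
            pred_noise = q < thr
            tpr = np.mean(pred_noise[is_noise])
            tnr = np.mean(~pred_noise[~is_noise])
            bacc = 0.5 * (tpr + tnr)
            if bacc > best_bacc + 1e-12:
                best_bacc, best_thr = bacc, float(thr)
        cal.noise_threshold = best_thr
    return cal


def build_detector_matrix(
    dataset: LabeledDataset,
    cal: DetectorCalibration,
    detector_names: tuple[str, ...] = DEFAULT_DETECTORS,
) -> DetectorMatrix:
    """AFib-score column per detector for every record in a dataset."""
    rows = []
    for rec in dataset:
        stats = _record_statistics(rec)
        rows.append({
            name: run_base_detector(name, rec, cal, _stats=stats).afib_score
            for name in detector_names
        })
    features = pd.DataFrame(rows, columns=list(detector_names))
    return DetectorMatrix(features=features, labels=dataset.labels,
                          posterior_columns=tuple(detector_names))
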