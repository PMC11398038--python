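"""Plain-text dataset layout: a CSV manifest plus one signal CSV per record.

Layout::

    <outdir>/manifest.csv        # record_id, label, fs, duration_s, source_tag, path
    <outdir>/signals/<id>.csv    # single "mv" column of amplitudes

Amplitudes are written at 6 decimal places (microvolt precision), so a
round-trip reproduces every sample within 5e-7 mV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import ECGRecord, LabeledDataset

SIGNAL_PRECISION = "%.6f"


def write_dataset(dataset: LabeledDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    sigdir = outdir / "signals"
    sigdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset:
        rel = f"signals/{rec.record_id}.csv"
        np.savetxt(outdir / rel, rec.samples, fmt=SIGNAL_PRECISION,
                   header="mv", comments="")
        rows.append({
            "record_id": rec.record_id,
            "label": rec.label,
            "fs": rec.fs,
            "duration_s": rec.duration_s,
            "source_tag": rec.source_tag,
            "path": rel,
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(outdir: str | Path, name: str | None = None) -> LabeledDataset:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv",
                           keep_default_na=False, dtype={"record_id": str})
    records = []
    for row in manifest.itertuples(index=False):
        samples = np.loadtxt(outdir / row.path, skiprows=1)
        records.append(ECGRecord(
            record_id=row.record_id, samples=samples, fs=float(row.fs),
            duration_s=float(row.duration_s), label=row.label,
            source_tag=row.source_tag,
        ))
    return LabeledDataset(records=records, name=name or outdir.name)
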