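"""Reading and writing multi-lead ECG records.

Records are exchanged as plain CSV: one row per sample, a ``time_s`` column
plus one column per lead in the canonical 12-lead order. Amplitudes are in
millivolts throughout. A dataset is a directory of record CSVs with a
manifest (record_id, label, fs) beside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical 12-lead order used everywhere in the package.
LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


class FormatError(ValueError):
    """Raised when an on-disk record violates the expected layout."""


@dataclass
class EcgRecord:
    """One subject's multi-lead ECG.

    Parameters
    ----------
    record_id : str
        Unique identifier within a dataset.
    label : str
        Group label, e.g. ``"DCM"``/``"ICM"`` or ``"A"``/``"B"``.
    fs : float
        Sampling rate in Hz.
    leads : dict[str, np.ndarray]
        Lead name -> samples (mV). All leads must share a length.
    r_peaks : np.ndarray | None
        Optional ground-truth R-peak sample indices (synthetic records).
    """

    record_id: str
    label: str
    fs: float
    leads: dict[str, np.ndarray]
    r_peaks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.leads:
            raise ValueError("record has no leads")
        unknown = set(self.leads) - set(LEAD_NAMES)
        if unknown:
            raise ValueError(f"unknown lead names: {sorted(unknown)}")
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) != 1:
            raise ValueError(f"leads have inconsistent lengths: {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise ValueError("leads are empty")
        # normalize storage order to the canonical one
        self.leads = {
            name: np.asarray(self.leads[name], dtype=float)
            for name in LEAD_NAMES
            if name in self.leads
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def lead_names(self) -> tuple[str, ...]:
        return tuple(self.leads)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.leads[name]
        except KeyError:
            raise KeyError(f"record {self.record_id!r} has no lead {name!r}") from None


def write_record(record: EcgRecord, path: str | Path) -> Path:
    """Write a record as CSV (time_s column + one column per lead).

    Values are written with enough digits to round-trip within 1e-6 mV.
    """
    path = Path(path)
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame({"time_s": t})
    for name in record.lead_names:
        df[name] = record.leads[name]
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_record(
    path: str | Path,
    *,
    record_id: str | None = None,
    label: str = "",
    fs: float | None = None,
) -> EcgRecord:
    """Read a record CSV written by :func:`write_record`.

    ``fs`` may be omitted when the file carries a ``time_s`` column, from
    which the rate is inferred.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [name for name in LEAD_NAMES if name not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing lead column(s) {missing}")
    if fs is None:
        if "time_s" not in df.columns:
            raise FormatError(f"{path.name}: no time_s column and no fs given")
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise FormatError(f"{path.name}: time_s column is not uniformly sampled")
        fs = 1.0 / dt[0]
    leads = {name: df[name].to_numpy(dtype=float) for name in LEAD_NAMES}
    return EcgRecord(
        record_id=record_id or path.stem,
        label=label,
        fs=float(fs),
        leads=leads,
    )


def write_dataset(records: list[EcgRecord], directory: str | Path) -> Path:
    """Write records plus a manifest and R-peak ground truth (if present)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    for rec in records:
        write_record(rec, directory / f"{rec.record_id}.csv")
        manifest_rows.append(
            {"record_id": rec.record_id, "label": rec.label, "fs": rec.fs}
        )
        if rec.r_peaks is not None:
            truth_rows.extend(
                {"record_id": rec.record_id, "r_peak_index": int(i)}
                for i in rec.r_peaks
            )
    pd.DataFrame(manifest_rows).to_csv(directory / "manifest.csv", index=False)
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(directory / "r_peaks.csv", index=False)
    return directory


def read_dataset(directory: str | Path) -> list[EcgRecord]:
    """Read back a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    truth_path = directory / "r_peaks.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    records = []
    for row in manifest.itertuples():
        rec = read_record(
            directory / f"{row.record_id}.csv",
            record_id=str(row.record_id),
            label=str(row.label),
            fs=float(row.fs),
        )
        if truth is not None:
            peaks = truth.loc[
                truth["record_id"] == row.record_id, "r_peak_index"
            ].to_numpy(dtype=int)
            if len(peaks):
                rec.r_peaks = peaks
        records.append(rec)
    return records
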