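"""File formats: EDF and CSV recordings, cohort tables.

EDF is the canonical raw format (ubiquitous for EEG); a two-column CSV
(time_s, fp1_uV, fp2_uV) is the plain-text fallback used for fixtures.
Reading EDF goes through MNE; writing uses a minimal EDF writer (fixed-layout
ASCII header plus little-endian int16 records) because the format is simple
and round-trips against MNE's reader within 16-bit quantization of the
physical range.

Cohort tables are CSV with header ``id,sex,age,edu,mmse_total,ot,op,rg,ac,
rc,lg,vc,dm`` (sex coded 1 = female, 0 = male); validation collects
row-level problems instead of failing on the first.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import CHANNEL_NAMES, EEGRecording
from .synth import DOMAIN_COLUMNS, DOMAIN_MAXIMA
from .prediction import assign_stage

#: EDF physical range in uV, matching the amplifier input range
EDF_PHYSICAL_RANGE_UV = 393.0

COHORT_COLUMNS = ["id", "sex", "age", "edu", "mmse_total", *DOMAIN_COLUMNS]


# ---------------------------------------------------------------------------
# EEG


def write_eeg_csv(rec: EEGRecording, path) -> None:
    """Two-column CSV: time_s, fp1_uV, fp2_uV (full float precision)."""
    df = pd.DataFrame(
        {"time_s": rec.times, "fp1_uV": rec.data[0], "fp2_uV": rec.data[1]}
    )
    df.to_csv(path, index=False)


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_eeg_edf(rec: EEGRecording, path, physical_range_uV: float = EDF_PHYSICAL_RANGE_UV) -> None:
    """Minimal EDF writer: one-second records, int16 samples, uV dimension.

    Samples are clipped to +/-``physical_range_uV`` and quantized to the
    16-bit digital range; the recording is truncated to whole seconds.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    ns = 2
    pmin, pmax = -physical_range_uV, physical_range_uV
    dmin, dmax = -32768, 32767

    buf = _io.BytesIO()
    header_bytes = 256 * (1 + ns)
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field(rec.subject_id, 80))
    buf.write(_edf_field("eegslow synthetic", 80))
    buf.write(_edf_field("01.01.20", 8))
    buf.write(_edf_field("00.00.00", 8))
    buf.write(_edf_field(header_bytes, 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(n_records, 8))
    buf.write(_edf_field(1, 8))  # record duration, s
    buf.write(_edf_field(ns, 4))
    for name in CHANNEL_NAMES:
        buf.write(_edf_field(name, 16))
    for _ in range(ns):
        buf.write(_edf_field("", 80))  # transducer
    for _ in range(ns):
        buf.write(_edf_field("uV", 8))
    for _ in range(ns):
        buf.write(_edf_field(pmin, 8))
    for _ in range(ns):
        buf.write(_edf_field(pmax, 8))
    for _ in range(ns):
        buf.write(_edf_field(dmin, 8))
    for _ in range(ns):
        buf.write(_edf_field(dmax, 8))
    for _ in range(ns):
        buf.write(_edf_field("", 80))  # prefiltering
    for _ in range(ns):
        buf.write(_edf_field(fs, 8))
    for _ in range(ns):
        buf.write(_edf_field("", 32))

    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((np.clip(rec.data, pmin, pmax) - pmin) * gain + dmin)
    digital = digital.astype("<i2")
    for r in range(n_records):
        for ch in range(ns):
            buf.write(digital[ch, r * fs : (r + 1) * fs].tobytes())
    Path(path).write_bytes(buf.getvalue())


def read_eeg(path, format: str | None = None) -> EEGRecording:
    """Read a two-channel recording from EDF or CSV.

    Channel labels are matched case-insensitively against Fp1/Fp2; a file
    missing either channel raises a descriptive error. EDF data are returned
    in uV using the file's physical scaling.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unsupported EEG format: {fmt!r}")


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = {name.lower(): name for name in raw.ch_names}
    picks = []
    for wanted in CHANNEL_NAMES:
        if wanted.lower() not in labels:
            raise ValueError(f"missing channel {wanted!r} in {path.name} "
                             f"(found: {raw.ch_names})")
        picks.append(labels[wanted.lower()])
    data = raw.get_data(picks=picks) * 1e6  # MNE holds EEG in volts
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]), subject_id=path.stem)


def _read_csv(path: Path) -> EEGRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    for wanted in ("time_s", "fp1_uv", "fp2_uv"):
        if wanted not in cols:
            raise ValueError(f"missing channel/column {wanted!r} in {path.name}")
    t = df[cols["time_s"]].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("truncated CSV recording")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise ValueError("non-uniform time axis in CSV recording")
    fs = 1.0 / float(np.mean(dt))
    data = np.vstack([df[cols["fp1_uv"]].to_numpy(float), df[cols["fp2_uv"]].to_numpy(float)])
    return EEGRecording(data=data, fs=fs, subject_id=path.stem)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortValidation:
    """Validated cohort with collected row-level issues.

    ``table`` contains the accepted rows with a ``stage`` column assigned
    from the MMSE cut points; ``issues`` is a list of dicts with keys
    row, column, severity ('error' rows are dropped, 'warning' rows kept)
    and message.
    """

    table: pd.DataFrame
    issues: list


def write_cohort(table: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_cohort(path) -> CohortValidation:
    """Load and validate a cohort CSV.

    Checks: schema columns present; unique ids; sex in {0, 1}; MMSE total in
    [0, 30] (violations reject the row); domain scores within maxima and
    summing to the total (violations are warnings). Stage labels are
    assigned from the fixed MMSE cut points.
    """
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    issues = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        if row["sex"] not in (0, 1):
            issues.append({"row": i, "column": "sex", "severity": "error",
                           "message": f"unknown sex code {row['sex']!r}"})
            keep[i] = False
        if not 0 <= row["mmse_total"] <= 30:
            issues.append({"row": i, "column": "mmse_total", "severity": "error",
                           "message": f"MMSE total {row['mmse_total']} out of [0, 30]"})
            keep[i] = False
            continue
        dsum = 0
        for col, mx in zip(DOMAIN_COLUMNS, DOMAIN_MAXIMA):
            v = row[col]
            if not 0 <= v <= mx:
                issues.append({"row": i, "column": col, "severity": "warning",
                               "message": f"domain score {v} outside [0, {mx}]"})
            dsum += v
        if dsum != row["mmse_total"]:
            issues.append({"row": i, "column": "mmse_total", "severity": "warning",
                           "message": f"domain sum {dsum} != total {row['mmse_total']}"})
    table = df.loc[keep].copy()
    table["stage"] = table["mmse_total"].map(assign_stage)
    return CohortValidation(table=table, issues=issues)
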