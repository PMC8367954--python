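"""Readers and writers for recordings, parameter tables and clinical tables.

All delimited text is comma-separated, "." decimal, UTF-8. Recordings can be
read from EDF (via :mod:`mne`) or from a delimited matrix whose first row
holds channel ids, one column per channel, one row per sample, plus an
optional boolean ``artifact`` column. A minimal EDF writer is provided so
recordings can round-trip without proprietary tooling; it writes a single
data record of 16-bit samples, which every standard EDF reader accepts.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import EEGRecording, FormatError, TemporalParams, PARAM_COLUMNS

CLINICAL_GROUPS = ("ASD", "TD")
#: Columns of a clinical table that are not scores.
CLINICAL_META_COLUMNS = ("subject_id", "group", "sex", "age_years")


# ---------------------------------------------------------------------------
# recordings


def read_recording(path: str, format: str | None = None, srate: float | None = None) -> EEGRecording:
    """Read an EEG recording from an EDF file or a delimited matrix.

    ``format`` is ``"edf"`` or ``"delimited_matrix"``; if omitted it is
    inferred from the file extension. For delimited matrices ``srate`` must
    be supplied (the text format carries no rate). The returned recording
    has ``reference="raw"``; the artifact mask defaults to all-``False``
    when no ``artifact`` column is present.
    """
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "delimited_matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited_matrix":
        if srate is None:
            raise ValueError("srate is required for delimited_matrix input")
        return _read_delimited(path, srate)
    raise ValueError(f"unknown format {format!r}")


def _read_delimited(path: str, srate: float) -> EEGRecording:
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed delimited file {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"empty recording file {path}")
    mask = None
    if "artifact" in df.columns:
        mask = df.pop("artifact").to_numpy().astype(bool)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"non-numeric cell in column {col!r}, data row {row}")
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
        raise FormatError(f"missing cell in data row {row}")
    data = df.to_numpy(dtype=float).T  # rows were samples
    return EEGRecording(data=data, srate=srate, channel_ids=list(df.columns),
                        artifact_mask=mask, reference="raw")


def _read_edf(path: str) -> EEGRecording:
    import mne

    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne uses volts internally
    return EEGRecording(data=data, srate=float(raw.info["sfreq"]),
                        channel_ids=list(raw.ch_names), reference="raw")


def write_recording_csv(rec: EEGRecording, path: str) -> None:
    """Write a recording as a delimited matrix (samples x channels)."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_ids)
    if rec.artifact_mask.any():
        df["artifact"] = rec.artifact_mask.astype(int)
    df.to_csv(path, index=False, float_format="%.17g")


def write_recording_edf(rec: EEGRecording, path: str) -> None:
    """Write a recording as EDF (16-bit, one data record).

    Physical units are microvolts; quantization error is bounded by the
    physical range divided by 2^16, negligible for round-trip testing and
    interchange.
    """
    n_ch, n_s = rec.data.shape
    if abs(round(rec.srate) - rec.srate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    record_dur = n_s / rec.srate
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def f(x: object, width: int) -> bytes:
        s = f"{x}"[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X", 80), f("X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 + 256 * n_ch, 8), f("", 44), f(1, 8),
        f(f"{record_dur:.6f}".rstrip("0").rstrip("."), 8), f(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(f(ch[:16], 16) for ch in rec.channel_ids),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{v:.6g}", 8) for v in phys_min),
        b"".join(f(f"{v:.6g}", 8) for v in phys_max),
        b"".join(f(dig_min, 8) for _ in range(n_ch)),
        b"".join(f(dig_max, 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(n_s, 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((rec.data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig)
        fh.write(digital.tobytes())  # one record: channel-major


# ---------------------------------------------------------------------------
# parameter tables


def write_params_table(params: Sequence[TemporalParams], path: str) -> None:
    """Write per-subject temporal parameters as a tidy CSV.

    One row per subject x map with columns (subject_id, map, gev,
    mean_duration_ms, coverage_pct, occurrence_per_s). Values round-trip at
    full floating precision.
    """
    if not params:
        raise ValueError("empty parameter list")
    frames = []
    for p in params:
        t = p.table.reset_index(names="map")
        t.insert(0, "subject_id", p.subject_id)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_params_table(path: str) -> list[TemporalParams]:
    """Read a tidy parameter CSV back into per-subject objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "map", *PARAM_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"parameter table missing columns {sorted(missing)}")
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        out.append(TemporalParams(subject_id=str(sid), table=sub.set_index("map")))
    return out


def params_to_frame(params: Iterable[TemporalParams]) -> pd.DataFrame:
    """Stack per-subject parameters into one tidy DataFrame."""
    frames = []
    for p in params:
        t = p.table.reset_index(names="map")
        t.insert(0, "subject_id", p.subject_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical_table(path: str) -> pd.DataFrame:
    """Read a clinical score table (CSV with header).

    Requires ``subject_id`` and ``group`` columns; ``group`` must be ASD or
    TD for every row. Unknown columns are preserved as extra score columns.
    Missing cells become NaN, never zeros.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise FormatError("clinical table lacks a 'group' column")
    if "subject_id" not in df.columns:
        raise FormatError("clinical table lacks a 'subject_id' column")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"duplicate subject_id {dup!r}")
    if df["group"].isna().any():
        raise FormatError("missing group value")
    bad = ~df["group"].isin(CLINICAL_GROUPS)
    if bad.any():
        raise FormatError(f"unknown group value {df.loc[bad, 'group'].iloc[0]!r}")
    if "age_years" in df.columns and (df["age_years"] <= 0).any():
        raise FormatError("ages must be positive")
    return df


def clinical_score_columns(clinical: pd.DataFrame) -> list[str]:
    """Names of the score columns (everything beyond the meta columns)."""
    return [c for c in clinical.columns if c not in CLINICAL_META_COLUMNS]
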