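"""Reading and writing the database CSV formats.

Two file kinds are supported:

* the per-record ECG CSV: a header row of 12 lead names followed by 5000
  data rows (10 s at 500 Hz), amplitudes in microvolts, one column per lead;
* the diagnostics CSV: one row per record with the rhythm label, additional
  condition labels, demographics and the vendor-supplied summary
  measurements (rates, intervals, axes, wave onsets/offsets).

Sample-index fields (``QOnset``, ``QOffset``, ``TOffset``) are 0-based
positions into the sample array.  Missing numeric metadata is represented by
``None`` (``NaN`` once it reaches a feature vector), never by 0, because 0 is
a legal rate/axis value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical 12-lead order: limb, augmented, precordial.
CANONICAL_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: A/D step in microvolts per least-significant bit.
ADC_LSB_UV = 4.88

#: A/D code limits (microvolt-scale codes).
ADC_MIN, ADC_MAX = -32768, 32767

_CANONICAL_BY_UPPER = {name.upper(): name for name in CANONICAL_LEADS}


class ECGFormatError(ValueError):
    """Malformed ECG CSV header (unknown or duplicated lead token)."""


class SchemaError(ValueError):
    """Structurally wrong file: wrong column count, empty lead list, ..."""


class ECGParseError(ValueError):
    """Non-numeric cell in the sample matrix; names row and column."""


def canonical_lead_name(token: str) -> str:
    """Normalize a lead-name token ("AVR", "avr", " aVR ") to canonical form.

    Raises :class:`ECGFormatError` for tokens that are not one of the 12
    standard lead names.
    """
    key = token.strip().upper()
    try:
        return _CANONICAL_BY_UPPER[key]
    except KeyError:
        raise ECGFormatError(
            f"unrecognized lead name {token!r}; expected one of {list(CANONICAL_LEADS)}"
        ) from None


@dataclass
class ECGRecord:
    """One subject's fixed-rate 12-lead signal matrix in microvolts."""

    record_id: str
    fs: float
    leads: tuple[str, ...]
    samples: np.ndarray  # shape (n_samples, n_leads), microvolts

    def __post_init__(self) -> None:
        self.leads = tuple(self.leads)
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.leads:
            raise SchemaError("record has an empty lead list")
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.leads):
            raise SchemaError(
                f"sample matrix shape {self.samples.shape} does not match "
                f"{len(self.leads)} leads"
            )
        if len(set(self.leads)) != len(self.leads):
            raise SchemaError(f"duplicate lead names in {self.leads}")
        if self.fs <= 0:
            raise SchemaError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead as a 1-D array (a view into the sample matrix)."""
        try:
            j = self.leads.index(canonical_lead_name(name))
        except ValueError:
            raise KeyError(f"lead {name!r} not in record (has {self.leads})") from None
        return self.samples[:, j]

    def with_samples(self, samples: np.ndarray, record_id: str | None = None) -> "ECGRecord":
        """Copy of this record with a replaced sample matrix."""
        return ECGRecord(
            record_id=record_id if record_id is not None else self.record_id,
            fs=self.fs,
            leads=self.leads,
            samples=np.asarray(samples, dtype=float),
        )

    def copy(self) -> "ECGRecord":
        return self.with_samples(self.samples.copy())


# Table-3 schema of the diagnostics file: (name, (lo, hi) numeric range or None)
_DIAG_NUMERIC_RANGES: dict[str, tuple[float, float]] = {
    "PatientAge": (0, 999),
    "VentricularRate": (0, 999),
    "AtrialRate": (0, 999),
    "QRSDuration": (0, 999),
    "QTInterval": (0, 999),
    "QTCorrected": (0, 999),
    "RAxis": (-179, 180),
    "TAxis": (-179, 180),
    "QRSCount": (0, 254),
    "QOnset": (0, 2**16 - 1),
    "QOffset": (0, 2**16 - 1),
    "TOffset": (0, 2**16 - 1),
}

DIAGNOSTICS_COLUMNS = (
    "FileName", "Rhythm", "Beat", "PatientAge", "Gender",
    "VentricularRate", "AtrialRate", "QRSDuration", "QTInterval",
    "QTCorrected", "RAxis", "TAxis", "QRSCount", "QOnset", "QOffset",
    "TOffset",
)


@dataclass
class DiagnosticsRow:
    """Per-record metadata: labels plus vendor summary measurements."""

    FileName: str
    Rhythm: str = ""
    Beat: str = ""
    PatientAge: float | None = None
    Gender: str = ""
    VentricularRate: float | None = None
    AtrialRate: float | None = None
    QRSDuration: float | None = None
    QTInterval: float | None = None
    QTCorrected: float | None = None
    RAxis: float | None = None
    TAxis: float | None = None
    QRSCount: float | None = None
    QOnset: float | None = None
    QOffset: float | None = None
    TOffset: float | None = None
    extra: dict[str, str] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def numeric(self, name: str) -> float:
        """Numeric field as a float, NaN when absent."""
        v = getattr(self, name)
        return float("nan") if v is None else float(v)


def _normalize_gender(raw: str) -> str:
    s = str(raw).strip().upper()
    if s.startswith("F"):
        return "FEMALE"
    if s.startswith("M"):
        return "MALE"
    return s


def read_ecg_csv(path: str | Path, record_id: str | None = None, fs: float = 500.0) -> ECGRecord:
    """Read one ECG CSV (header of lead names, then numeric microvolt rows).

    Column order is preserved exactly as in the file header; lead-name case
    variants ("AVR") are normalized to canonical form ("aVR").
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().strip()
    if not header_line:
        raise ECGFormatError(f"{path}: empty file, no header row")
    tokens = header_line.split(",")
    leads = tuple(canonical_lead_name(tok) for tok in tokens)
    if len(set(leads)) != len(leads):
        raise ECGFormatError(f"{path}: duplicate lead names in header {tokens}")
    if len(leads) != 12:
        raise SchemaError(f"{path}: expected 12 lead columns, found {len(leads)}")

    df = pd.read_csv(path, header=0, dtype=str, skip_blank_lines=True)
    if df.shape[1] != len(leads):
        raise SchemaError(
            f"{path}: data rows have {df.shape[1]} columns, header has {len(leads)}"
        )
    try:
        samples = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for a precise error message
        arr = df.to_numpy(dtype=object)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                try:
                    float(arr[i, j])
                except (TypeError, ValueError):
                    raise ECGParseError(
                        f"{path}: non-numeric value {arr[i, j]!r} at data row "
                        f"{i}, column {leads[j]!r}"
                    ) from None
        raise
    return ECGRecord(
        record_id=record_id if record_id is not None else path.stem,
        fs=fs,
        leads=leads,
        samples=samples,
    )


def write_ecg_csv(record: ECGRecord, path: str | Path) -> Path:
    """Write a record in the database dialect (lead-name header + data rows).

    Integer-valued sample matrices are written as integers so that the
    write -> read round trip is exact.
    """
    path = Path(path)
    samples = record.samples
    if samples.size and np.all(np.isfinite(samples)) and np.array_equal(samples, np.round(samples)):
        df = pd.DataFrame(samples.astype(np.int64), columns=list(record.leads))
    else:
        df = pd.DataFrame(samples, columns=list(record.leads))
    df.to_csv(path, index=False)
    return path


def _parse_diag_row(raw: dict[str, str], row_no: int) -> DiagnosticsRow | None:
    fname = str(raw.get("FileName", "") or "").strip()
    if not fname or fname.lower() == "nan":
        logger.warning("diagnostics row %d rejected: missing FileName", row_no)
        return None
    warnings: list[str] = []
    kwargs: dict = {"FileName": fname}
    kwargs["Rhythm"] = str(raw.get("Rhythm", "") or "").strip()
    kwargs["Beat"] = str(raw.get("Beat", "") or "").strip()
    kwargs["Gender"] = _normalize_gender(raw.get("Gender", "") or "")
    for name, (lo, hi) in _DIAG_NUMERIC_RANGES.items():
        tok = raw.get(name)
        if tok is None or str(tok).strip() in ("", "nan", "NA"):
            kwargs[name] = None
            continue
        try:
            val = float(tok)
        except ValueError:
            warnings.append(f"{name}: non-numeric value {tok!r}")
            kwargs[name] = None
            continue
        if not lo <= val <= hi:
            warnings.append(f"{name}: value {val:g} outside range {lo}-{hi}")
        kwargs[name] = val
    qon, qoff = kwargs.get("QOnset"), kwargs.get("QOffset")
    if qon is not None and qoff is not None and not qon < qoff:
        warnings.append(f"QOnset {qon:g} not before QOffset {qoff:g}")
    known = set(DIAGNOSTICS_COLUMNS)
    kwargs["extra"] = {k: str(v) for k, v in raw.items() if k not in known}
    kwargs["warnings"] = tuple(warnings)
    return DiagnosticsRow(**kwargs)


def read_diagnostics(path: str | Path) -> list[DiagnosticsRow]:
    """Read the diagnostics CSV; out-of-range values become per-row warnings.

    Rows without a FileName are rejected (with a logged reason) rather than
    raising; validation problems are collected on each row's ``warnings``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "FileName" not in df.columns:
        raise SchemaError(f"{path}: diagnostics file lacks a FileName column")
    rows: list[DiagnosticsRow] = []
    for i, raw in enumerate(df.to_dict(orient="records")):
        row = _parse_diag_row(raw, i)
        if row is not None:
            rows.append(row)
    return rows


def write_diagnostics(rows: Sequence[DiagnosticsRow], path: str | Path) -> Path:
    """Write diagnostics rows with the standard column header."""
    path = Path(path)
    out = []
    for r in rows:
        d = {}
        for name in DIAGNOSTICS_COLUMNS:
            v = getattr(r, name)
            if v is None:
                d[name] = ""
            elif isinstance(v, float) and float(v).is_integer():
                d[name] = int(v)
            else:
                d[name] = v
        d.update(r.extra)
        out.append(d)
    pd.DataFrame(out).to_csv(path, index=False)
    return path
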