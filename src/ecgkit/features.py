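"""Interpretable 230-dimensional feature extraction.

The vector decomposes as

* 12 lead-II features — ventricular rate (BPM), atrial rate (BPM), QRS
  duration (ms), QT interval (ms), R axis, T axis, QRS count, Q onset,
  Q offset, RR-interval mean (s), RR-interval variance (s^2), RR-interval
  count.  Rate/RR/QRS-count values are computed from the signal; the
  vendor summary measurements (atrial rate, axes, intervals, onsets) are
  passed through from the diagnostics metadata rather than re-derived.
* 216 morphology values — for each of the 12 leads, the detected local
  extrema are split into QRS peaks (within a window around an R-peak),
  non-QRS peaks, and valleys; each subset contributes the mean and the
  unbiased sample variance of height, width and prominence
  (12 x 3 x 3 x 2 = 216).
* age and gender (FEMALE = 0, MALE = 1).

Prominence is the standard topographic definition (vertical distance from
the extremum to its lowest enclosing contour line) and width is the full
width at half prominence, in samples.  Empty subsets produce NaN entries;
variance is NaN when a subset has fewer than two members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ADC_LSB_UV, CANONICAL_LEADS, DiagnosticsRow, ECGRecord

NAN = float("nan")


@dataclass(frozen=True)
class Extremum:
    """One local maximum or minimum with its morphology measurements."""

    index: int
    height: float      # signal value at index; sign-flipped for valleys
    prominence: float
    width: float       # samples, at half prominence
    kind: str          # "peak" | "valley"


@dataclass
class PeakSet:
    """Extrema partitioned into QRS peaks, non-QRS peaks and valleys."""

    qrs_peaks: list[Extremum] = field(default_factory=list)
    non_qrs_peaks: list[Extremum] = field(default_factory=list)
    valleys: list[Extremum] = field(default_factory=list)


@dataclass(frozen=True)
class FeatureConfig:
    qrs_window_ms: float = 100.0
    #: extrema below this prominence are quantization chatter (2 LSB)
    min_prominence_uv: float = 2 * ADC_LSB_UV
    rhythm_lead: str = "II"


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima.

    A peak is a sample strictly greater than both neighbors; a plateau of
    equal values reports its center sample (the left-center one when the
    plateau has even length).  Valleys are peaks of the negated signal.
    Endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    peaks, _ = sps.find_peaks(x)
    valleys, _ = sps.find_peaks(-x)
    return peaks, valleys


def compute_prominence(x: np.ndarray, index: int, kind: str = "peak") -> float:
    """Topographic prominence of one detected extremum.

    Extend left and right to the nearest strictly higher sample (or the
    signal edge); the base is the higher of the two interval minima and
    the prominence is height minus base.  Valleys are measured on the
    negated signal.
    """
    x = np.asarray(x, dtype=float)
    if kind == "valley":
        x = -x
    peaks, _ = sps.find_peaks(x)
    if index not in peaks:
        raise ValueError(f"index {index} is not a detected {kind}")
    prom, _, _ = sps.peak_prominences(x, np.array([index]))
    return float(prom[0])


def _measure(x: np.ndarray, idx: np.ndarray, kind: str) -> list[Extremum]:
    if idx.size == 0:
        return []
    sig = -x if kind == "valley" else x
    prom, lb, rb = sps.peak_prominences(sig, idx)
    widths, _, _, _ = sps.peak_widths(sig, idx, rel_height=0.5,
                                      prominence_data=(prom, lb, rb))
    return [
        Extremum(index=int(i), height=float(sig[i]), prominence=float(p),
                 width=float(w), kind=kind)
        for i, p, w in zip(idx, prom, widths)
    ]


def measure_extrema(x: np.ndarray, min_prominence_uv: float = 0.0
                    ) -> tuple[list[Extremum], list[Extremum]]:
    """Detect and measure all peaks and valleys of one lead, dropping
    extrema whose prominence is below ``min_prominence_uv``."""
    p_idx, v_idx = find_extrema(x)
    peaks = [e for e in _measure(x, p_idx, "peak") if e.prominence >= min_prominence_uv]
    valleys = [e for e in _measure(x, v_idx, "valley") if e.prominence >= min_prominence_uv]
    return peaks, valleys


def detect_r_peaks(lead_ii: np.ndarray, fs: float) -> np.ndarray:
    """Deterministic R-peak detector (derivative-energy style).

    Band emphasis (5-15 Hz zero-phase band-pass, then a difference filter)
    -> squaring -> 150 ms moving-window integration; candidate maxima at
    least 200 ms apart are thresholded against the upper range of the
    integrated energy, and each detection is refined to the local maximum
    of the raw signal within ±100 ms.
    """
    x = np.asarray(lead_ii, dtype=float)
    n = x.size
    if n < 2 * fs:
        raise ValueError("need at least 2 s of signal for R-peak detection")
    sos = sps.butter(2, [5.0 / (fs / 2), 15.0 / (fs / 2)], btype="band", output="sos")
    banded = sps.sosfiltfilt(sos, x)
    d = np.diff(banded, prepend=banded[0])
    energy = d * d
    win = max(int(round(0.150 * fs)), 1)
    m = np.convolve(energy, np.ones(win) / win, mode="same")
    if m.max() <= 0:
        return np.array([], dtype=int)
    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(m, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)
    ref = np.percentile(m[cand], 95)
    cand = cand[m[cand] >= 0.30 * ref]
    half = int(round(0.100 * fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(n, c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement, keeping the taller peak
    keep: list[int] = []
    for r in refined:
        if keep and r - keep[-1] < refractory:
            if x[r] > x[keep[-1]]:
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return np.asarray(keep, dtype=int)


def rr_features(r_peaks: np.ndarray, fs: float) -> dict[str, float]:
    """Rate and RR-interval statistics from detected R-peaks.

    With fewer than two peaks the rate and RR statistics are NaN; the
    variance additionally needs at least three peaks (two intervals).
    """
    r_peaks = np.asarray(r_peaks)
    out = {
        "ventricular_rate_bpm": NAN,
        "rr_mean_s": NAN,
        "rr_variance_s2": NAN,
        "rr_interval_count": float(max(len(r_peaks) - 1, 0)),
        "qrs_count": float(len(r_peaks)),
    }
    if len(r_peaks) >= 2:
        rr = np.diff(r_peaks) / fs
        out["rr_mean_s"] = float(rr.mean())
        out["ventricular_rate_bpm"] = 60.0 / out["rr_mean_s"]
        if rr.size >= 2:
            out["rr_variance_s2"] = float(rr.var(ddof=1))
    return out


def assign_peak_sets(peaks: Sequence[Extremum], valleys: Sequence[Extremum],
                     r_peaks: np.ndarray, fs: float,
                     qrs_window_ms: float = FeatureConfig.qrs_window_ms) -> PeakSet:
    """Partition extrema: peaks within ±window/2 of an R-peak are QRS peaks,
    the rest are non-QRS peaks; every valley goes to the valley set."""
    r_peaks = np.asarray(r_peaks)
    half = qrs_window_ms / 2.0 * fs / 1000.0
    ps = PeakSet(valleys=list(valleys))
    for e in peaks:
        if r_peaks.size and np.min(np.abs(r_peaks - e.index)) <= half:
            ps.qrs_peaks.append(e)
        else:
            ps.non_qrs_peaks.append(e)
    return ps


_MORPH_SUBSETS = ("qrs", "nonqrs", "valley")
_MORPH_MEASURES = ("height", "width", "prominence")
_MORPH_STATS = ("mean", "var")


def lead_morphology_features(peak_set: PeakSet) -> dict[str, float]:
    """18 values: {QRS, non-QRS, valley} x {height, width, prominence} x
    {mean, unbiased variance}; NaN for empty subsets (variance needs n >= 2)."""
    groups = {
        "qrs": peak_set.qrs_peaks,
        "nonqrs": peak_set.non_qrs_peaks,
        "valley": peak_set.valleys,
    }
    out: dict[str, float] = {}
    for sub in _MORPH_SUBSETS:
        members = groups[sub]
        for measure in _MORPH_MEASURES:
            vals = np.array([getattr(e, measure) for e in members], dtype=float)
            out[f"{sub}_{measure}_mean"] = float(vals.mean()) if vals.size else NAN
            out[f"{sub}_{measure}_var"] = (
                float(vals.var(ddof=1)) if vals.size >= 2 else NAN)
    return out


LEAD_II_FEATURES = (
    "ventricular_rate_bpm", "atrial_rate_bpm", "qrs_duration_ms",
    "qt_interval_ms", "r_axis", "t_axis", "qrs_count", "q_onset",
    "q_offset", "rr_mean_s", "rr_variance_s2", "rr_interval_count",
)


def feature_names() -> tuple[str, ...]:
    """The fixed, documented order of the 230 features."""
    names = list(LEAD_II_FEATURES)
    for lead in CANONICAL_LEADS:
        for sub in _MORPH_SUBSETS:
            for measure in _MORPH_MEASURES:
                for stat in _MORPH_STATS:
                    names.append(f"{lead}_{sub}_{measure}_{stat}")
    names += ["age_years", "gender"]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = feature_names()


@dataclass
class FeatureVector:
    """Named, ordered 230-dimensional feature vector for one record."""

    record_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("feature names and values disagree in length")

    def __len__(self) -> int:
        return self.values.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.record_id)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _encode_gender(gender: str) -> float:
    g = (gender or "").strip().upper()
    if g.startswith("F"):
        return 0.0
    if g.startswith("M"):
        return 1.0
    return NAN


def build_feature_vector(record: ECGRecord, meta: DiagnosticsRow,
                         config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Assemble the full 230-entry vector for one record.

    Rhythm-lead rate/RR statistics and the QRS count are computed from the
    signal; atrial rate, axes, intervals and wave onsets are passed
    through from the metadata (NaN when absent).
    """
    if meta.FileName != record.record_id:
        raise ValueError(
            f"metadata FileName {meta.FileName!r} does not match record "
            f"{record.record_id!r}")
    lead_ii = record.lead(config.rhythm_lead)
    r_peaks = detect_r_peaks(lead_ii, record.fs)
    rr = rr_features(r_peaks, record.fs)
    values = [
        rr["ventricular_rate_bpm"],
        meta.numeric("AtrialRate"),
        meta.numeric("QRSDuration"),
        meta.numeric("QTInterval"),
        meta.numeric("RAxis"),
        meta.numeric("TAxis"),
        rr["qrs_count"],
        meta.numeric("QOnset"),
        meta.numeric("QOffset"),
        rr["rr_mean_s"],
        rr["rr_variance_s2"],
        rr["rr_interval_count"],
    ]
    for lead in CANONICAL_LEADS:
        x = record.lead(lead)
        peaks, valleys = measure_extrema(x, config.min_prominence_uv)
        ps = assign_peak_sets(peaks, valleys, r_peaks, record.fs, config.qrs_window_ms)
        morph = lead_morphology_features(ps)
        for sub in _MORPH_SUBSETS:
            for measure in _MORPH_MEASURES:
                for stat in _MORPH_STATS:
                    values.append(morph[f"{sub}_{measure}_{stat}"])
    values.append(meta.numeric("PatientAge"))
    values.append(_encode_gender(meta.Gender))
    return FeatureVector(record_id=record.record_id, names=FEATURE_NAMES,
                         values=np.array(values, dtype=float))


def feature_table(records: Sequence[ECGRecord], metas: Sequence[DiagnosticsRow],
                  config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Feature matrix for many records, indexed by FileName."""
    by_name = {m.FileName: m for m in metas}
    rows = []
    for rec in records:
        if rec.record_id not in by_name:
            raise KeyError(f"no diagnostics row for record {rec.record_id!r}")
        rows.append(build_feature_vector(rec, by_name[rec.record_id], config).to_series())
    return pd.DataFrame(rows)
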