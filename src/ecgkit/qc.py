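"""Automatic consistency checking of 12-lead records.

Two physical constraints tie the limb leads together: the lead-II identity
(II = I + III, Einthoven) and the augmented-lead sum (aVR + aVL + aVF = 0,
Goldberger).  Electrodes that slip off during acquisition leave a lead
displaying a straight line.  Records violating any of these are flagged
for exclusion.

Default tolerances are anchored to the A/D step of 4.88 uV: identity
residuals up to 3 LSB are accepted on up to 1% of samples, and a lead is
"flat" when 2 s windows with variance below 1 LSB^2 cover at least 90% of
the record.

An LA/RA arm-electrode swap preserves *both* identities (lead I flips sign,
II/III and aVR/aVL exchange), so it cannot be caught by them; a heuristic
advisory flag (negative net R-wave deflection in lead I) is reported but
never causes exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import ADC_LSB_UV, ECGRecord


class QCCheckError(ValueError):
    """A required lead is missing from the record."""


@dataclass(frozen=True)
class QCPolicy:
    """Thresholds of the error-checking algorithm."""

    tol_uv: float = 3 * ADC_LSB_UV
    max_violation_frac: float = 0.01
    flatline_window_s: float = 2.0
    flatline_var_threshold: float = ADC_LSB_UV ** 2
    flatline_coverage: float = 0.90


@dataclass
class QCReport:
    record_id: str
    einthoven_ok: bool
    goldberger_ok: bool
    flatline_leads: list[str]
    max_einthoven_residual_uv: float
    max_goldberger_residual_uv: float
    einthoven_violation_frac: float
    goldberger_violation_frac: float
    excluded: bool
    reasons: list[str] = field(default_factory=list)
    advisories: list[str] = field(default_factory=list)


def _require_leads(record: ECGRecord, names: Iterable[str]) -> None:
    missing = [n for n in names if n not in record.leads]
    if missing:
        raise QCCheckError(f"record {record.record_id!r} lacks lead(s) {missing}")


def _identity_stats(residual: np.ndarray, tol_uv: float,
                    max_violation_frac: float) -> tuple[bool, float, float]:
    absres = np.abs(residual)
    frac = float(np.mean(absres > tol_uv))
    return frac <= max_violation_frac, float(absres.max(initial=0.0)), frac


def check_einthoven(record: ECGRecord, tol_uv: float = QCPolicy.tol_uv,
                    max_violation_frac: float = QCPolicy.max_violation_frac
                    ) -> tuple[bool, float, float]:
    """Lead-II identity: passes iff the fraction of samples with
    |II - (I + III)| > tol is at most ``max_violation_frac``.

    Returns (ok, max residual in uV, violation fraction).
    """
    _require_leads(record, ("I", "II", "III"))
    residual = record.lead("II") - (record.lead("I") + record.lead("III"))
    return _identity_stats(residual, tol_uv, max_violation_frac)


def check_goldberger(record: ECGRecord, tol_uv: float = QCPolicy.tol_uv,
                     max_violation_frac: float = QCPolicy.max_violation_frac
                     ) -> tuple[bool, float, float]:
    """Augmented-lead sum identity: |aVR + aVL + aVF| within tolerance."""
    _require_leads(record, ("aVR", "aVL", "aVF"))
    residual = record.lead("aVR") + record.lead("aVL") + record.lead("aVF")
    return _identity_stats(residual, tol_uv, max_violation_frac)


def detect_flatline(record: ECGRecord,
                    window_s: float = QCPolicy.flatline_window_s,
                    var_threshold: float = QCPolicy.flatline_var_threshold,
                    coverage: float = QCPolicy.flatline_coverage) -> list[str]:
    """Leads where low-variance sliding windows cover >= ``coverage`` of
    the record (a straight-line lead from a slipped electrode)."""
    n = record.n_samples
    w = int(round(window_s * record.fs))
    if w < 2:
        raise ValueError("flatline window must span at least 2 samples")
    w = min(w, n)
    flat: list[str] = []
    for name in record.leads:
        x = record.lead(name)
        # rolling mean/variance via cumulative sums, window start per sample
        c1 = np.concatenate([[0.0], np.cumsum(x)])
        c2 = np.concatenate([[0.0], np.cumsum(x * x)])
        s1 = c1[w:] - c1[:-w]
        s2 = c2[w:] - c2[:-w]
        var = s2 / w - (s1 / w) ** 2
        low = var <= var_threshold + 1e-12
        if not low.any():
            continue
        # union of flagged windows, as a difference array over samples
        cover = np.zeros(n + 1)
        starts = np.flatnonzero(low)
        cover[starts] += 1
        cover[starts + w] -= 1
        covered_frac = np.mean(np.cumsum(cover[:-1]) > 0)
        if covered_frac >= coverage:
            flat.append(name)
    return flat


def _swap_advisory(record: ECGRecord) -> list[str]:
    if "I" not in record.leads:
        return []
    x = record.lead("I")
    net = float(x.max(initial=0.0) + x.min(initial=0.0))
    if net < 0:
        return ["lead I net deflection negative: possible LA/RA electrode swap"]
    return []


def qc_record(record: ECGRecord, policy: QCPolicy = QCPolicy()) -> QCReport:
    """Run every check on one record and assemble the report."""
    e_ok, e_max, e_frac = check_einthoven(record, policy.tol_uv, policy.max_violation_frac)
    g_ok, g_max, g_frac = check_goldberger(record, policy.tol_uv, policy.max_violation_frac)
    flat = detect_flatline(record, policy.flatline_window_s,
                           policy.flatline_var_threshold, policy.flatline_coverage)
    reasons = []
    if not e_ok:
        reasons.append(
            f"lead-II identity violated on {e_frac:.1%} of samples "
            f"(max residual {e_max:.1f} uV)")
    if not g_ok:
        reasons.append(
            f"augmented-lead sum violated on {g_frac:.1%} of samples "
            f"(max residual {g_max:.1f} uV)")
    if flat:
        reasons.append("flatline lead(s): " + ", ".join(flat))
    return QCReport(
        record_id=record.record_id,
        einthoven_ok=e_ok,
        goldberger_ok=g_ok,
        flatline_leads=flat,
        max_einthoven_residual_uv=e_max,
        max_goldberger_residual_uv=g_max,
        einthoven_violation_frac=e_frac,
        goldberger_violation_frac=g_frac,
        excluded=bool(reasons),
        reasons=reasons,
        advisories=_swap_advisory(record),
    )


def qc_filter(records: Sequence[ECGRecord], policy: QCPolicy = QCPolicy()
              ) -> tuple[list[ECGRecord], list[QCReport]]:
    """Partition records into kept / excluded; one report per input."""
    reports = [qc_record(r, policy) for r in records]
    kept = [r for r, rep in zip(records, reports) if not rep.excluded]
    return kept, reports
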