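"""Composite immune-monitoring indices and per-subject derived quantities.

All indices are computed on the absolute MESF scale (post-harmonization
consensus values):

* CD64 index = (nCD64 / lymCD64) / (mCD64 / nCD64) — dimensionless;
  lymphocytes are CD64-negative and monocytes constitutively positive, so
  the index amplifies the infection-driven neutrophil signal.
* Sepsis Index SI = 100 * nCD64 / mHLA-DR — rises with the
  pro-inflammatory axis (nCD64) and with immunosuppression (low mHLA-DR).

Longitudinal change is Δx = x(second test) − x(first test); a subject is
"exacerbating" iff the SOFA score increased between the two tests.  The
renal SOFA component is only retained when creatinine crosses an absolute
threshold (default 171 μmol/L, the SOFA ≥ 2 renal boundary) or rises by a
configurable ratio over baseline — stable transplant recipients carry
chronically elevated creatinine that would otherwise inflate SOFA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "SubjectRecord",
    "LongitudinalPair",
    "MARKER_CUTOFFS",
    "cd64_index",
    "sepsis_index",
    "longitudinal_delta",
    "adjust_renal_sofa",
    "binarize_marker",
]

#: Youden-derived diagnostic cutoffs on the MESF scale (strict >).
MARKER_CUTOFFS: dict[str, float] = {"nCD64": 3089.0, "mHLA-DR": 2433.0}

RENAL_CREATININE_THRESHOLD = 171.0  # μmol/L, SOFA renal >= 2 boundary
RENAL_RELATIVE_RATIO = 1.5  # "obvious increase" over baseline


@dataclass
class SubjectRecord:
    """One subject at one timepoint: grouping, consensus MESFs, indices."""

    subject_id: str
    group: str  # 'HC' | 'stable' | 'infection'
    timepoint: int = 1
    sepsis: Optional[bool] = None
    pathogen: Optional[str] = None  # 'bacterial' | 'viral' | 'fungal'
    ncd64: Optional[float] = None
    mcd64: Optional[float] = None
    lymcd64: Optional[float] = None
    mhladr: Optional[float] = None
    tbnk_counts: dict[str, float] = field(default_factory=dict)  # cells/μl
    tbnk_percent: dict[str, float] = field(default_factory=dict)
    creatinine: Optional[float] = None  # μmol/L
    sofa: Optional[float] = None  # points

    @property
    def cd64_index(self) -> Optional[float]:
        try:
            return cd64_index(self.ncd64, self.lymcd64, self.mcd64)
        except (TypeError, ValueError):
            return None

    @property
    def sepsis_index(self) -> Optional[float]:
        try:
            return sepsis_index(self.ncd64, self.mhladr)
        except (TypeError, ValueError):
            return None


@dataclass(frozen=True)
class LongitudinalPair:
    subject_id: str
    deltas: dict[str, Optional[float]]  # marker/index -> second - first
    delta_sofa: Optional[float]
    exacerbation: Optional[bool]  # ΔSOFA > 0


def cd64_index(ncd64: float, lymcd64: float, mcd64: float) -> float:
    """(nCD64/lymCD64)/(mCD64/nCD64), algebraically nCD64²/(lymCD64·mCD64)."""
    for name, v in (("nCD64", ncd64), ("lymCD64", lymcd64), ("mCD64", mcd64)):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return (ncd64 / lymcd64) / (mcd64 / ncd64)


def sepsis_index(ncd64: float, mhladr: float) -> float:
    """SI = 100 * nCD64 / mHLA-DR."""
    if ncd64 is None or ncd64 <= 0:
        raise ValueError(f"nCD64 must be > 0, got {ncd64}")
    if mhladr is None or mhladr <= 0:
        raise ValueError(f"mHLA-DR must be > 0, got {mhladr}")
    return 100.0 * ncd64 / mhladr


def longitudinal_delta(first: SubjectRecord, second: SubjectRecord) -> LongitudinalPair:
    """Second-minus-first change in markers, indices and SOFA.

    A missing value at either timepoint yields a missing Δ for that
    quantity, never an error; the exacerbation flag is ΔSOFA > 0.
    """
    if first.subject_id != second.subject_id:
        raise ValueError(
            f"subject mismatch: {first.subject_id!r} vs {second.subject_id!r}"
        )
    if first.timepoint >= second.timepoint:
        raise ValueError("first timepoint must precede second")

    def _delta(a: Optional[float], b: Optional[float]) -> Optional[float]:
        return None if a is None or b is None else b - a

    deltas = {
        "nCD64": _delta(first.ncd64, second.ncd64),
        "mHLA-DR": _delta(first.mhladr, second.mhladr),
        "SI": _delta(first.sepsis_index, second.sepsis_index),
        "CD64 index": _delta(first.cd64_index, second.cd64_index),
    }
    dsofa = _delta(first.sofa, second.sofa)
    return LongitudinalPair(
        subject_id=first.subject_id,
        deltas=deltas,
        delta_sofa=dsofa,
        exacerbation=None if dsofa is None else dsofa > 0,
    )


def adjust_renal_sofa(
    creatinine: float,
    baseline_creatinine: Optional[float],
    raw_renal_sofa: float,
    absolute_threshold: float = RENAL_CREATININE_THRESHOLD,
    relative_ratio: float = RENAL_RELATIVE_RATIO,
) -> float:
    """Retain the renal SOFA contribution only under true renal dysfunction.

    Retained iff creatinine >= ``absolute_threshold`` (μmol/L) or
    creatinine >= ``relative_ratio`` x baseline; otherwise the renal
    component is set to 0.  With no baseline available only the absolute
    rule applies (with a warning when it alone decides).
    """
    if creatinine <= 0:
        raise ValueError(f"creatinine must be > 0, got {creatinine}")
    if creatinine >= absolute_threshold:
        return raw_renal_sofa
    if baseline_creatinine is None:
        warnings.warn(
            "baseline creatinine missing; relative-increase rule skipped, "
            "absolute rule only"
        )
        return 0.0
    if creatinine >= relative_ratio * baseline_creatinine:
        return raw_renal_sofa
    return 0.0


def binarize_marker(
    value: float,
    marker: str,
    cutoffs: Optional[dict[str, float]] = None,
) -> bool:
    """Strict greater-than dichotomization at the configured Youden cutoff."""
    cutoffs = cutoffs or MARKER_CUTOFFS
    if marker not in cutoffs:
        raise KeyError(f"no cutoff configured for marker {marker!r}")
    return value > cutoffs[marker]
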