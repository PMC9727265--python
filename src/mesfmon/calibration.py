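"""MFI -> MESF conversion via the bead calibration regression.

Calibration beads carry known numbers of PE molecules per bead level.
For each instrument protocol an ordinary least-squares line

    log10(MFI) = a + b * log10(MESF)

is fitted through the bead peaks; a sample MFI is then converted to the
absolute MESF scale by inverting that line.  Because the regression is
fitted with MFI as the response (as the bead kit protocol prescribes),
conversion inverts the fitted line rather than refitting the reverse
regression — valid since b > 0 is enforced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gating import BeadPeaks, MfiResult

__all__ = [
    "CalibrationCurve",
    "MarkerMeasurement",
    "fit_curve",
    "mfi_to_mesf",
    "calibrate_measurements",
    "save_curves",
    "load_curves",
]

#: R^2 below this raises a calibration-quality warning (not an error).
R2_WARN_FLOOR = 0.98


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log10(MFI) = intercept + slope * log10(MESF) for one protocol."""

    protocol_id: str
    slope: float
    intercept: float
    r_squared: float
    n_levels: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(
                f"protocol {self.protocol_id!r}: slope must be > 0 "
                f"(fluorescence must increase with PE molecules), got {self.slope}"
            )
        if self.n_levels < 2:
            raise ValueError("calibration needs >= 2 bead levels")


@dataclass(frozen=True)
class MarkerMeasurement:
    """One marker on one subject under one protocol, as MFI and MESF."""

    subject_id: str
    timepoint: int
    protocol_id: str
    population: str
    marker: str
    mfi: float
    mesf: float


def fit_curve(peaks: BeadPeaks, lot_mesf: Sequence[float]) -> CalibrationCurve:
    """OLS of log10(peak MFI) on log10(lot MESF).

    ``lot_mesf`` are the known PE-molecule values of the bead levels, in
    the same ascending order as ``peaks.mfi``.
    """
    mesf = np.asarray(lot_mesf, dtype=float)
    mfi = np.asarray(peaks.mfi, dtype=float)
    if len(mesf) != len(mfi):
        raise ValueError(
            f"peak count {len(mfi)} != lot level count {len(mesf)}"
        )
    if len(mesf) < 2:
        raise ValueError("need >= 2 bead levels to fit a line")
    if (mesf <= 0).any() or (mfi <= 0).any():
        raise ValueError("bead MESF and MFI values must be strictly positive")
    x = np.log10(mesf)
    yv = np.log10(mfi)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(MESF); cannot fit")
    slope, intercept = np.polyfit(x, yv, 1)
    resid = yv - (intercept + slope * x)
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    if r2 < R2_WARN_FLOOR:
        warnings.warn(
            f"protocol {peaks.protocol_id!r}: calibration R^2 = {r2:.4f} "
            f"below quality floor {R2_WARN_FLOOR}"
        )
    return CalibrationCurve(
        protocol_id=peaks.protocol_id,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_levels=len(mesf),
    )


def mfi_to_mesf(mfi: float, curve: CalibrationCurve) -> float:
    """Invert the calibration line: MESF = 10**((log10 MFI - a) / b)."""
    if mfi <= 0:
        raise ValueError(f"MFI must be > 0, got {mfi}")
    return float(10 ** ((np.log10(mfi) - curve.intercept) / curve.slope))


def calibrate_measurements(
    mfis: Sequence[MfiResult],
    curves: Mapping[str, CalibrationCurve],
) -> list[MarkerMeasurement]:
    """Convert a batch of MFI results to MESF, retaining protocol provenance."""
    out: list[MarkerMeasurement] = []
    for m in mfis:
        curve = curves.get(m.protocol_id)
        if curve is None:
            raise KeyError(
                f"no calibration curve for protocol {m.protocol_id!r}"
            )
        out.append(
            MarkerMeasurement(
                subject_id=m.sample_id,
                timepoint=m.timepoint,
                protocol_id=m.protocol_id,
                population=m.population,
                marker=m.marker,
                mfi=m.mfi,
                mesf=mfi_to_mesf(m.mfi, curve),
            )
        )
    return out


def save_curves(curves: Mapping[str, CalibrationCurve], path: str | Path) -> None:
    payload = {
        pid: {
            "slope": c.slope,
            "intercept": c.intercept,
            "r_squared": c.r_squared,
            "n_levels": c.n_levels,
        }
        for pid, c in curves.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_curves(path: str | Path) -> dict[str, CalibrationCurve]:
    payload = json.loads(Path(path).read_text())
    return {
        pid: CalibrationCurve(
            protocol_id=pid,
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            n_levels=d["n_levels"],
        )
        for pid, d in payload.items()
    }
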