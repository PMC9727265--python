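"""Population gating on event tables and bead-peak location.

Two staining panels are supported:

* ``nCD64`` panel — channels CD45, SSC, PE (anti-CD64-PE).  Leukocyte
  populations are separated on CD45 positivity and side scatter:
  lymphocytes are CD45-bright with low SSC, monocytes intermediate SSC,
  neutrophils high SSC.
* ``mHLA-DR`` panel — channels CD14, SSC, PE (anti-HLA-DR-PE).
  Monocytes are gated as CD14-positive.

Gates are rectangular thresholds in log10 fluorescence, configurable via
:class:`GatingParams`.  Bead runs are clustered on log10 PE intensity with
1-D k-means (quantile initialization) to locate one peak per bead level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "GatingParams",
    "GatedPopulations",
    "MfiResult",
    "BeadPeaks",
    "PANEL_CHANNELS",
    "gate_populations",
    "extract_mfi",
    "find_bead_peaks",
]

PANEL_CHANNELS: dict[str, tuple[str, ...]] = {
    "nCD64": ("CD45", "SSC", "PE"),
    "mHLA-DR": ("CD14", "SSC", "PE"),
    "beads": ("PE",),
}


@dataclass(frozen=True)
class EventTable:
    """Per-event channel intensities for one sample under one protocol."""

    sample_id: str
    protocol_id: str
    panel_id: str
    data: pd.DataFrame  # one column per channel, optional 'truth' column
    timepoint: int = 1
    compensated_pe: bool = False

    def __post_init__(self) -> None:
        required = PANEL_CHANNELS.get(self.panel_id)
        if required is None:
            raise ValueError(f"unknown panel {self.panel_id!r}")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel {self.panel_id!r} missing channels {missing}")
        vals = self.data[list(required)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite channel intensities")
        if (self.data["PE"].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative PE intensities; apply floor handling upstream")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        df.insert(0, "event_id", np.arange(len(df)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sample_id: str,
        protocol_id: str,
        panel_id: str,
        timepoint: int = 1,
    ) -> "EventTable":
        df = pd.read_csv(path)
        df = df.drop(columns=[c for c in ("event_id",) if c in df.columns])
        return cls(sample_id, protocol_id, panel_id, df, timepoint=timepoint)


@dataclass(frozen=True)
class GatingParams:
    """Rectangular gate thresholds, all in log10 fluorescence units."""

    cd45_positive: float = 2.0
    ssc_lymph_max: float = 1.95
    ssc_mono_max: float = 2.65
    cd14_positive: float = 2.2
    min_events: int = 100


@dataclass
class GatedPopulations:
    """Disjoint population -> event-index sets plus the params used."""

    populations: dict[str, np.ndarray]
    params: GatingParams
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {p: len(ix) for p, ix in self.populations.items()}


@dataclass(frozen=True)
class MfiResult:
    sample_id: str
    protocol_id: str
    population: str
    marker: str
    mfi: float
    n_events: int
    averaging: str  # 'arithmetic' | 'geometric'
    timepoint: int = 1
    warning: str | None = None


@dataclass(frozen=True)
class BeadPeaks:
    protocol_id: str
    mfi: tuple[float, ...]  # ascending, one per bead level
    n_events: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.mfi) != sorted(self.mfi):
            raise ValueError("bead peak MFIs must be strictly increasing")
        if len(set(self.mfi)) != len(self.mfi):
            raise ValueError("duplicate bead peak MFIs")


def gate_populations(
    events: EventTable,
    params: GatingParams | None = None,
) -> GatedPopulations:
    """Assign events to leukocyte populations with rectangular gates.

    Populations below ``params.min_events`` are flagged (never silently
    dropped); an empty event table is an error.
    """
    params = params or GatingParams()
    if events.n_events == 0:
        raise ValueError("no events to gate")
    df = events.data
    with np.errstate(divide="ignore"):
        log_ssc = np.log10(np.maximum(df["SSC"].to_numpy(dtype=float), 1e-12))

    pops: dict[str, np.ndarray] = {}
    if events.panel_id == "nCD64":
        log_cd45 = np.log10(np.maximum(df["CD45"].to_numpy(dtype=float), 1e-12))
        positive = log_cd45 > params.cd45_positive
        lymph = positive & (log_ssc <= params.ssc_lymph_max)
        mono = positive & (log_ssc > params.ssc_lymph_max) & (log_ssc <= params.ssc_mono_max)
        neut = positive & (log_ssc > params.ssc_mono_max)
        pops = {
            "neutrophils": np.flatnonzero(neut),
            "monocytes": np.flatnonzero(mono),
            "lymphocytes": np.flatnonzero(lymph),
        }
    elif events.panel_id == "mHLA-DR":
        log_cd14 = np.log10(np.maximum(df["CD14"].to_numpy(dtype=float), 1e-12))
        pops = {"monocytes": np.flatnonzero(log_cd14 > params.cd14_positive)}
    else:
        raise ValueError(f"panel {events.panel_id!r} has no gating scheme")

    gated = GatedPopulations(populations=pops, params=params)
    for name, ix in pops.items():
        if len(ix) == 0:
            gated.flags[name] = "empty"
        elif len(ix) < params.min_events:
            gated.flags[name] = f"low-count ({len(ix)} < {params.min_events})"
    return gated


def extract_mfi(
    events: EventTable,
    gated: GatedPopulations,
    population: str,
    marker: str,
    channel: str = "PE",
    averaging: str = "arithmetic",
) -> MfiResult:
    """Population MFI on one channel: arithmetic mean (default) or geometric."""
    ix = gated.populations.get(population)
    if ix is None:
        raise KeyError(f"population {population!r} not gated")
    if len(ix) == 0:
        raise ValueError(f"population {population!r} is empty")
    vals = events.data[channel].to_numpy(dtype=float)[ix]
    if averaging == "arithmetic":
        mfi = float(vals.mean())
    elif averaging == "geometric":
        if (vals <= 0).any():
            raise ValueError("geometric MFI requires strictly positive intensities")
        mfi = float(np.exp(np.log(vals).mean()))
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    warning = None
    if len(ix) < gated.params.min_events:
        warning = f"only {len(ix)} events (< {gated.params.min_events})"
        warnings.warn(f"{events.sample_id}/{population}: {warning}")
    return MfiResult(
        sample_id=events.sample_id,
        protocol_id=events.protocol_id,
        population=population,
        marker=marker,
        mfi=mfi,
        n_events=len(ix),
        averaging=averaging,
        timepoint=events.timepoint,
        warning=warning,
    )


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """1-D k-means with quantile initialization; returns (centers, labels)."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [x[labels == j].mean() if (labels == j).any() else centers[j] for j in range(k)]
        )
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    return centers, labels


def find_bead_peaks(events: EventTable, lot_mesf: Sequence[float]) -> BeadPeaks:
    """Locate one MFI peak per bead level by 1-D k-means on log10 PE.

    Raises if two lot levels collapse onto one detected location (merged
    peaks), naming the offending levels.
    """
    if events.n_events == 0:
        raise ValueError("bead run has no events")
    k = len(lot_mesf)
    pe = events.data["PE"].to_numpy(dtype=float)
    if (pe <= 0).any():
        raise ValueError("bead PE intensities must be strictly positive")
    log_pe = np.log10(pe)
    centers, labels = _kmeans_1d(log_pe, k)
    order = np.argsort(centers)
    peak_mfi, counts = [], []
    for j in order:
        members = pe[labels == j]
        if len(members) == 0:
            raise ValueError(f"bead level cluster {j} is empty (merged peaks)")
        peak_mfi.append(float(members.mean()))
        counts.append(int(len(members)))
    merged = [
        (i, i + 1)
        for i in range(k - 1)
        if not peak_mfi[i + 1] > peak_mfi[i] * (1 + 1e-9)
    ]
    if merged:
        raise ValueError(f"bead levels merged at adjacent positions {merged}")
    return BeadPeaks(
        protocol_id=events.protocol_id,
        mfi=tuple(peak_mfi),
        n_events=tuple(counts),
    )
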