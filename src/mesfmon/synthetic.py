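"""Seeded synthetic cytometry study generator.

Emulates the structure of a multi-protocol immune-monitoring study in
kidney transplantation: a cohort of healthy controls, stable transplant
recipients and infected recipients (with sepsis/pathogen subgroups), each
subject carrying true receptor quantities on the absolute MESF scale;
four instrument protocols that distort the truth through a log-domain
gain/offset plus multiplicative lognormal noise; four-level calibration
bead runs obeying the same gain law; and event-level cell clouds whose
gating channels (CD45, CD14, side scatter) separate the leukocyte
populations.

Marker truths are lognormal and *moment-matched*: the lognormal
parameters are chosen so the arithmetic mean and SD equal the group
targets exactly in expectation (markers are strictly positive and
heavy-tailed, which a lognormal captures).  Default group targets are the
published group summaries of the study population this generator
emulates; quantities the source tables do not print (lymphocyte/monocyte
CD64, bead lot values, scatter-channel locations) are declared defaults,
documented as such.

Every generator takes an explicit integer seed; identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gating import EventTable
from .harmonization import ProtocolMeasurementSet

__all__ = [
    "ProtocolSpec",
    "BeadLot",
    "SubgroupSpec",
    "CohortSpec",
    "SubjectTruth",
    "default_protocols",
    "default_bead_lot",
    "default_cohort_spec",
    "generate_cohort",
    "generate_protocol_measurements",
    "generate_bead_run",
    "generate_events",
    "protocol_transform",
]

MARKERS = ("nCD64", "mCD64", "lymCD64", "mHLA-DR")
TBNK_SUBSETS = ("CD3", "CD4", "CD8", "NK", "B")

#: floor for degenerate (≈0) receptor quantities, MESF units
POSITIVE_FLOOR = 1.0


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolSpec:
    """One instrument setting: log-domain gain/offset + multiplicative noise.

    A true quantity x (MESF) is observed as
    ``MFI = 10**(offset + gain * log10(x)) * noise`` with lognormal noise
    of unit mean and coefficient of variation ``noise_cv``.
    """

    protocol_id: str
    gain: float = 1.0
    offset: float = 0.0
    noise_cv: float = 0.05
    bead_lot: str = "default"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"protocol {self.protocol_id!r}: gain must be > 0")
        if self.noise_cv < 0:
            raise ValueError(f"protocol {self.protocol_id!r}: noise CV must be >= 0")


@dataclass(frozen=True)
class BeadLot:
    """Calibrated PE-molecule values per bead level, ascending."""

    mesf_levels: tuple[float, ...] = (500.0, 5_000.0, 25_000.0, 60_000.0)
    events_per_level: int = 2_000
    spread_cv: float = 0.02

    def __post_init__(self) -> None:
        lv = self.mesf_levels
        if any(v <= 0 for v in lv) or any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("bead levels must be strictly increasing and positive")


@dataclass(frozen=True)
class SubgroupSpec:
    """Target (mean, SD) parameters for one clinical subgroup."""

    group: str  # 'HC' | 'stable' | 'infection'
    n: int
    sepsis: Optional[bool] = None
    markers: dict[str, tuple[float, float]] = field(default_factory=dict)
    tbnk: dict[str, tuple[float, float]] = field(default_factory=dict)
    creatinine: tuple[float, float] = (100.0, 20.0)
    sofa: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for name, (m, s) in self.markers.items():
            if m <= 0 or s <= 0:
                raise ValueError(f"{self.group}/{name}: mean and SD must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    subgroups: tuple[SubgroupSpec, ...]
    pathogen_counts: dict[str, int] = field(
        default_factory=lambda: {"bacterial": 26, "viral": 13, "fungal": 11}
    )
    n_second_timepoint: int = 21  # infection subjects tested twice
    n_second_sepsis: int = 14
    n_exacerbation: int = 3  # ΔSOFA > 0 among the retested
    seed: int = 0


def default_protocols(noise_cv: float = 0.05) -> list[ProtocolSpec]:
    """Four instrument settings: three PMT voltages on one cytometer plus a
    fixed setting on a second instrument, with distinct gains/offsets."""
    return [
        ProtocolSpec("canto_high", gain=1.00, offset=0.60, noise_cv=noise_cv),
        ProtocolSpec("canto_medium", gain=1.00, offset=0.00, noise_cv=noise_cv),
        ProtocolSpec("canto_low", gain=1.00, offset=-0.40, noise_cv=noise_cv),
        ProtocolSpec("dxflex", gain=0.97, offset=0.20, noise_cv=noise_cv),
    ]


def default_bead_lot() -> BeadLot:
    return BeadLot()


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Study-sized cohort: 26 HC / 65 stable / 50 infection (19 sepsis).

    Marker and TBNK targets follow the published group summaries; CD64 on
    lymphocytes/monocytes and all healthy-control TBNK values are declared
    defaults chosen to give realistic composite-index magnitudes.
    """
    hc = SubgroupSpec(
        group="HC",
        n=26,
        markers={
            "nCD64": (1192.58, 537.61),
            "mHLA-DR": (2341.27, 781.75),
            "mCD64": (2000.0, 800.0),
            "lymCD64": (60.0, 24.0),
        },
        tbnk={
            "CD3": (1400.0, 400.0),
            "CD4": (800.0, 250.0),
            "CD8": (500.0, 200.0),
            "NK": (300.0, 150.0),
            "B": (250.0, 100.0),
        },
        creatinine=(70.0, 15.0),
        sofa=(0.0, 0.0),
    )
    stable = SubgroupSpec(
        group="stable",
        n=65,
        markers={
            "nCD64": (1697.89, 1056.32),
            "mHLA-DR": (2728.62, 854.87),
            "mCD64": (2500.0, 1000.0),
            "lymCD64": (65.0, 26.0),
        },
        tbnk={
            "CD3": (1141.11, 537.85),
            "CD4": (598.42, 322.91),
            "CD8": (471.15, 242.78),
            "NK": (223.26, 204.71),
            "B": (162.00, 113.84),
        },
        creatinine=(121.91, 54.94),
        sofa=(0.0, 0.0),
    )
    infection_tbnk = {
        "CD3": (628.52, 469.07),
        "CD4": (301.36, 228.33),
        "CD8": (284.68, 243.10),
        "NK": (123.40, 104.91),
        "B": (67.17, 66.67),
    }
    sepsis = SubgroupSpec(
        group="infection",
        n=19,
        sepsis=True,
        markers={
            "nCD64": (10265.47, 8293.09),
            "mHLA-DR": (1803.47, 1192.66),
            "mCD64": (5600.0, 2200.0),
            "lymCD64": (180.0, 70.0),
        },
        tbnk=infection_tbnk,
        creatinine=(190.0, 120.0),
        sofa=(4.0, 1.5),
    )
    non_sepsis = SubgroupSpec(
        group="infection",
        n=31,
        sepsis=False,
        markers={
            "nCD64": (8908.39, 8837.41),
            "mHLA-DR": (3021.52, 1260.32),
            "mCD64": (5600.0, 2200.0),
            "lymCD64": (180.0, 70.0),
        },
        tbnk=infection_tbnk,
        creatinine=(160.0, 100.0),
        sofa=(0.8, 0.7),
    )
    return CohortSpec(subgroups=(hc, stable, sepsis, non_sepsis), seed=seed)


# --------------------------------------------------------------------------
# subject truths
# --------------------------------------------------------------------------


@dataclass
class SubjectTruth:
    """Ground truth for one subject: quantities the generators draw from."""

    subject_id: str
    group: str
    sepsis: Optional[bool]
    pathogen: Optional[str]
    markers: dict[int, dict[str, float]]  # timepoint -> marker -> MESF
    tbnk: dict[str, float]  # cells/μl
    creatinine: dict[int, float]  # timepoint -> μmol/L
    sofa: dict[int, float]  # timepoint -> points

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.markers)


def _lognormal_moment_matched(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Lognormal draws whose arithmetic mean/SD equal (mean, sd) exactly
    in expectation (sigma^2 = ln(1 + cv^2), mu = ln mean - sigma^2/2)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and SD must be strictly positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _unit_mean_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with E = 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size)


def generate_cohort(spec: CohortSpec) -> list[SubjectTruth]:
    """Draw subject truths for every subgroup of ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectTruth] = []
    sid = 0
    for sg in spec.subgroups:
        marker_draws = {
            m: _lognormal_moment_matched(rng, mu, sd, sg.n)
            for m, (mu, sd) in sg.markers.items()
        }
        tbnk_draws = {
            t: np.maximum(_lognormal_moment_matched(rng, mu, sd, sg.n), 1.0)
            for t, (mu, sd) in sg.tbnk.items()
        }
        cre = np.maximum(rng.normal(*sg.creatinine, sg.n), 30.0)
        if sg.sofa[1] > 0:
            sofa = np.round(np.maximum(rng.normal(*sg.sofa, sg.n), 0.0))
            if sg.sepsis:
                sofa = np.maximum(sofa, 2.0)  # sepsis requires organ dysfunction
        else:
            sofa = np.full(sg.n, sg.sofa[0])
        for i in range(sg.n):
            markers = {m: float(marker_draws[m][i]) for m in sg.markers}
            for m, v in markers.items():
                if v < POSITIVE_FLOOR:
                    warnings.warn(
                        f"subject S{sid:03d}: {m} = {v:.3g} clamped to floor "
                        f"{POSITIVE_FLOOR}"
                    )
                    markers[m] = POSITIVE_FLOOR
            subjects.append(
                SubjectTruth(
                    subject_id=f"S{sid:03d}",
                    group=sg.group,
                    sepsis=sg.sepsis,
                    pathogen=None,
                    markers={1: markers},
                    tbnk={t: float(tbnk_draws[t][i]) for t in sg.tbnk},
                    creatinine={1: float(cre[i])},
                    sofa={1: float(sofa[i])},
                )
            )
            sid += 1

    _assign_pathogens(spec, subjects, rng)
    _add_second_timepoint(spec, subjects, rng)
    return subjects


def _assign_pathogens(
    spec: CohortSpec, subjects: list[SubjectTruth], rng: np.random.Generator
) -> None:
    infected = [s for s in subjects if s.group == "infection"]
    labels: list[str] = []
    for pathogen, count in spec.pathogen_counts.items():
        labels.extend([pathogen] * count)
    if len(labels) != len(infected):
        raise ValueError(
            f"pathogen counts sum to {len(labels)} but there are "
            f"{len(infected)} infection subjects"
        )
    rng.shuffle(labels)  # type: ignore[arg-type]
    for s, lab in zip(infected, labels):
        s.pathogen = lab


def _add_second_timepoint(
    spec: CohortSpec, subjects: list[SubjectTruth], rng: np.random.Generator
) -> None:
    """Retest a subset of infection subjects ~1 week later.

    The second-timepoint truth is the first-timepoint truth shifted in
    log10 space, with the shift's sign tied to the SOFA trajectory:
    exacerbating subjects lose monocyte HLA-DR and keep neutrophil CD64
    high; recovering subjects regain HLA-DR and shed CD64.
    """
    septic = [s for s in subjects if s.group == "infection" and s.sepsis]
    non_sept = [s for s in subjects if s.group == "infection" and not s.sepsis]
    retested = (
        list(rng.choice(len(septic), spec.n_second_sepsis, replace=False)),
        list(
            rng.choice(
                len(non_sept), spec.n_second_timepoint - spec.n_second_sepsis, replace=False
            )
        ),
    )
    chosen = [septic[i] for i in retested[0]] + [non_sept[i] for i in retested[1]]
    exac_ix = set(rng.choice(len(chosen), spec.n_exacerbation, replace=False).tolist())
    # log10 shifts (mean, sd) per marker, by trajectory
    shifts_exac = {"nCD64": (0.05, 0.15), "mHLA-DR": (-0.30, 0.12),
                   "mCD64": (0.0, 0.08), "lymCD64": (0.0, 0.08)}
    shifts_recov = {"nCD64": (-0.40, 0.20), "mHLA-DR": (0.10, 0.08),
                    "mCD64": (0.0, 0.08), "lymCD64": (0.0, 0.08)}
    for i, s in enumerate(chosen):
        exac = i in exac_ix
        shifts = shifts_exac if exac else shifts_recov
        s.markers[2] = {
            m: max(v * 10 ** rng.normal(*shifts[m]), POSITIVE_FLOOR)
            for m, v in s.markers[1].items()
        }
        dsofa = float(rng.integers(1, 4)) if exac else -float(rng.integers(0, 3))
        s.sofa[2] = max(s.sofa[1] + dsofa, 0.0)
        if not exac and s.sofa[2] == s.sofa[1] == 0.0:
            pass  # ΔSOFA 0: still non-exacerbation
        s.creatinine[2] = max(
            s.creatinine[1] * (1.15 if exac else 0.9) + rng.normal(0, 10), 30.0
        )


# --------------------------------------------------------------------------
# protocol-level measurements
# --------------------------------------------------------------------------


def protocol_transform(x: np.ndarray | float, protocol: ProtocolSpec) -> np.ndarray | float:
    """Noise-free instrument response: 10**(offset + gain * log10(x))."""
    return 10 ** (protocol.offset + protocol.gain * np.log10(x))


def generate_protocol_measurements(
    truths: Sequence[SubjectTruth],
    protocols: Sequence[ProtocolSpec],
    seed: int,
    timepoint: int = 1,
) -> dict[str, ProtocolMeasurementSet]:
    """Raw MFI matrices (subject x protocol), one per marker.

    MFI = 10**(offset + gain*log10(true MESF)) x unit-mean lognormal noise.
    Subjects lacking the requested timepoint are omitted.
    """
    if not protocols:
        raise ValueError("need at least one protocol")
    rng = np.random.default_rng(seed)
    rows = [s for s in truths if timepoint in s.markers]
    out: dict[str, ProtocolMeasurementSet] = {}
    for marker in MARKERS:
        mat = np.empty((len(rows), len(protocols)))
        truth_vec = np.array([s.markers[timepoint][marker] for s in rows])
        for j, proto in enumerate(protocols):
            clean = protocol_transform(truth_vec, proto)
            mat[:, j] = clean * _unit_mean_noise(rng, proto.noise_cv, len(rows))
        out[marker] = ProtocolMeasurementSet(
            marker=marker,
            values=pd.DataFrame(
                mat,
                index=[s.subject_id for s in rows],
                columns=[p.protocol_id for p in protocols],
            ),
        )
    return out


# --------------------------------------------------------------------------
# event-level generators
# --------------------------------------------------------------------------

#: log10 locations/SDs of the gating channels per population (declared
#: defaults; chosen so rectangular gates separate populations cleanly)
_SCATTER_MODEL = {
    "lymphocytes": {"CD45": (2.90, 0.08), "SSC": (1.60, 0.08), "CD14": (1.40, 0.15)},
    "monocytes": {"CD45": (2.75, 0.08), "SSC": (2.30, 0.08), "CD14": (2.80, 0.08)},
    "neutrophils": {"CD45": (2.50, 0.08), "SSC": (3.00, 0.08), "CD14": (1.70, 0.15)},
}

_PANEL_PE_SOURCE = {
    "nCD64": {"neutrophils": "nCD64", "monocytes": "mCD64", "lymphocytes": "lymCD64"},
    "mHLA-DR": {"monocytes": "mHLA-DR", "neutrophils": None, "lymphocytes": None},
}

#: default events per population (acquisition-count defaults, declared)
DEFAULT_POP_EVENTS = {"neutrophils": 5_000, "monocytes": 1_000, "lymphocytes": 2_000}

#: PE background (MESF-equivalents) for populations not expressing the marker
_PE_BACKGROUND = 30.0


def generate_bead_run(protocol: ProtocolSpec, lot: BeadLot, seed: int) -> EventTable:
    """Bead-run event cloud: one cluster per lot level on the PE channel.

    Cluster locations follow the same gain law as cell measurements, with
    multiplicative spread ``lot.spread_cv`` (unit-mean, so the arithmetic
    cluster mean is the transformed lot value in expectation).
    """
    rng = np.random.default_rng(seed)
    pe = np.concatenate(
        [
            protocol_transform(level, protocol)
            * _unit_mean_noise(rng, lot.spread_cv, lot.events_per_level)
            for level in lot.mesf_levels
        ]
    )
    truth = np.repeat(np.arange(len(lot.mesf_levels)), lot.events_per_level)
    return EventTable(
        sample_id=f"beads_{protocol.protocol_id}",
        protocol_id=protocol.protocol_id,
        panel_id="beads",
        data=pd.DataFrame({"PE": pe, "truth": truth}),
    )


def generate_events(
    subject: SubjectTruth,
    panel: str,
    protocol: ProtocolSpec,
    seed: int,
    timepoint: int = 1,
    pop_events: dict[str, int] | None = None,
    event_cv: float = 0.35,
    scatter_sd_scale: float = 1.0,
) -> EventTable:
    """Event-level cell cloud for one subject/panel/protocol.

    The PE channel is centered per population on the protocol-transformed
    true marker value (unit-mean multiplicative spread ``event_cv``); the
    gating channels follow the declared per-population scatter model.  A
    ``truth`` column records the generating population for every event.
    """
    if panel not in _PANEL_PE_SOURCE:
        raise ValueError(f"unknown panel {panel!r}")
    if timepoint not in subject.markers:
        raise ValueError(f"subject {subject.subject_id} has no timepoint {timepoint}")
    pop_events = pop_events or DEFAULT_POP_EVENTS
    rng = np.random.default_rng(seed)
    frames = []
    for pop, n in pop_events.items():
        loc = _SCATTER_MODEL[pop]
        marker = _PANEL_PE_SOURCE[panel][pop]
        if marker is None:
            center = _PE_BACKGROUND
        else:
            truth_val = subject.markers[timepoint][marker]
            if truth_val < POSITIVE_FLOOR:
                warnings.warn(
                    f"{subject.subject_id}/{marker}: truth {truth_val:.3g} "
                    f"clamped to floor {POSITIVE_FLOOR}"
                )
                truth_val = POSITIVE_FLOOR
            center = float(protocol_transform(truth_val, protocol))
        cols = {
            ch: 10 ** rng.normal(mu, sd * scatter_sd_scale, n)
            for ch, (mu, sd) in loc.items()
            if ch in ("CD45", "SSC", "CD14")
        }
        cols["PE"] = center * _unit_mean_noise(rng, event_cv, n)
        frame = pd.DataFrame(cols)
        frame["truth"] = pop
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    keep = {"nCD64": ["CD45", "SSC", "PE", "truth"],
            "mHLA-DR": ["CD14", "SSC", "PE", "truth"]}[panel]
    return EventTable(
        sample_id=subject.subject_id,
        protocol_id=protocol.protocol_id,
        panel_id=panel,
        data=data[keep],
        timepoint=timepoint,
    )
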