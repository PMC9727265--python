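"""End-to-end orchestration of the synthetic study and analysis stages.

Two entry modes mirror the two kinds of evidence the analysis handles:

* **event mode** (:func:`run_full_pipeline`) — simulate (or load) an
  event-level study, then gate -> population MFI -> bead calibration ->
  cross-protocol harmonization -> per-subject indices -> group statistics,
  returning one JSON-ready report.
* **stats-only mode** (:func:`stats_only_report`) — consume printed
  (n, mean, SD) group summaries and recompute the comparison p-values;
  identical report structure, no event data required.

All randomness flows from the single ``seed`` in :class:`PipelineConfig`;
per-stage generator seeds are spawned from it deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import calibration, gating, harmonization, indices, stats, synthetic
from .reference_tables import (
    COHORT_GROUPS,
    DELTA_GROUPS,
    PATHOGEN_GROUPS,
    SEPSIS_GROUPS,
    SEX_BY_GROUP,
)

__all__ = ["PipelineConfig", "run_simulate", "run_full_pipeline", "stats_only_report"]

log = logging.getLogger("mesfmon")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative knobs for the whole pipeline (unknown keys rejected)."""

    seed: int = 0
    noise_cv: float = 0.05
    gating: gating.GatingParams = field(default_factory=gating.GatingParams)
    loa_multiplier: float = 1.96
    outlier_sd_multiplier: float = 3.0
    marker_cutoffs: dict[str, float] = field(
        default_factory=lambda: dict(indices.MARKER_CUTOFFS)
    )
    renal_absolute_threshold: float = 171.0
    renal_relative_ratio: float = 1.5
    pop_events: dict[str, int] = field(
        default_factory=lambda: {"neutrophils": 2000, "monocytes": 500, "lymphocytes": 1000}
    )
    event_cv: float = 0.35
    n_event_csv_subjects: int = 3  # subjects whose event tables run_simulate writes

    def __post_init__(self) -> None:
        if self.loa_multiplier <= 0 or self.outlier_sd_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        if any(v <= 0 for v in self.marker_cutoffs.values()):
            raise ValueError("marker cutoffs must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gating" in raw:
            raw["gating"] = gating.GatingParams(**raw["gating"])
        return cls(**raw)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """n independent child seeds derived from one root seed (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Write a synthetic study bundle: cohort CSV, bead CSVs, a few event
    CSVs, and the ground-truth JSON.  Deterministic per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.default_cohort_spec(seed=config.seed)
    truths = synthetic.generate_cohort(spec)
    protocols = synthetic.default_protocols(noise_cv=config.noise_cv)
    lot = synthetic.default_bead_lot()
    seeds = _spawn_seeds(config.seed, len(protocols) + 2 * config.n_event_csv_subjects)

    rows = []
    for s in truths:
        for tp in s.timepoints:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "sepsis": s.sepsis,
                    "pathogen": s.pathogen,
                    "timepoint": tp,
                    **{m: s.markers[tp][m] for m in synthetic.MARKERS},
                    **{f"tbnk_{t}": s.tbnk[t] for t in synthetic.TBNK_SUBSETS},
                    "creatinine": s.creatinine[tp],
                    "sofa": s.sofa[tp],
                }
            )
    cohort_df = pd.DataFrame(rows)
    cohort_df.to_csv(out / "cohort.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps([dataclasses.asdict(s) for s in truths], indent=1, default=str)
    )

    for proto, sd in zip(protocols, seeds):
        run = synthetic.generate_bead_run(proto, lot, seed=sd)
        run.to_csv(out / f"beads_{proto.protocol_id}.csv")

    k = len(protocols)
    for i, subj in enumerate(truths[: config.n_event_csv_subjects]):
        for j, panel in enumerate(("nCD64", "mHLA-DR")):
            ev = synthetic.generate_events(
                subj, panel, protocols[0], seed=seeds[k + 2 * i + j],
                pop_events=config.pop_events, event_cv=config.event_cv,
            )
            ev.to_csv(out / f"events_{subj.subject_id}_{panel}.csv")
    log.info("simulated study written to %s (%d subjects)", out, len(truths))
    return {"n_subjects": len(truths), "out_dir": str(out)}


# --------------------------------------------------------------------------
# full event-level pipeline
# --------------------------------------------------------------------------


def _calibrate_study(
    truths: Sequence[synthetic.SubjectTruth],
    protocols: Sequence[synthetic.ProtocolSpec],
    lot: synthetic.BeadLot,
    config: PipelineConfig,
    timepoint: int = 1,
) -> tuple[
    dict[str, calibration.CalibrationCurve],
    dict[str, harmonization.ProtocolMeasurementSet],
    dict[str, harmonization.ProtocolMeasurementSet],
]:
    """Events -> gates -> MFI -> MESF for every subject/marker/protocol.

    Returns (curves, raw-MFI sets, calibrated-MESF sets), the latter two
    keyed by marker with subject rows and protocol columns.
    """
    subjects = [s for s in truths if timepoint in s.markers]
    n_seeds = len(protocols) * (1 + 2 * len(subjects))
    seeds = iter(_spawn_seeds(config.seed + 1, n_seeds))

    curves: dict[str, calibration.CalibrationCurve] = {}
    mfi_rows: dict[str, dict[str, dict[str, float]]] = {m: {} for m in synthetic.MARKERS}
    pop_marker = {
        ("nCD64", "neutrophils"): "nCD64",
        ("nCD64", "monocytes"): "mCD64",
        ("nCD64", "lymphocytes"): "lymCD64",
        ("mHLA-DR", "monocytes"): "mHLA-DR",
    }
    for proto in protocols:
        run = synthetic.generate_bead_run(proto, lot, seed=next(seeds))
        peaks = gating.find_bead_peaks(run, lot.mesf_levels)
        curves[proto.protocol_id] = calibration.fit_curve(peaks, lot.mesf_levels)
        for subj in subjects:
            for panel in ("nCD64", "mHLA-DR"):
                ev = synthetic.generate_events(
                    subj, panel, proto, seed=next(seeds), timepoint=timepoint,
                    pop_events=config.pop_events, event_cv=config.event_cv,
                )
                gated = gating.gate_populations(ev, config.gating)
                for (p_panel, pop), marker in pop_marker.items():
                    if p_panel != panel:
                        continue
                    mfi = gating.extract_mfi(ev, gated, pop, marker)
                    mfi_rows[marker].setdefault(subj.subject_id, {})[
                        proto.protocol_id
                    ] = mfi.mfi

    raw_sets, mesf_sets = {}, {}
    for marker in synthetic.MARKERS:
        raw = pd.DataFrame(mfi_rows[marker]).T
        raw = raw.loc[[s.subject_id for s in subjects], [p.protocol_id for p in protocols]]
        raw_sets[marker] = harmonization.ProtocolMeasurementSet(marker, raw)
        mesf = raw.copy()
        for pid in mesf.columns:
            mesf[pid] = [
                calibration.mfi_to_mesf(v, curves[pid]) for v in mesf[pid]
            ]
        mesf_sets[marker] = harmonization.ProtocolMeasurementSet(marker, mesf)
    return curves, raw_sets, mesf_sets


def _subject_records(
    truths: Sequence[synthetic.SubjectTruth],
    consensus_by_marker: dict[str, dict[str, float]],
    config: PipelineConfig,
    timepoint: int = 1,
) -> list[indices.SubjectRecord]:
    recs = []
    for s in truths:
        if timepoint not in s.markers:
            continue
        vals = {m: consensus_by_marker[m].get(s.subject_id) for m in synthetic.MARKERS}
        recs.append(
            indices.SubjectRecord(
                subject_id=s.subject_id,
                group=s.group,
                timepoint=timepoint,
                sepsis=s.sepsis,
                pathogen=s.pathogen,
                ncd64=vals["nCD64"],
                mcd64=vals["mCD64"],
                lymcd64=vals["lymCD64"],
                mhladr=vals["mHLA-DR"],
                tbnk_counts=dict(s.tbnk),
                creatinine=s.creatinine[timepoint],
                sofa=s.sofa[timepoint],
            )
        )
    return recs


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Simulate the default study and run every analysis stage on it.

    Report sections: calibration curves, reliability (ICC raw vs
    calibrated, Bland–Altman, outliers), consensus-based group
    comparisons, ROC for infection, and logistic risk factors.
    """
    log.info("simulating cohort (seed %d)", config.seed)
    spec = synthetic.default_cohort_spec(seed=config.seed)
    truths = synthetic.generate_cohort(spec)
    protocols = synthetic.default_protocols(noise_cv=config.noise_cv)
    lot = synthetic.default_bead_lot()

    log.info("calibrating %d subjects x %d protocols", len(truths), len(protocols))
    curves, raw_sets, mesf_sets = _calibrate_study(truths, protocols, lot, config)

    reliability = {}
    consensus_by_marker: dict[str, dict[str, float]] = {}
    for marker in synthetic.MARKERS:
        rep = harmonization.reliability_report(
            mesf_sets[marker], config.loa_multiplier, config.outlier_sd_multiplier
        )
        rep["icc_raw_mfi"] = harmonization.icc(raw_sets[marker]).icc
        reliability[marker] = rep
        excl = harmonization.outlier_map(
            mesf_sets[marker], config.loa_multiplier, config.outlier_sd_multiplier
        )
        cons = harmonization.consensus(mesf_sets[marker], excl)
        consensus_by_marker[marker] = {c.subject_id: c.mesf for c in cons}

    records = _subject_records(truths, consensus_by_marker, config)

    # group comparisons on consensus values (raw-vector ANOVA via summaries)
    def _summaries(values: dict[str, list[float]]) -> list[stats.GroupSummary]:
        return [
            stats.GroupSummary(g, len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
            for g, v in values.items()
            if len(v) >= 2
        ]

    group_tables = {}
    for name, getter in [
        ("nCD64", lambda r: r.ncd64),
        ("mHLA-DR", lambda r: r.mhladr),
        ("CD64 index", lambda r: r.cd64_index),
        ("SI", lambda r: r.sepsis_index),
    ]:
        by_group: dict[str, list[float]] = {"HC": [], "stable": [], "infection": []}
        for r in records:
            v = getter(r)
            if v is not None:
                by_group[r.group].append(v)
        summ = _summaries(by_group)
        F, p = stats.anova_oneway_from_summary(summ)
        group_tables[name] = {
            "groups": [dataclasses.asdict(g) for g in summ],
            "anova_F": F,
            "anova_p": p,
        }

    # ROC: infection vs stable on nCD64 consensus
    roc_records = [r for r in records if r.group in ("stable", "infection")]
    roc = stats.roc_analysis(
        [r.ncd64 for r in roc_records],
        [1 if r.group == "infection" else 0 for r in roc_records],
    )

    # logistic: infection vs stable; binarized markers + TBNK counts
    design = pd.DataFrame(
        {
            "nCD64_high": [
                int(indices.binarize_marker(r.ncd64, "nCD64", config.marker_cutoffs))
                for r in roc_records
            ],
            "B_cells": [r.tbnk_counts["B"] for r in roc_records],
            "CD3_T_cells": [r.tbnk_counts["CD3"] for r in roc_records],
        }
    )
    outcome = [1 if r.group == "infection" else 0 for r in roc_records]
    uni = stats.logistic_fit(design, outcome, mode="univariate")
    try:
        multi = stats.logistic_fit(design, outcome, mode="multivariate")
    except ValueError:
        multi = []

    report = {
        "seed": config.seed,
        "n_subjects": len(records),
        "calibration": {
            pid: {"slope": c.slope, "intercept": c.intercept, "r_squared": c.r_squared}
            for pid, c in curves.items()
        },
        "reliability": reliability,
        "group_comparisons": group_tables,
        "roc_infection_ncd64": dataclasses.asdict(roc),
        "logistic": {
            "univariate": [f.table().to_dict("records") for f in uni],
            "multivariate": [f.table().to_dict("records") for f in multi],
        },
    }
    return report


# --------------------------------------------------------------------------
# stats-only mode
# --------------------------------------------------------------------------


def stats_only_report(
    cohort_groups=None,
    pathogen_groups=None,
    sepsis_groups=None,
    delta_groups=None,
    sex_table=None,
) -> dict:
    """Recompute the comparison p-values from (n, mean, SD) summaries.

    Defaults to the built-in reference tables; pass replacements to run
    the same report on new summary data.  Report structure matches the
    statistics sections of :func:`run_full_pipeline`.
    """
    cohort_groups = cohort_groups or COHORT_GROUPS
    pathogen_groups = pathogen_groups or PATHOGEN_GROUPS
    sepsis_groups = sepsis_groups or SEPSIS_GROUPS
    delta_groups = delta_groups or DELTA_GROUPS
    sex_table = sex_table or SEX_BY_GROUP

    def _anova_block(tables):
        out = {}
        for marker, groups in tables.items():
            F, p = stats.anova_oneway_from_summary(groups)
            out[marker] = {
                "groups": [dataclasses.asdict(g) for g in groups],
                "anova_F": F,
                "anova_p": p,
            }
        return out

    sepsis_lsd = {}
    for marker, groups in sepsis_groups.items():
        i = next(k for k, g in enumerate(groups) if g.label == "sepsis")
        j = next(k for k, g in enumerate(groups) if g.label == "non-sepsis")
        t, p = stats.lsd_pairwise_from_summary(groups, i, j)
        sepsis_lsd[marker] = {"t": t, "p": p}

    delta_tests = {}
    for marker, (g1, g2) in delta_groups.items():
        t, df, p = stats.t_test_from_summary(g1, g2, variant="pooled")
        delta_tests[marker] = {"t": t, "df": df, "p": p}

    chi2, chi2_p = stats.chi_square_test(sex_table, method="pearson")

    return {
        "cohort_anova": _anova_block(cohort_groups),
        "pathogen_anova": _anova_block(pathogen_groups),
        "sepsis_anova": _anova_block(sepsis_groups),
        "sepsis_vs_non_sepsis_lsd": sepsis_lsd,
        "longitudinal_t_tests": delta_tests,
        "sex_chi_square": {"chi2": chi2, "p": chi2_p},
    }
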