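"""Cross-protocol harmonization of MESF measurements.

The same blood sample measured under several instrument protocols yields
one MESF per protocol.  This module quantifies how well the bead
calibration removed instrument effects (ICC, Bland–Altman against the
per-sample mean), excludes gross outliers (> 3 SD of the differences),
and averages the remaining protocol values into a consensus MESF.

The ICC reported is ICC(2,1): two-way random effects, absolute agreement,
single measurement — the form that asks whether protocols agree on the
absolute MESF scale, which is exactly what bead standardization claims.
It is computed from the two-way ANOVA mean squares:

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

with MS_R the between-subject, MS_C the between-protocol and MS_E the
residual mean square.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolMeasurementSet",
    "IccResult",
    "BlandAltmanResult",
    "ConsensusValue",
    "icc",
    "bland_altman",
    "consensus",
    "outlier_map",
    "reliability_report",
]


@dataclass(frozen=True)
class ProtocolMeasurementSet:
    """Subjects x protocols MESF matrix for one marker.

    ``values`` is indexed by subject id with one column per protocol id;
    missing cells are NaN and dropped listwise by the reliability
    statistics.
    """

    marker: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate protocol columns")

    @property
    def protocol_ids(self) -> list[str]:
        return list(self.values.columns)

    def complete(self) -> pd.DataFrame:
        return self.values.dropna(axis=0, how="any")


@dataclass(frozen=True)
class IccResult:
    marker: str
    icc: float
    model: str
    n_subjects: int
    n_protocols: int


@dataclass(frozen=True)
class BlandAltmanResult:
    protocol_id: str
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    outliers: tuple[str, ...]
    loa_multiplier: float = 1.96
    outlier_sd_multiplier: float = 3.0


@dataclass(frozen=True)
class ConsensusValue:
    subject_id: str
    marker: str
    mesf: float
    included: tuple[str, ...]
    excluded: tuple[str, ...]
    warning: str | None = None


def icc(mset: ProtocolMeasurementSet) -> IccResult:
    """ICC(2,1) absolute agreement from the two-way ANOVA decomposition."""
    mat = mset.complete().to_numpy(dtype=float)
    n, k = mat.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 protocols")
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        raise ValueError("zero total variance; ICC undefined")
    return IccResult(
        marker=mset.marker,
        icc=float((ms_r - ms_e) / denom),
        model="ICC(2,1) two-way random, absolute agreement, single measurement",
        n_subjects=n,
        n_protocols=k,
    )


def bland_altman(
    mset: ProtocolMeasurementSet,
    protocol_id: str,
    loa_multiplier: float = 1.96,
    outlier_sd_multiplier: float = 3.0,
) -> BlandAltmanResult:
    """Agreement of one protocol against the per-subject all-protocol mean.

    Differences are (protocol value - per-subject mean); limits of
    agreement are bias ± 1.96 SD; outliers are subjects whose difference
    lies more than ``outlier_sd_multiplier`` SDs from the bias.
    """
    if protocol_id not in mset.values.columns:
        raise KeyError(f"protocol {protocol_id!r} not in measurement set")
    mat = mset.complete()
    if len(mat) < 3:
        raise ValueError("Bland-Altman needs >= 3 subjects for a stable SD")
    per_subject_mean = mat.mean(axis=1)
    diffs = mat[protocol_id] - per_subject_mean
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    outliers = tuple(
        str(s) for s in diffs.index[np.abs(diffs - bias) > outlier_sd_multiplier * sd]
    )
    return BlandAltmanResult(
        protocol_id=protocol_id,
        bias=bias,
        sd=sd,
        loa_lower=bias - loa_multiplier * sd,
        loa_upper=bias + loa_multiplier * sd,
        outliers=outliers,
        loa_multiplier=loa_multiplier,
        outlier_sd_multiplier=outlier_sd_multiplier,
    )


def outlier_map(
    mset: ProtocolMeasurementSet,
    loa_multiplier: float = 1.96,
    outlier_sd_multiplier: float = 3.0,
) -> dict[str, set[str]]:
    """subject id -> set of protocols excluded by the 3 SD rule (one pass)."""
    excl: dict[str, set[str]] = {}
    for pid in mset.protocol_ids:
        res = bland_altman(mset, pid, loa_multiplier, outlier_sd_multiplier)
        for sid in res.outliers:
            excl.setdefault(sid, set()).add(pid)
    return excl


def consensus(
    mset: ProtocolMeasurementSet,
    excluded: dict[str, set[str]] | None = None,
) -> list[ConsensusValue]:
    """Per-subject mean over non-excluded protocol values.

    If every protocol is excluded for a subject, falls back to the
    unfiltered mean with a warning — a consensus is always emitted.
    """
    excluded = excluded or {}
    out: list[ConsensusValue] = []
    for sid, row in mset.values.iterrows():
        sid = str(sid)
        avail = row.dropna()
        excl = excluded.get(sid, set()) & set(avail.index)
        kept = [p for p in avail.index if p not in excl]
        warning = None
        if not kept:
            kept = list(avail.index)
            excl = set()
            warning = "all protocols flagged as outliers; unfiltered mean used"
            warnings.warn(f"subject {sid}: {warning}")
        out.append(
            ConsensusValue(
                subject_id=sid,
                marker=mset.marker,
                mesf=float(avail[kept].mean()),
                included=tuple(kept),
                excluded=tuple(sorted(excl)),
                warning=warning,
            )
        )
    return out


def reliability_report(
    mset: ProtocolMeasurementSet,
    loa_multiplier: float = 1.96,
    outlier_sd_multiplier: float = 3.0,
) -> dict:
    """ICC + per-protocol Bland-Altman blocks + outlier lists, JSON-ready."""
    icc_res = icc(mset)
    blocks = {}
    for pid in mset.protocol_ids:
        ba = bland_altman(mset, pid, loa_multiplier, outlier_sd_multiplier)
        blocks[pid] = {
            "bias": ba.bias,
            "sd": ba.sd,
            "loa": [ba.loa_lower, ba.loa_upper],
            "outliers": list(ba.outliers),
        }
    return {
        "marker": mset.marker,
        "icc": icc_res.icc,
        "icc_model": icc_res.model,
        "n_subjects": icc_res.n_subjects,
        "n_protocols": icc_res.n_protocols,
        "bland_altman": blocks,
        "outlier_rule": f"|difference - bias| > {outlier_sd_multiplier} SD (per protocol comparison)",
    }


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
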