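"""Reference group summaries for the kidney-transplant immune-monitoring cohort.

These are the printed group-level statistics (n, mean, SD) of the cohort
the synthetic generator emulates: 26 healthy controls (HC), 65 stable
kidney-transplant recipients, 50 infected recipients — the latter split
19 sepsis / 31 non-sepsis, and 26 bacterial / 13 viral / 11 fungal by
pathogen; 21 infected subjects were retested (3 exacerbating by ΔSOFA).
They serve as the inputs to the summary-statistic analysis layer
(stats-only mode), so the published comparison p-values can be recomputed
directly from the table cells.
"""

from __future__ import annotations

from .stats import ContingencyTable, GroupSummary

__all__ = [
    "COHORT_GROUPS",
    "PATHOGEN_GROUPS",
    "SEPSIS_GROUPS",
    "DELTA_GROUPS",
    "SEX_BY_GROUP",
    "INFECTION_NCD64_MEAN",
]

# marker -> [HC, stable, infection] (n, mean, SD), MESF / dimensionless units
COHORT_GROUPS: dict[str, list[GroupSummary]] = {
    "nCD64": [
        GroupSummary("HC", 26, 1192.58, 537.61),
        GroupSummary("stable", 65, 1697.89, 1056.32),
        GroupSummary("infection", 50, 9424.08, 8574.58),
    ],
    "mHLA-DR": [
        GroupSummary("HC", 26, 2341.27, 781.75),
        GroupSummary("stable", 65, 2728.62, 854.87),
        GroupSummary("infection", 50, 2558.66, 1360.77),
    ],
    "CD64 index": [
        GroupSummary("HC", 26, 11.63, 4.97),
        GroupSummary("stable", 65, 17.60, 12.03),
        GroupSummary("infection", 50, 88.33, 75.69),
    ],
    "SI": [
        GroupSummary("HC", 26, 58.86, 35.74),
        GroupSummary("stable", 65, 64.50, 32.69),
        GroupSummary("infection", 50, 488.76, 613.43),
    ],
}

# marker -> [bacterial, viral, fungal] infection subgroups
PATHOGEN_GROUPS: dict[str, list[GroupSummary]] = {
    "nCD64": [
        GroupSummary("bacterial", 26, 11361.46, 9428.95),
        GroupSummary("viral", 13, 4099.15, 5347.64),
        GroupSummary("fungal", 11, 11137.91, 7337.20),
    ],
    "mHLA-DR": [
        GroupSummary("bacterial", 26, 2426.73, 1187.87),
        GroupSummary("viral", 13, 3176.31, 1601.28),
        GroupSummary("fungal", 11, 2140.55, 1317.32),
    ],
    "CD64 index": [
        GroupSummary("bacterial", 26, 102.42, 81.11),
        GroupSummary("viral", 13, 44.75, 55.29),
        GroupSummary("fungal", 11, 106.51, 67.89),
    ],
    "SI": [
        GroupSummary("bacterial", 26, 504.29, 376.84),
        GroupSummary("viral", 13, 170.73, 262.07),
        GroupSummary("fungal", 11, 827.91, 1071.35),
    ],
}

# marker -> [stable, sepsis, non-sepsis]
SEPSIS_GROUPS: dict[str, list[GroupSummary]] = {
    "nCD64": [
        GroupSummary("stable", 65, 1697.89, 1056.32),
        GroupSummary("sepsis", 19, 10265.47, 8293.09),
        GroupSummary("non-sepsis", 31, 8908.39, 8837.41),
    ],
    "mHLA-DR": [
        GroupSummary("stable", 65, 2728.62, 854.87),
        GroupSummary("sepsis", 19, 1803.47, 1192.66),
        GroupSummary("non-sepsis", 31, 3021.52, 1260.32),
    ],
    "CD64 index": [
        GroupSummary("stable", 65, 17.60, 12.03),
        GroupSummary("sepsis", 19, 100.47, 74.46),
        GroupSummary("non-sepsis", 31, 80.98, 76.68),
    ],
    "SI": [
        GroupSummary("stable", 65, 64.50, 32.69),
        GroupSummary("sepsis", 19, 773.96, 868.31),
        GroupSummary("non-sepsis", 31, 313.96, 281.34),
    ],
}

# Δ(second test - first test) -> [exacerbation, non-exacerbation]
DELTA_GROUPS: dict[str, list[GroupSummary]] = {
    "ΔnCD64": [
        GroupSummary("exacerbation", 3, 143.67, 5631.89),
        GroupSummary("non-exacerbation", 18, -6309.61, 9163.02),
    ],
    "ΔmHLA-DR": [
        GroupSummary("exacerbation", 3, -1273.33, 2049.93),
        GroupSummary("non-exacerbation", 18, 811.06, 1461.78),
    ],
    "ΔSI": [
        GroupSummary("exacerbation", 3, 701.67, 857.79),
        GroupSummary("non-exacerbation", 18, -383.17, 458.87),
    ],
    "ΔCD64 index": [
        GroupSummary("exacerbation", 3, 0.33, 70.29),
        GroupSummary("non-exacerbation", 18, -52.67, 69.44),
    ],
}

#: male/female counts, stable vs infection recipients
SEX_BY_GROUP = ContingencyTable(
    counts=((45, 20), (25, 25)),
    row_labels=("stable", "infection"),
    col_labels=("male", "female"),
)

#: infection-group nCD64 mean — equals the n-weighted mean of the three
#: pathogen-subgroup means (internal-consistency check)
INFECTION_NCD64_MEAN = 9424.08
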