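"""Cohort-level statistics operating on summary triples or raw vectors.

Group comparisons in clinical flow-cytometry papers are reported as
``mean ± SD`` per group, so the ANOVA, LSD post-hoc and two-sample t
routines here work directly from ``(n, mean, SD)`` summaries — printed
tables can be typed in and their p-values recomputed exactly.  ROC and
logistic regression need subject-level data and take raw vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "RocResult",
    "LogisticFit",
    "anova_oneway_from_summary",
    "lsd_pairwise_from_summary",
    "t_test_from_summary",
    "chi_square_test",
    "roc_analysis",
    "logistic_fit",
]


@dataclass(frozen=True)
class GroupSummary:
    """A labelled (n, mean, SD) triple, the unit of a printed table cell."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: SD must be >= 0, got {self.sd}")
        if self.sd > 0 and self.n < 2:
            raise ValueError(f"group {self.label!r}: SD requires n >= 2")


@dataclass(frozen=True)
class ContingencyTable:
    """2 x k count table with labels; margins are derived, never stored."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != 2:
            raise ValueError("contingency table must be 2 x k")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts)


@dataclass(frozen=True)
class RocResult:
    auc: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: Literal["greater", "less"]
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    converged: bool
    model_type: Literal["univariate", "multivariate"]
    warnings_: tuple[str, ...] = field(default=())

    def table(self) -> pd.DataFrame:
        """OR (95% CI) / p table, one row per non-intercept term."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coefficients,
                "OR": self.odds_ratios,
                "ci_low": self.ci_lower,
                "ci_high": self.ci_upper,
                "p": self.p_values,
            }
        )


# --------------------------------------------------------------------------
# summary-statistic ANOVA / LSD / t
# --------------------------------------------------------------------------


def _pooled_msw(groups: Sequence[GroupSummary]) -> tuple[float, int]:
    """Within-group mean square pooled over all supplied groups, and its df."""
    N = sum(g.n for g in groups)
    k = len(groups)
    ssw = sum((g.n - 1) * g.sd**2 for g in groups)
    return ssw / (N - k), N - k


def anova_oneway_from_summary(groups: Sequence[GroupSummary]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from per-group (n, mean, SD).

    Uses the algebraic identities SSB = sum n_i (m_i - grand)^2 and
    SSW = sum (n_i - 1) s_i^2, which recover the raw-data F exactly.
    Returns ``(F, p)``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if all(g.n == 1 for g in groups):
        raise ValueError("all groups have n = 1; no within-group variance")
    ns = np.array([g.n for g in groups], dtype=float)
    ms = np.array([g.mean for g in groups])
    N, k = ns.sum(), len(groups)
    grand = float(np.dot(ns, ms) / N)
    ssb = float(np.dot(ns, (ms - grand) ** 2))
    msw, dfw = _pooled_msw(groups)
    if msw == 0:
        if ssb > 0:
            warnings.warn("zero within-group variance with unequal means; p = 0")
            return np.inf, 0.0
        return 0.0, 1.0
    F = (ssb / (k - 1)) / msw
    return F, float(sps.f.sf(F, k - 1, dfw))


def lsd_pairwise_from_summary(
    groups: Sequence[GroupSummary], i: int, j: int
) -> tuple[float, float]:
    """Fisher's LSD comparison of groups i and j.

    The within mean square pools over *all* supplied groups (not just the
    pair), df = N - k, and no multiplicity adjustment is applied — the
    defining properties of the LSD post-hoc.  Returns ``(t, p)``.
    """
    if len(groups) < 2:
        raise ValueError("LSD needs at least two groups for pooling")
    gi, gj = groups[i], groups[j]
    msw, dfw = _pooled_msw(groups)
    if msw == 0:
        raise ValueError("pooled within-group variance is zero")
    t = (gi.mean - gj.mean) / np.sqrt(msw * (1 / gi.n + 1 / gj.n))
    return float(t), float(2 * sps.t.sf(abs(t), dfw))


def t_test_from_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    variant: Literal["pooled", "welch"] = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t test from summaries; returns ``(t, df, p)``.

    ``pooled`` is the classical equal-variance Student test
    (df = n1 + n2 - 2); ``welch`` uses the Satterthwaite df.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("both groups need n >= 2")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# --------------------------------------------------------------------------
# categorical tests
# --------------------------------------------------------------------------


def chi_square_test(
    table: ContingencyTable, method: Literal["pearson", "fisher"] = "pearson"
) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) or Fisher's exact test.

    Fisher is restricted to 2x2 tables and returns the hypergeometric
    odds-ratio statistic; Pearson returns the chi-squared statistic.
    """
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    if method == "pearson":
        chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
        return float(chi2), float(p)
    if method == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = sps.fisher_exact(arr, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# ROC / Youden
# --------------------------------------------------------------------------


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: Literal["greater", "less"] = "greater",
) -> RocResult:
    """ROC with rank-based AUC and the Youden-optimal cutoff.

    AUC uses the Mann-Whitney formulation with the midrank tie correction:
    AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) on the (oriented)
    scores.  The cutoff maximizes J = sensitivity + specificity - 1 over
    the observed score values, ties broken toward the lower threshold.
    The AUC p-value is the normal approximation to the Mann-Whitney test
    of AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    oriented = s if direction == "greater" else -s

    ranks = sps.rankdata(oriented)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # Youden scan over observed thresholds: predict positive iff score >= t.
    # Vectorized with sorted-array counts; argmax over ascending thresholds
    # keeps the lower threshold on ties.
    thresholds = np.unique(oriented)
    pos_sorted = np.sort(oriented[y == 1])
    neg_sorted = np.sort(oriented[y == 0])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n_pos
    spec = 1 - fp / n_neg
    j = sens + spec - 1
    best = int(np.argmax(j))
    best_t, best_se, best_sp, best_j = (
        float(thresholds[best]), float(sens[best]), float(spec[best]), float(j[best]),
    )

    # Mann-Whitney normal approximation with tie correction for the p-value
    u = auc * n_pos * n_neg
    n = n_pos + n_neg
    _, tie_counts = np.unique(oriented, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n_pos * n_neg / 12 * (n + 1 - tie_term)
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n_pos * n_neg / 2) / np.sqrt(var_u)
        p = float(2 * sps.norm.sf(abs(z)))

    cutoff = best_t if direction == "greater" else -best_t
    return RocResult(
        auc=float(auc),
        p_value=p,
        cutoff=float(cutoff),
        sensitivity=best_se,
        specificity=best_sp,
        youden_j=float(best_j),
        direction=direction,
        n_positive=n_pos,
        n_negative=n_neg,
    )


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------


def logistic_fit(
    design: pd.DataFrame,
    outcome: Sequence[int],
    mode: Literal["univariate", "multivariate"] = "multivariate",
    entry_p: float = 0.05,
) -> list[LogisticFit]:
    """Maximum-likelihood logistic regression with Wald inference.

    ``univariate`` fits each column of ``design`` alone (one
    :class:`LogisticFit` per column).  ``multivariate`` first screens each
    covariate univariately and jointly fits those with univariate
    p < ``entry_p`` (the conventional entry rule for a multivariable
    table); returns a single-element list.  95% CIs are exp(beta ± 1.96 SE).
    Separation or non-convergence is flagged, not raised — estimates are
    still reported with a warning string attached.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if design.shape[1] < 1:
        raise ValueError("need at least one covariate")

    def _fit(cols: list[str], model_type: str) -> LogisticFit:
        X = sm.add_constant(design[cols].astype(float), has_constant="add")
        warns: list[str] = []
        converged = True
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception as exc:  # separation -> singular Hessian in Newton
                res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
                converged = False
                warns.append(f"Newton fit failed ({exc}); quasi-Newton estimates reported")
            for w in rec:
                warns.append(str(w.message))
        params = np.asarray(res.params)[1:]
        try:
            se = np.asarray(res.bse)[1:]
        except Exception:
            se = np.full_like(params, np.nan)
            warns.append("standard errors unavailable (singular information matrix)")
        z = params / se
        pvals = 2 * sps.norm.sf(np.abs(z))
        if not converged:
            warns.append("fit did not converge; estimates unreliable")
        with np.errstate(over="ignore"):  # inf CI bound under separation
            ci_lo, ci_hi = np.exp(params - 1.96 * se), np.exp(params + 1.96 * se)
        return LogisticFit(
            terms=tuple(cols),
            coefficients=params,
            standard_errors=se,
            odds_ratios=np.exp(params),
            ci_lower=ci_lo,
            ci_upper=ci_hi,
            p_values=pvals,
            converged=converged,
            model_type=model_type,  # type: ignore[arg-type]
            warnings_=tuple(warns),
        )

    uni = [_fit([c], "univariate") for c in design.columns]
    if mode == "univariate":
        return uni
    selected = [f.terms[0] for f in uni if f.p_values[0] < entry_p]
    if not selected:
        raise ValueError(f"no covariate passed the univariate p < {entry_p} screen")
    return [_fit(selected, "multivariate")]
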