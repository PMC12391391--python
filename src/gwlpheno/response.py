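"""Phenotypic drug-response statistic and generic group comparisons.

The response statistic is the Euclidean distance *d* between the cell-cycle
class proportion vectors (2N, S, 4N, 8N+, in percent) of a control and a
treated population; a dose profile of *d* is reduced to a scalar
sensitivity score by its trapezoidal area under the curve.

Group comparisons follow a Shapiro-Wilk normality gate: an unpaired
two-tailed t-test when both samples look normal at alpha = 0.05, otherwise
an unpaired two-tailed Wilcoxon rank-sum test. Effect sizes are Cohen's d
with pooled SD; families of p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ResponseProfile:
    """Euclidean distance per dose plus its AUC (doses ascending, µM)."""

    doses: np.ndarray
    d: np.ndarray
    auc: float


@dataclass
class GroupComparison:
    test: str  # "t" | "wilcoxon" | "none"
    statistic: float
    p: float
    p_adj: float | None
    cohen_d: float
    shapiro_p_a: float
    shapiro_p_b: float


def euclidean_response(p_control, p_treated, atol: float = 1e-6) -> float:
    """L2 distance between two class-proportion vectors in percent.

    Both vectors must cover the same ordered classes and sum to 100; the
    distance therefore lives in [0, 100*sqrt(2)].
    """
    a = np.asarray(p_control, dtype=float)
    b = np.asarray(p_treated, dtype=float)
    if a.shape != b.shape:
        raise ValueError("proportion vectors must cover the same class set")
    for name, v in (("control", a), ("treated", b)):
        if abs(v.sum() - 100.0) > max(atol, 1e-9 * 100):
            raise ValueError(f"{name} proportions must sum to 100 (got {v.sum()!r})")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def profile_auc(doses, d) -> float:
    """Trapezoidal integral of the distance profile over dose."""
    doses = np.asarray(doses, dtype=float)
    d = np.asarray(d, dtype=float)
    if doses.size != d.size:
        raise ValueError("length mismatch")
    if doses.size < 2:
        raise ValueError("need at least 2 doses")
    if np.any(np.diff(doses) < 0):
        raise ValueError("doses must be ascending")
    return float(np.trapezoid(d, doses))


def build_profile(doses, d) -> ResponseProfile:
    return ResponseProfile(np.asarray(doses, float), np.asarray(d, float),
                           profile_auc(doses, d))


def cohens_d(a, b) -> float:
    """Cohen's d with pooled SD (n-1 denominators); 0 when both samples are
    constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def compare_groups(a, b, normality_alpha: float = 0.05) -> GroupComparison:
    """Shapiro-gated two-sample comparison with Cohen's d.

    ``p_adj`` is left unset; apply :func:`adjust_comparisons` across the
    family of comparisons reported together.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    d = cohens_d(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no variability anywhere, no test applicable
        return GroupComparison("none", float("nan"), float("nan"), None, 0.0,
                               float("nan"), float("nan"))
    sw_a = stats.shapiro(a).pvalue if a.var(ddof=1) > 0 else 0.0
    sw_b = stats.shapiro(b).pvalue if b.var(ddof=1) > 0 else 0.0
    if sw_a >= normality_alpha and sw_b >= normality_alpha:
        res = stats.ttest_ind(a, b)
        return GroupComparison("t", float(res.statistic), float(res.pvalue),
                               None, d, float(sw_a), float(sw_b))
    res = stats.ranksums(a, b)
    return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue),
                           None, d, float(sw_a), float(sw_b))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def adjust_comparisons(comparisons) -> list[GroupComparison]:
    """BH-adjust a family of :class:`GroupComparison` results."""
    adj = bh_adjust([c.p for c in comparisons])
    return [replace(c, p_adj=(None if np.isnan(q) else float(q)))
            for c, q in zip(comparisons, adj)]
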