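"""GWL/B55α expression-ratio model of sensitivity to Greatwall inhibition.

The predictive model is a simple unweighted linear regression of the
experimentally determined median effective dose on the scalar expression
ratio,

    *ED50 = gradient x GWL / B55α + intercept        (µM),

fitted by ordinary least squares. Biological rationale: abundant B55α makes
unscheduled PP2A-B55α activation more toxic, so a low GWL/B55α ratio marks
cells that cannot tolerate further loss of Greatwall activity. Expression
inputs may be GAPDH-normalised, max-scaled protein densitometry or
untransformed TPM/FPKM RNA abundances.

Cohort analysis compares tumour and matched normal tissue per cancer group
(median shift, unpaired two-tailed Wilcoxon rank-sum, BH across groups;
groups without normals are reported "nd").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .response import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class RatioModel:
    gradient: float  # µM per ratio unit
    intercept: float  # µM
    r_squared: float
    pearson_r: float
    p: float  # two-tailed t-test on r
    n: int

    def predict(self, ratio):
        return self.gradient * np.asarray(ratio, dtype=float) + self.intercept


def scale_expression(raw: pd.DataFrame, loading_control,
                     analytes=None) -> pd.DataFrame:
    """Densitometry scaling: divide each analyte by the per-sample loading
    control, then by the per-analyte maximum, so each analyte's top sample
    equals 1. Invariant to global multiplicative factors on the raw values.
    """
    ctrl = np.asarray(loading_control, dtype=float)
    if np.any(ctrl <= 0):
        raise ValueError("loading control must be positive for every sample")
    if len(ctrl) != len(raw):
        raise ValueError("loading control length must match sample count")
    analytes = analytes or [c for c in raw.columns
                            if pd.api.types.is_numeric_dtype(raw[c])]
    out = raw.copy()
    for col in analytes:
        v = raw[col].to_numpy(dtype=float) / ctrl
        m = v.max()
        if not m > 0:
            raise ValueError(f"analyte {col!r} has non-positive maximum")
        out[col] = v / m
    return out


def fit_ratio_model(panel: pd.DataFrame, ed50=None,
                    gwl_col: str = "gwl", b55a_col: str = "b55a") -> RatioModel:
    """OLS of ED50 (µM) on the GWL/B55α ratio."""
    gwl = panel[gwl_col].to_numpy(dtype=float)
    b55a = panel[b55a_col].to_numpy(dtype=float)
    if np.any(b55a <= 0):
        raise ValueError("B55α must be positive for every sample")
    y = np.asarray(panel["ed50_um"] if ed50 is None else ed50, dtype=float)
    if len(y) != len(gwl):
        raise ValueError("ED50 length must match panel")
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    ratio = gwl / b55a
    if np.ptp(ratio) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(ratio, y)
    return RatioModel(
        gradient=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(y),
    )


def predict_ed50(model: RatioModel, panel: pd.DataFrame,
                 gwl_col: str = "gwl", b55a_col: str = "b55a") -> pd.Series:
    """Per-sample predicted *ED50; NaN (flagged in the log) where B55α = 0."""
    gwl = panel[gwl_col].to_numpy(dtype=float)
    b55a = panel[b55a_col].to_numpy(dtype=float)
    pred = np.full(len(panel), np.nan)
    ok = b55a > 0
    if (~ok).any():
        log.warning("%d sample(s) with B55α = 0: no prediction", int((~ok).sum()))
    pred[ok] = model.predict(gwl[ok] / b55a[ok])
    return pd.Series(pred, index=panel.index, name="pred_ed50_um")


def rank_and_flag(predictions, fraction: float = 0.05) -> pd.Series:
    """Flag the ceil(fraction x n) samples with the lowest predicted *ED50.

    Ties are broken by stable input order (and logged). Invariant to any
    strictly increasing transform of the predictions.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    pred = pd.Series(predictions)
    if len(pred) == 0:
        raise ValueError("empty input")
    k = math.ceil(fraction * len(pred))
    order = np.argsort(pred.to_numpy(), kind="stable")
    flags = np.zeros(len(pred), dtype=bool)
    flags[order[:k]] = True
    vals = pred.to_numpy()
    if k < len(pred) and vals[order[k - 1]] == vals[order[k]]:
        log.warning("tie at the flag boundary broken by stable sample order")
    return pd.Series(flags, index=pred.index, name="flagged")


def cohort_median_shift(cohort: pd.DataFrame,
                        min_exact_n: int = 25) -> pd.DataFrame:
    """Per-group, per-gene tumour-minus-normal median shift with Wilcoxon test.

    Expects a long table with columns group, tissue ("tumour"/"normal"),
    gene and a value column (last column, e.g. ``fpkm``). Returns one row
    per (group, gene) with the median difference, unpaired two-tailed
    Wilcoxon rank-sum p-value (exact below ``min_exact_n`` per arm, normal
    approximation otherwise), BH adjustment across all determined tests,
    and status "nd" for groups without normal samples.
    """
    value_col = cohort.columns[-1]
    rows = []
    for (group, gene), sub in cohort.groupby(["group", "gene"], sort=True):
        t = sub.loc[sub["tissue"] == "tumour", value_col].to_numpy(dtype=float)
        n_ = sub.loc[sub["tissue"] == "normal", value_col].to_numpy(dtype=float)
        if len(t) < 1:
            raise ValueError(f"group {group!r} has no tumour samples")
        if len(n_) == 0:
            rows.append((group, gene, float(np.median(t)), np.nan, np.nan,
                         np.nan, "nd"))
            continue
        method = "exact" if min(len(t), len(n_)) < min_exact_n else "asymptotic"
        p = float(stats.mannwhitneyu(t, n_, alternative="two-sided",
                                     method=method).pvalue)
        rows.append((group, gene, float(np.median(t)), float(np.median(n_)),
                     float(np.median(t) - np.median(n_)), p, "tested"))
    out = pd.DataFrame(rows, columns=["group", "gene", "median_tumour",
                                      "median_normal", "median_shift", "p",
                                      "status"])
    out["p_adj"] = bh_adjust(out["p"])
    return out


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with its two-tailed t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
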