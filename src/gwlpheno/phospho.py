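"""Differential phosphosite statistics.

The processing chain for a sites x samples XIC intensity matrix:

1. per-sample sum normalisation (each column divided by its total);
2. log2 transform;
3. zero intensities imputed as that sample's minimum log2 value minus 1;
4. per-sample median centring;
5. per-site moderated t-test (empirical-Bayes variance shrinkage towards a
   pooled prior, prior df and scale estimated by the method of moments on
   the log residual variances), two-group log2 fold change;
6. Benjamini-Hochberg FDR across sites; hits require p < 0.05 AND
   FDR < 0.1, signed by the fold change.

Motif analysis computes per-class residue frequencies over the ±7-residue
windows (position 0 = phosphoresidue; 'X' padding excluded from
denominators) and a Fisher exact test of proline at +1 in hits versus the
not-significant background — the minimal Cdk1 consensus signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .response import bh_adjust

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def normalize_phospho(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum-normalise, log2, impute zeros as (sample min log2 - 1), median-centre.

    Non-numeric columns (e.g. ``window``) are passed through untouched. The
    result is invariant to per-sample multiplicative rescaling of the raw
    intensities. Raises on an all-zero sample.
    """
    meta_cols = [c for c in matrix.columns
                 if not pd.api.types.is_numeric_dtype(matrix[c])]
    data = matrix.drop(columns=meta_cols).astype(float)
    if (data.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    totals = data.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    frac = data / totals

    out = np.empty(frac.shape)
    arr = frac.to_numpy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        pos = col > 0
        logged = np.full(col.shape, np.nan)
        logged[pos] = np.log2(col[pos])
        if pos.any():
            logged[~pos] = logged[pos].min() - 1.0
        out[:, j] = logged - np.median(logged)
    processed = pd.DataFrame(out, index=matrix.index, columns=data.columns)
    for c in meta_cols:
        processed.insert(0, c, matrix[c])
    return processed


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x  # good starting point: trigamma(y) ~ 1/y for large y
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for residual variances.

    Models s² ~ s0² F(df, d0) and returns (d0, s0²); d0 may be inf when the
    observed spread of log variances is no wider than chi-square sampling
    alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("no positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _split_design(columns, design: Mapping[str, str]) -> tuple[list, list, tuple]:
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValueError("design must define exactly two groups")
    g1 = [c for c in columns if design.get(c) == groups[0]]
    g2 = [c for c in columns if design.get(c) == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 replicates per group")
    return g1, g2, (groups[0], groups[1])


def moderated_test(processed: pd.DataFrame, design: Mapping[str, str],
                   prior_df: float | None = None,
                   prior_s2: float | None = None) -> pd.DataFrame:
    """Per-site moderated two-sample t-test on a processed (log2) matrix.

    Fold change is mean(second group) - mean(first group) with groups in
    sorted name order. Site variances are shrunk towards the pooled prior:
    s̃² = (d0·s0² + df·s²)/(d0 + df), and the moderated t is referred to a
    t distribution with df + d0 degrees of freedom. ``prior_df=0`` recovers
    the ordinary two-sample t-test exactly; ``prior_df=inf`` (with a given
    ``prior_s2``) uses the pooled prior SE alone. By default both prior
    parameters are estimated from the data by the method of moments.

    Returns a tidy frame indexed like ``processed`` with columns
    log2fc, t, p, fdr (and ``window`` when present).
    """
    meta_cols = [c for c in processed.columns
                 if not pd.api.types.is_numeric_dtype(processed[c])]
    data = processed.drop(columns=meta_cols)
    g1, g2, _ = _split_design(data.columns, design)
    x1 = data[g1].to_numpy(dtype=float)
    x2 = data[g2].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    df_res = n1 + n2 - 2
    if df_res <= 0:
        raise ValueError("zero residual degrees of freedom")

    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m2 - m1
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_res

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df_res)
    else:
        d0 = float(prior_df)
        if d0 > 0 and prior_s2 is None and np.isfinite(d0):
            _, s0_sq = estimate_prior(s2, df_res)
        else:
            s0_sq = prior_s2 if prior_s2 is not None else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_res
    else:
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = df_res + d0
    # zero residual variance with no prior mass: no test possible there
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = lfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    out = pd.DataFrame({"log2fc": lfc, "t": tstat, "p": p},
                       index=processed.index)
    out["fdr"] = bh_adjust(out["p"])
    if "window" in processed.columns:
        out.insert(0, "window", processed["window"])
    return out


def classify_hits(site_stats: pd.DataFrame, p_max: float = 0.05,
                  fdr_max: float = 0.1) -> pd.DataFrame:
    """Label sites: hits need p < p_max AND FDR < fdr_max, signed by FC."""
    out = site_stats.copy()
    sig = (out["p"] < p_max) & (out["fdr"] < fdr_max)
    out["hit_class"] = np.where(
        sig & (out["log2fc"] < 0), "negative hit",
        np.where(sig & (out["log2fc"] > 0), "positive hit", "not significant"),
    )
    return out


def hit_counts(classified: pd.DataFrame) -> dict:
    c = classified["hit_class"].value_counts()
    return {k: int(c.get(k, 0))
            for k in ("negative hit", "positive hit", "not significant")}


def motif_frequencies(windows: Sequence[str], labels: Sequence[str]
                      ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Position x residue frequencies per class, plus +1-proline enrichment.

    Windows are 15-mers aligned on the phosphoresidue ('X' pads truncated
    termini and is excluded from frequency denominators). Enrichment rows
    give the odds ratio and two-sided Fisher exact p of proline at +1 in
    each hit class against the "not significant" background.
    """
    if len(windows) != len(labels):
        raise ValueError("windows and labels must align")
    if len(windows) == 0:
        raise ValueError("no windows supplied")
    positions = list(range(-7, 8))
    freqs: dict[str, pd.DataFrame] = {}
    plus1_p = {}
    for cls in sorted(set(labels)):
        wins = [w for w, l in zip(windows, labels) if l == cls]
        if not wins:
            raise ValueError(f"no windows in class {cls!r}")
        if any(len(w) != 15 for w in wins):
            raise ValueError("windows must be 15-mers")
        counts = pd.DataFrame(0, index=positions, columns=list(AMINO_ACIDS))
        for w in wins:
            for pos, aa in zip(positions, w):
                if aa != "X":
                    counts.loc[pos, aa] += 1
        totals = counts.sum(axis=1)
        freqs[cls] = counts.div(totals.replace(0, np.nan), axis=0)
        n_p = sum(1 for w in wins if w[8] == "P")
        n_tot = sum(1 for w in wins if w[8] != "X")
        plus1_p[cls] = (n_p, n_tot)

    enrich_rows = []
    bg = plus1_p.get("not significant")
    for cls, (n_p, n_tot) in plus1_p.items():
        if cls == "not significant" or bg is None:
            continue
        table = [[n_p, n_tot - n_p], [bg[0], bg[1] - bg[0]]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        enrich_rows.append((cls, n_p / n_tot if n_tot else np.nan,
                            bg[0] / bg[1] if bg[1] else np.nan,
                            float(odds), float(p)))
    enrichment = pd.DataFrame(
        enrich_rows,
        columns=["hit_class", "freq_plus1_pro", "bg_plus1_pro", "odds_ratio", "fisher_p"],
    )
    return freqs, enrichment


@dataclass
class IntersectionResult:
    """Venn partition over named hit sets."""

    regions: dict[tuple[str, ...], int]  # exclusive region -> size
    common: int
    union: int

    @property
    def shared_fraction(self) -> float:
        return self.common / self.union if self.union else float("nan")


def intersect_hits(hit_sets: Mapping[str, set]) -> IntersectionResult:
    """All exclusive Venn regions plus |common to all| / |union|."""
    names = list(hit_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    sets = {k: set(v) for k, v in hit_sets.items()}
    union = set().union(*sets.values())
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            regions[combo] = len(inside - outside)
    common = len(set.intersection(*sets.values()))
    return IntersectionResult(regions=regions, common=common, union=len(union))
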