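"""Phenotypic-similarity scoring via 2D embedding and optimal transport.

The off-target screen logic: subsample a fixed number of cells per
condition, co-embed five per-cell features (DNA, EdU, p21 intensity, cell
area, nuclear count) into 2D with UMAP fitted jointly on the pooled cells
(so coordinates are comparable across conditions), then score each
condition by the exact 1-Wasserstein distance of its point cloud to a
reference condition. Low distance = the condition phenocopies the
reference.

Right-skewed intensities are log1p-transformed and all features are
z-scored over the pooled cells before embedding.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

DEFAULT_FEATURES = ("dna_norm", "edu_norm", "p21_norm", "area_norm", "nuclei")
_LOG_FEATURES = ("dna_norm", "edu_norm", "p21_norm")


@dataclass
class Embedding2D:
    """Joint 2D embedding partitioned back by condition."""

    coords: dict[str, np.ndarray]  # condition -> (n, 2)
    seed: int
    params: dict = field(default_factory=dict)


@dataclass
class SimilarityScore:
    condition: str
    distance: float
    n: int


def subsample_cells(table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of ``n`` rows without replacement (all rows, with a
    logged warning, when the population is smaller)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(table) == 0:
        raise ValueError("empty table")
    if len(table) <= n:
        if len(table) < n:
            log.warning("population (%d) smaller than requested n=%d; using all",
                        len(table), n)
        return table.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=False)
    return table.iloc[np.sort(idx)].copy()


def embed_conditions(
    tables: Mapping[str, pd.DataFrame],
    features: Sequence[str] = DEFAULT_FEATURES,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> Embedding2D:
    """Fit one UMAP on the pooled cells of all conditions.

    A single joint embedding is required for cross-condition Wasserstein
    distances to be meaningful. Deterministic given the seed (UMAP runs
    single-threaded when seeded).
    """
    import umap  # deferred: numba compilation is slow at import time

    names = list(tables)
    mats = []
    for name in names:
        t = tables[name]
        missing = [f for f in features if f not in t.columns]
        if missing:
            raise ValueError(f"condition {name!r} lacks feature(s) {missing}")
        mats.append(t[list(features)].to_numpy(dtype=float))
    pooled = np.vstack(mats)
    if len(pooled) < 20:
        raise ValueError("too few pooled cells to embed (< 20)")

    X = pooled.copy()
    for j, f in enumerate(features):
        if f in _LOG_FEATURES:
            X[:, j] = np.log1p(X[:, j])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    emb = reducer.fit_transform(X)

    coords = {}
    start = 0
    for name, m in zip(names, mats):
        coords[name] = emb[start:start + len(m)]
        start += len(m)
    return Embedding2D(coords=coords, seed=seed,
                       params={"n_neighbors": n_neighbors, "min_dist": min_dist,
                               "features": list(features)})


def wasserstein_2d(a, b, method: str = "exact", seed: int = 0,
                   n_projections: int = 200) -> float:
    """1-Wasserstein distance between two 2D point clouds (Euclidean cost).

    Clouds are treated as uniform empirical measures. Unequal sizes are
    equalised by subsampling the larger cloud (seeded). For equal-size
    uniform measures the optimal transport plan is a point-to-point
    assignment, solved exactly (``method="exact"``); ``method="sliced"``
    averages 1D transport costs over random projections instead — a fast
    approximation that is itself a metric but generally underestimates the
    2D value.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty point cloud")
    if a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("point clouds must be n x 2")
    rng = np.random.default_rng(seed)
    if len(a) != len(b):
        n = min(len(a), len(b))
        if len(a) > n:
            a = a[rng.choice(len(a), n, replace=False)]
        else:
            b = b[rng.choice(len(b), n, replace=False)]

    if method == "exact":
        cost = cdist(a, b)
        rows, cols = linear_sum_assignment(cost)
        return float(cost[rows, cols].mean())
    if method == "sliced":
        thetas = rng.uniform(0, np.pi, n_projections)
        dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        pa = np.sort(a @ dirs.T, axis=0)
        pb = np.sort(b @ dirs.T, axis=0)
        return float(np.mean(np.abs(pa - pb)))
    raise ValueError(f"unknown method {method!r}")


def wasserstein_bruteforce(a, b) -> float:
    """Minimum mean matched distance over all assignments (oracle; <= 8 pts)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) > 8:
        raise ValueError("equal-size clouds of at most 8 points")
    cost = cdist(a, b)
    best = min(
        sum(cost[i, p[i]] for i in range(len(a)))
        for p in itertools.permutations(range(len(b)))
    )
    return float(best / len(a))


def similarity_profile(embedding: Embedding2D, reference: str,
                       seed: int = 0) -> list[SimilarityScore]:
    """Wasserstein distance of every condition to the reference cloud.

    The first entry is a finite-sample noise floor: the distance between
    two disjoint random halves of the reference cloud itself.
    """
    if reference not in embedding.coords:
        raise ValueError(f"reference condition {reference!r} not embedded")
    rng = np.random.default_rng(seed)
    ref = embedding.coords[reference]
    scores = []

    half = len(ref) // 2
    if half >= 1:
        perm = rng.permutation(len(ref))
        floor = wasserstein_2d(ref[perm[:half]], ref[perm[half:2 * half]],
                               seed=int(rng.integers(2**31)))
        scores.append(SimilarityScore(f"{reference} (split-half baseline)",
                                      floor, half))
    for name, pts in embedding.coords.items():
        if name == reference:
            continue
        d = wasserstein_2d(ref, pts, seed=int(rng.integers(2**31)))
        scores.append(SimilarityScore(name, d, min(len(ref), len(pts))))
    return scores
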