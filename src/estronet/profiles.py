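"""Expression-profile clustering and condition-level summaries.

Implements the profile-side analyses that accompany the network: k-means
clustering of median-centred log2FC profiles (with a silhouette-based
choice of k), PAM clustering and PCA of samples, the condition-vs-
condition correlation matrix over a gene set, and per-condition "wave"
summaries of fold-change distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .expression_io import ProfileMatrix

__all__ = [
    "ClusterResult",
    "median_center",
    "kmeans_profiles",
    "choose_k",
    "pca_samples",
    "pam_samples",
    "condition_corr_matrix",
    "wave_summary",
]


def median_center(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Subtract each row's median; output rows have median 0. Idempotent."""
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("median_center requires a 2-D matrix with >= 1 column")
    out = values - np.median(values, axis=1, keepdims=True)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass
class ClusterResult:
    """Result of a profile clustering run.

    ``assignment``: gene -> cluster id in 1..k (Series indexed by gene for
    DataFrame input, by row number otherwise).
    """

    assignment: pd.Series
    k: int
    centroids: np.ndarray
    n_iter: int
    inertia: float  # within-cluster sum of squares
    seed: int


def _as_values(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.index)
    values = np.asarray(matrix, dtype=float)
    return values, list(range(values.shape[0]))


def _kmeans_once(values: np.ndarray, k: int, max_iter: int, rng) -> tuple:
    """One seeded k-means++ initialisation followed by Lloyd iterations."""
    n = values.shape[0]
    chosen = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = ((values[:, None, :] - values[None, chosen, :]) ** 2).sum(2).min(1)
        total = d2.sum()
        if total > 0:
            chosen.append(int(rng.choice(n, p=d2 / total)))
        else:  # all remaining rows coincide with a centre: pick any unchosen
            chosen.append(int(next(i for i in range(n) if i not in chosen)))
    centroids = values[chosen].copy()
    labels = np.zeros(n, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((values[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        for c in range(k):
            members = values[new_labels == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
            else:  # re-seed an empty cluster with the worst-fitted point
                worst = d2[np.arange(n), new_labels].argmax()
                centroids[c] = values[worst]
                new_labels[worst] = c
        if n_iter > 1 and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    d2 = ((values[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(n), labels].sum())
    return labels, centroids, inertia, n_iter


def kmeans_profiles(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 5,
    max_iter: int = 1000,
    seed: int = 0,
    center: bool = True,
    n_init: int = 10,
) -> ClusterResult:
    """Seeded k-means on (median-centred) profile rows.

    Runs ``n_init`` k-means++ initialisations (first centre uniform,
    later centres with probability proportional to squared distance from
    the nearest chosen centre) followed by Lloyd iterations, and keeps
    the solution with the lowest within-cluster sum of squares; ties in
    the nearest-centroid step break to the lowest cluster index; empty
    clusters re-seed to the worst-fitted point.  Fully deterministic
    given the seed.  The within-cluster sum of squares is non-increasing
    across Lloyd iterations and the final assignment is a fixed point.
    """
    values, index = _as_values(matrix)
    n = values.shape[0]
    if n == 0:
        raise ValueError("cannot cluster an empty matrix")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows {n}")
    if n_init < 1:
        raise ValueError(f"n_init must be >= 1, got {n_init}")
    if center:
        values = median_center(values)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        labels, centroids, inertia, n_iter = _kmeans_once(values, k, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, n_iter)
    labels, centroids, inertia, n_iter = best
    assignment = pd.Series(labels + 1, index=index, name="cluster")
    return ClusterResult(assignment, k, centroids, n_iter, inertia, seed)


def choose_k(
    matrix: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(2, 9),
    seed: int = 0,
    max_iter: int = 1000,
) -> tuple[int, pd.DataFrame]:
    """Pick k by maximum mean silhouette width over candidate values.

    Ties go to the smaller k.  Returns (best k, score table with one row
    per candidate).
    """
    values, _ = _as_values(matrix)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > values.shape[0] - 1:
        raise ValueError(
            f"k range {ks} must lie within 2..{values.shape[0] - 1} for "
            f"{values.shape[0]} rows"
        )
    centred = median_center(values)
    rows = []
    for k in ks:
        res = kmeans_profiles(centred, k=k, max_iter=max_iter, seed=seed, center=False)
        score = float(silhouette_score(centred, res.assignment.to_numpy()))
        rows.append((k, score, res.inertia))
    table = pd.DataFrame(rows, columns=["k", "silhouette", "inertia"])
    best = int(table.loc[table["silhouette"].idxmax(), "k"])  # idxmax: first max
    return best, table


def pca_samples(
    log_expr: pd.DataFrame | np.ndarray, n_components: int | None = None
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """PCA of samples (rows) via SVD of the column-mean-centred matrix.

    Returns (scores, explained variance fractions); fractions are
    non-increasing and sum to 1 over the full rank.
    """
    values, index = _as_values(log_expr)
    if values.shape[0] < 2:
        raise ValueError(f"need >= 2 samples for PCA, got {values.shape[0]}")
    centred = values - values.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = u * s
    total = float((s**2).sum())
    explained = (s**2) / total if total > 0 else np.zeros_like(s)
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
    if isinstance(log_expr, pd.DataFrame):
        scores = pd.DataFrame(
            scores,
            index=log_expr.index,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        )
    return scores, explained


def pam_samples(
    log_expr: pd.DataFrame | np.ndarray, k: int = 3, seed: int = 0, max_iter: int = 100
) -> ClusterResult:
    """Partitioning Around Medoids (build + swap) on Euclidean distances.

    Deterministic given the seed (the seed only matters for breaking
    exact cost ties during the build phase, which are resolved to the
    lowest row index).
    """
    values, index = _as_values(log_expr)
    n = values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")
    dist = np.sqrt(((values[:, None, :] - values[None, :, :]) ** 2).sum(axis=2))

    # build: greedily add the medoid giving the largest cost reduction
    medoids = [int(dist.sum(axis=1).argmin())]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -1.0
        medoids.append(int(gains.argmax()))

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    # swap: steepest-descent swaps until no improvement
    best_cost = cost(medoids)
    for _ in range(max_iter):
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_swap = (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    medoids = sorted(medoids)
    labels = dist[:, medoids].argmin(axis=1)
    inertia = float(dist[np.arange(n), [medoids[l] for l in labels]].sum())
    assignment = pd.Series(labels + 1, index=index, name="cluster")
    centroids = values[medoids]
    return ClusterResult(assignment, k, centroids, 0, inertia, seed)


def condition_corr_matrix(
    profiles: ProfileMatrix, gene_set: set[str] | list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between condition columns over a gene set.

    Returns (matrix, flagged) where ``flagged`` lists zero-variance
    conditions whose correlations were set to 0 (diagonal stays 1).
    """
    genes = [g for g in profiles.genes if g in set(gene_set)]
    missing = set(gene_set) - set(profiles.genes)
    if missing:
        raise ValueError(f"gene(s) not in profiles: {sorted(missing)[:5]}")
    if len(genes) < 3:
        raise ValueError(f"need >= 3 genes for condition correlations, got {len(genes)}")
    sub = profiles.data.loc[genes]
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=0)
    flagged = [c for c, s in zip(sub.columns, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=sub.columns, columns=sub.columns), flagged


def wave_summary(
    profiles: ProfileMatrix,
    gene_set: set[str] | list[str],
    highlight_abs_fc: float = 3.0,
) -> pd.DataFrame:
    """Per-condition five-number summary of log2FC over a gene set, plus
    the count of genes with |log2FC| strictly above ``highlight_abs_fc``."""
    genes = [g for g in profiles.genes if g in set(gene_set)]
    if not genes:
        raise ValueError("gene_set is empty or disjoint from the profiles")
    sub = profiles.data.loc[genes]
    rows = []
    for (tissue, day), col in zip(profiles.conditions, sub.columns):
        v = sub[col].to_numpy()
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "tissue": tissue,
                "day": day,
                "min": float(v.min()),
                "q1": float(q1),
                "median": float(q2),
                "q3": float(q3),
                "max": float(v.max()),
                "n_highlight": int((np.abs(v) > highlight_abs_fc).sum()),
            }
        )
    return pd.DataFrame(rows)
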