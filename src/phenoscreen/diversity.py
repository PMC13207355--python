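"""Phenotypic-diversity diagnostics for above-threshold compounds.

Compounds passing both the survival threshold (robust Z < -3) and the
phenotypic-distance threshold (-log10 p > 2) are clustered in principal-
component space with k-means (k = 2..20, Lloyd's algorithm, 10
iterations, best of 25 restarts initialized at distinct dataset rows).
Cluster structure is judged by the within-cluster sum of squared
point-to-centroid distances (WSS) versus k, an elbow heuristic (maximum
second difference), and the mean silhouette coefficient

    s(i) = (b(i) - a(i)) / max{a(i), b(i)},

with a(i) the mean distance from i to its cluster co-members and b(i),
by default, the mean distance to the members of the nearest other
cluster (a centroid-distance variant of b(i) is available). A screen
with maximum mean silhouette below a small bound is reported as having
no noticeable cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

DEFAULT_K_RANGE = range(2, 21)
DEFAULT_ITERS = 10
DEFAULT_RESTARTS = 25
NO_STRUCTURE_SILHOUETTE = 0.25


@dataclass
class ClusterDiagnostics:
    k: int
    wss: float
    assignments: np.ndarray
    mean_silhouette: float | None = None


def threshold_subset(records: pd.DataFrame, score_cols: list[str] | None = None,
                     z_thresh: float = -3.0, p_thresh: float = 2.0) -> pd.DataFrame:
    """Unique compounds passing BOTH thresholds, one median score row each.

    Note the conjunction: diversity analysis restricts to compounds that
    cross the survival AND the distance threshold (strict inequalities).
    """
    if score_cols is None:
        score_cols = [c for c in records.columns if c.startswith("PC")]
    passing = records[(records["survival_z"] < z_thresh)
                      & (records["neglog10p"] > p_thresh)]
    if passing.empty:
        raise ValueError("nothing to cluster: no compound passes both thresholds")
    return passing.groupby("compound", as_index=False)[score_cols].median()


def _lloyd(X: np.ndarray, centroids: np.ndarray, iters: int) -> tuple[np.ndarray, np.ndarray, float]:
    for _ in range(iters):
        labels = cdist(X, centroids).argmin(axis=1)
        new = centroids.copy()
        for j in range(len(centroids)):
            members = X[labels == j]
            if len(members):
                new[j] = members.mean(axis=0)
        if np.array_equal(new, centroids):
            break
        centroids = new
    labels = cdist(X, centroids).argmin(axis=1)
    wss = float(((X - centroids[labels]) ** 2).sum())
    return labels, centroids, wss


def kmeans_wss(scores: np.ndarray | pd.DataFrame, k_range=DEFAULT_K_RANGE,
               iters: int = DEFAULT_ITERS, restarts: int = DEFAULT_RESTARTS,
               seed: int = 0) -> dict[int, ClusterDiagnostics]:
    """Best-of-restarts Lloyd's k-means over a k grid.

    Each restart initializes the k centroids at distinct dataset rows.
    Rows are canonically (lexicographically) ordered before restart
    sampling so the reported WSS does not depend on input row order.
    """
    X = np.asarray(scores, dtype=float) if not isinstance(scores, pd.DataFrame) else \
        scores.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    n = len(X)
    canon = np.lexsort(X.T[::-1])  # row order independence for restart draws
    Xc = X[canon]
    out: dict[int, ClusterDiagnostics] = {}
    for k in k_range:
        if k > n:
            raise ValueError(f"k={k} exceeds {n} points")
        rng = np.random.default_rng((seed, k))
        best: tuple[float, np.ndarray] | None = None
        for _ in range(restarts):
            init_rows = rng.choice(n, size=k, replace=False)
            labels, _, wss = _lloyd(Xc, Xc[init_rows].copy(), iters)
            if best is None or wss < best[0]:
                best = (wss, labels)
        labels_orig = np.empty(n, dtype=int)
        labels_orig[canon] = best[1]
        out[k] = ClusterDiagnostics(k=k, wss=best[0], assignments=labels_orig)
    return out


def silhouette_values(scores: np.ndarray, assignments: np.ndarray,
                      b_definition: str = "mean") -> np.ndarray:
    """Per-point silhouette s(i); singleton-cluster points get s(i) = 0.

    ``b_definition``: "mean" (standard; mean distance to members of the
    nearest other cluster) or "centroid" (distance from i to the nearest
    other cluster's centroid).
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    D = cdist(X, X)
    s = np.zeros(len(X))
    centroids = {c: X[labels == c].mean(axis=0) for c in uniq}
    for i in range(len(X)):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            s[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        if b_definition == "mean":
            b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        elif b_definition == "centroid":
            b = min(np.linalg.norm(X[i] - centroids[c]) for c in uniq if c != labels[i])
        else:
            raise ValueError("b_definition must be 'mean' or 'centroid'")
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def silhouette_mean(scores: np.ndarray, assignments: np.ndarray,
                    b_definition: str = "mean") -> tuple[float, np.ndarray]:
    s = silhouette_values(scores, assignments, b_definition)
    return float(s.mean()), s


def diversity_report(diagnostics: dict[int, ClusterDiagnostics],
                     scores: np.ndarray,
                     silhouette_bound: float = NO_STRUCTURE_SILHOUETTE) -> dict:
    """WSS curve, elbow (max second difference), silhouettes, and a verdict.

    The verdict is "no noticeable cluster structure" when the maximum
    mean silhouette over the k grid stays below ``silhouette_bound``.
    """
    ks = sorted(diagnostics)
    wss = [diagnostics[k].wss for k in ks]
    sils = {}
    for k in ks:
        m, _ = silhouette_mean(scores, diagnostics[k].assignments)
        diagnostics[k].mean_silhouette = m
        sils[k] = m
    elbow = None
    if len(ks) >= 3:
        second_diff = [wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, len(ks) - 1)]
        elbow = ks[1 + int(np.argmax(second_diff))]
    max_sil = max(sils.values())
    return {
        "k": ks,
        "wss": wss,
        "mean_silhouette": sils,
        "elbow_k": elbow,
        "silhouette_peak_k": max(sils, key=sils.get),
        "max_mean_silhouette": max_sil,
        "verdict": ("no noticeable cluster structure" if max_sil < silhouette_bound
                    else "cluster structure present"),
    }
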