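"""Hierarchical clustering of OM distance matrices with internal validation.

Ward's minimum-variance agglomeration is applied directly to the pairwise
dissimilarity matrix through the Lance–Williams recurrence.  Two
conventions are shipped because the literature uses both names loosely:

* ``"D2"`` (default) — the recurrence acts on squared dissimilarities and
  merge heights are reported on the original distance scale (the
  ``ward.D2`` convention, equivalent to scipy's ``linkage(..., "ward")``);
* ``"D"`` — the recurrence acts on the dissimilarities themselves
  (the historical ``ward.D`` convention).

The number of clusters is selected by maximising the average silhouette
width, with Hubert's C index (lower is better) reported alongside; when
the two criteria disagree, both candidate k values are exposed and the
silhouette choice wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.cluster.hierarchy import fcluster

from .om import DistanceMatrix

__all__ = [
    "ClusterSolution",
    "ward_tree",
    "cut",
    "avg_silhouette",
    "hubert_c",
    "select_k",
    "dendrogram_newick",
]


@dataclass
class ClusterSolution:
    """A cut of the Ward tree plus its validation scores.

    ``diagnostics`` maps every candidate k to its (silhouette, C index)
    pair; ``best_k_by_c`` records the C-index favourite so disagreement
    with the silhouette choice is visible.
    """

    k: int
    labels: np.ndarray
    avg_silhouette: float
    hubert_c: float
    merge_tree: np.ndarray
    diagnostics: dict[int, tuple[float, float]] = field(default_factory=dict)
    best_k_by_c: int | None = None
    degenerate: bool = False


def _as_square(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.D
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    return D


def ward_tree(D: DistanceMatrix | np.ndarray, variant: str = "D2") -> np.ndarray:
    """Agglomerate a dissimilarity matrix with Ward's method.

    Returns a scipy-format linkage matrix (one row per merge:
    ``[id_left, id_right, height, size]``) so the scipy cutting and
    plotting utilities apply directly.
    """
    d = _as_square(D).copy()
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if variant not in ("D", "D2"):
        raise ValueError("variant must be 'D' or 'D2'")
    work = d ** 2 if variant == "D2" else d
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n)
    # cluster_ids[i] = scipy id currently stored in row/col i of `work`
    cluster_ids = list(range(n))
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        h = work[i, j]
        height = float(np.sqrt(h)) if variant == "D2" else float(h)
        ni, nj = sizes[i], sizes[j]
        lo, hi = sorted((cluster_ids[i], cluster_ids[j]))
        Z[step] = (lo, hi, height, ni + nj)
        # Lance-Williams update with Ward coefficients
        k_mask = active.copy()
        k_mask[[i, j]] = False
        nk = sizes[k_mask]
        upd = (
            (ni + nk) * work[i, k_mask]
            + (nj + nk) * work[j, k_mask]
            - nk * h
        ) / (ni + nj + nk)
        work[i, k_mask] = upd
        work[k_mask, i] = upd
        active[j] = False
        sizes[i] = ni + nj
        cluster_ids[i] = n + step
    # enforce monotone heights against tiny float noise only
    Z[:, 2] = np.maximum.accumulate(np.maximum(Z[:, 2], 0.0))
    return Z


def cut(tree: np.ndarray, k: int) -> np.ndarray:
    """Labels (1..k) induced by removing the k−1 highest merges."""
    n = tree.shape[0] + 1
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    return fcluster(tree, t=k, criterion="maxclust")


def avg_silhouette(D: DistanceMatrix | np.ndarray, labels: Iterable[int]) -> float:
    """Average silhouette width of a partition under a precomputed distance.

    s(i) = (b − a)/max(a, b) with a the mean distance to own-cluster
    members (excluding self) and b the smallest mean distance to another
    cluster; members of singleton clusters score 0, as do points where
    a = b = 0.
    """
    d = _as_square(D)
    labels = np.asarray(list(labels))
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two clusters")
    n = d.shape[0]
    if labels.size != n:
        raise ValueError("one label per observation required")
    s = np.zeros(n)
    for idx in range(n):
        own = labels == labels[idx]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton convention: 0
        a = d[idx, own].sum() / (n_own - 1)
        b = min(d[idx, labels == g].mean() for g in uniq if g != labels[idx])
        m = max(a, b)
        s[idx] = 0.0 if m == 0 else (b - a) / m
    return float(s.mean())


def hubert_c(D: DistanceMatrix | np.ndarray, labels: Iterable[int]) -> float:
    """Hubert's C index in [0, 1] (lower is better).

    C = (S − S_min)/(S_max − S_min), where S sums the within-cluster
    pairwise distances and S_min / S_max sum the N_w smallest / largest
    distances overall, N_w being the number of within-cluster pairs.
    """
    d = _as_square(D)
    labels = np.asarray(list(labels))
    if np.unique(labels).size < 2:
        raise ValueError("C index needs at least two clusters")
    iu = np.triu_indices(d.shape[0], k=1)
    dist = d[iu]
    within = labels[iu[0]] == labels[iu[1]]
    n_w = int(within.sum())
    if n_w == 0:
        raise ValueError("C index needs at least one within-cluster pair")
    s = float(dist[within].sum())
    ordered = np.sort(dist)
    s_min = float(ordered[:n_w].sum())
    s_max = float(ordered[-n_w:].sum())
    if s_max == s_min:
        warnings.warn("all pairwise distances equal; C index defined as 0", stacklevel=2)
        return 0.0
    return (s - s_min) / (s_max - s_min)


def select_k(
    D: DistanceMatrix | np.ndarray,
    k_range: Iterable[int] = range(2, 9),
    variant: str = "D2",
) -> ClusterSolution:
    """Cut the Ward tree at every candidate k and pick the best partition.

    The silhouette criterion is primary; the C-index favourite is reported
    alongside (``best_k_by_c``) so criterion disagreement is never silent.
    A matrix of all-identical points is flagged ``degenerate``.
    """
    d = _as_square(D)
    n = d.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k range must lie within [2, {n - 1}]")
    tree = ward_tree(d, variant=variant)
    diagnostics: dict[int, tuple[float, float]] = {}
    results: dict[int, np.ndarray] = {}
    iu = np.triu_indices(n, k=1)
    degenerate = bool(np.allclose(d[iu], d[iu][0] if iu[0].size else 0.0))
    for k in ks:
        labels = cut(tree, k)
        if np.unique(labels).size < 2:
            continue
        sil = avg_silhouette(d, labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = hubert_c(d, labels)
        diagnostics[k] = (sil, c)
        results[k] = labels
    if not diagnostics:
        if degenerate:
            # all points identical: no k is preferable; return the first
            # candidate cut flagged degenerate with neutral scores
            k0 = ks[0]
            return ClusterSolution(
                k=k0, labels=cut(tree, k0), avg_silhouette=0.0,
                hubert_c=0.0, merge_tree=tree, diagnostics={},
                best_k_by_c=None, degenerate=True,
            )
        raise ValueError("no valid partition in the supplied k range")
    best_k = max(diagnostics, key=lambda k: diagnostics[k][0])
    best_k_by_c = min(diagnostics, key=lambda k: diagnostics[k][1])
    sil, c = diagnostics[best_k]
    return ClusterSolution(
        k=best_k,
        labels=results[best_k],
        avg_silhouette=sil,
        hubert_c=c,
        merge_tree=tree,
        diagnostics=diagnostics,
        best_k_by_c=best_k_by_c,
        degenerate=degenerate,
    )


def dendrogram_newick(tree: np.ndarray, ids: list[str] | None = None) -> str:
    """Nested-parenthesis (Newick-style) text encoding of the merge tree."""
    n = tree.shape[0] + 1
    ids = ids or [str(i) for i in range(n)]
    nodes: dict[int, str] = {i: ids[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for step, (a, b, h, _) in enumerate(tree):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + step] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + step] = h
    return nodes[2 * n - 2] + ";"
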