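"""Partitioning around medoids (PAM) for temporal expression profiles.

The changing-transcript set is grouped by the Kaufman–Rousseeuw BUILD+SWAP
algorithm on a profile dissimilarity matrix (default: 1 − Pearson
correlation of log2 time profiles, a shape-based metric).  Cluster quality
is summarized by silhouette scores — classical by default, with the
medoid-based variant (similarity to the own-cluster medoid vs. the other
medoids) available — and a k-scan picks the silhouette-optimal number of
subsets unless overridden.

Everything here is deterministic: BUILD and SWAP break ties to the lowest
item index, and SWAP accepts the first strictly improving
(medoid, candidate) exchange in (medoid index, candidate index) order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "profile_dissimilarity",
    "pam",
    "silhouette",
    "scan_k",
    "normalize_for_heatmap",
    "heatmap_gene_order",
    "ClusterResult",
]

_EPS = 1e-12


def _validate_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if (d < -_EPS).any():
        raise ValueError("dissimilarities must be non-negative")
    if np.abs(d - d.T).max(initial=0.0) > 1e-12:
        raise ValueError("dissimilarity matrix must be symmetric within 1e-12")
    if np.abs(np.diag(d)).max(initial=0.0) > _EPS:
        raise ValueError("dissimilarity diagonal must be zero")
    return d


def profile_dissimilarity(
    profiles: pd.DataFrame, metric: str = "correlation"
) -> pd.DataFrame:
    """Pairwise profile dissimilarity.

    ``profiles``: items (genes) × time points, typically replicate-mean
    log2 expression.  ``metric``:

    * ``"correlation"`` — ``1 − Pearson r`` of the two profiles, in [0, 2];
      zero-variance profiles are defined as uncorrelated (d = 1) with a
      warning;
    * ``"euclidean"`` — Euclidean distance between per-profile z-scores.
    """
    x = profiles.to_numpy(dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError("profiles contain missing values")
    n = x.shape[0]
    sd = x.std(axis=1)
    flat = sd == 0
    if metric == "correlation":
        if flat.any():
            warnings.warn(f"{int(flat.sum())} zero-variance profiles: d set to 1")
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.where(flat, 1.0, np.linalg.norm(xc, axis=1))
        xn = xc / denom[:, None]
        r = xn @ xn.T
        np.clip(r, -1.0, 1.0, out=r)
        d = 1.0 - r
        d[flat, :] = 1.0
        d[:, flat] = 1.0
    elif metric == "euclidean":
        denom = np.where(flat, 1.0, sd)
        z = (x - x.mean(axis=1, keepdims=True)) / denom[:, None]
        sq = (z ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (z @ z.T)
        d = np.sqrt(np.clip(d2, 0.0, None))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class ClusterResult:
    """Outcome of one PAM run."""

    k: int
    medoid_indices: np.ndarray  # positions into the item list, sorted
    labels: np.ndarray  # per item: position into medoid_indices
    cost: float  # sum of item-to-assigned-medoid dissimilarities
    item_ids: list | None = None

    @property
    def medoid_ids(self) -> list:
        if self.item_ids is None:
            return list(self.medoid_indices)
        return [self.item_ids[i] for i in self.medoid_indices]

    def cluster_members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def _assign(d: np.ndarray, medoids: np.ndarray):
    dm = d[:, medoids]  # n × k
    order = np.argsort(dm, axis=1, kind="stable")
    labels = order[:, 0]
    d1 = dm[np.arange(d.shape[0]), labels]
    if medoids.size > 1:
        second = order[:, 1]
        d2 = dm[np.arange(d.shape[0]), second]
    else:
        d2 = np.full(d.shape[0], np.inf)
    return labels, d1, d2


def pam(d: np.ndarray | pd.DataFrame, k: int, max_swaps: int = 10_000) -> ClusterResult:
    """BUILD + SWAP k-medoids on a precomputed dissimilarity matrix.

    BUILD greedily seeds ``k`` medoids (first: minimal total dissimilarity;
    then: maximal summed reduction of nearest-medoid distances).  SWAP
    repeatedly accepts the first (medoid, non-medoid) exchange that
    strictly decreases total cost, scanning in (medoid index, candidate
    index) order, until no improving exchange exists.  The total cost is
    non-increasing throughout and the result is deterministic.
    """
    item_ids = None
    if isinstance(d, pd.DataFrame):
        item_ids = list(d.index)
        d = d.to_numpy()
    d = _validate_dissimilarity(d)
    n = d.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        medoids = np.arange(n)
        return ClusterResult(k=k, medoid_indices=medoids,
                             labels=np.arange(n), cost=0.0, item_ids=item_ids)

    # ---- BUILD ----
    totals = d.sum(axis=1)
    first = int(np.argmin(totals))  # argmin takes the lowest index on ties
    medoids = [first]
    d1 = d[:, first].copy()
    while len(medoids) < k:
        gain = np.maximum(d1[:, None] - d, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        nxt = int(np.argmax(gain))
        medoids.append(nxt)
        d1 = np.minimum(d1, d[:, nxt])
    medoids = np.array(sorted(medoids))

    # ---- SWAP (first improvement, deterministic scan order) ----
    labels, d1, d2 = _assign(d, medoids)
    cost = float(d1.sum())
    for _ in range(max_swaps):
        improved = False
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        candidates = np.flatnonzero(~is_medoid)
        for mi in range(len(medoids)):
            # base distance after removing medoid mi, before adding anything
            owned = labels == mi
            base = np.where(owned, d2, d1)
            newd = np.minimum(base[:, None], d[:, candidates])
            deltas = newd.sum(axis=0) - cost
            better = np.flatnonzero(deltas < -_EPS)
            if better.size:
                h = candidates[better[0]]
                medoids = np.array(sorted(np.concatenate(
                    (np.delete(medoids, mi), [h]))))
                labels, d1, d2 = _assign(d, medoids)
                new_cost = float(d1.sum())
                assert new_cost < cost + _EPS
                cost = new_cost
                improved = True
                break
        if not improved:
            break
    return ClusterResult(k=k, medoid_indices=medoids, labels=labels,
                         cost=cost, item_ids=item_ids)


def silhouette(
    result: ClusterResult,
    d: np.ndarray | pd.DataFrame,
    variant: str = "classical",
) -> pd.DataFrame:
    """Per-item silhouette scores plus per-cluster summaries.

    ``classical``: s_i = (b_i − a_i) / max(a_i, b_i) with a_i the mean
    dissimilarity to the item's own cluster (excluding itself) and b_i the
    smallest mean dissimilarity to any other cluster; items in singleton
    clusters get s = 0.

    ``medoid``: a_i and b_i are replaced by the dissimilarity to the own
    and to the nearest other medoid.

    Returns a DataFrame with columns ``cluster`` and ``s``; summaries
    (mean s and negative fraction per cluster) are attached in
    ``result_frame.attrs["per_cluster"]``.
    """
    if isinstance(d, pd.DataFrame):
        d = d.to_numpy()
    d = _validate_dissimilarity(d)
    labels = result.labels
    k = result.k
    if k < 2:
        raise ValueError("silhouette undefined for k=1")
    n = d.shape[0]
    if variant == "classical":
        # mean distance of every item to every cluster
        sums = np.zeros((n, k))
        counts = np.zeros(k, dtype=np.int64)
        for c in range(k):
            mask = labels == c
            counts[c] = mask.sum()
            sums[:, c] = d[:, mask].sum(axis=1)
        own_count = counts[labels]
        a = np.where(own_count > 1,
                     sums[np.arange(n), labels] / np.maximum(own_count - 1, 1),
                     0.0)
        means = sums / counts[None, :]
        means[np.arange(n), labels] = np.inf
        b = means.min(axis=1)
        s = np.where(own_count > 1, (b - a) / np.maximum(a, b), 0.0)
        s = np.where(np.maximum(a, b) == 0, 0.0, s)
    elif variant == "medoid":
        dm = d[:, result.medoid_indices]
        a = dm[np.arange(n), labels]
        dm_other = dm.copy()
        dm_other[np.arange(n), labels] = np.inf
        b = dm_other.min(axis=1)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    else:
        raise ValueError(f"unknown silhouette variant {variant!r}")
    frame = pd.DataFrame({
        "cluster": labels, "s": s,
    }, index=result.item_ids if result.item_ids is not None else np.arange(n))
    per_cluster = frame.groupby("cluster")["s"].agg(
        mean_s="mean", neg_fraction=lambda x: float((x < 0).mean()), n="size"
    )
    frame.attrs["per_cluster"] = per_cluster
    frame.attrs["average_s"] = float(np.mean(s))
    return frame


def scan_k(
    d: np.ndarray | pd.DataFrame,
    k_range: range | list[int] = range(2, 31),
    variant: str = "classical",
    chosen_k: int | None = None,
) -> tuple[pd.DataFrame, int, dict[int, ClusterResult]]:
    """PAM over a range of k; chosen k maximizes the average silhouette.

    Returns ``(table, chosen_k, results)`` where the table has one row per
    k with the average silhouette and total cost.  ``chosen_k`` overrides
    the silhouette argmax (the study fixed a seven-subset grouping by
    inspection).  Ties go to the smallest k.
    """
    rows = []
    results: dict[int, ClusterResult] = {}
    for k in k_range:
        res = pam(d, k)
        sil = silhouette(res, d, variant=variant)
        rows.append({"k": k, "average_silhouette": sil.attrs["average_s"],
                     "cost": res.cost})
        results[k] = res
    table = pd.DataFrame(rows)
    if chosen_k is None:
        best = table.loc[table["average_silhouette"].idxmax(), "k"]
        chosen = int(best)
    else:
        chosen = int(chosen_k)
    return table, chosen, results


def normalize_for_heatmap(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene min-max scaling to [0, 1] for relative-abundance display.

    Constant profiles map to 0.5 everywhere (with a warning) — they carry
    no relative dynamics.
    """
    x = profiles.to_numpy(dtype=np.float64)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant profiles set to 0.5")
    span[flat] = 1.0
    out = (x - lo) / span
    out[flat] = 0.5
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)


def heatmap_gene_order(result: ClusterResult, d: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Display order: cluster blocks; medoid first, then increasing
    dissimilarity to the medoid (i.e. decreasing similarity)."""
    if isinstance(d, pd.DataFrame):
        d = d.to_numpy()
    order: list[int] = []
    for c in range(result.k):
        members = result.cluster_members(c)
        med = result.medoid_indices[c]
        dm = d[members, med]
        members = members[np.lexsort((members, dm))]
        members = np.concatenate(([med], members[members != med]))
        order.extend(members.tolist())
    return np.array(order)
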