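"""Sample-level structure: PCA trajectories, dendrograms, sham-vs-PH maps.

PCA runs on the gene-centered log2(RPKM + 1) matrix of detected genes (no
unit-variance scaling — amplitude carries the trajectory).  Sample
dendrograms use 1 − Pearson distance with average linkage.  The sham arm
is compared to the PH arm per matched hour by log2 ratio maps and by
Spearman correlation of pathway-gene profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PcaResult",
    "pca_samples",
    "hcluster_samples",
    "dendrogram_to_newick",
    "cophenetic_groups",
    "ph_sham_ratio",
    "spearman_arm_correlation",
]

PSEUDOCOUNT = 1.0


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # genes × components, orthonormal columns
    variance_ratio: np.ndarray

    def averaged_scores(self, design: pd.DataFrame) -> pd.DataFrame:
        """Replicate-averaged scores per (arm, hours) with per-condition sd
        — display convention only, computed after the SVD."""
        joined = self.scores.join(design[["arm", "hours"]])
        grouped = joined.groupby(["arm", "hours"])
        mean = grouped.mean()
        sd = grouped.std(ddof=0).add_suffix("_sd")
        return mean.join(sd)


def pca_samples(
    expr: pd.DataFrame,
    n_components: int | None = None,
    log_transform: bool = True,
    pseudocount: float = PSEUDOCOUNT,
) -> PcaResult:
    """SVD-based PCA of samples in gene space.

    ``expr``: genes × samples (RPKM unless ``log_transform`` is off).
    Genes are centered; variance proportions are sigma_i^2 / sum(sigma^2).
    """
    x = expr.to_numpy(dtype=np.float64)
    if log_transform:
        x = np.log2(x + pseudocount)
    n_samples = x.shape[1]
    if n_samples < 2:
        raise ValueError("need >=2 samples")
    max_comp = min(x.shape)
    if n_components is None:
        n_components = min(n_samples, max_comp)
    if n_components > max_comp:
        raise ValueError(f"cannot extract {n_components} components from shape {x.shape}")
    xc = x - x.mean(axis=1, keepdims=True)  # center each gene
    # samples are observations: SVD of the samples × genes matrix
    u, s, vt = np.linalg.svd(xc.T, full_matrices=False)
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(u[:, :n_components] * s[:n_components],
                          index=expr.columns, columns=comps)
    loadings = pd.DataFrame(vt[:n_components].T, index=expr.index, columns=comps)
    return PcaResult(scores=scores, loadings=loadings,
                     variance_ratio=ratio[:n_components])


def hcluster_samples(
    expr: pd.DataFrame,
    log_transform: bool = True,
    method: str = "average",
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples under 1 − Pearson distance.

    Returns the scipy linkage matrix and the sample id list (leaf ids).
    """
    x = expr.to_numpy(dtype=np.float64)
    if x.shape[1] < 2:
        raise ValueError("need >=2 samples")
    if log_transform:
        x = np.log2(x + pseudocount)
    xt = x.T  # samples × genes
    xc = xt - xt.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    norms[norms == 0] = 1.0
    xn = xc / norms[:, None]
    r = np.clip(xn @ xn.T, -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    link = hierarchy.linkage(squareform(d, checks=False), method=method)
    return link, list(expr.columns)


def dendrogram_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cophenetic_groups(link: np.ndarray, n_groups: int) -> np.ndarray:
    """Cut the dendrogram into ``n_groups`` flat clusters (labels per leaf)."""
    return hierarchy.fcluster(link, t=n_groups, criterion="maxclust")


def _arm_time_means(
    expr: pd.DataFrame, design: pd.DataFrame, arm: str, hour: float
) -> pd.Series | None:
    cols = design.index[(design["arm"] == arm) & (design["hours"] == hour)]
    if len(cols) == 0:
        return None
    return expr[cols].mean(axis=1)


def ph_sham_ratio(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    matched_hours: tuple[float, ...] = (1, 4, 10, 20, 48),
    pseudocount: float = PSEUDOCOUNT,
    mask_undetected: bool = True,
) -> pd.DataFrame:
    """Per-gene log2(PH/sham) of replicate-mean RPKM at matched hours.

    Genes whose log2 RPKM is below 0 in both arms at an hour are masked
    (NaN) — they are displayed as absent in the ratio map.
    """
    out = {}
    for h in matched_hours:
        ph = _arm_time_means(expr, design, "PH", h)
        sham = _arm_time_means(expr, design, "sham", h)
        if ph is None or sham is None:
            warnings.warn(f"hour {h}: arm missing, skipped")
            continue
        ratio = np.log2((ph + pseudocount) / (sham + pseudocount))
        if mask_undetected:
            low = (ph < 1.0) & (sham < 1.0)  # log2 RPKM below 0 in both arms
            ratio[low] = np.nan
        out[h] = ratio
    if not out:
        raise ValueError("no matched hours with both arms present")
    return pd.DataFrame(out)


def spearman_arm_correlation(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    gene_set: list[str],
    hour: float,
) -> float:
    """Spearman rho between the two arms' replicate-mean profiles over a
    gene set at one matched hour (average-rank tie handling)."""
    if len(gene_set) < 3:
        raise ValueError("gene set too small for a rank correlation")
    ph = _arm_time_means(expr, design, "PH", hour)
    sham = _arm_time_means(expr, design, "sham", hour)
    if ph is None or sham is None:
        raise ValueError(f"hour {hour}: both arms required")
    a = ph.loc[gene_set].to_numpy()
    b = sham.loc[gene_set].to_numpy()
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
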