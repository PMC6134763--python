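"""Transcript set classification and gene-set statistics.

Genes are partitioned into three sets: Set 1 — transcripts never detected;
Set 2 — detected but stable across the regeneration time course; Set 3 —
detected and changing.  "Changing" is a per-gene one-way F test across
time points on log2(RPKM + 1), Benjamini–Hochberg corrected, at the study
thresholds (adjusted p < 1e-7 and max |log2 fold-change vs. 0 h| > 0.5).

Also here: mapping a pathway gene list onto the sets/subsets with printed
integer percentages, and a hypergeometric over-representation statistic
standing in for a full GO analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "REFERENCE_SET_COUNTS",
    "check_count_consistency",
    "detect_genes",
    "classify_stable_changing",
    "map_to_pathway",
    "round_percent",
    "over_representation",
]

DEFAULT_ALPHA = 1e-7
DEFAULT_LFC = 0.5
PSEUDOCOUNT = 1.0  # RPKM-equivalent added before log2

#: Published reference counts for the mouse-liver regeneration transcript
#: universe (Ensembl 67/NCBI37 protein-coding + non-coding genes); used by
#: consistency checks, never by the classifier itself.
REFERENCE_SET_COUNTS = {"set1": 25_966, "set2": 6_528, "set3": 5_497}


def check_count_consistency(counts: dict[str, int]) -> dict[str, int]:
    """Conservation arithmetic on a set-size table.

    Returns derived totals: detected = set2 + set3, universe = all three.
    Raises if any count is negative.
    """
    for k in ("set1", "set2", "set3"):
        if counts[k] < 0:
            raise ValueError(f"negative count for {k}")
    detected = counts["set2"] + counts["set3"]
    return {"detected": detected, "universe": counts["set1"] + detected}


def detect_genes(
    expr: pd.DataFrame, min_log2_rpkm: float = 0.0, min_samples: int = 1
) -> pd.Series:
    """Detection flag: log2(RPKM) >= threshold in at least ``min_samples``.

    With the defaults a gene is detected iff RPKM >= 1 in any sample.
    """
    if expr.size == 0:
        raise ValueError("empty expression matrix")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    hits = (expr >= 2.0 ** min_log2_rpkm).sum(axis=1)
    return hits >= min_samples


def _f_test_over_time(
    log2x: np.ndarray, groups: list[np.ndarray]
) -> tuple[float, float]:
    """One-way F statistic across time-point groups for one gene.

    Implemented from the ANOVA decomposition so the test is explicit:
    F = (SSB/(g−1)) / (SSW/(N−g)), p from the F distribution.
    """
    means = [log2x[g].mean() for g in groups]
    sizes = [g.size for g in groups]
    grand = float(np.concatenate([log2x[g] for g in groups]).mean())
    ssb = sum(n * (m - grand) ** 2 for n, m in zip(sizes, means))
    ssw = sum(((log2x[g] - m) ** 2).sum() for g, m in zip(groups, means))
    df1 = len(groups) - 1
    df2 = sum(sizes) - len(groups)
    if df1 <= 0 or df2 <= 0:
        return np.nan, np.nan
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def classify_stable_changing(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    detected: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    arms: tuple[str, ...] = ("control", "PH"),
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Assign set1/set2/set3 labels over the gene universe.

    ``design`` is indexed by sample id with columns ``arm``, ``hours``,
    ``replicate``.  The F test runs across the time points of the chosen
    arms (resting 0 h controls plus the post-PH course by default); time
    points with fewer than 2 replicates are excluded with a warning.
    log2 fold-changes are taken against the 0 h mean.

    Returns a frame indexed by gene with columns ``label``, ``F``,
    ``p_raw``, ``p_adj``, ``max_abs_lfc``.
    """
    if detected is None:
        detected = detect_genes(expr)
    sub = design[design["arm"].isin(arms)]
    hours = sorted(sub["hours"].unique())
    groups_cols: list[list[str]] = []
    used_hours = []
    for h in hours:
        cols = list(sub.index[sub["hours"] == h])
        if len(cols) < 2:
            warnings.warn(f"time point {h} h has a single replicate; excluded from F test")
            continue
        groups_cols.append(cols)
        used_hours.append(h)
    if len(groups_cols) < 2:
        raise ValueError("need >=2 time points with >=2 replicates")
    if 0 not in used_hours and 0 not in hours:
        raise ValueError("0 h baseline required for fold-changes")

    log2x = np.log2(expr.to_numpy(dtype=np.float64) + pseudocount)
    col_pos = {c: i for i, c in enumerate(expr.columns)}
    groups = [np.array([col_pos[c] for c in cols]) for cols in groups_cols]

    # vectorized one-way ANOVA over all genes at once
    sizes = np.array([g.size for g in groups])
    gmeans = np.stack([log2x[:, g].mean(axis=1) for g in groups], axis=1)
    allcols = np.concatenate(groups)
    grand = log2x[:, allcols].mean(axis=1)
    ssb = (sizes[None, :] * (gmeans - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros(expr.shape[0])
    for g, m in zip(groups, gmeans.T):
        ssw += ((log2x[:, g] - m[:, None]) ** 2).sum(axis=1)
    df1 = len(groups) - 1
    df2 = int(sizes.sum()) - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)
    p_raw = stats.f.sf(F, df1, df2)
    p_raw = np.where(np.isinf(F), 0.0, p_raw)
    p_raw = np.where(F == 0, 1.0, p_raw)

    zero_cols = [col_pos[c] for c in design.index
                 if design.loc[c, "hours"] == 0 and design.loc[c, "arm"] in arms]
    base = log2x[:, zero_cols].mean(axis=1)
    lfc_by_time = np.stack(
        [log2x[:, g].mean(axis=1) - base for g in groups], axis=1
    )
    max_abs_lfc = np.abs(lfc_by_time).max(axis=1)

    det = detected.reindex(expr.index).to_numpy(dtype=bool)
    p_adj = np.full(expr.shape[0], np.nan)
    if det.any():
        _, adj, _, _ = multipletests(p_raw[det], method="fdr_bh")
        p_adj[det] = adj

    label = np.where(~det, "set1",
                     np.where((p_adj < alpha) & (max_abs_lfc > lfc), "set3", "set2"))
    out = pd.DataFrame({
        "label": label,
        "F": F,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "max_abs_lfc": max_abs_lfc,
    }, index=expr.index)
    out.loc[~det, ["F", "p_raw", "p_adj", "max_abs_lfc"]] = np.nan
    return out


def round_percent(count: int, total: int) -> int:
    """Percentage rounded to the nearest integer, ties away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    x = 100.0 * count / total
    return int(np.floor(x + 0.5))


def map_to_pathway(
    labels: pd.Series,
    pathway_genes: list[str],
    subcluster: pd.Series | None = None,
) -> pd.DataFrame:
    """Map a pathway gene list onto the sets (and optional subclusters).

    Returns one row per set/subset with ``count`` and integer ``percent``
    of the pathway size; unresolved ids are reported under ``unmapped``.
    """
    if not pathway_genes:
        raise ValueError("empty pathway list")
    total = len(pathway_genes)
    in_universe = [g for g in pathway_genes if g in labels.index]
    unmapped = total - len(in_universe)
    rows = []
    sub = labels.loc[in_universe]
    for s in ("set1", "set2", "set3"):
        cnt = int((sub == s).sum())
        rows.append({"group": s, "count": cnt, "percent": round_percent(cnt, total)})
    if subcluster is not None:
        member = subcluster.reindex(in_universe).dropna()
        for c in sorted(member.unique()):
            cnt = int((member == c).sum())
            rows.append({"group": f"subset_{c}", "count": cnt,
                         "percent": round_percent(cnt, total)})
    rows.append({"group": "unmapped", "count": unmapped,
                 "percent": round_percent(unmapped, total)})
    return pd.DataFrame(rows).set_index("group")


def over_representation(
    gene_set: set[str] | list[str],
    term_to_genes: dict[str, set[str] | list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a gene set.

    For each term: p = P(X >= k) with X ~ Hypergeom(N universe, K term
    genes, n set size).  BH-adjusted q values across terms.  Terms with no
    genes in the universe are skipped with a warning.
    """
    universe = set(universe)
    gene_set = set(gene_set) & universe
    n = len(gene_set)
    N = len(universe)
    rows = []
    for term, genes in term_to_genes.items():
        tg = set(genes) & universe
        K = len(tg)
        if K == 0:
            warnings.warn(f"term {term!r} has no genes in universe; skipped")
            continue
        k = len(tg & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q"]).set_index("term")
    out = pd.DataFrame(rows).set_index("term")
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    return out
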