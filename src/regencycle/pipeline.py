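"""End-to-end orchestration: simulate → classify → cluster → trajectory →
window quantification → exon-anchored analysis, with a machine-readable
summary.

Stages run in dependency order; each output file carries the run's config
hash and seed in the summary JSON.  Chromatin tracks are generated one at
a time and quantified immediately — a full (mark × time) tensor of
per-base tracks over a multi-megabase chromosome would not fit in memory.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anchor as _anchor
from . import annotation as _ann
from . import chip as _chip
from . import clustering as _clust
from . import sets as _sets
from . import simulate as _sim
from . import trajectory as _traj

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    sim: _sim.SimulationConfig = field(default_factory=_sim.SimulationConfig)
    outdir: str = "regencycle_run"
    alpha: float = _sets.DEFAULT_ALPHA
    lfc: float = _sets.DEFAULT_LFC
    detection_min_log2_rpkm: float = 0.0
    post_ph_quantile: float = 0.25
    post_ph_fold: float = 2.0
    epsilon: float = _chip.DEFAULT_EPSILON
    metric: str = "correlation"
    k_range: tuple[int, int] = (2, 10)
    chosen_k: int | None = None
    silhouette_variant: str = "classical"
    spike_normalize: bool = False
    zscore_axis: str = "row"
    chip_times: tuple[float, ...] = (0, 4, 36, 60)
    anchor_time: float = 60.0
    matched_hours: tuple[float, ...] = (1, 4, 10, 20, 48)
    max_cluster_genes: int = 3000  # PAM is O(n^2); subsample above this
    write_tracks: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = _sim.SimulationConfig(**raw.pop("sim", {}))
        for key in ("k_range", "chip_times", "matched_hours"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        # analysis parameters only — where the run is written does not
        # change what it computes
        payload = {k: (v.__dict__ if isinstance(v, _sim.SimulationConfig) else v)
                   for k, v in self.__dict__.items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data; write outputs + summary.

    Returns the summary dict (also written to ``summary.json``).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.sim.seed}

    # ---- simulate ----
    tus, chrom_len = _sim.simulate_annotation(cfg.sim)
    expr, design, truth = _sim.simulate_expression(cfg.sim, tus)
    tu_truth = _sim.tu_truth_frame(cfg.sim, tus, truth)
    _ann.write_bed12(tus, str(out / "annotation.bed12"))
    _ann.write_gtf(tus, str(out / "annotation.gtf"))
    expr.to_csv(out / "expression.tsv", sep="\t")
    design.to_csv(out / "design.tsv", sep="\t")
    truth.to_csv(out / "truth_genes.tsv", sep="\t")
    tu_truth.to_csv(out / "truth_tus.tsv", sep="\t")
    summary["n_genes"] = int(cfg.sim.n_genes)
    summary["chrom_length"] = int(chrom_len)

    # ---- transcript sets ----
    detected = _sets.detect_genes(expr, cfg.detection_min_log2_rpkm)
    labels = _sets.classify_stable_changing(
        expr, design, detected=detected, alpha=cfg.alpha, lfc=cfg.lfc)
    labels.to_csv(out / "set_labels.tsv", sep="\t")
    set_sizes = labels["label"].value_counts().to_dict()
    summary["set_sizes"] = {k: int(v) for k, v in sorted(set_sizes.items())}

    # ---- clustering of the changing set ----
    ph_cols = design.index[design["arm"].isin(("control", "PH"))]
    ph_design = design.loc[ph_cols]
    set3 = labels.index[labels["label"] == "set3"]
    summary["clustering"] = None
    cluster_assign = None
    if len(set3) >= 10:
        prof = _mean_log2_profiles(expr.loc[set3, ph_cols], ph_design)
        if len(set3) > cfg.max_cluster_genes:
            rng = np.random.default_rng(cfg.sim.seed + 11)
            keep = rng.choice(len(prof), cfg.max_cluster_genes, replace=False)
            prof = prof.iloc[np.sort(keep)]
        d = _clust.profile_dissimilarity(prof, metric=cfg.metric)
        kmax = min(cfg.k_range[1], len(prof) - 1)
        table, chosen, results = _clust.scan_k(
            d, range(cfg.k_range[0], kmax + 1),
            variant=cfg.silhouette_variant, chosen_k=cfg.chosen_k)
        table.to_csv(out / "k_scan.tsv", sep="\t", index=False)
        res = results[chosen]
        sil = _clust.silhouette(res, d, variant=cfg.silhouette_variant)
        assign = pd.DataFrame({"cluster": res.labels, "silhouette": sil["s"]},
                              index=prof.index)
        assign.to_csv(out / "cluster_assignments.tsv", sep="\t")
        heat = _clust.normalize_for_heatmap(prof)
        order = _clust.heatmap_gene_order(res, d)
        heat.iloc[order].to_csv(out / "heatmap_matrix.tsv", sep="\t")
        per_cluster = sil.attrs["per_cluster"]
        summary["clustering"] = {
            "chosen_k": int(chosen),
            "average_silhouette": float(sil.attrs["average_s"]),
            "per_cluster_mean_s": {int(c): float(v)
                                   for c, v in per_cluster["mean_s"].items()},
            "medoids": [str(m) for m in res.medoid_ids],
        }
        cluster_assign = assign["cluster"]

    # ---- trajectory ----
    det_expr = expr.loc[detected]
    pca = _traj.pca_samples(det_expr)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    link, leaves = _traj.hcluster_samples(det_expr)
    (out / "samples.nwk").write_text(_traj.dendrogram_to_newick(link, leaves))
    ratios = _traj.ph_sham_ratio(expr, design, cfg.matched_hours)
    ratios.to_csv(out / "ph_sham_ratio.tsv", sep="\t")
    summary["pca_variance_ratio"] = [float(v) for v in pca.variance_ratio[:5]]

    # ---- chromatin quantification (streamed per track) ----
    rep_tus = {tu.gene_id: tu for tu in tus}
    marks = ("polII", "h3k4me3", "h3k36me3", "input")
    win_rows = []
    anchor_tracks = {}
    for mark in marks + ("h3k36me2",):
        times = cfg.chip_times if mark != "h3k36me2" else (cfg.anchor_time,)
        for t in times:
            track = _sim.simulate_track(cfg.sim, tus, truth, tu_truth,
                                        chrom_len, mark, t)
            if cfg.spike_normalize and mark != "input":
                track = track.scaled(_chip.spike_in_factor(track))
            if cfg.write_tracks:
                _chip.write_bedgraph(track, str(out / f"{mark}_{_sim._fmt_hour(t)}h.bedGraph"))
            if mark in ("h3k36me2", "h3k36me3") and t == cfg.anchor_time:
                anchor_tracks[mark] = track
            if mark == "h3k36me2":
                continue
            for tu in rep_tus.values():
                if truth.loc[tu.gene_id, "gene_class"] == "undetected":
                    continue
                if tu.length <= 500:  # body window undefined
                    continue
                prom = _ann.promoter_window(tu, 250, chrom_len)
                k4 = _ann.promoter_window(tu, 500, chrom_len)
                body = _ann.body_window(tu, chrom_length=chrom_len)
                win = {"polII": prom, "h3k4me3": k4, "h3k36me3": body,
                       "input": body}[mark]
                win_rows.append({
                    "gene_id": tu.gene_id, "mark": mark, "time": t,
                    "window": win.anchor_label,
                    "density": _chip.quantify_window(track, win),
                })
                if mark == "polII":
                    win_rows.append({
                        "gene_id": tu.gene_id, "mark": mark, "time": t,
                        "window": "body",
                        "density": _chip.quantify_window(track, body),
                    })
            del track
    win_table = pd.DataFrame(win_rows)
    win_table.to_csv(out / "mark_signal.tsv", sep="\t", index=False)

    ppg = _chip.post_ph_genes(expr, design, detected,
                              cfg.post_ph_quantile, cfg.post_ph_fold)
    pd.Series(ppg, name="gene_id").to_csv(out / "post_ph_genes.tsv",
                                          sep="\t", index=False)
    summary["n_post_ph_genes"] = int(len(ppg))

    # ---- exon-anchored me2/me3 analysis ----
    summary["exon_anchor"] = None
    if "h3k36me3" in anchor_tracks and "h3k36me2" in anchor_tracks:
        eligible, excl = _anchor.eligible_tus(tus, labels["label"])
        if len(eligible) >= 4:
            me3 = anchor_tracks["h3k36me3"]
            me2 = anchor_tracks["h3k36me2"]
            scores = pd.Series(
                {tu.tu_id: _anchor.first_exon_me3_score(tu, me3) for tu in eligible})
            upper_ids, lower_ids = _anchor.median_split(scores)
            by_id = {tu.tu_id: tu for tu in eligible}
            upper = [by_id[t] for t in upper_ids]
            lower = [by_id[t] for t in lower_ids]
            m_up_me2 = _anchor.build_anchored_matrix(upper, me2)
            m_lo_me2 = _anchor.build_anchored_matrix(lower, me2)
            m_up_me3 = _anchor.build_anchored_matrix(upper, me3)
            contrast = _anchor.me2_depletion_contrast(m_up_me2, m_lo_me2)
            m_up_me3.zscored(cfg.zscore_axis).to_frame().to_csv(
                out / "anchored_me3_upper_z.tsv", sep="\t")
            summary["exon_anchor"] = {
                "n_eligible": len(eligible),
                "excluded": excl,
                "upper": int(len(upper_ids)),
                "lower": int(len(lower_ids)),
                "me2_contrast": {k: (None if not np.isfinite(v) else float(v))
                                 for k, v in contrast.items()},
            }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _mean_log2_profiles(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean log2(RPKM+1) profiles over the design's time points."""
    log2x = np.log2(expr + 1.0)
    hours = sorted(design["hours"].unique())
    cols = {}
    for h in hours:
        ids = design.index[design["hours"] == h]
        cols[h] = log2x[ids].mean(axis=1)
    return pd.DataFrame(cols)
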