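"""Synthetic liver-regeneration data with planted ground truth.

The generator emulates the statistical structure the downstream stages
assume, on one synthetic chromosome:

* an annotation of non-overlapping stranded TUs with a controllable
  mixture of 1-, 2- and >=3-exon gene models;
* a triplicate RPKM expression matrix over the post-PH time grid
  (0, 1, 4, 10, 20, 28, 36, 44, 48, 60, 72 h, 1 w, 4 w) and the post-sham
  grid (1, 4, 10, 20, 48 h), with planted gene classes — undetected,
  stable, and changing along seven temporal archetypes (three decreasing,
  four increasing, the last a 36–72 h proliferation wave that is PH-only;
  early archetypes with extrema at or before 20 h are shared by the sham
  arm) — plus circadian genes oscillating with a 24 h Zeitgeber-phased
  sinusoid identical in both arms;
* per-base density tracks for Pol II, H3K4me3, H3K36me2, H3K36me3 and
  input, with promoter Pol II recruitment preceding gene-body elongation
  on induced genes, H3K4me3 pre-marking from 0 h, an H3K36me2 platform
  over transcribed bodies, H3K36me3 onset at the 5' end of the first
  internal exon (with me2 depleted downstream on me3-dominant TUs and
  retained on mixed TUs), and an acute-response class carrying Pol II and
  me2 but neither H3K4me3 nor H3K36me3.

Everything is driven by one seeded generator; a given config + seed is
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotation import TranscriptionUnit, first_internal_exon

__all__ = [
    "SimulationConfig",
    "ARCHETYPE_KNOTS",
    "SHARED_ARCHETYPES",
    "archetype_curve",
    "simulate_annotation",
    "simulate_expression",
    "simulate_chip",
    "simulate_track",
    "tu_truth_frame",
    "CHIP_MARKS",
]

PH_GRID = (0, 1, 4, 10, 20, 28, 36, 44, 48, 60, 72, 168, 672)
SHAM_GRID = (1, 4, 10, 20, 48)
CHIP_MARKS = ("polII", "h3k4me3", "h3k36me2", "h3k36me3", "input")
SURGERY_ZT = 2.0  # surgery performed at Zeitgeber Time 2

# Piecewise-linear log2-offset templates (unit amplitude) on the hour axis.
# 1-3 decrease (extrema at 10, 36, 72 h), 4-7 increase (peaks 4, 20, 28 h
# and the 36-72 h proliferation wave).
ARCHETYPE_KNOTS: dict[int, list[tuple[float, float]]] = {
    1: [(0, 0), (4, -0.6), (10, -1), (28, -0.6), (48, 0), (672, 0)],
    2: [(0, 0), (10, -0.3), (20, -0.7), (36, -1), (60, -0.7), (168, 0), (672, 0)],
    3: [(0, 0), (20, -0.3), (48, -0.8), (72, -1), (168, -0.5), (672, 0)],
    4: [(0, 0), (1, 0.5), (4, 1), (10, 0.5), (20, 0), (672, 0)],
    5: [(0, 0), (4, 0.2), (10, 0.7), (20, 1), (28, 0.5), (48, 0), (672, 0)],
    6: [(0, 0), (10, 0), (20, 0.5), (28, 1), (44, 0.4), (60, 0), (672, 0)],
    7: [(0, 0), (20, 0), (28, 0.2), (36, 0.8), (44, 1), (48, 1), (60, 0.7),
        (72, 0.3), (168, 0), (672, 0)],
}
#: archetypes whose extremum falls at or before 20 h: the surgery response
#: shared by the sham arm
SHARED_ARCHETYPES = frozenset({1, 4, 5})
PROLIFERATION_ARCHETYPE = 7

_U = 37_991  # reference universe size used for the default class mix


def _default_class_fractions() -> dict[str, float]:
    # published proportions: 25,966 undetected / 6,528 stable / 5,497
    # changing, the latter split with 1,036 in the proliferation subset and
    # the remainder spread over the other six archetypes
    frac = {"undetected": 25_966 / _U, "stable": 6_528 / _U}
    rest = (5_497 - 1_036) / 6
    for a in range(1, 7):
        frac[f"changing_{a}"] = rest / _U
    frac["changing_7"] = 1_036 / _U
    return frac


@dataclass
class SimulationConfig:
    """The stated world of the simulator.

    Noise defaults reflect the study's tight triplicates (within-series
    Pearson >= 0.98): sigma = 0.2 on the log2 scale.  Archetype amplitude
    defaults to 2 log2 units.
    """

    n_genes: int = 2000
    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    time_grid_ph: tuple[float, ...] = PH_GRID
    time_grid_sham: tuple[float, ...] = SHAM_GRID
    n_replicates: int = 3
    noise_sd: float = 0.2
    archetype_amplitude: float = 2.0
    circadian_fraction: float = 0.05
    circadian_amplitude: float = 1.5
    baseline_log2_mean: float = 3.5
    baseline_log2_sd: float = 1.0
    post_ph_fraction: float = 0.3  # of increasing-archetype genes, planted low at 0 h
    saa_fraction: float = 0.25  # of early-acute (archetype 4) genes: Pol II + me2, no K4/K36me3
    seed: int = 0
    exon_count_range: tuple[int, int] = (1, 9)
    exon_len_range: tuple[int, int] = (80, 500)
    intron_len_range: tuple[int, int] = (2000, 6000)
    long_internal_exon_fraction: float = 0.001  # internal exon forced > 2 kb
    intergenic_gap: int = 6000
    me3_dominant_fraction: float = 0.5
    spike_in_fraction: float = 0.05
    chip_depth: float = 20.0  # expected counts per base at unit density
    chip_background: float = 0.05

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        for name, p in self.class_fractions.items():
            if not 0 <= p <= 1:
                raise ValueError(f"fraction {name}={p} outside [0,1]")
        for grid, zero_ok in ((self.time_grid_ph, True), (self.time_grid_sham, False)):
            if list(grid) != sorted(set(grid)):
                raise ValueError("time grids must be strictly increasing")
            if not zero_ok and 0 in grid:
                raise ValueError("0 h belongs to the PH/control grid only")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.exon_count_range[0] < 1 or self.exon_count_range[0] > self.exon_count_range[1]:
            raise ValueError("exon_count_range must satisfy 1 <= min <= max")
        for r in (self.exon_len_range, self.intron_len_range):
            if r[0] < 1 or r[0] > r[1]:
                raise ValueError("length ranges must satisfy 1 <= min <= max")
        for p in (self.circadian_fraction, self.me3_dominant_fraction,
                  self.spike_in_fraction, self.long_internal_exon_fraction,
                  self.post_ph_fraction, self.saa_fraction):
            if not 0 <= p <= 1:
                raise ValueError("proportions must lie in [0,1]")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("time_grid_ph", "time_grid_sham", "exon_count_range",
                    "exon_len_range", "intron_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def archetype_curve(archetype: int, hours, amplitude: float = 1.0) -> np.ndarray:
    """Piecewise-linear log2 offset of an archetype at the given hours."""
    xs, ys = zip(*ARCHETYPE_KNOTS[archetype])
    return amplitude * np.interp(np.asarray(hours, dtype=float), xs, ys)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    cfg: SimulationConfig, chrom: str = "chrS", chrom_length: int | None = None
) -> tuple[list[TranscriptionUnit], int]:
    """Place ``n_genes`` non-overlapping TUs on one chromosome.

    Returns the TU list (one TU per gene) and the chromosome length.  If a
    ``chrom_length`` is imposed and the TUs do not fit, the error names the
    required length.
    """
    rng = np.random.default_rng(cfg.seed)
    tus: list[TranscriptionUnit] = []
    cursor = cfg.intergenic_gap
    for i in range(cfg.n_genes):
        gene_id = f"g{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        ex_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1,
                               size=n_ex).tolist()
        if n_ex >= 3 and rng.random() < cfg.long_internal_exon_fraction:
            ex_lens[1] = int(rng.integers(2100, 3000))
        in_lens = rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1,
                               size=max(n_ex - 1, 0)).tolist()
        blocks = []
        pos = cursor
        for j, el in enumerate(ex_lens):
            blocks.append((pos, pos + el))
            pos += el
            if j < len(in_lens):
                pos += in_lens[j]
        cursor = pos + cfg.intergenic_gap
        order = tuple(blocks) if strand == "+" else tuple(blocks[::-1])
        tus.append(TranscriptionUnit(
            tu_id=f"{gene_id}.t1", gene_id=gene_id, chrom=chrom,
            strand=strand, exons=order,
        ))
    needed = cursor
    if chrom_length is not None and needed > chrom_length:
        raise ValueError(
            f"placement overflow: {cfg.n_genes} TUs need a chromosome of "
            f"{needed} bp, got {chrom_length}"
        )
    return tus, (chrom_length if chrom_length is not None else needed)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _design_frame(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for h in cfg.time_grid_ph:
        arm = "control" if h == 0 else "PH"
        prefix = "C" if h == 0 else "X"
        for r in range(1, cfg.n_replicates + 1):
            rows.append({"sample": f"{prefix}{_fmt_hour(h)}_r{r}", "arm": arm,
                         "hours": float(h), "replicate": r})
    for h in cfg.time_grid_sham:
        for r in range(1, cfg.n_replicates + 1):
            rows.append({"sample": f"S{_fmt_hour(h)}_r{r}", "arm": "sham",
                         "hours": float(h), "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def _fmt_hour(h: float) -> str:
    return str(int(h)) if float(h).is_integer() else str(h)


def simulate_expression(
    cfg: SimulationConfig, tus: list[TranscriptionUnit]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix + design + per-gene ground truth.

    Returns ``(expr, design, truth)``: ``expr`` is genes × samples RPKM;
    ``truth`` carries ``gene_class``, ``archetype_id`` (0 when not
    changing), ``is_circadian``, ``is_post_ph``, ``baseline_log2``,
    ``circadian_phase``.
    """
    if len(tus) != cfg.n_genes:
        raise ValueError("annotation gene count must match cfg.n_genes")
    if cfg.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = [tu.gene_id for tu in tus]
    classes = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes])
    gene_class = rng.choice(classes, size=cfg.n_genes, p=probs / probs.sum())
    archetype = np.array([int(c.rsplit("_", 1)[1]) if c.startswith("changing") else 0
                          for c in gene_class])
    is_circ = (gene_class == "stable") & (rng.random(cfg.n_genes) < cfg.circadian_fraction)
    circ_phase = rng.uniform(0, 24, cfg.n_genes)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    increasing = np.isin(archetype, (4, 5, 6, 7))
    is_post_ph = increasing & (rng.random(cfg.n_genes) < cfg.post_ph_fraction)
    # planted dormant-then-activated genes sit well below the resting-liver
    # low quantile; other induced genes are kept above it so the truth
    # channel is unambiguous
    baseline[is_post_ph] = rng.normal(0.5, 0.3, int(is_post_ph.sum()))
    ambiguous = increasing & ~is_post_ph
    low_cut = cfg.baseline_log2_mean - 0.6 * cfg.baseline_log2_sd
    baseline[ambiguous] = np.maximum(baseline[ambiguous], low_cut)

    design = _design_frame(cfg)
    n_samples = len(design)
    log2_mean = np.tile(baseline[:, None], (1, n_samples))
    hours = design["hours"].to_numpy()
    arms = design["arm"].to_numpy()

    for a in range(1, 8):
        sel = archetype == a
        if not sel.any():
            continue
        curve_ph = archetype_curve(a, hours, cfg.archetype_amplitude)
        if a in SHARED_ARCHETYPES:
            curve = curve_ph  # same response in every arm
        else:
            curve = np.where(arms == "sham", 0.0, curve_ph)
        log2_mean[sel] += curve[None, :]

    if is_circ.any():
        zt = (SURGERY_ZT + hours) % 24.0
        phase = circ_phase[is_circ][:, None]
        osc = cfg.circadian_amplitude * np.cos(2 * np.pi * (zt[None, :] - phase) / 24.0)
        log2_mean[is_circ] += osc

    noise = rng.normal(0.0, cfg.noise_sd, log2_mean.shape) if cfg.noise_sd > 0 else 0.0
    rpkm = 2.0 ** (log2_mean + noise)
    rpkm[gene_class == "undetected"] = 0.0

    expr = pd.DataFrame(rpkm, index=genes, columns=design.index)
    truth = pd.DataFrame({
        "gene_class": gene_class,
        "archetype_id": archetype,
        "is_circadian": is_circ,
        "is_post_ph": is_post_ph,
        "baseline_log2": baseline,
        "circadian_phase": circ_phase,
    }, index=genes)
    return expr, design, truth


# ---------------------------------------------------------------------------
# chromatin tracks
# ---------------------------------------------------------------------------

# occupancy templates (unit scale) for planted dormant-then-activated genes:
# promoter Pol II fires in an early 4-20 h wave and again at 28-44 h, body
# Pol II / H3K36me3 only with the second wave
_POSTPH_PROMOTER_KNOTS = [(0, 0.1), (4, 0.6), (10, 1.0), (20, 0.5), (28, 0.9),
                          (36, 1.0), (44, 1.0), (48, 0.8), (60, 0.5), (72, 0.3),
                          (168, 0.1), (672, 0.1)]
_POSTPH_BODY_KNOTS = [(0, 0.05), (20, 0.05), (28, 0.1), (36, 0.6), (44, 1.0),
                      (48, 1.0), (60, 0.7), (72, 0.4), (168, 0.1), (672, 0.05)]
POSTPH_PROMOTER_ONSET_H = 4.0  # planted promoter-recruitment onset
POSTPH_BODY_ONSET_H = 36.0  # planted elongation / H3K36me3 onset

_AMPLITUDE = {"polII_promoter": 3.0, "polII_body": 1.0, "h3k4me3": 3.0,
              "h3k36me2": 1.5, "h3k36me3": 1.5, "input": 1.0}


def _interp(knots, h: float) -> float:
    xs, ys = zip(*knots)
    return float(np.interp(h, xs, ys))


def tu_truth_frame(
    cfg: SimulationConfig, tus: list[TranscriptionUnit], truth: pd.DataFrame
) -> pd.DataFrame:
    """Per-TU chromatin ground truth (me2/me3 class, planted transition
    coordinate, acute-response flag, planted onset hours)."""
    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for tu in tus:
        g = truth.loc[tu.gene_id]
        detected = g["gene_class"] != "undetected"
        ex = first_internal_exon(tu)
        if ex is not None:
            s, e = ex
            transition = s if tu.strand == "+" else e - 1  # 5' end, genomic
        else:
            transition = -1
        me3_class = "dominant" if rng.random() < cfg.me3_dominant_fraction else "mixed"
        is_saa = bool(detected and g["archetype_id"] == 4
                      and rng.random() < cfg.saa_fraction)
        rows.append({
            "tu_id": tu.tu_id, "gene_id": tu.gene_id,
            "tu_me3_class": me3_class if detected else "silent",
            "transition_bp": transition,
            "is_saa": is_saa,
            "onset_promoter_h": POSTPH_PROMOTER_ONSET_H if g["is_post_ph"] else np.nan,
            "onset_body_h": POSTPH_BODY_ONSET_H if g["is_post_ph"] else np.nan,
        })
    return pd.DataFrame(rows).set_index("tu_id")


def simulate_track(
    cfg: SimulationConfig,
    tus: list[TranscriptionUnit],
    truth: pd.DataFrame,
    tu_truth: pd.DataFrame,
    chrom_length: int,
    mark: str,
    time: float,
    noise: bool = True,
):
    """One (mark, time) coverage track with planted chromatin structure.

    ``noise=False`` emits the exact expected densities (useful for forced
    examples); otherwise per-base counts are Poisson at ``cfg.chip_depth``
    expected counts per unit density.  The track is seeded per
    (mark, time), so generation order never changes the output.
    """
    from .chip import CoverageTrack  # local import to avoid cycle at import time

    if mark not in CHIP_MARKS:
        raise ValueError(f"unknown mark: {mark!r}")
    rng = np.random.default_rng(
        [cfg.seed, 3, CHIP_MARKS.index(mark), int(round(float(time) * 100))]
    )
    lam = np.full(chrom_length, cfg.chip_background, dtype=np.float64)
    if mark == "input":
        lam[:] = _AMPLITUDE["input"]
    else:
        _add_signal(lam, cfg, tus, truth, tu_truth, mark, float(time))
    if noise:
        values = rng.poisson(lam * cfg.chip_depth).astype(np.float64) / cfg.chip_depth
    else:
        values = lam
    n_frag = max(int(round(values.sum() / 50.0)), 1)
    if cfg.spike_in_fraction > 0:
        mix_total = max(int(n_frag / (1 - cfg.spike_in_fraction)), 1)
        spike = max(int(rng.binomial(mix_total, cfg.spike_in_fraction)), 1)
    else:
        spike = 0
    return CoverageTrack(
        chrom=tus[0].chrom if tus else "chrS", values=values,
        mark=mark, time=float(time), n_fragments=n_frag,
        spike_fragments=spike,
    )


def simulate_chip(
    cfg: SimulationConfig,
    tus: list[TranscriptionUnit],
    truth: pd.DataFrame,
    tu_truth: pd.DataFrame,
    chrom_length: int,
    marks: tuple[str, ...] = CHIP_MARKS,
    times: tuple[float, ...] = (0, 4, 10, 20, 28, 36, 44, 48, 60, 72),
    noise: bool = True,
):
    """Coverage tracks for every requested (mark, time) pair.

    Returns ``{(mark, time): CoverageTrack}``; see :func:`simulate_track`.
    """
    bad = set(marks) - set(CHIP_MARKS)
    if bad:
        raise ValueError(f"unknown marks: {sorted(bad)}")
    return {
        (mark, float(t)): simulate_track(cfg, tus, truth, tu_truth,
                                         chrom_length, mark, t, noise=noise)
        for mark in marks
        for t in times
    }


def _activity(cfg, g: pd.Series, t: float) -> tuple[float, float]:
    """(promoter, body) occupancy in [0,1] for one gene at hour t."""
    if g["gene_class"] == "undetected":
        return 0.0, 0.0
    if g["is_post_ph"]:
        return _interp(_POSTPH_PROMOTER_KNOTS, t), _interp(_POSTPH_BODY_KNOTS, t)
    if g["archetype_id"] > 0:
        off = archetype_curve(int(g["archetype_id"]), [t], 1.0)[0]
        rel = 2.0 ** (cfg.archetype_amplitude * off)
        if g["archetype_id"] in (4, 5, 6, 7):
            rel /= 2.0 ** cfg.archetype_amplitude  # peak-normalized induction
        act = float(np.clip(rel, 0.0, 1.0))
        return act, act
    return 0.7, 0.7  # stable


def _add_signal(lam, cfg, tus, truth, tu_truth, mark, t: float) -> None:
    L = lam.size
    for tu in tus:
        g = truth.loc[tu.gene_id]
        if g["gene_class"] == "undetected":
            continue
        tt = tu_truth.loc[tu.tu_id]
        prom_act, body_act = _activity(cfg, g, t)
        gs, ge = tu.start, tu.end
        if mark == "polII":
            p0, p1 = max(tu.tss - 250, 0), min(tu.tss + 250, L)
            lam[p0:p1] += _AMPLITUDE["polII_promoter"] * prom_act
            lam[gs:ge] += _AMPLITUDE["polII_body"] * body_act
        elif mark == "h3k4me3":
            if tt["is_saa"]:
                continue
            p0, p1 = max(tu.tss - 500, 0), min(tu.tss + 500, L)
            lam[p0:p1] += _AMPLITUDE["h3k4me3"]  # pre-marking: time-constant
        elif mark == "h3k36me2":
            level = _AMPLITUDE["h3k36me2"]
            tb = int(tt["transition_bp"])
            if tb >= 0 and tt["tu_me3_class"] == "dominant":
                # depleted downstream of the me3 transition
                if tu.strand == "+":
                    lam[gs:tb] += level
                    lam[tb:ge] += 0.3 * level
                else:
                    lam[tb + 1:ge] += level
                    lam[gs:tb + 1] += 0.3 * level
            else:
                lam[gs:ge] += level
        elif mark == "h3k36me3":
            if tt["is_saa"]:
                continue
            tb = int(tt["transition_bp"])
            level = _AMPLITUDE["h3k36me3"] * body_act
            if tt["tu_me3_class"] == "mixed":
                level *= 0.6
            if tb >= 0:
                if tu.strand == "+":
                    lam[tb:ge] += level
                else:
                    lam[gs:tb + 1] += level
            else:
                mid = (gs + ge) // 2
                lam[mid:ge] += level
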