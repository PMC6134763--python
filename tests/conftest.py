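import numpy as np
import pandas as pd
import pytest

from regencycle.annotation import TranscriptionUnit
from regencycle.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_chip,
    simulate_expression,
    tu_truth_frame,
)


@pytest.fixture(scope="session")
def small_world():
    """A small fully-transcribed cohort with chromatin tracks at 60 h."""
    cfg = SimulationConfig(
        n_genes=40,
        class_fractions={"stable": 1.0},
        circadian_fraction=0.0,
        exon_count_range=(3, 5),
        seed=11,
    )
    tus, chrom_len = simulate_annotation(cfg)
    expr, design, truth = simulate_expression(cfg, tus)
    tu_truth = tu_truth_frame(cfg, tus, truth)
    tracks = simulate_chip(cfg, tus, truth, tu_truth, chrom_len,
                           marks=("h3k36me2", "h3k36me3", "input"),
                           times=(60,))
    return dict(cfg=cfg, tus=tus, chrom_len=chrom_len, expr=expr,
                design=design, truth=truth, tu_truth=tu_truth, tracks=tracks)


@pytest.fixture(scope="session")
def mixed_classes_world():
    """Default class mix, moderate size, expression only."""
    cfg = SimulationConfig(n_genes=600, seed=5)
    tus, chrom_len = simulate_annotation(cfg)
    expr, design, truth = simulate_expression(cfg, tus)
    return dict(cfg=cfg, tus=tus, chrom_len=chrom_len, expr=expr,
                design=design, truth=truth)


def make_tu(tu_id="t1", gene_id="g1", strand="+", exons=((100, 200), (300, 400), (500, 700)),
            chrom="chrS"):
    blocks = sorted(exons)
    if strand == "-":
        blocks = blocks[::-1]
    return TranscriptionUnit(tu_id=tu_id, gene_id=gene_id, chrom=chrom,
                             strand=strand, exons=tuple(blocks))


@pytest.fixture
def plus_tu():
    return make_tu()


@pytest.fixture
def minus_tu():
    return make_tu(strand="-")
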