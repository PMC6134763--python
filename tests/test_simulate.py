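"""The synthetic-data generator: determinism, planted structure, truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regencycle.annotation import first_internal_exon, write_gtf
from regencycle.simulate import (
    ARCHETYPE_KNOTS,
    SHARED_ARCHETYPES,
    SimulationConfig,
    archetype_curve,
    simulate_annotation,
    simulate_chip,
    simulate_expression,
    simulate_track,
    tu_truth_frame,
)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_fractions={"stable": 0.4, "undetected": 0.4})

    def test_zero_only_in_ph_grid(self):
        with pytest.raises(ValueError, match="PH"):
            SimulationConfig(time_grid_sham=(0, 4, 10))

    def test_grids_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            SimulationConfig(time_grid_ph=(0, 4, 4, 10))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SimulationConfig(noise_sd=-0.1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_genes=17, seed=42, noise_sd=0.3)
        p = tmp_path / "c.yaml"
        cfg.to_yaml(str(p))
        assert SimulationConfig.from_yaml(str(p)) == cfg


class TestAnnotationGeneration:
    def test_forced_three_exons_all_have_internal(self):
        cfg = SimulationConfig(n_genes=10, exon_count_range=(3, 3), seed=0)
        tus, _ = simulate_annotation(cfg)
        assert len(tus) == 10
        assert all(first_internal_exon(tu) is not None for tu in tus)

    def test_single_exon_genes_have_no_internal(self):
        cfg = SimulationConfig(n_genes=10, exon_count_range=(1, 1), seed=0)
        tus, _ = simulate_annotation(cfg)
        assert all(first_internal_exon(tu) is None for tu in tus)

    def test_seeded_gtf_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_genes=25, seed=7)
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        for p in (p1, p2):
            tus, _ = simulate_annotation(cfg)
            write_gtf(tus, str(p))
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_overlaps_and_flanks(self):
        cfg = SimulationConfig(n_genes=50, seed=1)
        tus, chrom_len = simulate_annotation(cfg)
        spans = sorted((tu.start, tu.end) for tu in tus)
        assert spans[0][0] >= cfg.intergenic_gap
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 >= cfg.intergenic_gap
        assert spans[-1][1] + cfg.intergenic_gap <= chrom_len

    def test_placement_overflow_names_required_length(self):
        cfg = SimulationConfig(n_genes=50, seed=1)
        with pytest.raises(ValueError, match="placement overflow"):
            simulate_annotation(cfg, chrom_length=10_000)

    def test_long_internal_exon_fraction_planted(self):
        cfg = SimulationConfig(n_genes=400, exon_count_range=(3, 3),
                               long_internal_exon_fraction=0.2, seed=2)
        tus, _ = simulate_annotation(cfg)
        lens = np.array([first_internal_exon(tu)[1] - first_internal_exon(tu)[0]
                         for tu in tus])
        frac = (lens > 2000).mean()
        assert 0.1 < frac < 0.3


class TestExpressionGeneration:
    def test_zero_noise_stable_gene_constant(self):
        cfg = SimulationConfig(n_genes=100, noise_sd=0.0, circadian_fraction=0.0,
                               seed=3)
        tus, _ = simulate_annotation(cfg)
        expr, design, truth = simulate_expression(cfg, tus)
        stable = truth.index[truth["gene_class"] == "stable"]
        assert len(stable) > 0
        sub = expr.loc[stable]
        assert (sub.nunique(axis=1) == 1).all()

    def test_proliferation_archetype_flat_in_sham(self):
        cfg = SimulationConfig(
            n_genes=60, noise_sd=0.0, circadian_fraction=0.0,
            class_fractions={"changing_7": 1.0}, post_ph_fraction=0.0, seed=3)
        tus, _ = simulate_annotation(cfg)
        expr, design, truth = simulate_expression(cfg, tus)
        sham_cols = design.index[design["arm"] == "sham"]
        sham = expr[sham_cols]
        assert (sham.nunique(axis=1) == 1).all()
        # ... while the PH arm moves
        ph_cols = design.index[design["arm"] == "PH"]
        assert (expr[ph_cols].nunique(axis=1) > 1).all()

    def test_early_archetypes_shared_between_arms(self):
        cfg = SimulationConfig(
            n_genes=40, noise_sd=0.0, circadian_fraction=0.0,
            class_fractions={"changing_4": 1.0}, post_ph_fraction=0.0, seed=4)
        tus, _ = simulate_annotation(cfg)
        expr, design, truth = simulate_expression(cfg, tus)
        for h in (1, 4, 10, 20):
            ph = design.index[(design["arm"] == "PH") & (design["hours"] == h)]
            sham = design.index[(design["arm"] == "sham") & (design["hours"] == h)]
            np.testing.assert_allclose(expr[ph].mean(axis=1), expr[sham].mean(axis=1))

    def test_archetype_mean_recovery_law_of_large_numbers(self):
        # replicate means converge to the archetype curve at n_replicates=30
        cfg = SimulationConfig(
            n_genes=30, n_replicates=30, circadian_fraction=0.0,
            class_fractions={"changing_6": 1.0}, post_ph_fraction=0.0, seed=5)
        tus, _ = simulate_annotation(cfg)
        expr, design, truth = simulate_expression(cfg, tus)
        log2x = np.log2(expr)
        tol = 3 * cfg.noise_sd / np.sqrt(cfg.n_replicates)
        for h in cfg.time_grid_ph:
            cols = design.index[(design["hours"] == h)
                                & design["arm"].isin(("control", "PH"))]
            offsets = (log2x[cols].mean(axis=1) - truth["baseline_log2"]).to_numpy()
            expected = archetype_curve(6, [h], cfg.archetype_amplitude)[0]
            assert np.abs(offsets - expected).max() < tol * 3  # 30 genes, max stat

    def test_class_fractions_match_multinomial(self):
        cfg = SimulationConfig(n_genes=10_000, seed=6)
        tus, _ = simulate_annotation(cfg)
        _, _, truth = simulate_expression(cfg, tus)
        observed = truth["gene_class"].value_counts()
        classes = list(cfg.class_fractions)
        obs = np.array([observed.get(c, 0) for c in classes])
        exp = np.array([cfg.class_fractions[c] for c in classes]) * cfg.n_genes
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(classes) - 1)
        assert p > 0.01

    def test_circadian_genes_identical_oscillation_in_both_arms(self):
        cfg = SimulationConfig(n_genes=400, circadian_fraction=0.5, seed=7)
        tus, _ = simulate_annotation(cfg)
        expr, design, truth = simulate_expression(cfg, tus)
        circ = truth.index[truth["is_circadian"]]
        assert len(circ) >= 10

        def fit_sin(hours, values):
            # linear least squares on the 24 h harmonic: deterministic fit
            zt = 2 * np.pi * (2 + hours) / 24
            X = np.column_stack([np.ones_like(zt), np.cos(zt), np.sin(zt)])
            (base, a, b), *_ = np.linalg.lstsq(X, values, rcond=None)
            return np.hypot(a, b), np.arctan2(-b, a) % (2 * np.pi)

        log2x = np.log2(expr + 1)
        matched = [1, 4, 10, 20, 48]
        ok = 0
        for g in circ[:10]:
            fits = {}
            for arm in ("PH", "sham"):
                cols = design.index[(design["arm"] == arm)
                                    & design["hours"].isin(matched)]
                hrs = design.loc[cols, "hours"].to_numpy()
                amp, phase = fit_sin(hrs, log2x.loc[g, cols].to_numpy())
                fits[arm] = (amp, phase)
            amp_close = abs(fits["PH"][0] - fits["sham"][0]) < 0.5
            dphi = abs(fits["PH"][1] - fits["sham"][1])
            phase_close = min(dphi, 2 * np.pi - dphi) < np.pi / 4
            if amp_close and phase_close:
                ok += 1
        assert ok >= 8

    def test_rejects_mismatched_annotation(self):
        cfg = SimulationConfig(n_genes=10, seed=0)
        tus, _ = simulate_annotation(cfg)
        cfg2 = SimulationConfig(n_genes=11, seed=0)
        with pytest.raises(ValueError, match="match"):
            simulate_expression(cfg2, tus)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_genes=50, seed=9)
        tus, _ = simulate_annotation(cfg)
        e1, _, t1 = simulate_expression(cfg, tus)
        e2, _, t2 = simulate_expression(cfg, tus)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(t1, t2)


class TestChipGeneration:
    def test_unknown_mark_rejected(self, small_world):
        w = small_world
        with pytest.raises(ValueError, match="unknown mark"):
            simulate_track(w["cfg"], w["tus"], w["truth"], w["tu_truth"],
                           w["chrom_len"], "h3k27ac", 60)

    def test_noiseless_input_constant(self, small_world):
        w = small_world
        tr = simulate_track(w["cfg"], w["tus"], w["truth"], w["tu_truth"],
                            w["chrom_len"], "input", 60, noise=False)
        assert np.unique(tr.values).size == 1

    def test_me3_zero_upstream_positive_downstream_of_anchor(self, small_world):
        w = small_world
        tr = simulate_track(w["cfg"], w["tus"], w["truth"], w["tu_truth"],
                            w["chrom_len"], "h3k36me3", 60, noise=False)
        for tu in w["tus"][:10]:
            s, e = first_internal_exon(tu)
            anchor5 = s if tu.strand == "+" else e - 1
            if tu.strand == "+":
                up = tr.values[anchor5 - 1500:anchor5 - 500]
                dn = tr.values[anchor5:anchor5 + 1000]
            else:
                up = tr.values[anchor5 + 500:anchor5 + 1500]
                dn = tr.values[anchor5 - 1000:anchor5 + 1]
            assert up.mean() == pytest.approx(w["cfg"].chip_background)
            assert dn.mean() > 5 * w["cfg"].chip_background

    def test_track_determinism_independent_of_batch(self, small_world):
        w = small_world
        solo = simulate_track(w["cfg"], w["tus"], w["truth"], w["tu_truth"],
                              w["chrom_len"], "h3k36me3", 60)
        batch = w["tracks"][("h3k36me3", 60.0)]
        np.testing.assert_array_equal(solo.values, batch.values)
        assert solo.spike_fragments == batch.spike_fragments

    def test_spike_fraction_near_nominal(self, small_world):
        w = small_world
        tr = w["tracks"][("input", 60.0)]
        frac = tr.spike_fragments / (tr.spike_fragments + tr.n_fragments)
        assert frac == pytest.approx(w["cfg"].spike_in_fraction, rel=0.5)
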