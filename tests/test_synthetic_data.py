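"""The generator's planted structure, determinism and null behaviour."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ese_scan import synthetic_data as sd
from ese_scan.genomic_core import centered_window, window_mean


def _hash_dir(d: Path) -> dict:
    return {
        p.relative_to(d).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.rglob("*"))
        if p.is_file()
    }


class TestAnnotation:
    def test_deterministic_under_seed(self, small_config):
        a = sd.simulate_annotation(small_config)
        b = sd.simulate_annotation(small_config)
        assert a == b

    def test_zero_genes(self):
        cfg = sd.SimConfig(seed=0, n_genes=0, n_activated=0, n_suppressed=0)
        assert sd.simulate_annotation(cfg) == []

    def test_spacing_all_pairs(self, small_sim):
        by_chrom = {}
        for g in small_sim.annotation:
            by_chrom.setdefault(g.locus.chrom, []).append(g.locus)
        for loci in by_chrom.values():
            loci = sorted(loci, key=lambda iv: iv.start)
            gaps = [b.start - a.end for a, b in zip(loci, loci[1:])]
            assert min(gaps) >= 12_000

    def test_locus_sizes_and_tss_inside(self, small_sim):
        for g in small_sim.annotation:
            assert 2_000 <= len(g.locus) <= 10_000
            for t in g.tss_list:
                assert g.locus.start <= t < g.locus.end

    def test_genome_too_small_errors(self):
        cfg = sd.SimConfig(seed=0, n_genes=100, n_activated=1, n_suppressed=1,
                           genome=(("c", 100_000),))
        with pytest.raises(ValueError, match="too small"):
            sd.simulate_annotation(cfg)


class TestLabels:
    def test_labels_partition(self, small_sim):
        counts = small_sim.truth.gene_labels.label.value_counts()
        cfg = small_sim.config
        assert counts.get("activated", 0) == cfg.n_activated
        assert counts.get("suppressed", 0) == cfg.n_suppressed
        assert counts.sum() == cfg.n_genes


class TestCounts:
    def test_same_seed_identical(self, small_config, small_sim):
        again = sd.simulate_all(small_config)
        pd.testing.assert_frame_equal(again.gene_counts, small_sim.gene_counts)
        pd.testing.assert_frame_equal(again.tss_counts, small_sim.tss_counts)

    def test_null_effect_means_balanced(self):
        cfg = sd.SimConfig(seed=3, de_log2fc=0.0)
        ann = sd.simulate_annotation(cfg)
        truth = sd.assign_gene_labels(cfg, ann)
        gc, _, design = sd.simulate_counts(cfg, ann, truth)
        planted = truth.gene_labels.loc[
            truth.gene_labels.label == "activated", "gene_id"
        ]
        sg = design[design.tissue == "SG"]
        hs = gc.loc[planted, sg[sg.condition == "HS"].sample_id].to_numpy().mean()
        nhs = gc.loc[planted, sg[sg.condition == "NHS"].sample_id].to_numpy().mean()
        assert 0.8 <= hs / nhs <= 1.25

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = sd.SimConfig(seed=4, n_genes=400, n_activated=1, n_suppressed=1,
                           nb_dispersion=0.0, baseline_sigma=0.0,
                           genome=(("c1", 4_500_000), ("c2", 4_500_000)))
        ann = sd.simulate_annotation(cfg)
        truth = sd.assign_gene_labels(cfg, ann)
        gc, _, _ = sd.simulate_counts(cfg, ann, truth)
        null = truth.gene_labels.loc[truth.gene_labels.label == "null", "gene_id"]
        # within one library all null genes share one mean (flat baseline),
        # so the across-gene variance/mean ratio approaches the Poisson 1
        ratios = [
            gc.loc[null, c].var() / gc.loc[null, c].mean() for c in gc.columns
        ]
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.15)

    def test_nb_dispersion_inflates_variance(self):
        cfg = sd.SimConfig(seed=4, n_genes=400, n_activated=1, n_suppressed=1,
                           baseline_sigma=0.0,
                           genome=(("c1", 4_500_000), ("c2", 4_500_000)))
        ann = sd.simulate_annotation(cfg)
        truth = sd.assign_gene_labels(cfg, ann)
        gc, _, _ = sd.simulate_counts(cfg, ann, truth)
        null = truth.gene_labels.loc[truth.gene_labels.label == "null", "gene_id"]
        c = gc.columns[0]
        mu = gc.loc[null, c].mean()
        expected = mu + cfg.nb_dispersion * mu**2
        assert gc.loc[null, c].var() == pytest.approx(expected, rel=0.25)

    def test_planted_fold_change_direction(self, default_sim):
        s = default_sim
        labels = s.truth.gene_labels.set_index("gene_id").label
        act = labels[labels == "activated"].index
        nhs = s.gene_counts.loc[act, ["SG_NHS_r1", "SG_NHS_r2"]].to_numpy().mean()
        hs = s.gene_counts.loc[act, ["SG_HS_r1", "SG_HS_r2"]].to_numpy().mean()
        assert np.log2(nhs / hs) == pytest.approx(s.config.de_log2fc, abs=0.5)


class TestPeaksAndTracks:
    def test_eses_per_locus_near_mean(self, default_sim):
        eses = default_sim.truth.eses
        per_locus = eses.groupby("locus_id").size()
        assert per_locus.mean() == pytest.approx(
            default_sim.config.eses_per_locus_mean, rel=0.2
        )
        assert per_locus.min() >= 1

    def test_ese_labels_partition(self, default_sim):
        eses = default_sim.truth.eses
        assert set(eses.location_class) <= {"proximal", "distal"}
        assert set(eses.activity_class) <= {"active", "poised"}

    def test_background_ratio_near_one(self, small_sim):
        chrom = small_sim.config.genome[0][0]
        w = centered_window(chrom, 2_500, 250)  # upstream of first locus
        chip = window_mean(small_sim.tracks[("ecr", "NHS", 1)], w)
        inp = window_mean(small_sim.tracks[("input", "NHS", 1)], w)
        assert chip / inp == pytest.approx(1.0, abs=0.15)

    def test_null_drop_leaves_tracks_balanced(self):
        cfg = sd.SimConfig(seed=9, n_genes=12, n_activated=6, n_suppressed=2,
                           signal_drop_hs=1.0, genome=(("c", 350_000),))
        ann = sd.simulate_annotation(cfg)
        truth = sd.assign_gene_labels(cfg, ann)
        _, tracks = sd.simulate_peaks_and_tracks(cfg, ann, truth)
        ratios = []
        for r in truth.eses.itertuples():
            w = centered_window(r.chrom, r.summit, 250)
            nhs = window_mean(tracks[("ecr", "NHS", 1)], w)
            hs = window_mean(tracks[("ecr", "HS", 1)], w)
            ratios.append(nhs / hs)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_planted_drop_halves_active_window_signal(self, default_sim):
        s = default_sim
        active = s.truth.eses[s.truth.eses.activity_class == "active"]
        ratios = []
        for r in active.itertuples():
            w = centered_window(r.chrom, r.summit, 500)
            nhs = np.mean([window_mean(s.tracks[("h3k27ac", "NHS", k)], w) for k in (1, 2)])
            hs = np.mean([window_mean(s.tracks[("h3k27ac", "HS", k)], w) for k in (1, 2)])
            ratios.append(nhs / hs)
        assert np.median(ratios) == pytest.approx(1 / s.config.signal_drop_hs, rel=0.1)

    def test_poised_keep_chip_lose_accessibility(self, default_sim):
        s = default_sim
        poised = s.truth.eses[s.truth.eses.activity_class == "poised"].head(40)
        chip_r, faire_r = [], []
        for r in poised.itertuples():
            w = centered_window(r.chrom, r.summit, 250)
            chip_r.append(
                window_mean(s.tracks[("ecr", "NHS", 1)], w)
                / window_mean(s.tracks[("ecr", "HS", 1)], w)
            )
            faire_r.append(
                window_mean(s.tracks[("faire", "NHS", 1)], w)
                / window_mean(s.tracks[("faire", "HS", 1)], w)
            )
        assert np.median(chip_r) == pytest.approx(1.0, abs=0.1)
        assert np.median(faire_r) == pytest.approx(2.0, rel=0.15)


class TestWriters:
    def test_written_files_deterministic(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.write_simulation(sd.simulate_all(small_config), d1)
        sd.write_simulation(sd.simulate_all(small_config), d2)
        h1, h2 = _hash_dir(d1), _hash_dir(d2)
        assert h1 and h1 == h2
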