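import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from bindscan.core import BindingSite
from bindscan.enrichment import classify_transcribed, element_proximity_fraction
from bindscan.regulation import RegulationThresholds, call_genes
from bindscan.simulate import (
    ElementTrackConfig,
    SimulationConfig,
    simulate_dataset,
    simulate_elements,
    simulate_expression,
    simulate_genome,
    simulate_peaks,
)
from bindscan.tss import nearest_tss, random_site_set


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestGenome:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            simulate_dataset(SimulationConfig(seed=7), outdir=tmp_path / sub)
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")

    def test_gc_content_within_binomial_error(self):
        cfg = SimulationConfig(
            seed=1, n_chroms=1, chrom_length_bp=1_000_000, n_genes=10, gc_content=0.5
        )
        _, seqs = simulate_genome(cfg)
        seq = seqs["chr1"]
        gc = np.isin(seq, np.frombuffer(b"GC", dtype=np.uint8)).mean()
        sd = math.sqrt(0.25 / 1_000_000)
        assert abs(gc - 0.5) < 3 * sd

    def test_no_genes_means_everything_non_transcribed(self):
        cfg = SimulationConfig(seed=2, n_genes=0, n_sites=50, generate_sequence=False)
        ann, _ = simulate_genome(cfg)
        assert ann.transcribed_regions == []
        peaks, _ = simulate_peaks(ann, cfg)
        assert classify_transcribed(peaks, ann) == (0, 50)

    def test_overfull_chromosome_rejected(self):
        cfg = SimulationConfig(
            seed=3, n_chroms=1, chrom_length_bp=100_000, n_genes=50,
            gene_length_mean_bp=40_000, generate_sequence=False,
        )
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_genome(cfg)


class TestPeaks:
    def test_fully_proximal_peaks_hug_tss(self):
        cfg = SimulationConfig(
            seed=4, n_sites=1000, tss_proximal_fraction=1.0, tss_bell_sd_bp=1000.0,
            generate_sequence=False, motif_plant_fraction=0.0,
        )
        ann, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(ann, cfg)
        within = sum(1 for p in peaks if abs(nearest_tss(p, ann).distance) <= 4000)
        # normal tail: P(|N(0,1k)| > 4k) ~ 6e-5; allow generous slack
        assert within / len(peaks) >= 0.95

    def test_zero_sites_empty_outputs(self):
        cfg = SimulationConfig(seed=5, n_sites=0, generate_sequence=False)
        ann, _ = simulate_genome(cfg)
        peaks, manifest = simulate_peaks(ann, cfg)
        assert peaks == [] and manifest == {}

    def test_manifest_covers_every_peak_exactly_once(self, default_dataset):
        ds = default_dataset
        assert set(ds.manifest["peaks"]) == {p.id for p in ds.peaks}
        planted = sum(1 for r in ds.manifest["peaks"].values() if r["motif"])
        assert planted == round(ds.config.motif_plant_fraction * len(ds.peaks))

    def test_planted_instances_present_in_sequence(self, default_dataset):
        from bindscan.motif import compile_pattern, scan_sequence

        ds = default_dataset
        pat = compile_pattern(ds.config.consensus)
        by_id = {p.id: p for p in ds.peaks}
        checked = 0
        for pid, rec in ds.manifest["peaks"].items():
            if not rec["motif"]:
                continue
            iv = by_id[pid].interval
            window = ds.sequences[iv.chrom][rec["motif_pos"] : rec["motif_pos"] + 6]
            assert scan_sequence(window, pat) != []
            checked += 1
            if checked >= 25:
                break
        assert checked == 25


class TestElements:
    def test_unit_fold_matches_uniform_baseline(self):
        cfg = SimulationConfig(
            seed=6, generate_sequence=False,
            element_tracks={"flat": ElementTrackConfig(250, 300, 1.0)},
        )
        ann, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(ann, cfg)
        tracks, info = simulate_elements(ann, peaks, cfg)
        assert info["flat"]["n_targeted"] == 0
        distal = [p for p in peaks if abs(nearest_tss(p, ann).distance) > 4000]
        rand = random_site_set(ann, 4 * len(distal), widths=[p.width for p in distal], seed=6)
        f_obs = element_proximity_fraction(distal, tracks["flat"])
        f_rnd = element_proximity_fraction(rand, tracks["flat"])
        se = math.sqrt(f_rnd * (1 - f_rnd) / len(distal))
        assert abs(f_obs - f_rnd) < 4 * se

    def test_zero_elements_zero_fraction(self):
        cfg = SimulationConfig(
            seed=7, generate_sequence=False,
            element_tracks={"none": ElementTrackConfig(0, 300, 1.5)},
        )
        ann, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(ann, cfg)
        tracks, _ = simulate_elements(ann, peaks, cfg)
        assert tracks["none"] == []
        assert element_proximity_fraction(peaks, tracks["none"]) == 0.0

    def test_infeasible_fold_rejected(self):
        cfg = SimulationConfig(
            seed=8, generate_sequence=False,
            element_tracks={"bad": ElementTrackConfig(100, 300, 0.5)},
        )
        ann, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(ann, cfg)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_elements(ann, peaks, cfg)


class TestExpression:
    def test_all_activated_means_down_kd_up_oe(self):
        cfg = SimulationConfig(
            seed=9, generate_sequence=False, activated_share=1.0,
            kd_only_share=0.0, oe_only_share=0.0,  # every planted gene responds in both
        )
        ann, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(ann, cfg)
        expr, manifest = simulate_expression(ann, peaks, cfg)
        planted = [g for g, r in manifest.items() if r["regulated"]]
        assert planted
        for gid in planted:
            rows = expr[expr["gene"] == gid].set_index("contrast")
            assert rows.loc["KD", "log2fc"] < 0
            assert rows.loc["OE", "log2fc"] > 0

    def test_no_planting_stays_below_null_crossing_rate(self, big_noseq_config):
        cfg = big_noseq_config(10)
        cfg = SimulationConfig(**{**cfg.__dict__, "regulated_fraction": 0.0})
        ds = simulate_dataset(cfg)
        calls, _ = call_genes(ds.expression, RegulationThresholds(1.25, 0.05))
        # null crossing per contrast: P(|N(0,sd)| >= log2(1.25)) * 0.05, two contrasts
        from scipy.stats import norm

        per_contrast = 2 * norm.sf(math.log2(1.25) / cfg.null_log2fc_sd) * 0.05
        nominal = 2 * per_contrast
        frac = calls["regulated"].mean()
        se = math.sqrt(nominal / len(calls))
        assert frac <= nominal + 4 * se

    def test_same_seed_identical_table(self):
        cfg = SimulationConfig(seed=11, generate_sequence=False)
        ann, _ = simulate_genome(cfg)
        peaks, _ = simulate_peaks(ann, cfg)
        a, _ = simulate_expression(ann, peaks, cfg)
        b, _ = simulate_expression(ann, peaks, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_sub_one_planting_warns(self):
        cfg = SimulationConfig(
            seed=12, n_genes=4, regulated_fraction=0.01, generate_sequence=False
        )
        ann, _ = simulate_genome(cfg)
        with pytest.warns(UserWarning):
            simulate_expression(ann, [], cfg)

    def test_distance_decay_mode_concentrates_near_tss(self, big_noseq_config):
        cfg = big_noseq_config(13)
        cfg = SimulationConfig(**{**cfg.__dict__, "distance_decay": True,
                                  "regulated_fraction": 0.2})
        ds = simulate_dataset(cfg)
        from bindscan.tss import gene_distance_map

        dmap = gene_distance_map(ds.peaks, ds.annotation)
        planted = [g for g, r in ds.manifest["genes"].items() if r["regulated"]]
        others = [g for g, r in ds.manifest["genes"].items() if not r["regulated"]]
        cap = 10 * cfg.distance_decay_scale_bp
        d_p = np.mean([min(abs(dmap.get(g, cap)), cap) for g in planted])
        d_o = np.mean([min(abs(dmap.get(g, cap)), cap) for g in others])
        assert d_p < d_o


class TestManifest:
    def test_manifest_covers_every_gene(self, default_dataset):
        ds = default_dataset
        assert set(ds.manifest["genes"]) == {g.id for g in ds.annotation.genes}

    def test_written_bundle_parses_back(self, tmp_path):
        from bindscan.core import read_bed, read_gene_table
        from bindscan.regulation import read_expression

        ds = simulate_dataset(SimulationConfig(seed=14), outdir=tmp_path)
        ann = read_gene_table(tmp_path / "genes.tsv", tmp_path / "chroms.tsv")
        assert ann.n_genes == ds.annotation.n_genes
        peaks = read_bed(tmp_path / "peaks.bed")
        assert [(p.id, p.interval) for p in peaks] == [
            (p.id, p.interval) for p in ds.peaks
        ]
        expr = read_expression(tmp_path / "expression.tsv")
        assert len(expr) == 2 * ann.n_genes
        manifest = json.loads((tmp_path / "ground_truth.json").read_text())
        assert set(manifest) == {"seed", "peaks", "genes", "elements"}
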