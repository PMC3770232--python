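import math

import numpy as np
import pandas as pd
import pytest

from bindscan.core import BindingSite, Gene, GenomeAnnotation, Interval
from bindscan.regulation import (
    RegulationThresholds,
    call_contrast,
    call_genes,
    classify_gene_position,
    combine_calls,
    regulated_by_distance_bin,
    regulated_by_position_type,
    regulated_by_site_count,
    regulated_fraction,
    summarize_regulation,
)
from bindscan.simulate import SimulationConfig, simulate_dataset

THR15 = RegulationThresholds(1.5, 0.05)
THR125 = RegulationThresholds(1.25, 0.05)


def _site(start, end, name="s", chrom="c"):
    return BindingSite(Interval(chrom, start, end), name)


class TestCallContrast:
    def test_fold_060_is_down_at_15(self):
        assert call_contrast(math.log2(0.60), 0.01, THR15) == "down"

    def test_threshold_boundary_between_125_and_15(self):
        lf = math.log2(1.30)
        assert call_contrast(lf, 0.01, THR15) == "unchanged"
        assert call_contrast(lf, 0.01, THR125) == "up"

    def test_p_failure_blocks_call(self):
        assert call_contrast(1.0, 0.20, THR15) == "unchanged"

    def test_exact_threshold_fold_passes(self):
        assert call_contrast(math.log2(1.5), 0.049, THR15) == "up"

    def test_exact_p_threshold_fails(self):
        assert call_contrast(1.0, 0.05, THR15) == "unchanged"

    def test_missing_values_raise(self):
        with pytest.raises(ValueError):
            call_contrast(float("nan"), 0.01, THR15)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            RegulationThresholds(1.0, 0.05)
        with pytest.raises(ValueError):
            RegulationThresholds(1.5, 0.0)


class TestCombineCalls:
    @pytest.mark.parametrize(
        "kd,oe,expected",
        [
            ("down", "unchanged", "activated_by_factor"),
            ("unchanged", "down", "repressed_by_factor"),
            ("up", "up", "conflicting"),
            ("down", "down", "conflicting"),
            ("unchanged", "unchanged", "unchanged"),
            ("down", "up", "activated_by_factor"),
            ("up", "down", "repressed_by_factor"),
        ],
    )
    def test_mapping(self, kd, oe, expected):
        assert combine_calls(kd, oe) == expected


class TestCallGenes:
    def _expr(self):
        return pd.DataFrame(
            {
                "gene": ["a", "a", "b", "b", "c", "c", "d"],
                "log2fc": [-1.0, 1.0, 0.0, 0.1, float("nan"), float("nan"), 2.0],
                "p": [0.01, 0.01, 0.5, 0.5, 0.01, 0.01, 0.001],
                "contrast": ["KD", "OE", "KD", "OE", "KD", "OE", "KD"],
            }
        )

    def test_partition_of_genes(self):
        calls, excluded = call_genes(self._expr(), THR15)
        assert set(calls.index) | set(excluded) == {"a", "b", "c", "d"}
        assert excluded == ["c"]

    def test_single_contrast_gene_called_on_it(self):
        calls, _ = call_genes(self._expr(), THR15)
        assert calls.loc["d", "kd_status"] == "up"
        assert calls.loc["d", "overall"] == "repressed_by_factor"

    def test_activated_gene_called(self):
        calls, _ = call_genes(self._expr(), THR15)
        assert calls.loc["a", "overall"] == "activated_by_factor"

    def test_threshold_monotonicity(self, big_noseq_config):
        ds = simulate_dataset(big_noseq_config(2))
        strict, _ = call_genes(ds.expression, THR15)
        loose, _ = call_genes(ds.expression, THR125)
        reg_strict = set(strict.index[strict["regulated"]])
        reg_loose = set(loose.index[loose["regulated"]])
        assert reg_strict <= reg_loose

    def test_planted_directions_never_flip(self, big_noseq_config):
        # every planted activated gene whose contrasts pass is called activated
        ds = simulate_dataset(big_noseq_config(3))
        calls, _ = call_genes(ds.expression, THR15)
        for gid, rec in ds.manifest["genes"].items():
            if rec["regulated"] and gid in calls.index and calls.loc[gid, "regulated"]:
                expected = (
                    "activated_by_factor"
                    if rec["direction"] == "activated"
                    else "repressed_by_factor"
                )
                assert calls.loc[gid, "overall"] == expected

    def test_kd_heavy_planting_gives_union_above_oe(self, big_noseq_config):
        ds = simulate_dataset(big_noseq_config(4))
        calls, _ = call_genes(ds.expression, THR15)
        summary = summarize_regulation(calls)
        assert summary.loc["union", "regulated"] > summary.loc["OE", "regulated"]
        assert summary.loc["KD", "regulated"] > summary.loc["OE", "regulated"]


class TestSummaries:
    def _calls(self, regulated_genes, all_genes):
        rows = []
        for g in all_genes:
            reg = g in regulated_genes
            rows.append(
                {
                    "gene": g,
                    "kd_status": "down" if reg else "unchanged",
                    "oe_status": "unchanged",
                    "overall": "activated_by_factor" if reg else "unchanged",
                    "regulated": reg,
                }
            )
        return pd.DataFrame(rows).set_index("gene")

    def test_regulated_fraction_arithmetic(self):
        genes = [f"g{i}" for i in range(4140)]
        calls = self._calls(set(genes[:347]), genes)
        summary = regulated_fraction(genes, calls)
        assert summary.loc["union", "regulated"] == 347
        assert round(100 * summary.loc["union", "fraction_regulated"], 1) == 8.4

    def test_all_regulated_toy_bins_at_100_percent(self):
        genes = ["a", "b", "c"]
        calls = self._calls(set(genes), genes)
        table, stat, p = regulated_by_distance_bin({"a": 0, "b": -600, "c": 41_000}, calls)
        nonempty = table[table["n_genes"] > 0]
        assert (nonempty["fraction"] == 1.0).all()
        assert p == 1.0  # no heterogeneity when everything is regulated

    def test_site_count_groups(self):
        genes = [f"g{i}" for i in range(613)]
        calls = self._calls(set(genes[:255]), genes)
        counts = {g: (2 if i % 2 == 0 else 3) for i, g in enumerate(genes)}
        table = regulated_by_site_count(counts, {"1.25": calls})
        assert table.loc["2+", "n_regulated_1.25"] == 255
        assert round(100 * table.loc["2+", "fraction_1.25"], 1) == 41.6
        assert table.loc["1", "n_targets"] == 0
        assert math.isnan(table.loc["1", "fraction_1.25"])


class TestGenePosition:
    def test_constructed_three_gene_ordering(self):
        # site midpoint at 100_000; TSSs at 90k (left), 102k (right), 130k (right)
        genes = [
            Gene("left10k", Interval("c", 50_000, 90_001, "-")),   # tss 90_000
            Gene("right2k", Interval("c", 102_000, 120_000, "+")),  # tss 102_000
            Gene("right30k", Interval("c", 130_000, 150_000, "+")),  # tss 130_000
        ]
        ann = GenomeAnnotation({"c": 1_000_000}, genes)
        pos = classify_gene_position(_site(99_800, 100_200), ann)
        assert pos.type1 == "right2k"
        assert pos.type2 == "left10k"
        assert pos.type3 == "right30k"

    def test_single_gene_chromosome(self):
        ann = GenomeAnnotation({"c": 1_000_000}, [Gene("g", Interval("c", 10_000, 20_000, "+"))])
        pos = classify_gene_position(_site(500_000, 500_400), ann)
        assert (pos.type1, pos.type2, pos.type3) == ("g", None, None)

    def test_equidistant_opposite_genes_tie_by_id(self):
        genes = [
            Gene("geneA", Interval("c", 105_000, 120_000, "+")),  # tss 105_000, right
            Gene("geneB", Interval("c", 80_000, 95_001, "-")),    # tss 95_000, left
        ]
        ann = GenomeAnnotation({"c": 1_000_000}, genes)
        # site [99_800, 100_200): both TSSs exactly 4_800 bp from the site edges
        pos = classify_gene_position(_site(99_800, 100_200), ann)
        assert pos.type1 == "geneA"  # tie resolved lexicographically
        assert pos.type2 == "geneB"  # the loser becomes the opposite-side gene
        assert pos.type3 is None


class TestPositionTypeSummary:
    def test_no_regulated_genes_gives_zeros(self):
        genes = [
            Gene("a", Interval("c", 10_000, 20_000, "+")),
            Gene("b", Interval("c", 50_000, 60_000, "+")),
            Gene("d", Interval("c", 90_000, 99_000, "+")),
        ]
        ann = GenomeAnnotation({"c": 1_000_000}, genes)
        calls = pd.DataFrame(
            {
                "kd_status": ["unchanged"] * 3,
                "oe_status": ["unchanged"] * 3,
                "overall": ["unchanged"] * 3,
                "regulated": [False] * 3,
            },
            index=pd.Index(["a", "b", "d"], name="gene"),
        )
        table = regulated_by_position_type([_site(30_000, 30_400)], ann, {"1.5": calls})
        assert (table["n_regulated_1.5"] == 0).all()

    def test_two_gene_genome_flags_type3(self):
        genes = [
            Gene("a", Interval("c", 10_000, 20_000, "+")),
            Gene("b", Interval("c", 50_000, 60_000, "+")),
        ]
        ann = GenomeAnnotation({"c": 1_000_000}, genes)
        calls = pd.DataFrame(
            {
                "kd_status": ["unchanged"] * 2,
                "oe_status": ["unchanged"] * 2,
                "overall": ["unchanged"] * 2,
                "regulated": [False] * 2,
            },
            index=pd.Index(["a", "b"], name="gene"),
        )
        table = regulated_by_position_type([_site(30_000, 30_400)], ann, {"1.5": calls})
        assert table.loc["3", "n_genes"] == 0
        assert math.isnan(table.loc["3", "fraction_1.5"])
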