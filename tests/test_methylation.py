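"""Region partition, weighted methylation, TE stratification, correlation."""

import numpy as np
import pandas as pd
import pytest

from psgscan.io_formats import GeneModel
from psgscan.methylation import (
    REGIONS,
    methylation_expression_correlation,
    partition_gene_regions,
    profile_genes,
    te_overlap_stratification,
    weighted_methylation,
)


def _calls(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "count_methylated", "count_total"])
    df["covered"] = df["count_total"] > 0
    return df


class TestPartition:
    def test_plus_strand_promoter_immediately_upstream(self, plus_gene):
        # TSS at 0-based 5000 (1-based 5001); 2000 bp promoter = 3001..5000
        rs = partition_gene_regions(plus_gene, promoter_length=2000)
        assert rs.intervals["promoter"] == [(3000, 5000)]

    def test_minus_strand_promoter_downstream_in_genome_coords(self, minus_gene):
        # transcript ends at 1-based 8000; promoter covers 8001..10000
        rs = partition_gene_regions(minus_gene, promoter_length=2000)
        assert rs.intervals["promoter"] == [(8000, 10000)]

    def test_strand_aware_utr_assignment(self, plus_gene, minus_gene):
        plus = partition_gene_regions(plus_gene)
        minus = partition_gene_regions(minus_gene)
        assert plus.intervals["UTR5"] == [(5000, 5200)]
        assert plus.intervals["UTR3"] == [(6300, 6500)]
        # on the minus strand UTR5 sits at the high-coordinate end
        assert minus.intervals["UTR5"] == [(7800, 8000)]
        assert minus.intervals["UTR3"] == [(6500, 6700)]

    def test_single_exon_cds_equals_transcript(self):
        m = GeneModel(gene_id="g", chrom="Chr01", strand="+", tx_start=100,
                      tx_end=400, exons=((100, 400),), cds_start=100,
                      cds_end=400)
        rs = partition_gene_regions(m)
        for region in ("UTR5", "UTR3", "intron"):
            assert rs.intervals[region] == []
        assert rs.intervals["exon"] == [(100, 400)]

    def test_promoter_truncated_at_chromosome_start(self):
        m = GeneModel(gene_id="g", chrom="Chr01", strand="+", tx_start=500,
                      tx_end=900, exons=((500, 900),), cds_start=500,
                      cds_end=900)
        with pytest.warns(RuntimeWarning, match="truncated"):
            rs = partition_gene_regions(m, promoter_length=2000)
        assert rs.intervals["promoter"] == [(0, 500)]

    def test_transcribed_regions_tile_the_transcript_span(self, plus_gene,
                                                          minus_gene):
        for model in (plus_gene, minus_gene):
            rs = partition_gene_regions(model)
            pieces = sorted(
                iv for region in ("UTR5", "exon", "intron", "UTR3")
                for iv in rs.intervals[region]
            )
            covered = 0
            prev_end = model.tx_start
            for s, e in pieces:
                assert s == prev_end  # no gap, no overlap
                covered += e - s
                prev_end = e
            assert prev_end == model.tx_end
            assert covered == model.tx_end - model.tx_start


class TestWeightedLevel:
    def test_single_site(self):
        calls = _calls([("Chr01", 10, "+", "CG", 30, 100)])
        out = weighted_methylation(calls, [(0, 50)], "CG")
        assert out["level"] == pytest.approx(0.30)

    def test_read_weighted_not_site_averaged(self):
        calls = _calls([("Chr01", 10, "+", "CG", 3, 10),
                        ("Chr01", 20, "+", "CG", 0, 90)])
        out = weighted_methylation(calls, [(0, 50)], "CG")
        assert out["level"] == pytest.approx(0.03)  # 3/100, not mean(0.3, 0)
        site_avg = weighted_methylation(calls, [(0, 50)], "CG",
                                        site_average=True)
        assert site_avg["level"] == pytest.approx(0.15)

    def test_no_covered_sites_is_undefined(self):
        calls = _calls([("Chr01", 10, "+", "CG", 0, 0)])
        out = weighted_methylation(calls, [(0, 50)], "CG")
        assert np.isnan(out["level"]) and out["total_reads"] == 0

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            weighted_methylation(_calls([]), [(0, 10)], "CXX")


class TestProfiles:
    def test_read_count_conservation_over_transcribed_regions(self, small_study):
        """Sum of UTR5+exon+intron+UTR3 reads equals transcript-span totals."""
        region_sets = [partition_gene_regions(m, small_study.config.promoter_length)
                       for m in small_study.models]
        profiles = profile_genes(small_study.methylation_calls, region_sets)
        calls = small_study.methylation_calls
        models = {m.gene_id: m for m in small_study.models}
        transcribed = ("UTR5", "exon", "intron", "UTR3")
        for gid in list(models)[:15]:
            m = models[gid]
            sub = calls[(calls["chrom"] == m.chrom)
                        & (calls["pos"] >= m.tx_start)
                        & (calls["pos"] < m.tx_end)]
            for ctx in ("CG", "CHG", "CHH"):
                expected = int(sub.loc[sub["context"] == ctx,
                                       "count_total"].sum())
                got = int(profiles[(profiles["gene_id"] == gid)
                                   & (profiles["context"] == ctx)
                                   & (profiles["region"].isin(transcribed))
                                   ]["total_reads"].sum())
                assert got == expected

    def test_levels_bounded(self, small_study):
        region_sets = [partition_gene_regions(m, small_study.config.promoter_length)
                       for m in small_study.models]
        profiles = profile_genes(small_study.methylation_calls, region_sets)
        defined = profiles["level"].dropna()
        assert ((defined >= 0) & (defined <= 1)).all()

    def test_assignment_matches_naive_all_pairs_overlap(self, rng):
        """Interval-tree region assignment equals an O(n*m) position scan."""
        models = []
        for i in range(5):
            start = 1000 + i * 4000
            models.append(GeneModel(
                gene_id=f"g{i}", chrom="Chr01", strand="+",
                tx_start=start, tx_end=start + 2000,
                exons=((start, start + 800), (start + 1300, start + 2000)),
                cds_start=start + 200, cds_end=start + 1800))
        region_sets = [partition_gene_regions(m, 500) for m in models]
        pos = rng.integers(0, 22000, size=300)
        calls = _calls([("Chr01", int(p), "+", "CG", 1, 2) for p in pos])
        profiles = profile_genes(calls, region_sets)
        for rs in region_sets:
            for region in REGIONS:
                naive = sum(
                    2 for p in pos
                    if any(s <= p < e for s, e in rs.intervals[region])
                )
                got = profiles[(profiles["gene_id"] == rs.gene_id)
                               & (profiles["region"] == region)
                               ]["total_reads"].sum()
                assert got == naive


class TestTeStratification:
    def test_half_open_adjacency_is_no_overlap(self):
        m = GeneModel(gene_id="g", chrom="Chr01", strand="+", tx_start=5000,
                      tx_end=6000, exons=((5000, 6000),), cds_start=5000,
                      cds_end=6000)
        rs = partition_gene_regions(m, promoter_length=1000)
        calls = _calls([("Chr01", 4500, "+", "CG", 5, 10)])
        profiles = profile_genes(calls, [rs])
        te = pd.DataFrame({"chrom": ["Chr01"], "start": [3000], "end": [4000]})
        out = te_overlap_stratification(profiles, [rs], te)
        prom = out[(out["region"] == "promoter") & (out["context"] == "CG")]
        assert prom.iloc[0]["n_with_te"] == 0  # TE ends where promoter begins

    def test_empty_te_set_flags_with_group(self, small_study):
        region_sets = [partition_gene_regions(m, small_study.config.promoter_length)
                       for m in small_study.models[:10]]
        profiles = profile_genes(small_study.methylation_calls, region_sets)
        te = pd.DataFrame(columns=["chrom", "start", "end"])
        out = te_overlap_stratification(profiles, region_sets, te)
        assert (out["n_with_te"] == 0).all()
        assert (out["note"] == "empty_group").any()

    def test_planted_te_effect_shifts_levels(self):
        """+0.2 TE effect appears as a with-minus-without difference."""
        from psgscan.synthetic import (SimulationConfig,
                                       simulate_genome_annotation,
                                       simulate_methylation)

        cfg = SimulationConfig(seed=31, n_genes=150, te_insertion_rate=0.4,
                               te_methylation_effect=0.2, site_spacing=20)
        models, te, truth = simulate_genome_annotation(cfg)
        calls, _ledger = simulate_methylation(models, truth, cfg)
        region_sets = [partition_gene_regions(m, cfg.promoter_length)
                       for m in models]
        profiles = profile_genes(calls, region_sets)
        out = te_overlap_stratification(profiles, region_sets, te)
        prom = out[(out["region"] == "promoter")
                   & (out["context"] == "CG")].iloc[0]
        assert prom["difference"] == pytest.approx(0.2, abs=0.05)


class TestCorrelation:
    def test_monotone_decreasing_gives_rho_minus_one(self):
        genes = [f"g{i}" for i in range(10)]
        profiles = pd.DataFrame({
            "gene_id": genes, "region": "exon", "context": "CG",
            "methylated_reads": np.arange(10, 0, -1) * 10,
            "total_reads": 100, "n_sites": 5,
            "level": np.arange(10, 0, -1) / 10,
        })
        matrix = pd.DataFrame(
            np.tile(np.arange(1.0, 11.0)[:, None], (1, 6)),
            index=genes,
            columns=["root", "stem", "leaf", "flower", "silique", "callus"])
        rho, _p = methylation_expression_correlation(profiles, matrix,
                                                     regions=("exon",))
        assert rho == pytest.approx(-1.0)

    def test_too_few_genes_rejected(self):
        profiles = pd.DataFrame({
            "gene_id": ["g1"], "region": "exon", "context": "CG",
            "methylated_reads": [5], "total_reads": [10], "n_sites": [1],
            "level": [0.5]})
        matrix = pd.DataFrame(
            [[1.0] * 6], index=["g1"],
            columns=["root", "stem", "leaf", "flower", "silique", "callus"])
        with pytest.raises(ValueError, match=">= 3 genes"):
            methylation_expression_correlation(profiles, matrix,
                                               regions=("exon",))

    def test_planted_negative_coupling_detected(self):
        from psgscan.synthetic import SimulationConfig, simulate_study

        cfg = SimulationConfig(seed=41, n_genes=200, meth_expr_coupling=0.3,
                               site_spacing=25)
        study = simulate_study(cfg, with_sequences=False)
        region_sets = [partition_gene_regions(m, cfg.promoter_length)
                       for m in study.models]
        profiles = profile_genes(study.methylation_calls, region_sets)
        rho, p = methylation_expression_correlation(profiles,
                                                    study.expression)
        assert rho < 0 and p < 0.05
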