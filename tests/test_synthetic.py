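"""Generator properties: determinism, planted truth, pileup statistics."""

import numpy as np
import pytest

from editome_kit import (
    CoverageModel,
    EditModel,
    ExpressionModel,
    GENOTYPES,
    GenomeConfig,
    SampleDesign,
    generate_genome,
    make_design,
    plant_truth,
    simulate_expression,
    simulate_pileups,
)
from editome_kit.annotation import CATEGORIES
from editome_kit.genome import REPEAT_CLASSES
from editome_kit.io import write_fasta, write_gff3

from conftest import TINY_EDITS, TINY_GENOME


class TestGenerateGenome:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        paths = []
        for tag in ("a", "b"):
            g = generate_genome(TINY_GENOME, seed=11)
            fa, gff = tmp_path / f"{tag}.fa", tmp_path / f"{tag}.gff3"
            write_fasta(g, fa)
            write_gff3(g, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self):
        a = generate_genome(TINY_GENOME, seed=1)
        b = generate_genome(TINY_GENOME, seed=2)
        assert a.contigs[0].sequence != b.contigs[0].sequence

    def test_zero_repeats(self):
        import dataclasses

        g = generate_genome(dataclasses.replace(TINY_GENOME, n_repeats=0), seed=3)
        assert g.repeats == []

    def test_isg_fraction_exact(self):
        cfg = GenomeConfig(
            n_contigs=2, contig_length=30_000, n_genes=20, isg_fraction=0.5,
            gene_length_range=(600, 1_000), intergenic_gap_range=(50, 300),
        )
        g = generate_genome(cfg, seed=5)
        assert sum(gene.is_isg for gene in g.genes) == 10

    def test_oversized_genes_rejected(self):
        cfg = GenomeConfig(contig_length=2_000, gene_length_range=(3_000, 4_000))
        with pytest.raises(ValueError, match="contig"):
            generate_genome(cfg, seed=0)

    def test_all_feature_categories_present(self, tiny_genome):
        g = tiny_genome
        assert all(gene.cds and gene.utr5 and gene.utr3 for gene in g.genes)
        assert any(gene.introns for gene in g.genes)
        assert {r.repeat_class for r in g.repeats} == set(REPEAT_CLASSES)

    def test_model_invariants(self, tiny_genome):
        tiny_genome.validate()  # exon partition, bounds, strand checks


class TestPlantTruth:
    def test_double_het_ratio_exact(self, tiny_genome):
        model = EditModel(wt_sites=50, adar_het_sites=50, rdrp_tg_sites=50,
                          double_het_ratio=1.6)
        truth = plant_truth(tiny_genome, model, snp_count=5, seed=1)
        n = {g: len(truth.sites_for(g)) for g in GENOTYPES}
        assert n["WT"] == 50
        assert n["RdRp_Adar_het"] == 80  # 50 x 1.6, planted not sampled

    def test_snps_never_collide_with_edit_sites_many_seeds(self, tiny_genome):
        for seed in range(100):
            truth = plant_truth(tiny_genome, TINY_EDITS, snp_count=15, seed=seed)
            edit_pos = {(s.contig, s.pos) for s in truth.edit_sites}
            snp_pos = {(s.contig, s.pos) for s in truth.snps}
            assert not edit_pos & snp_pos
            assert len(truth.snps) == 15

    def test_truth_sites_at_transcript_strand_a(self, tiny_genome, tiny_truth):
        seqs = tiny_genome.sequences
        for s in tiny_truth.edit_sites:
            base = seqs[s.contig][s.pos]
            if s.transcript_strand == "+":
                assert base == "A" and s.change == "A>G"
            elif s.transcript_strand == "-":
                assert base == "T" and s.change == "T>C"
            else:
                assert base in "AT"

    def test_fractions_in_unit_interval(self, tiny_truth):
        for s in tiny_truth.edit_sites:
            assert all(0.0 <= f <= 1.0 for f in s.fractions.values())

    def test_zero_wt_sites_means_no_wt_truth(self, tiny_genome):
        model = EditModel(wt_sites=0, adar_het_sites=30, rdrp_tg_sites=30,
                          double_het_ratio=1.6, shared_core_fraction=0.5)
        truth = plant_truth(tiny_genome, model, snp_count=5, seed=2)
        assert truth.sites_for("WT") == []
        assert all(s.fractions["WT"] == 0.0 for s in truth.edit_sites)

    def test_impossible_site_count_errors(self, tiny_genome):
        model = EditModel(wt_sites=100_000, adar_het_sites=100_000,
                          rdrp_tg_sites=100_000)
        with pytest.raises(ValueError, match="short"):
            plant_truth(tiny_genome, model, snp_count=5, seed=0)


class TestSimulatePileups:
    def test_fixed_seed_identical(self, tiny_genome, tiny_truth):
        design = [SampleDesign("s1", "WT", 1), SampleDesign("s2", "Adar_het", 1)]
        a = simulate_pileups(tiny_genome, tiny_truth, design, seed=9)
        b = simulate_pileups(tiny_genome, tiny_truth, design, seed=9)
        for sid in a:
            assert a[sid].equals(b[sid])

    def test_zero_error_no_spurious_mismatches(self, tiny_genome, tiny_truth):
        design = [SampleDesign("s1", "WT", 1)]
        pil = simulate_pileups(
            tiny_genome, tiny_truth, design, error_rate=0.0, seed=4
        )["s1"]
        variant = {(s.contig, s.pos) for s in tiny_truth.edit_sites}
        variant |= {(s.contig, s.pos) for s in tiny_truth.snps}
        clean = pil[~pil.apply(lambda r: (r["contig"], r["pos"]) in variant, axis=1)]
        at_a = clean[clean["ref"] == "A"]
        assert (at_a[["C", "G", "T"]].to_numpy() == 0).all()

    def test_binomial_mean_at_forced_coverage(self, tiny_genome):
        # fraction 0.5 at constant coverage 1000: mean edited ~ 500 over sites
        model = EditModel(wt_sites=100, adar_het_sites=100, rdrp_tg_sites=100,
                          double_het_ratio=1.0, shared_core_fraction=1.0,
                          fraction_range=(0.5, 0.5))
        truth = plant_truth(tiny_genome, model, snp_count=0, seed=5)
        cov = CoverageModel(mean_depth=1_000, size=None, gene_depth_sigma=0.0)
        pil = simulate_pileups(
            tiny_genome, truth, [SampleDesign("s1", "WT", 1)], cov,
            error_rate=0.0, seed=5,
        )["s1"]
        pil = pil.set_index(["contig", "pos"])
        edited = []
        for s in truth.edit_sites:
            row = pil.loc[(s.contig, s.pos)]
            edited.append(row["G"] if s.change == "A>G" else row["C"])
        assert abs(np.mean(edited) - 500) < 50

    def test_fraction_recovery_at_extreme_depth(self, tiny_genome):
        # law of large numbers: realized fraction -> planted fraction
        model = EditModel(wt_sites=50, adar_het_sites=50, rdrp_tg_sites=50,
                          double_het_ratio=1.0, shared_core_fraction=1.0,
                          fraction_range=(0.3, 0.3))
        truth = plant_truth(tiny_genome, model, snp_count=0, seed=6)
        cov = CoverageModel(mean_depth=10_000, size=None, gene_depth_sigma=0.0)
        pil = simulate_pileups(
            tiny_genome, truth, [SampleDesign("s1", "WT", 1)], cov,
            error_rate=0.0, seed=6,
        )["s1"].set_index(["contig", "pos"])
        fracs = []
        for s in truth.edit_sites:
            row = pil.loc[(s.contig, s.pos)]
            edited = row["G"] if s.change == "A>G" else row["C"]
            fracs.append(edited / (row["A"] + row["C"] + row["G"] + row["T"]))
        assert abs(np.mean(fracs) - 0.3) < 0.01

    def test_het_snp_alt_fraction_near_half(self, tiny_genome, tiny_truth):
        cov = CoverageModel(mean_depth=500, size=None, gene_depth_sigma=0.0)
        pil = simulate_pileups(
            tiny_genome, tiny_truth, [SampleDesign("s1", "WT", 1)], cov,
            error_rate=0.0, seed=8,
        )["s1"].set_index(["contig", "pos"])
        fracs = []
        for s in tiny_truth.snps:
            row = pil.loc[(s.contig, s.pos)]
            fracs.append(row[s.alt] / (row["A"] + row["C"] + row["G"] + row["T"]))
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_unknown_genotype_rejected(self, tiny_genome, tiny_truth):
        from editome_kit import TruthSet, TruthSite

        # a truth set that only knows WT cannot serve an RdRp_tg sample
        restricted = TruthSet(
            edit_sites=[
                TruthSite(s.contig, s.pos, s.transcript_strand, s.change,
                          {"WT": 0.3}, s.category, s.repeat_class)
                for s in tiny_truth.edit_sites[:3]
            ],
            snps=[],
        )
        with pytest.raises(ValueError, match="absent from truth"):
            simulate_pileups(
                tiny_genome, restricted, [SampleDesign("s1", "RdRp_tg", 1)], seed=0
            )


class TestSimulateExpression:
    def test_design_needs_two_replicates(self):
        with pytest.raises(ValueError):
            make_design(1)

    def test_transgene_zero_outside_rdrp_genotypes(self, tiny_genome):
        design = make_design(3)
        counts, _ = simulate_expression(tiny_genome, design, seed=3)
        tg = counts.loc["RdRp_transgene"]
        for d in design:
            if d.genotype in ("WT", "Adar_het"):
                assert tg[d.sample_id] == 0
            else:
                assert tg[d.sample_id] > 0

    def test_non_isg_flat_across_genotypes(self, rng):
        cfg = GenomeConfig(n_contigs=2, contig_length=60_000, n_genes=60,
                           isg_fraction=0.0, gene_length_range=(500, 900),
                           intergenic_gap_range=(50, 300))
        genome = generate_genome(cfg, seed=12)
        design = make_design(4)
        model = ExpressionModel(baseline_mean=500, baseline_sigma=0.0)
        counts, fold = simulate_expression(genome, design, model, seed=12)
        assert all(m == 1.0 for per in fold.values() for m in per.values())
        by_geno = {}
        for d in design:
            by_geno.setdefault(d.genotype, []).append(d.sample_id)
        means = {g: counts.loc[counts.index != "RdRp_transgene", cols].mean().mean()
                 for g, cols in by_geno.items()}
        ratios = [means[g] / means["WT"] for g in means]
        assert all(0.8 < r < 1.2 for r in ratios)

    def test_isg_tier_mean_matches_nb_expectation(self):
        # NB mean = baseline x multiplier: 10 x 400 = 4000 per sample
        cfg = GenomeConfig(n_contigs=2, contig_length=100_000, n_genes=220,
                           isg_fraction=1.0, gene_length_range=(300, 500),
                           intergenic_gap_range=(30, 120), n_exons_range=(2, 2))
        genome = generate_genome(cfg, seed=13)
        assert sum(g.is_isg for g in genome.genes) >= 200
        design = make_design(2)
        model = ExpressionModel(baseline_mean=10, baseline_sigma=0.0,
                                tier_jitter_sigma=0.0,
                                isg_tiers={"WT": 1, "Adar_het": 3,
                                           "RdRp_tg": 100, "RdRp_Adar_het": 400})
        counts, _ = simulate_expression(genome, design, model, seed=13)
        dh_cols = [d.sample_id for d in design if d.genotype == "RdRp_Adar_het"]
        isg_rows = counts.index[:200]
        mean = counts.loc[isg_rows, dh_cols].to_numpy().mean()
        assert 2_000 <= mean <= 6_000
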