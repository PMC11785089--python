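"""ISG expression tiers and the edited-ISG proportion test.

Counts are CPM-normalized and log2(x+1)-transformed, each genotype is
tested against wild type gene-by-gene (Welch + Benjamini-Hochberg), DEGs
are classified against the ISG reference list, and a conditional exact test
asks whether the double heterozygote's uniquely edited sites concentrate in
ISG transcripts.
"""

from editome_kit import (
    classify_isg_fraction,
    edited_isg_proportion_test,
    run_editome_pipeline,
    simulate_study,
    summarize_expression,
)

study = simulate_study(seed=1)
isg_genes = {g.gene_id for g in study.genome.genes if g.is_isg}

tables = summarize_expression(study.counts, study.design, isg_genes)
for genotype, tab in tables.items():
    up = tab.index[tab["is_deg"] & (tab["log2fc"] > 0)]
    summary = classify_isg_fraction(up, isg_genes, universe=study.counts.index)
    mean_fc = tab.loc[tab["is_isg"], "log2fc"].mean()
    print(f"{genotype:>14} vs WT: {summary.text} upregulated DEGs are ISGs; "
          f"mean ISG log2FC {mean_fc:+.2f}")

tg = study.counts.loc["RdRp_transgene"]
by_geno = {}
for d in study.design:
    by_geno.setdefault(d.genotype, []).append(tg[d.sample_id])
print("RdRp transgene mean counts:",
      {g: round(sum(v) / len(v)) for g, v in by_geno.items()})

snp_positions = {(s.contig, s.pos) for s in study.truth.snps}
comparison, editomes, _ = run_editome_pipeline(
    study.pileups, study.genome, snp_positions, study.design
)


def unique_annotated(genotype):
    keys = comparison.unique_sites[genotype]
    return [s for s in editomes[genotype].annotated if s.key in keys]


res = edited_isg_proportion_test(
    unique_annotated("RdRp_Adar_het"), unique_annotated("WT"), isg_genes,
    label_a="RdRp_Adar_het", label_b="WT",
)
print(f"unique genic sites in ISG vs other, double-het {res.table[0]} "
      f"vs WT {res.table[1]}: odds ratio {res.odds_ratio:.2f}, "
      f"exact p = {res.p_value:.3f}")
# ISG induction is tiered (mild with one Adar allele lost, large with the
# RdRp transgene, largest in the double het), the transgene row is expressed
# only in transgene-bearing genotypes, and — as in the underlying biology —
# the double het's unique editing is not significantly concentrated in ISGs.
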