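"""End-to-end convenience: pileups -> calls -> consensus -> comparison."""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

from .annotation import AnnotatedSite, FeatureIndex, annotate_sites
from .calling import (
    EditCall,
    Thresholds,
    call_candidate_sites,
    exclude_snps,
    orient_edits,
)
from .compare import ConsensusEditome, GenotypeComparison, build_consensus, summarize
from .genome import GenomeModel
from .synthetic import SampleDesign


def call_sample(
    pileup: pd.DataFrame,
    reference: Mapping[str, str],
    snp_positions: set[tuple[str, int]],
    index: FeatureIndex,
    thresholds: Thresholds = Thresholds(),
    sample_id: str = "",
    drop_ambiguous: bool = False,
) -> list[AnnotatedSite]:
    """One sample: threshold scan, SNP exclusion, strand orientation,
    feature/repeat annotation."""
    calls = call_candidate_sites(pileup, reference, thresholds, sample_id)
    calls = exclude_snps(calls, snp_positions)
    calls = orient_edits(calls, index)
    if drop_ambiguous:
        calls = [c for c in calls if c.transcript_strand != "ambiguous"]
    return annotate_sites(calls, index)


def run_editome_pipeline(
    pileups: Mapping[str, pd.DataFrame],
    genome: GenomeModel,
    snp_positions: set[tuple[str, int]],
    design: Sequence[SampleDesign],
    thresholds: Thresholds = Thresholds(),
    min_replicates: int | None = None,
) -> tuple[GenotypeComparison, dict[str, ConsensusEditome], dict[str, list[AnnotatedSite]]]:
    """Run the full editome comparison on per-sample pileups.

    Returns the genotype comparison (counts table, Venn partitions, unique
    sets, region distributions and the double-het/WT site ratio), the four
    consensus editomes, and the per-sample annotated call lists.
    """
    index = FeatureIndex(genome.genes, genome.repeats)
    reference = genome.sequences
    per_sample: dict[str, list[AnnotatedSite]] = {}
    for d in design:
        per_sample[d.sample_id] = call_sample(
            pileups[d.sample_id], reference, snp_positions, index, thresholds,
            d.sample_id,
        )
    by_genotype: dict[str, list[list[AnnotatedSite]]] = {}
    for d in design:
        by_genotype.setdefault(d.genotype, []).append(per_sample[d.sample_id])
    editomes = {
        g: build_consensus(g, reps, index, min_replicates)
        for g, reps in by_genotype.items()
    }
    return summarize(editomes), editomes, per_sample
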