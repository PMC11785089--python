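"""Replicate-consensus editomes and four-genotype comparison.

The consensus rule is absolute: a site counts for a genotype only if the
identical (contig, position, change) is called in every replicate of that
genotype; a gene counts if every replicate has at least one call anywhere in
the gene body, so the supporting sites may differ between replicates. Site
identity never includes the edit fraction — the comparison is of presence,
not level.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .annotation import (
    AnnotatedSite,
    CATEGORIES,
    FeatureIndex,
    region_distribution,
    repeat_distribution,
)
from .genome import REPEAT_CLASSES

SiteKey = tuple[str, int, str]  # (contig, pos, change)


def _as_key(x) -> SiteKey:
    return x if isinstance(x, tuple) else x.key


def consensus_sites(replicate_calls: Sequence[Iterable]) -> set[SiteKey]:
    """Sites present in every replicate: the n-fold set intersection.

    Accepts per-replicate collections of ``SiteKey`` tuples, ``EditCall`` or
    ``AnnotatedSite`` objects. A replicate with zero calls yields an empty
    consensus.
    """
    if len(replicate_calls) < 2:
        raise ValueError("consensus requires >= 2 replicates")
    sets = [{_as_key(c) for c in rep} for rep in replicate_calls]
    return set.intersection(*sets)


def consensus_genes(replicate_sites: Sequence[Iterable[AnnotatedSite]]) -> set[str]:
    """Genes with >= 1 genic call in every replicate (any site)."""
    if len(replicate_sites) < 2:
        raise ValueError("consensus requires >= 2 replicates")
    sets = [
        {s.gene_id for s in rep if s.gene_id is not None} for rep in replicate_sites
    ]
    return set.intersection(*sets)


@dataclass
class ConsensusEditome:
    genotype: str
    sites: set[SiteKey]
    genes: set[str]
    #: site -> (category, gene_id, repeat_class), taken from the shared
    #: annotation so it is replicate-invariant by construction
    site_annotations: dict[SiteKey, tuple[str, str | None, str | None]] = field(
        default_factory=dict
    )

    @property
    def annotated(self) -> list[AnnotatedSite]:
        from .annotation import RegionLabel
        from .calling import EditCall

        out = []
        for key in sorted(self.sites):
            contig, pos, change = key
            cat, gid, rep = self.site_annotations[key]
            call = EditCall(
                contig=contig,
                pos=pos,
                ref_base=change[0],
                change=change,
                transcript_strand="ambiguous",
                coverage=0,
                edited_reads=0,
                edit_fraction=0.0,
            )
            out.append(AnnotatedSite(call, RegionLabel(cat, gid), rep))
        return out


def build_consensus(
    genotype: str,
    replicate_sites: Sequence[Sequence[AnnotatedSite]],
    index: FeatureIndex,
    min_replicates: int | None = None,
) -> ConsensusEditome:
    """Consensus editome for one genotype from its annotated replicate calls.

    ``min_replicates`` defaults to all replicates (the all-animals rule); a
    smaller k relaxes it to presence in >= k replicates.
    """
    n = len(replicate_sites)
    if n < 2:
        raise ValueError("consensus requires >= 2 replicates")
    k = n if min_replicates is None else min_replicates
    if not 2 <= k <= n:
        raise ValueError("min_replicates must be in [2, n_replicates]")

    if k == n:
        sites = consensus_sites(replicate_sites)
        genes = consensus_genes(replicate_sites)
    else:
        site_sets = [{s.key for s in rep} for rep in replicate_sites]
        gene_sets = [
            {s.gene_id for s in rep if s.gene_id is not None}
            for rep in replicate_sites
        ]
        sites = {
            s for s in set.union(*site_sets) if sum(s in ss for ss in site_sets) >= k
        }
        genes = {
            g for g in set.union(*gene_sets) if sum(g in gs for gs in gene_sets) >= k
        }

    annotations = {}
    for contig, pos, change in sites:
        region = index.region_at(contig, pos)
        annotations[(contig, pos, change)] = (
            region.category,
            region.gene_id,
            index.repeat_class_at(contig, pos),
        )
    return ConsensusEditome(genotype, sites, genes, annotations)


# ---------------------------------------------------------------------------
# four-set Venn partition


def venn_partition(sets: Mapping[str, set]) -> dict[frozenset, set]:
    """The 2^n - 1 disjoint membership cells of n named sets.

    Each element of the union lands in exactly the cell keyed by the subset
    of set names containing it, so cell sizes sum to the union size. The
    singleton cells are the per-set unique elements.
    """
    names = list(sets)
    cells: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            cells[frozenset(combo)] = set()
    for x in set.union(*[set(s) for s in sets.values()]) if sets else set():
        members = frozenset(n for n in names if x in sets[n])
        cells[members].add(x)
    return cells


def venn_counts_frame(cells: Mapping[frozenset, set], names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for members, elems in cells.items():
        rows.append(
            {**{n: (n in members) for n in names}, "count": len(elems)}
        )
    return (
        pd.DataFrame(rows)
        .sort_values(list(names), ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# summary


@dataclass
class GenotypeComparison:
    counts_table: pd.DataFrame
    region_distributions: dict[str, dict[str, tuple[int, float | None]]]
    venn_sites: dict[frozenset, set]
    venn_genes: dict[frozenset, set]
    unique_sites: dict[str, set]
    unique_genes: dict[str, set]
    double_het_wt_site_ratio: float | None


def summarize(
    editomes: Mapping[str, ConsensusEditome],
    wt: str = "WT",
    double_het: str = "RdRp_Adar_het",
) -> GenotypeComparison:
    """Counts table, per-genotype region/repeat breakdowns, Venn partitions
    and unique sets, plus the double-het / wild-type site-count ratio."""
    if len(editomes) != 4:
        raise ValueError("expected exactly four genotypes")
    rows = []
    region_dists = {}
    for g, ed in editomes.items():
        ann = ed.annotated
        dist = region_distribution(ann)
        region_dists[g] = dist
        reps = repeat_distribution(ann)
        row = {"genotype": g, "edited_genes": len(ed.genes), "edited_sites": len(ed.sites)}
        row.update({c: dist[c][0] for c in CATEGORIES})
        row.update({c: reps[c] for c in REPEAT_CLASSES})
        rows.append(row)
    counts_table = pd.DataFrame(rows).set_index("genotype")

    venn_s = venn_partition({g: ed.sites for g, ed in editomes.items()})
    venn_g = venn_partition({g: ed.genes for g, ed in editomes.items()})
    unique_sites = {g: venn_s[frozenset([g])] for g in editomes}
    unique_genes = {g: venn_g[frozenset([g])] for g in editomes}

    n_wt = len(editomes[wt].sites) if wt in editomes else 0
    ratio = (
        len(editomes[double_het].sites) / n_wt
        if double_het in editomes and n_wt
        else None
    )
    return GenotypeComparison(
        counts_table=counts_table,
        region_distributions=region_dists,
        venn_sites=venn_s,
        venn_genes=venn_g,
        unique_sites=unique_sites,
        unique_genes=unique_genes,
        double_het_wt_site_ratio=ratio,
    )
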