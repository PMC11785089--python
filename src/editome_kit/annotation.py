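"""Attribution of edit sites to RNA elements and repeat classes.

Every site receives exactly one region category from the priority ladder
3'UTR > 5'UTR > CDS-exon > intron > intergenic, evaluated across all genes
overlapping the position, and — independently — at most one repeat class.
The two attributions are orthogonal: a site can be both 3'UTR and SINE,
which matters because retroelements concentrate in ISG 3'UTRs.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from intervaltree import IntervalTree

from .calling import EditCall
from .genome import GeneModel, REPEAT_CLASSES, RepeatInterval

CATEGORIES = ("three_prime_utr", "five_prime_utr", "exon_cds", "intron", "intergenic")
#: lower rank wins when several genes overlap a position
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}
_REPEAT_RANK = {c: i for i, c in enumerate(REPEAT_CLASSES)}


@dataclass(frozen=True)
class RegionLabel:
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.gene_id is None):
            raise ValueError("gene_id must be None iff category is intergenic")


@dataclass(frozen=True)
class AnnotatedSite:
    call: EditCall
    region: RegionLabel
    repeat_class: str | None

    @property
    def key(self) -> tuple[str, int, str]:
        return self.call.key

    @property
    def gene_id(self) -> str | None:
        return self.region.gene_id


class FeatureIndex:
    """Point-queryable interval index over genes and repeats.

    Built on one interval tree per contig; construction is order-independent
    and queries return all overlapping features.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel] = (),
        repeats: Iterable[RepeatInterval] = (),
    ) -> None:
        self._gene_trees: dict[str, IntervalTree] = {}
        self._repeat_trees: dict[str, IntervalTree] = {}
        self.genes = list(genes)
        self.repeats = list(repeats)
        for g in self.genes:
            self._gene_trees.setdefault(g.contig, IntervalTree()).addi(
                g.start, g.end, g
            )
        for r in self.repeats:
            self._repeat_trees.setdefault(r.contig, IntervalTree()).addi(
                r.start, r.end, r
            )

    def genes_at(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self._gene_trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: g.gene_id)

    def repeats_at(self, contig: str, pos: int) -> list[RepeatInterval]:
        tree = self._repeat_trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def region_at(self, contig: str, pos: int, collapse_utr5: bool = False) -> RegionLabel:
        """Single region category by the priority ladder across all genes."""
        best: tuple[int, str, str] | None = None  # (rank, gene_id, category)
        for g in self.genes_at(contig, pos):
            cat = _gene_category(g, pos)
            if collapse_utr5 and cat == "five_prime_utr":
                cat = "exon_cds"
            cand = (_PRIORITY[cat], g.gene_id, cat)
            if best is None or cand < best:
                best = cand
        if best is None:
            return RegionLabel("intergenic", None)
        return RegionLabel(best[2], best[1])

    def repeat_class_at(self, contig: str, pos: int) -> str | None:
        """Class of the smallest overlapping repeat; class-order tiebreak."""
        hits = self.repeats_at(contig, pos)
        if not hits:
            return None
        best = min(
            hits,
            key=lambda r: (r.end - r.start, _REPEAT_RANK[r.repeat_class], r.start),
        )
        return best.repeat_class


def _gene_category(gene: GeneModel, pos: int) -> str:
    for ivs, cat in (
        (gene.utr3, "three_prime_utr"),
        (gene.utr5, "five_prime_utr"),
        (gene.cds, "exon_cds"),
    ):
        for s, e in ivs:
            if s <= pos < e:
                return cat
    # inside the gene span but in no exon sub-interval
    return "intron"


def build_interval_index(
    genes: Iterable[GeneModel], repeats: Iterable[RepeatInterval]
) -> FeatureIndex:
    return FeatureIndex(genes, repeats)


def annotate_site(
    site: EditCall, index: FeatureIndex, collapse_utr5: bool = False
) -> AnnotatedSite:
    region = index.region_at(site.contig, site.pos, collapse_utr5=collapse_utr5)
    repeat = index.repeat_class_at(site.contig, site.pos)
    return AnnotatedSite(call=site, region=region, repeat_class=repeat)


def annotate_sites(
    sites: Iterable[EditCall], index: FeatureIndex, collapse_utr5: bool = False
) -> list[AnnotatedSite]:
    return [annotate_site(s, index, collapse_utr5) for s in sites]


def region_distribution(
    sites: Sequence[AnnotatedSite],
) -> dict[str, tuple[int, float | None]]:
    """Per-category (count, proportion); proportions are None on empty input
    rather than a silent 0/0."""
    counts = Counter(s.region.category for s in sites)
    total = len(sites)
    return {
        cat: (counts.get(cat, 0), counts.get(cat, 0) / total if total else None)
        for cat in CATEGORIES
    }


def repeat_distribution(
    sites: Sequence[AnnotatedSite],
) -> dict[str, int]:
    counts = Counter(s.repeat_class for s in sites if s.repeat_class is not None)
    return {cls: counts.get(cls, 0) for cls in REPEAT_CLASSES}
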