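"""Domain model for a miniature annotated genome.

Coordinates are 0-based half-open everywhere in memory; conversion to the
1-based conventions of FASTA-adjacent text formats (GFF3, VCF, pileup TSV)
happens only at file boundaries (:mod:`editome_kit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

REPEAT_CLASSES = ("LINE", "SINE", "DNA_transposon", "other_retroelement")

Interval = tuple[int, int]


def _intervals_sorted_disjoint(ivs: list[Interval]) -> bool:
    for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
        if not (s0 < e0 <= s1 < e1):
            return False
    return all(s < e for s, e in ivs)


@dataclass
class Contig:
    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with exon structure partitioned into 5'UTR / CDS / 3'UTR.

    ``exons`` are sorted, disjoint genomic intervals; ``cds``, ``utr5`` and
    ``utr3`` are sub-intervals of the exons and together partition the exonic
    span exactly. Introns are implicit: the gaps between consecutive exons.
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval]
    utr3: list[Interval]
    is_isg: bool = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons or not _intervals_sorted_disjoint(self.exons):
            raise ValueError(f"{self.gene_id}: exons must be sorted and disjoint")
        pieces = sorted(self.cds + self.utr5 + self.utr3)
        exonic = []
        for s, e in pieces:
            if exonic and exonic[-1][1] == s:
                exonic[-1] = (exonic[-1][0], e)
            else:
                exonic.append((s, e))
        if [tuple(x) for x in exonic] != [tuple(x) for x in self.exons]:
            raise ValueError(
                f"{self.gene_id}: cds/utr5/utr3 do not partition the exons"
            )


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat/retroelement interval with a class label (0-based half-open)."""

    contig: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat_class {self.repeat_class!r} not in {REPEAT_CLASSES}"
            )
        if not 0 <= self.start < self.end:
            raise ValueError("invalid repeat interval")


@dataclass
class GenomeModel:
    contigs: list[Contig]
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatInterval] = field(default_factory=list)

    @property
    def sequences(self) -> dict[str, str]:
        return {c.name: c.sequence for c in self.contigs}

    def validate(self) -> None:
        lengths = {}
        for c in self.contigs:
            if c.name in lengths:
                raise ValueError(f"duplicate contig name {c.name}")
            lengths[c.name] = len(c)
        for g in self.genes:
            g.validate()
            if g.contig not in lengths:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig}")
            if not (0 <= g.start < g.end <= lengths[g.contig]):
                raise ValueError(f"{g.gene_id}: outside contig bounds")
        for r in self.repeats:
            if r.contig not in lengths or r.end > lengths[r.contig]:
                raise ValueError(f"repeat {r} outside contig bounds")
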