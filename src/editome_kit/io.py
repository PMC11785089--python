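"""Readers and writers for the pipeline's file formats.

In-memory coordinates are 0-based half-open throughout the package; this
module is the only place where conversion to the 1-based conventions of
GFF3, VCF and the pileup/call TSVs happens. BED stays 0-based half-open.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import EditCall, PILEUP_COLUMNS
from .genome import Contig, GeneModel, GenomeModel, RepeatInterval
from .synthetic import GENOTYPES, SampleDesign, TruthSet


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: GenomeModel, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="")
        for c in genome.contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (1-based, closed intervals)


def write_gff3(genome: GenomeModel, path: str | os.PathLike) -> None:
    def row(seqid, ftype, s, e, strand, attrs):
        return "\t".join(
            [seqid, "editome_kit", ftype, str(s + 1), str(e), ".", strand, ".", attrs]
        )

    lines = ["##gff-version 3"]
    for c in genome.contigs:
        lines.append(f"##sequence-region {c.name} 1 {len(c)}")
    for g in genome.genes:
        tid = f"{g.gene_id}.t1"
        lines.append(
            row(g.contig, "gene", g.start, g.end, g.strand,
                f"ID={g.gene_id};is_isg={'true' if g.is_isg else 'false'}")
        )
        lines.append(row(g.contig, "mRNA", g.start, g.end, g.strand,
                         f"ID={tid};Parent={g.gene_id}"))
        for ftype, ivs in (
            ("exon", g.exons),
            ("CDS", g.cds),
            ("five_prime_UTR", g.utr5),
            ("three_prime_UTR", g.utr3),
        ):
            for s, e in ivs:
                lines.append(row(g.contig, ftype, s, e, g.strand, f"Parent={tid}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        def ivs(ftype):
            return sorted(
                (f.start - 1, f.end)
                for f in db.children(g, featuretype=ftype, level=2)
            )

        genes.append(
            GeneModel(
                gene_id=g.id,
                contig=g.seqid,
                strand=g.strand,
                exons=ivs("exon"),
                cds=ivs("CDS"),
                utr5=ivs("five_prime_UTR"),
                utr3=ivs("three_prime_UTR"),
                is_isg=g.attributes.get("is_isg", ["false"])[0] == "true",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# repeats BED (0-based half-open; name column = repeat class)


def write_repeats_bed(repeats: Iterable[RepeatInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.repeat_class}\n")


def read_repeats_bed(path: str | os.PathLike) -> list[RepeatInterval]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "repeat_class"],
    )
    return [
        RepeatInterval(r.contig, int(r.start), int(r.end), r.repeat_class)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# exome variants VCF v4.2 (1-based)


def write_vcf(
    truth: TruthSet,
    genome: GenomeModel,
    path: str | os.PathLike,
    line_name: str = "colony",
) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=editome_kit"]
    for c in genome.contigs:
        lines.append(f"##contig=<ID={c.name},length={len(c)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + line_name
    )
    for s in sorted(truth.snps, key=lambda s: (s.contig, s.pos)):
        gt = "0/1" if s.heterozygous else "1/1"
        lines.append(
            f"{s.contig}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_positions(path: str | os.PathLike) -> set[tuple[str, int]]:
    """SNP positions (0-based) from a VCF; position-only, allele ignored."""
    from cyvcf2 import VCF

    return {(v.CHROM, v.POS - 1) for v in VCF(str(path))}


# ---------------------------------------------------------------------------
# pileup TSV (pos 1-based on disk)


def write_pileup(pileup: pd.DataFrame, path: str | os.PathLike) -> None:
    out = pileup[PILEUP_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_pileup(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df[PILEUP_COLUMNS]


# ---------------------------------------------------------------------------
# edit-call TSV (pos 1-based on disk)

CALL_COLUMNS = [
    "contig", "pos", "ref", "change", "strand", "coverage", "edited",
    "fraction", "sample",
]


def write_calls(calls: Sequence[EditCall], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "contig": c.contig,
                "pos": c.pos + 1,
                "ref": c.ref_base,
                "change": c.change,
                "strand": c.transcript_strand,
                "coverage": c.coverage,
                "edited": c.edited_reads,
                "fraction": c.edit_fraction,
                "sample": c.sample_id,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_calls(path: str | os.PathLike) -> list[EditCall]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        EditCall(
            contig=str(r.contig),
            pos=int(r.pos) - 1,
            ref_base=str(r.ref),
            change=str(r.change),
            transcript_strand=str(r.strand),
            coverage=int(r.coverage),
            edited_reads=int(r.edited),
            edit_fraction=float(r.fraction),
            sample_id="" if pd.isna(r.sample) else str(r.sample),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# design / counts / ISG list / truth tables


def write_design(design: Sequence[SampleDesign], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {"sample_id": d.sample_id, "genotype": d.genotype, "replicate": d.replicate}
            for d in design
        ]
    ).to_csv(path, sep="\t", index=False)


def read_design(path: str | os.PathLike) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleDesign(str(r.sample_id), str(r.genotype), int(r.replicate))
        for r in df.itertuples()
    ]


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def read_isg_list(path: str | os.PathLike) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_isg_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_truth(truth: TruthSet, sites_path, snps_path) -> None:
    pd.DataFrame(
        [
            {
                "contig": s.contig,
                "pos": s.pos + 1,
                "strand": s.transcript_strand,
                "change": s.change,
                **{f"frac_{g}": s.fractions.get(g, 0.0) for g in GENOTYPES},
                "category": s.category,
                "repeat_class": s.repeat_class or ".",
            }
            for s in truth.edit_sites
        ]
    ).to_csv(sites_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "contig": s.contig,
                "pos": s.pos + 1,
                "ref": s.ref,
                "alt": s.alt,
                "het": int(s.heterozygous),
            }
            for s in truth.snps
        ]
    ).to_csv(snps_path, sep="\t", index=False)
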