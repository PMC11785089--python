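"""A-to-I edit-site calling from per-sample pileups.

A-to-I editing leaves an A→G signature in RNA reads relative to genomic DNA
(inosine is read as guanosine by sequencers and reverse transcriptases). On
the reference strand that signature is A>G for plus-strand transcripts and
T>C for minus-strand ones; no other mismatch class is ever emitted. Germline
variation is removed afterwards by subtracting exome-derived SNP positions,
so the surviving calls are RNA–DNA differences attributable to editing.
"""

from __future__ import annotations

from collections.abc import Collection, Iterable, Mapping
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

PILEUP_COLUMNS = ["contig", "pos", "ref", "A", "C", "G", "T"]

AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Thresholds:
    """Filter thresholds for candidate edit sites.

    The fraction window is half-open: ``min_edit_fraction <= f <
    max_edit_fraction``. The ceiling guards against unfiltered homozygous
    variants, which present as fraction ~1.
    """

    min_coverage: int = 10
    min_edited_reads: int = 2
    min_edit_fraction: float = 0.05
    max_edit_fraction: float = 0.95
    error_rate_assumed: float = 0.003

    def __post_init__(self) -> None:
        if not 0 <= self.min_edit_fraction < self.max_edit_fraction <= 1:
            raise ValueError("need 0 <= min_edit_fraction < max_edit_fraction <= 1")
        if not self.min_coverage >= self.min_edited_reads >= 1:
            raise ValueError("need min_coverage >= min_edited_reads >= 1")


@dataclass(frozen=True)
class EditCall:
    """One candidate A-to-I site in one sample (pos is 0-based internal)."""

    contig: str
    pos: int
    ref_base: str
    change: str  # 'A>G' or 'T>C' on the reference strand
    transcript_strand: str  # '+', '-', or 'ambiguous'
    coverage: int
    edited_reads: int
    edit_fraction: float
    sample_id: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity used for consensus and set comparison."""
        return (self.contig, self.pos, self.change)


def call_candidate_sites(
    pileup: pd.DataFrame,
    reference: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    sample_id: str = "",
) -> list[EditCall]:
    """Scan a pileup for A>G / T>C signatures passing the thresholds.

    Parameters
    ----------
    pileup
        Table with columns ``contig pos ref A C G T`` (pos 0-based).
    reference
        Contig name → sequence; every pileup ref base is checked against it
        and a mismatch raises ``ValueError`` naming the position.
    """
    if pileup.empty:
        return []
    contigs = pileup["contig"].to_numpy()
    pos = pileup["pos"].to_numpy()
    ref = pileup["ref"].to_numpy()

    for contig in np.unique(contigs):
        seq = reference[contig]
        m = contigs == contig
        expected = np.frombuffer(seq.encode(), dtype="S1")[pos[m]].astype("U1")
        bad = expected != ref[m]
        if bad.any():
            i = np.flatnonzero(bad)[0]
            p = pos[m][i]
            raise ValueError(
                f"pileup ref base {ref[m][i]!r} at {contig}:{p} disagrees with "
                f"genome base {expected[i]!r} (corrupt input)"
            )

    counts = pileup[["A", "C", "G", "T"]].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative base counts in pileup")
    coverage = counts.sum(axis=1)
    edited = np.where(ref == "A", counts[:, 2], np.where(ref == "T", counts[:, 1], 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(coverage > 0, edited / np.maximum(coverage, 1), 0.0)
    keep = (
        ((ref == "A") | (ref == "T"))
        & (edited >= thresholds.min_edited_reads)
        & (coverage >= thresholds.min_coverage)
        & (fraction >= thresholds.min_edit_fraction)
        & (fraction < thresholds.max_edit_fraction)
    )
    calls = []
    for i in np.flatnonzero(keep):
        base = ref[i]
        calls.append(
            EditCall(
                contig=str(contigs[i]),
                pos=int(pos[i]),
                ref_base=str(base),
                change="A>G" if base == "A" else "T>C",
                transcript_strand=AMBIGUOUS,
                coverage=int(coverage[i]),
                edited_reads=int(edited[i]),
                edit_fraction=float(fraction[i]),
                sample_id=sample_id,
            )
        )
    return calls


def exclude_snps(
    candidates: Iterable[EditCall],
    snp_positions: Collection[tuple[str, int]],
) -> list[EditCall]:
    """Drop calls at known germline SNP positions (position-only match).

    Matching by position alone, not allele, is the conservative reading of
    SNP exclusion: any exome-documented variant position is distrusted.
    Order is preserved; calls are not otherwise mutated.
    """
    snp_positions = set(snp_positions)
    return [c for c in candidates if (c.contig, c.pos) not in snp_positions]


def orient_edits(candidates: Iterable[EditCall], index) -> list[EditCall]:
    """Resolve transcript strand against gene annotation.

    A>G is A-to-I only on a plus-strand transcript, T>C only on a minus-strand
    one. A call whose change is consistent with at least one overlapping gene
    keeps that strand; a call lying only in genes of the inconsistent strand
    is discarded (it is not A-to-I on the transcribed strand); calls in
    unannotated space are retained with strand ``ambiguous`` so that
    intergenic editing survives.
    """
    oriented = []
    for call in candidates:
        genes = index.genes_at(call.contig, call.pos)
        if not genes:
            oriented.append(replace(call, transcript_strand=AMBIGUOUS))
            continue
        strands = {g.strand for g in genes}
        wanted = "+" if call.change == "A>G" else "-"
        if wanted in strands:
            oriented.append(replace(call, transcript_strand=wanted))
        # else: only genes of the opposite strand cover it -> discard
    return oriented
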