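"""Synthetic study generator: miniature genome, planted editome, pileups.

Emulates a four-genotype mouse study (wild type, *Adar* heterozygote, viral
RdRp transgenic, and the double heterozygote) at desk scale so that every
pipeline stage can be verified by recovering planted parameters:

* genotype-specific edit-site sets with per-site edit fractions, the double
  heterozygote carrying a configurable excess (default 1.6x the wild-type
  site count) concentrated in 3'UTRs and retroelements;
* heterozygous germline A/G (T/C) SNPs that appear both in the exome variant
  set and, at ~50% allele fraction, in every RNA pileup;
* per-base sequencing error and negative-binomial coverage with gene-level
  depth multipliers;
* a negative-binomial expression matrix with genotype-tiered ISG induction
  and an ``RdRp_transgene`` pseudo-gene row expressed only in the
  transgene-bearing genotypes.

Every stage is a pure function of (config, seed). A single top-level seed
fans out through ``numpy.random.SeedSequence(seed, spawn_key=...)`` with a
fixed spawn key per stage (genome=0, truth=1, pileups=2 — one child per
sample — expression=3), so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import CATEGORIES, FeatureIndex
from .genome import (
    Contig,
    GeneModel,
    GenomeModel,
    REPEAT_CLASSES,
    RepeatInterval,
)

GENOTYPES = ("WT", "Adar_het", "RdRp_tg", "RdRp_Adar_het")
#: genotypes carrying the viral RdRp transgene
RDRP_GENOTYPES = ("RdRp_tg", "RdRp_Adar_het")
TRANSGENE_ID = "RdRp_transgene"

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_STAGE = {"genome": 0, "truth": 1, "pileups": 2, "expression": 3}


def stage_rng(seed: int, stage: str, *sub: int) -> np.random.Generator:
    """Derive the documented per-stage generator from the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGE[stage], *sub))
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GenomeConfig:
    n_contigs: int = 2
    contig_length: int = 100_000
    n_genes: int = 40
    isg_fraction: float = 0.25
    n_repeats: int = 120
    gene_length_range: tuple[int, int] = (1_500, 4_000)
    intergenic_gap_range: tuple[int, int] = (300, 2_000)
    n_exons_range: tuple[int, int] = (2, 5)
    utr5_fraction: float = 0.10
    utr3_fraction: float = 0.30
    repeat_in_utr3_prob: float = 0.5


@dataclass(frozen=True)
class EditModel:
    """Per-genotype planted-site counts and edit-fraction distribution.

    The double-heterozygote site count is ``round(double_het_ratio *
    wt_sites)`` exactly — sites are planted, not sampled into existence — and
    its genotype-specific extras are drawn with 3'UTR- and repeat-boosted
    weights so the planted editome shifts toward 3'UTRs and retroelements.
    """

    wt_sites: int = 500
    adar_het_sites: int = 500
    rdrp_tg_sites: int = 500
    double_het_ratio: float = 1.6
    shared_core_fraction: float = 0.6
    fraction_range: tuple[float, float] = (0.2, 0.6)
    category_weights: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.35,
            "three_prime_utr": 0.30,
            "exon_cds": 0.13,
            "intron": 0.13,
            "five_prime_utr": 0.09,
        }
    )
    double_het_extra_weights: dict[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.20,
            "three_prime_utr": 0.55,
            "exon_cds": 0.10,
            "intron": 0.10,
            "five_prime_utr": 0.05,
        }
    )
    repeat_preference: float = 0.35
    double_het_repeat_preference: float = 0.65

    def site_counts(self) -> dict[str, int]:
        return {
            "WT": self.wt_sites,
            "Adar_het": self.adar_het_sites,
            "RdRp_tg": self.rdrp_tg_sites,
            "RdRp_Adar_het": int(round(self.double_het_ratio * self.wt_sites)),
        }


@dataclass(frozen=True)
class CoverageModel:
    """Negative-binomial depth: var = mu + mu^2/size; ``size=None`` forces a
    constant depth (useful for law-of-large-numbers checks)."""

    mean_depth: float = 30.0
    size: float | None = 8.0
    gene_depth_sigma: float = 0.3


@dataclass(frozen=True)
class ExpressionModel:
    baseline_mean: float = 200.0
    baseline_sigma: float = 1.0
    #: NB size; CV^2 = 1/mu + 1/size, i.e. ~0.22 biological CV between
    #: replicates, typical of inbred littermate bulk RNA-seq
    dispersion_size: float = 20.0
    #: genotype-tier ISG fold-change multipliers: mild (one Adar allele lost),
    #: large (chronic RdRp dsRNA), largest (the synergistic double het)
    isg_tiers: dict[str, float] = field(
        default_factory=lambda: {
            "WT": 1.0,
            "Adar_het": 3.0,
            "RdRp_tg": 100.0,
            "RdRp_Adar_het": 400.0,
        }
    )
    tier_jitter_sigma: float = 0.25
    transgene_mean: float = 500.0


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    genotype: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


def make_design(n_replicates: int = 4) -> list[SampleDesign]:
    """Four genotypes x n replicates (n >= 2), sample ids ``<genotype>_<i>``."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per genotype")
    return [
        SampleDesign(f"{g}_{i}", g, i)
        for g in GENOTYPES
        for i in range(1, n_replicates + 1)
    ]


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class TruthSite:
    contig: str
    pos: int  # 0-based
    transcript_strand: str  # '+', '-' or '.' (unannotated)
    change: str  # 'A>G' or 'T>C' on the reference strand
    fractions: dict[str, float]  # genotype -> edit fraction (0 = inactive)
    category: str
    repeat_class: str | None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.change)


@dataclass(frozen=True)
class TruthSnp:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    heterozygous: bool = True


@dataclass
class TruthSet:
    edit_sites: list[TruthSite]
    snps: list[TruthSnp]
    isg_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)

    def sites_for(self, genotype: str) -> list[TruthSite]:
        return [s for s in self.edit_sites if s.fractions.get(genotype, 0.0) > 0]

    @property
    def genotypes(self) -> set[str]:
        out: set[str] = set()
        for s in self.edit_sites:
            out.update(s.fractions)
        return out or set(GENOTYPES)


# ---------------------------------------------------------------------------
# genome generation


def _composition(rng, total: int, k: int, minimum: int) -> list[int]:
    """k positive parts of `total`, each >= minimum, multinomial remainder."""
    if k == 0:
        return []
    spare = total - k * minimum
    if spare < 0:
        raise ValueError("interval too small for requested parts")
    extra = rng.multinomial(spare, np.full(k, 1.0 / k))
    return [minimum + int(e) for e in extra]


_MIN_EXON, _MIN_INTRON = 80, 40


def _build_gene(rng, gene_id, contig, start, length, cfg: GenomeConfig, is_isg):
    strand = "+" if rng.random() < 0.5 else "-"
    lo, hi = cfg.n_exons_range
    n_ex = int(rng.integers(lo, hi + 1))
    while n_ex > 1 and length < n_ex * _MIN_EXON + (n_ex - 1) * _MIN_INTRON:
        n_ex -= 1
    exonic_total = max(n_ex * _MIN_EXON, int(round(length * 0.6)))
    intron_total = length - exonic_total
    if n_ex > 1 and intron_total < (n_ex - 1) * _MIN_INTRON:
        intron_total = (n_ex - 1) * _MIN_INTRON
        exonic_total = length - intron_total
    exon_lens = _composition(rng, exonic_total, n_ex, _MIN_EXON)
    intron_lens = _composition(rng, intron_total, n_ex - 1, _MIN_INTRON)

    exons = []
    cur = start
    for i, el in enumerate(exon_lens):
        exons.append((cur, cur + el))
        cur += el
        if i < len(intron_lens):
            cur += intron_lens[i]

    e_total = sum(e - s for s, e in exons)
    u5 = max(1, int(round(cfg.utr5_fraction * e_total)))
    u3 = max(1, int(round(cfg.utr3_fraction * e_total)))
    cds_len = e_total - u5 - u3
    if cds_len < 1:
        u5, u3, cds_len = 1, 1, e_total - 2
    # genomic (left-to-right) order of the transcript segments
    if strand == "+":
        seg_lens = [("utr5", u5), ("cds", cds_len), ("utr3", u3)]
    else:
        seg_lens = [("utr3", u3), ("cds", cds_len), ("utr5", u5)]
    pieces: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "utr3": []}
    it = iter(seg_lens)
    label, remaining = next(it)
    for s, e in exons:
        cur = s
        while cur < e:
            take = min(remaining, e - cur)
            if take > 0:
                pieces[label].append((cur, cur + take))
            cur += take
            remaining -= take
            if remaining == 0:
                try:
                    label, remaining = next(it)
                except StopIteration:
                    remaining = e - cur if cur < e else 1
    return GeneModel(
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=exons,
        cds=pieces["cds"],
        utr5=pieces["utr5"],
        utr3=pieces["utr3"],
        is_isg=is_isg,
    )


def generate_genome(config: GenomeConfig = GenomeConfig(), seed: int = 0) -> GenomeModel:
    """Deterministically generate the annotated miniature genome.

    Raises ``ValueError`` if the configured gene lengths cannot fit on the
    configured contigs.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if config.gene_length_range[1] > config.contig_length:
        raise ValueError(
            f"genes up to {config.gene_length_range[1]} bp cannot fit on "
            f"{config.contig_length} bp contigs"
        )
    rng = stage_rng(seed, "genome")
    contigs = [
        Contig(f"chr{i + 1}", "".join(_BASES[rng.integers(0, 4, config.contig_length)]))
        for i in range(config.n_contigs)
    ]

    n_isg = int(round(config.n_genes * config.isg_fraction))
    isg_idx = set(rng.permutation(config.n_genes)[:n_isg].tolist())

    genes: list[GeneModel] = []
    per_contig = [config.n_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_genes % config.n_contigs):
        per_contig[i] += 1
    gi = 0
    for contig, n_here in zip(contigs, per_contig):
        cursor = int(rng.integers(*config.intergenic_gap_range))
        for _ in range(n_here):
            length = int(rng.integers(*config.gene_length_range))
            if cursor + length > len(contig):
                raise ValueError(
                    f"cannot place gene of {length} bp at offset {cursor} on "
                    f"{contig.name} ({len(contig)} bp): enlarge contigs or "
                    "reduce n_genes"
                )
            genes.append(
                _build_gene(
                    rng, f"gene{gi + 1:03d}", contig.name, cursor, length,
                    config, gi in isg_idx,
                )
            )
            cursor = genes[-1].end + int(rng.integers(*config.intergenic_gap_range))
            gi += 1

    repeats: list[RepeatInterval] = []
    for ri in range(config.n_repeats):
        # guarantee every class appears when enough repeats are requested
        cls = (
            REPEAT_CLASSES[ri]
            if ri < len(REPEAT_CLASSES) and config.n_repeats >= len(REPEAT_CLASSES)
            else REPEAT_CLASSES[rng.choice(4, p=[0.3, 0.4, 0.2, 0.1])]
        )
        if genes and rng.random() < config.repeat_in_utr3_prob:
            g = genes[int(rng.integers(len(genes)))]
            s, e = g.utr3[int(rng.integers(len(g.utr3)))]
            span = e - s
            length = min(int(rng.integers(100, 400)), span)
            off = int(rng.integers(0, span - length + 1))
            repeats.append(RepeatInterval(g.contig, s + off, s + off + length, cls))
        else:
            c = contigs[int(rng.integers(len(contigs)))]
            length = int(rng.integers(150, 600))
            start = int(rng.integers(0, len(c) - length))
            repeats.append(RepeatInterval(c.name, start, start + length, cls))

    genome = GenomeModel(contigs=contigs, genes=genes, repeats=repeats)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# truth planting


def _paint_arrays(genome: GenomeModel):
    """Per-contig category / strand / repeat arrays (genes are disjoint)."""
    cat = {}
    strand = {}
    in_rep = {}
    cat_code = {c: i for i, c in enumerate(CATEGORIES)}
    for c in genome.contigs:
        cat[c.name] = np.full(len(c), cat_code["intergenic"], dtype=np.int8)
        strand[c.name] = np.full(len(c), 2, dtype=np.int8)  # 2 = unannotated
        in_rep[c.name] = np.zeros(len(c), dtype=bool)
    for g in genome.genes:
        cat[g.contig][g.start : g.end] = cat_code["intron"]
        for ivs, name in ((g.cds, "exon_cds"), (g.utr5, "five_prime_utr"), (g.utr3, "three_prime_utr")):
            for s, e in ivs:
                cat[g.contig][s:e] = cat_code[name]
        strand[g.contig][g.start : g.end] = 0 if g.strand == "+" else 1
    for r in genome.repeats:
        in_rep[r.contig][r.start : r.end] = True
    return cat, strand, in_rep


def _largest_remainder(weights: dict[str, float], total: int) -> dict[str, int]:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


class _Pools:
    """Candidate transcript-A positions, by category and repeat overlap."""

    def __init__(self, genome: GenomeModel):
        cat, strand, in_rep = _paint_arrays(genome)
        self.pools: dict[tuple[str, bool], list[tuple[str, int]]] = {}
        self.strand = strand
        for c in genome.contigs:
            seq = np.frombuffer(c.sequence.encode(), dtype="S1").astype("U1")
            plus_a = (strand[c.name] == 0) & (seq == "A")
            minus_a = (strand[c.name] == 1) & (seq == "T")
            none_at = (strand[c.name] == 2) & ((seq == "A") | (seq == "T"))
            ok = plus_a | minus_a | none_at
            for ci, cname in enumerate(CATEGORIES):
                m = ok & (cat[c.name] == ci)
                for rep_flag in (True, False):
                    mm = m & (in_rep[c.name] == rep_flag)
                    self.pools.setdefault((cname, rep_flag), []).extend(
                        (c.name, int(p)) for p in np.flatnonzero(mm)
                    )
        self.used: set[tuple[str, int]] = set()

    def available(self, category: str, rep: bool) -> list[tuple[str, int]]:
        return [p for p in self.pools.get((category, rep), []) if p not in self.used]

    def take(self, rng, category: str, rep: bool, n: int) -> list[tuple[str, int]]:
        avail = self.available(category, rep)
        n = min(n, len(avail))
        picked = [avail[i] for i in rng.choice(len(avail), size=n, replace=False)] if n else []
        self.used.update(picked)
        return picked


def _draw_sites(rng, pools: _Pools, n: int, weights: dict[str, float], repeat_pref: float):
    out: list[tuple[str, int]] = []
    per_cat = _largest_remainder(weights, n)
    for cname, k in per_cat.items():
        k_rep = int(round(repeat_pref * k))
        got = pools.take(rng, cname, True, k_rep)
        got += pools.take(rng, cname, False, k - len(got))
        if len(got) < k:  # category exhausted: spill into any remaining pool
            got += pools.take(rng, cname, True, k - len(got))
        out.extend(got)
    short = n - len(out)
    if short > 0:
        spill = [p for key in pools.pools for p in pools.available(*key)]
        if len(spill) < short:
            raise ValueError(
                f"cannot plant {n} sites: short by {short - len(spill)} "
                "candidate A positions"
            )
        picked = [spill[i] for i in rng.choice(len(spill), size=short, replace=False)]
        pools.used.update(picked)
        out.extend(picked)
    return out


def plant_truth(
    genome: GenomeModel,
    edit_model: EditModel = EditModel(),
    snp_count: int = 50,
    seed: int = 0,
) -> TruthSet:
    """Plant genotype-specific edit sites and heterozygous germline SNPs.

    A shared core (``shared_core_fraction`` of the smallest genotype count)
    is edited in all four genotypes; each genotype's remaining sites are
    genotype-specific, the double heterozygote's drawn with 3'UTR/repeat
    enrichment. No SNP position coincides with an edit site.
    """
    rng = stage_rng(seed, "truth")
    pools = _Pools(genome)
    index = FeatureIndex(genome.genes, genome.repeats)
    cat_arrays, strand_arrays, _ = _paint_arrays(genome)
    seqs = genome.sequences

    counts = edit_model.site_counts()
    core_n = int(round(edit_model.shared_core_fraction * min(counts.values())))
    core = _draw_sites(
        rng, pools, core_n, edit_model.category_weights, edit_model.repeat_preference
    )
    extras: dict[str, list[tuple[str, int]]] = {}
    for g in GENOTYPES:
        n_extra = counts[g] - core_n
        if n_extra < 0:
            raise ValueError(f"shared core larger than {g} site count")
        w = (
            edit_model.double_het_extra_weights
            if g == "RdRp_Adar_het"
            else edit_model.category_weights
        )
        pref = (
            edit_model.double_het_repeat_preference
            if g == "RdRp_Adar_het"
            else edit_model.repeat_preference
        )
        extras[g] = _draw_sites(rng, pools, n_extra, w, pref)

    lo, hi = edit_model.fraction_range

    def make_site(contig: str, pos: int, active: Iterable[str]) -> TruthSite:
        s_code = strand_arrays[contig][pos]
        base = seqs[contig][pos]
        if s_code == 0:
            strand, change = "+", "A>G"
        elif s_code == 1:
            strand, change = "-", "T>C"
        else:
            strand, change = ".", ("A>G" if base == "A" else "T>C")
        fractions = {g: 0.0 for g in GENOTYPES}
        for g in active:
            fractions[g] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        return TruthSite(
            contig=contig,
            pos=pos,
            transcript_strand=strand,
            change=change,
            fractions=fractions,
            category=CATEGORIES[cat_arrays[contig][pos]],
            repeat_class=index.repeat_class_at(contig, pos),
        )

    sites = [make_site(c, p, GENOTYPES) for c, p in core]
    for g in GENOTYPES:
        sites.extend(make_site(c, p, [g]) for c, p in extras[g])

    # heterozygous A>G / T>C germline SNPs, never colliding with edit sites
    edit_pos = {(s.contig, s.pos) for s in sites}
    snp_cands = []
    for c in genome.contigs:
        seq = np.frombuffer(c.sequence.encode(), dtype="S1").astype("U1")
        at = np.flatnonzero((seq == "A") | (seq == "T"))
        snp_cands.extend((c.name, int(p)) for p in at if (c.name, int(p)) not in edit_pos)
    if len(snp_cands) < snp_count:
        raise ValueError(
            f"cannot place {snp_count} SNPs: only {len(snp_cands)} free A/T "
            f"positions (short by {snp_count - len(snp_cands)})"
        )
    picked = [snp_cands[i] for i in rng.choice(len(snp_cands), size=snp_count, replace=False)]
    snps = []
    for contig, pos in picked:
        ref = seqs[contig][pos]
        snps.append(TruthSnp(contig, pos, ref, "G" if ref == "A" else "C"))

    return TruthSet(edit_sites=sites, snps=snps)


# ---------------------------------------------------------------------------
# pileup simulation


def _nb_counts(rng, mean: np.ndarray, size: float | None) -> np.ndarray:
    if size is None:
        return np.round(mean).astype(np.int64)
    p = size / (size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size, p)


def simulate_pileups(
    genome: GenomeModel,
    truth: TruthSet,
    design: list[SampleDesign],
    coverage_model: CoverageModel = CoverageModel(),
    error_rate: float = 0.003,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-sample pileup tables over every genomic position.

    At a planted edit site with fraction ``f`` the edited-base count is
    binomial in the realized coverage with success probability
    ``f(1-e) + (1-f)e/3``; heterozygous SNPs behave identically with
    ``f = 0.5``; elsewhere mismatches arise only from the per-base error
    ``e`` (rate ``e/3`` to each non-reference base).
    """
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if coverage_model.mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    known = truth.genotypes
    for d in design:
        if d.genotype not in known:
            raise ValueError(f"design genotype {d.genotype!r} absent from truth")

    # gene-level depth multipliers are a property of the locus, shared across
    # samples, so replicate dropout at a weak gene is consistent
    g_rng = stage_rng(seed, "pileups")
    sigma = coverage_model.gene_depth_sigma
    gene_mult = {
        g.gene_id: float(np.exp(g_rng.normal(-sigma**2 / 2, sigma))) if sigma > 0 else 1.0
        for g in genome.genes
    }
    lam: dict[str, np.ndarray] = {}
    for c in genome.contigs:
        lam[c.name] = np.full(len(c), float(coverage_model.mean_depth))
    for g in genome.genes:
        lam[g.contig][g.start : g.end] *= gene_mult[g.gene_id]

    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref_codes = {
        c.name: np.frombuffer(
            c.sequence.translate(str.maketrans("ACGT", "\0\1\2\3")).encode("latin1"),
            dtype=np.uint8,
        ).astype(np.int64)
        for c in genome.contigs
    }

    out: dict[str, pd.DataFrame] = {}
    for si, d in enumerate(design):
        rng = stage_rng(seed, "pileups", si + 1)
        frames = []
        for c in genome.contigs:
            n = len(c)
            r = ref_codes[c.name]
            alt = (r + 1) % 4  # placeholder alt for invariant positions (f=0)
            f = np.zeros(n)
            for s in truth.edit_sites:
                if s.contig != c.name:
                    continue
                frac = s.fractions.get(d.genotype, 0.0)
                if frac > 0:
                    f[s.pos] = frac
                    alt[s.pos] = base_code["G" if s.change == "A>G" else "C"]
            for snp in truth.snps:
                if snp.contig == c.name and snp.heterozygous:
                    f[snp.pos] = 0.5
                    alt[snp.pos] = base_code[snp.alt]

            cov = _nb_counts(rng, lam[c.name], coverage_model.size)
            e = error_rate
            p = np.full((4, n), e / 3)
            idx = np.arange(n)
            p[r, idx] = (1 - f) * (1 - e) + f * e / 3
            p[alt, idx] = f * (1 - e) + (1 - f) * e / 3

            counts = np.zeros((4, n), dtype=np.int64)
            remaining = cov.copy()
            acc = np.zeros(n)
            for b in range(3):
                denom = np.maximum(1.0 - acc, 1e-12)
                pb = np.clip(p[b] / denom, 0.0, 1.0)
                counts[b] = rng.binomial(remaining, pb)
                remaining -= counts[b]
                acc += p[b]
            counts[3] = remaining

            frames.append(
                pd.DataFrame(
                    {
                        "contig": c.name,
                        "pos": np.arange(n),
                        "ref": _BASES[r],
                        "A": counts[0],
                        "C": counts[1],
                        "G": counts[2],
                        "T": counts[3],
                    }
                )
            )
        out[d.sample_id] = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    genome: GenomeModel,
    design: list[SampleDesign],
    model: ExpressionModel = ExpressionModel(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Negative-binomial count matrix (genes x samples) with tiered ISG
    induction, plus the per-gene per-genotype multiplier map planted.

    The ``RdRp_transgene`` pseudo-gene row is nonzero only in the two
    transgene-bearing genotypes, at a similar level in both.
    """
    rng = stage_rng(seed, "expression")
    gene_ids = [g.gene_id for g in genome.genes]
    sigma = model.baseline_sigma
    baseline = {
        gid: model.baseline_mean * float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
        for gid in gene_ids
    }
    fold: dict[str, dict[str, float]] = {}
    for g in genome.genes:
        if g.is_isg:
            fold[g.gene_id] = {
                gt: (
                    1.0
                    if gt == "WT"
                    else model.isg_tiers[gt]
                    * float(np.exp(rng.normal(0, model.tier_jitter_sigma)))
                )
                for gt in GENOTYPES
            }
        else:
            fold[g.gene_id] = {gt: 1.0 for gt in GENOTYPES}

    data = {}
    for d in design:
        means = np.array(
            [baseline[gid] * fold[gid][d.genotype] for gid in gene_ids]
        )
        tg_mean = model.transgene_mean if d.genotype in RDRP_GENOTYPES else 0.0
        col = _nb_counts(rng, means, model.dispersion_size)
        tg = (
            int(_nb_counts(rng, np.array([tg_mean]), model.dispersion_size)[0])
            if tg_mean > 0
            else 0
        )
        data[d.sample_id] = np.append(col, tg)
    counts = pd.DataFrame(data, index=gene_ids + [TRANSGENE_ID])
    return counts, fold


# ---------------------------------------------------------------------------
# one-call study bundle


@dataclass
class StudyData:
    genome: GenomeModel
    truth: TruthSet
    design: list[SampleDesign]
    pileups: dict[str, pd.DataFrame]
    counts: pd.DataFrame


def simulate_study(
    genome_config: GenomeConfig = GenomeConfig(),
    edit_model: EditModel = EditModel(),
    coverage_model: CoverageModel = CoverageModel(),
    expression_model: ExpressionModel = ExpressionModel(),
    n_replicates: int = 4,
    snp_count: int = 50,
    error_rate: float = 0.003,
    seed: int = 0,
) -> StudyData:
    """Generate the full four-genotype study from one seed."""
    genome = generate_genome(genome_config, seed)
    truth = plant_truth(genome, edit_model, snp_count, seed)
    design = make_design(n_replicates)
    pileups = simulate_pileups(genome, truth, design, coverage_model, error_rate, seed)
    counts, fold = simulate_expression(genome, design, expression_model, seed)
    truth.isg_fold_changes = fold
    return StudyData(genome, truth, design, pileups, counts)
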