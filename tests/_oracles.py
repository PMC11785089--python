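"""Independent brute-force oracles used by the test suite.

Each function implements the relevant definition literally and naively —
per-row scans, per-element membership checks, factorial-based enumeration —
so the package's optimized paths can be checked against them.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import factorial


def brute_force_calls(pileup_df, thresholds):
    """Literal per-row threshold scan over a pileup table."""
    out = []
    for row in pileup_df.itertuples():
        cov = row.A + row.C + row.G + row.T
        if row.ref == "A":
            edited, change = row.G, "A>G"
        elif row.ref == "T":
            edited, change = row.C, "T>C"
        else:
            continue
        if cov == 0:
            continue
        frac = edited / cov
        if (
            cov >= thresholds.min_coverage
            and edited >= thresholds.min_edited_reads
            and thresholds.min_edit_fraction <= frac < thresholds.max_edit_fraction
        ):
            out.append((row.contig, row.pos, change))
    return out


def linear_scan_region(genes, pos, contig):
    """Region label by scanning every gene's every sub-interval."""
    priority = ["three_prime_utr", "five_prime_utr", "exon_cds", "intron", "intergenic"]
    candidates = []
    for g in genes:
        if g.contig != contig or not (g.start <= pos < g.end):
            continue
        cat = "intron"
        for ivs, name in (
            (g.utr3, "three_prime_utr"),
            (g.utr5, "five_prime_utr"),
            (g.cds, "exon_cds"),
        ):
            if any(s <= pos < e for s, e in ivs):
                cat = name
                break
        candidates.append((priority.index(cat), g.gene_id, cat))
    if not candidates:
        return ("intergenic", None)
    rank, gid, cat = min(candidates)
    return (cat, gid)


def linear_scan_repeat(repeats, pos, contig):
    order = ["LINE", "SINE", "DNA_transposon", "other_retroelement"]
    hits = [r for r in repeats if r.contig == contig and r.start <= pos < r.end]
    if not hits:
        return None
    best = min(hits, key=lambda r: (r.end - r.start, order.index(r.repeat_class), r.start))
    return best.repeat_class


def brute_force_venn(sets):
    """Per-element membership scan into the 2^n - 1 cells."""
    names = list(sets)
    cells = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            cells[frozenset(combo)] = set()
    union = set().union(*sets.values())
    for x in union:
        members = frozenset(n for n in names if x in sets[n])
        cells[members].add(x)
    return cells


def fisher_two_sided_exact(a, b, c, d):
    """Conditional two-sided exact p via factorial-based enumeration.

    Enumerates every table with the observed margins, computes each table's
    probability as an exact Fraction, and sums those <= the observed one.
    """

    def table_prob(a_, b_, c_, d_):
        n = a_ + b_ + c_ + d_
        return Fraction(
            factorial(a_ + b_) * factorial(c_ + d_) * factorial(a_ + c_) * factorial(b_ + d_),
            factorial(n) * factorial(a_) * factorial(b_) * factorial(c_) * factorial(d_),
        )

    r1, c1 = a + b, a + c
    n = a + b + c + d
    obs = table_prob(a, b, c, d)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        b_, c_ = r1 - x, c1 - x
        d_ = n - r1 - c_
        if min(b_, c_, d_) < 0:
            continue
        p = table_prob(x, b_, c_, d_)
        if p <= obs:
            total += p
    return float(total)
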