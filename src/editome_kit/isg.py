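"""ISG expression summaries and editing/ISG enrichment testing.

Expression is normalized per-million (length-scaled when gene lengths are
given), log2-transformed with one pseudocount, and compared between
genotypes with a Welch-type two-sample test plus Benjamini–Hochberg FDR
control. Differentially expressed genes are then classified against a
user-supplied interferon-stimulated-gene (ISG) reference list — membership
is an input, not a bundled database. A rational-arithmetic conditional
exact test asks whether a genotype's uniquely edited sites concentrate in
ISG transcripts.
"""

from __future__ import annotations

import warnings
from collections.abc import Collection, Iterable, Mapping, Sequence
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotatedSite
from .synthetic import SampleDesign


# ---------------------------------------------------------------------------
# normalization and per-gene statistics


def normalize_log(
    counts: pd.DataFrame, gene_lengths: pd.Series | None = None
) -> pd.DataFrame:
    """log2(normalized + 1): CPM, or FPKM-like when lengths are supplied.

    Raises ``ValueError`` for a sample with zero total counts, where
    per-million scaling is undefined.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total counts in sample(s): {list(zero.index)}")
    norm = counts / totals * 1e6
    if gene_lengths is not None:
        kb = gene_lengths.reindex(counts.index) / 1e3
        norm = norm.div(kb, axis=0)
    return np.log2(norm + 1)


def _genotype_means(lognorm: pd.DataFrame, design: Sequence[SampleDesign]) -> pd.DataFrame:
    groups: dict[str, list[str]] = {}
    for d in design:
        groups.setdefault(d.genotype, []).append(d.sample_id)
    return pd.DataFrame(
        {g: lognorm[samples].mean(axis=1) for g, samples in groups.items()}
    )


def fold_changes(
    lognorm: pd.DataFrame, design: Sequence[SampleDesign], wt: str = "WT"
) -> pd.DataFrame:
    """Per-gene log2 fold change vs wild type, per genotype (WT column is 0)."""
    means = _genotype_means(lognorm, design)
    if wt not in means:
        raise ValueError(f"reference genotype {wt!r} not in design")
    return means.sub(means[wt], axis=0)


def test_differential(
    lognorm: pd.DataFrame,
    design: Sequence[SampleDesign],
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Welch two-sample test per gene on log-normalized values, BH-adjusted.

    A gene with zero variance in both groups gets p = 1 when the means are
    equal (no evidence) and p = 0 when they differ (infinite t in the limit).
    """
    ga, gb = contrast
    a_cols = [d.sample_id for d in design if d.genotype == ga]
    b_cols = [d.sample_id for d in design if d.genotype == gb]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 replicates per group in the contrast")
    a = lognorm[a_cols].to_numpy()
    b = lognorm[b_cols].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": a.mean(axis=1) - b.mean(axis=1), "p": p, "q": q},
        index=lognorm.index,
    )


def summarize_expression(
    counts: pd.DataFrame,
    design: Sequence[SampleDesign],
    isg_genes: Collection[str],
    wt: str = "WT",
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    gene_lengths: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-genotype (vs WT) expression summary tables.

    Each table carries the genotype and WT mean log-normalized expression,
    log2FC, p, BH q, and the DEG flag ``|log2FC| >= fc_threshold and
    q <= q_threshold``, plus ISG membership.
    """
    lognorm = normalize_log(counts, gene_lengths)
    means = _genotype_means(lognorm, design)
    isg = set(isg_genes)
    out = {}
    for g in means.columns:
        if g == wt:
            continue
        res = test_differential(lognorm, design, (g, wt))
        res.insert(0, "mean_wt", means[wt])
        res.insert(0, "mean_expr", means[g])
        res["is_deg"] = (res["log2fc"].abs() >= fc_threshold) & (
            res["q"] <= q_threshold
        )
        res["is_isg"] = res.index.isin(isg)
        out[g] = res
    return out


# ---------------------------------------------------------------------------
# ISG classification of DEGs


@dataclass(frozen=True)
class IsgFractionSummary:
    n_deg: int
    n_deg_isg: int

    @property
    def fraction(self) -> float | None:
        return self.n_deg_isg / self.n_deg if self.n_deg else None

    @property
    def text(self) -> str:
        return f"{self.n_deg_isg} out of {self.n_deg}"


def classify_isg_fraction(
    deg_genes: Iterable[str],
    isg_genes: Collection[str],
    universe: Collection[str] | None = None,
) -> IsgFractionSummary:
    """Count DEGs that are known ISGs ('N out of M').

    If ``universe`` (the expression matrix's gene ids) shares no id with the
    ISG list, a namespace-mismatch warning is raised instead of silently
    reporting zero.
    """
    isg = set(isg_genes)
    if not isg:
        raise ValueError("ISG reference list is empty")
    if universe is not None and not isg.intersection(universe):
        warnings.warn(
            "no overlap between expression gene ids and the ISG list: "
            "likely a gene-id namespace mismatch",
            stacklevel=2,
        )
    degs = list(deg_genes)
    return IsgFractionSummary(len(degs), sum(g in isg for g in degs))


# ---------------------------------------------------------------------------
# conditional exact test on a 2x2 table


def exact_test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided conditional exact test on [[a, b], [c, d]].

    The p-value sums, over the hypergeometric support with all margins
    fixed, the probabilities of tables no more probable than the observed
    one. Numerators are compared as exact integers, so ties are handled
    without a floating-point epsilon. Returns (odds_ratio, p); the odds
    ratio ad/bc uses the Haldane 0.5 correction when any cell is zero.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    if min(a + c, b + d) == 0 or min(a + b, c + d) == 0:
        raise ValueError("degenerate margin: test undefined")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    num = sum(
        w
        for x in range(lo, hi + 1)
        if (w := comb(r1, x) * comb(r2, c1 - x)) <= obs
    )
    p = float(Fraction(num, comb(n, c1)))
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return odds, p


@dataclass(frozen=True)
class ProportionTestResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: genotype A, B
    odds_ratio: float | None
    p_value: float | None
    testable: bool
    label_a: str = "A"
    label_b: str = "B"


def edited_isg_proportion_test(
    unique_sites_a: Iterable[AnnotatedSite],
    unique_sites_b: Iterable[AnnotatedSite],
    isg_genes: Collection[str],
    label_a: str = "A",
    label_b: str = "B",
) -> ProportionTestResult:
    """Are one genotype's uniquely edited sites enriched in ISG transcripts?

    Builds the 2x2 table [in-ISG, in-other] x [genotype A, genotype B] over
    uniquely edited *genic* sites — intergenic sites have no transcript to
    classify and are excluded — and applies the conditional exact test. A
    zero margin (e.g. a genotype with no genic unique sites) is flagged
    untestable rather than forced through the test.
    """
    isg = set(isg_genes)

    def split(sites):
        in_isg = other = 0
        for s in sites:
            if s.gene_id is None:
                continue
            if s.gene_id in isg:
                in_isg += 1
            else:
                other += 1
        return in_isg, other

    a, b = split(unique_sites_a)
    c, d = split(unique_sites_b)
    table = ((a, b), (c, d))
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        return ProportionTestResult(table, None, None, False, label_a, label_b)
    odds, p = exact_test_2x2(a, b, c, d)
    return ProportionTestResult(table, odds, p, True, label_a, label_b)
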