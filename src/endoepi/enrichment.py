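"""Contingency statistics: Fisher overlap tests, pairwise Fisher families
with Benjamini-Hochberg correction, and promoter k-mer overrepresentation.

The two-sided Fisher exact p uses the probability-mass criterion (sum over
tables with the observed margins whose probability does not exceed the
observed table's), computed with exact integer arithmetic.  Each call to a
family-level function is its own multiple-testing family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust as _bh
from ._stats import fisher_exact_2x2
from .genome_io import GeneModel, GenomeSequence, promoter, reverse_complement


@dataclass(frozen=True)
class ContingencyResult:
    """One 2x2 Fisher test: table counts, odds ratio, p and (optional) q."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float | None = None

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def fisher_overlap(
    set_a: set, set_b: set, universe: set
) -> ContingencyResult:
    """Fisher exact test of the overlap of two gene sets within a universe.

    Table: a = |A and B|, b = |A only|, c = |B only|, d = |neither|.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    odds, p = fisher_exact_2x2(a, b, c, d)
    return ContingencyResult(a, b, c, d, odds, p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (input order preserved)."""
    return _bh(p_values)


def pairwise_fisher_bh(
    success_counts: Sequence[int],
    totals: Sequence[int],
    group_labels: Sequence[str],
) -> pd.DataFrame:
    """Fisher test for every unordered pair of groups on success/failure
    counts, BH-corrected across the pairs.

    Groups with zero total are flagged and excluded from testing.
    """
    if len(success_counts) != len(totals) or len(totals) != len(group_labels):
        raise ValueError("success_counts, totals and group_labels must align")
    if len(group_labels) < 2:
        raise ValueError("need at least two groups")
    usable = [i for i, t in enumerate(totals) if t > 0]
    excluded = [group_labels[i] for i in range(len(totals)) if totals[i] == 0]
    rows = []
    for i, j in itertools.combinations(usable, 2):
        a, b = int(success_counts[i]), int(totals[i] - success_counts[i])
        c, d = int(success_counts[j]), int(totals[j] - success_counts[j])
        odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {
                "group1": group_labels[i],
                "group2": group_labels[j],
                "success1": a,
                "total1": int(totals[i]),
                "success2": c,
                "total2": int(totals[j]),
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["group1", "group2", "success1", "total1", "success2", "total2",
                 "odds_ratio", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    out.attrs["excluded_groups"] = excluded
    return out


def _promoter_kmers(seq: str, k: int) -> set[str]:
    """K-mers present on either strand of a promoter (presence, not counts)."""
    found = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    found |= {reverse_complement(km) for km in found}
    return {km for km in found if "N" not in km}


def kmer_promoter_enrichment(
    target_genes: Iterable[str],
    background_genes: Iterable[str],
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    k: int = 6,
    promoter_length: int = 1000,
    min_target_with: int = 3,
) -> pd.DataFrame:
    """Overrepresentation of k-mers in target promoters versus background.

    Promoters are the 1-kb sequences upstream of the translational start.  A
    promoter counts once per k-mer regardless of occurrence number, and a
    k-mer on either strand counts as present.  Fisher tests run for every
    k-mer seen in at least ``min_target_with`` target promoters, with BH
    correction across those tested k-mers.
    """
    if k > 8:
        raise ValueError("k > 8 would enumerate too large a k-mer table")
    gene_map = {g.gene_id: g for g in genes}
    target_genes = [g for g in target_genes if g in gene_map]
    background_genes = [g for g in background_genes if g in gene_map]

    def presence(gene_ids: list[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for gid in gene_ids:
            g = gene_map[gid]
            region = promoter(g, promoter_length, genome.length(g.body.chrom))
            if region is None:
                continue
            for km in _promoter_kmers(genome.fetch(region), k):
                counts[km] = counts.get(km, 0) + 1
        return counts

    n_target = len(target_genes)
    n_background = len(background_genes)
    target_counts = presence(target_genes)
    background_counts = presence(background_genes)

    rows = []
    for km, t_with in sorted(target_counts.items()):
        if t_with < min_target_with:
            continue
        b_with = background_counts.get(km, 0)
        odds, p = fisher_exact_2x2(
            t_with, n_target - t_with, b_with, n_background - b_with
        )
        rows.append(
            {
                "kmer": km,
                "target_with": t_with,
                "target_without": n_target - t_with,
                "background_with": b_with,
                "background_without": n_background - b_with,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["kmer", "target_with", "target_without", "background_with",
                 "background_without", "odds_ratio", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values(["p", "kmer"]).reset_index(drop=True)
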