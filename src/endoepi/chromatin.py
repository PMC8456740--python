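"""Stratify genes by combinations of repressive histone marks.

Genes fall into four strata from their overlap with H3K27me3 and H3K9me2
domains (maternal-allele domains by default): K27_only, K9_only, K27_K9 and
unmarked.  A mark counts as present when the gene body's overlap fraction
with the mark's (merged) domains exceeds ``min_overlap_fraction``; the
default 0.0 means any overlap of at least one base pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_io import ChromatinDomain, GeneModel, MARKS

STATES = ("K27_only", "K9_only", "K27_K9", "unmarked")

_STATE_FROM_FLAGS = {
    (True, False): "K27_only",
    (False, True): "K9_only",
    (True, True): "K27_K9",
    (False, False): "unmarked",
}


@dataclass(frozen=True)
class ChromatinState:
    gene_id: str
    state: str
    overlap_fractions: dict[str, float]


def _domain_trees(
    domains: Iterable[ChromatinDomain], allele: str | None
) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {m: {} for m in MARKS}
    for d in domains:
        if allele is not None and d.allele != allele:
            continue
        tree = trees[d.mark].setdefault(d.region.chrom, IntervalTree())
        # half-open internally to the tree
        tree.addi(d.region.start, d.region.end + 1)
    for per_mark in trees.values():
        for tree in per_mark.values():
            tree.merge_overlaps()
    return trees


def _overlap_fraction(gene: GeneModel, trees: dict[str, IntervalTree]) -> float:
    tree = trees.get(gene.body.chrom)
    if tree is None:
        return 0.0
    total = 0
    for iv in tree.overlap(gene.body.start, gene.body.end + 1):
        total += min(iv.end - 1, gene.body.end) - max(iv.begin, gene.body.start) + 1
    return total / gene.body.length


def assign_state(
    gene: GeneModel,
    domains: Iterable[ChromatinDomain],
    min_overlap_fraction: float = 0.0,
    allele: str | None = "maternal",
) -> ChromatinState:
    """Chromatin stratum of a single gene (see module docstring)."""
    trees = _domain_trees(domains, allele)
    fracs = {mark: _overlap_fraction(gene, trees[mark]) for mark in MARKS}
    flags = (
        fracs["H3K27me3"] > min_overlap_fraction,
        fracs["H3K9me2"] > min_overlap_fraction,
    )
    return ChromatinState(gene.gene_id, _STATE_FROM_FLAGS[flags], fracs)


def state_table(
    genes: Sequence[GeneModel],
    domains: Iterable[ChromatinDomain],
    min_overlap_fraction: float = 0.0,
    allele: str | None = "maternal",
) -> pd.DataFrame:
    """Per-gene strata for many genes; the four strata partition the genes."""
    trees = _domain_trees(domains, allele)
    rows = []
    for g in genes:
        fracs = {mark: _overlap_fraction(g, trees[mark]) for mark in MARKS}
        flags = (
            fracs["H3K27me3"] > min_overlap_fraction,
            fracs["H3K9me2"] > min_overlap_fraction,
        )
        rows.append(
            (g.gene_id, _STATE_FROM_FLAGS[flags], fracs["H3K27me3"], fracs["H3K9me2"])
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "state", "frac_H3K27me3", "frac_H3K9me2"]
    )


def state_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Gene-id sets per stratum (all four keys always present)."""
    out = {s: set() for s in STATES}
    for state, grp in table.groupby("state"):
        out[str(state)] = set(grp["gene_id"])
    return out
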