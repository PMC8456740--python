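"""REF6-binding-site motif scanning and cytosine-context annotation.

The H3K27me3 demethylase REF6 binds the 8-bp motif CTCTGYTY (Y = C or T)
through its zinc fingers; CHG methylation within the site blocks binding.
This module finds motif occurrences on both strands of gene bodies and
annotates, for every motif position, whether a cytosine sits there (on either
strand) and in which bisulfite context (CG / CHG / CHH) it falls.

Motif positions are always numbered in motif orientation (position 1 is the
first C of CTCTGYTY), for minus-strand sites too, so that per-position
statistics aggregate across strands.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import GeneModel, GenomeSequence, GenomicInterval, reverse_complement

REF6_MOTIF = "CTCTGYTY"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _check_iupac(motif: str) -> str:
    motif = motif.upper()
    for i, letter in enumerate(motif):
        if letter not in IUPAC:
            raise ValueError(f"non-IUPAC letter {letter!r} at motif position {i + 1}")
    return motif


def iupac_to_regex(motif: str) -> str:
    """Translate an IUPAC motif into a character-class regex."""
    motif = _check_iupac(motif)
    parts = []
    for letter in motif:
        bases = IUPAC[letter]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def iupac_reverse_complement(motif: str) -> str:
    return _check_iupac(motif).translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CytosinePositionAnnotation:
    """Cytosine status of one motif position.

    ``cytosine_strand`` is the genomic strand carrying the cytosine ("+"/"-"),
    or None when the motif-orientation base is neither C nor G.  ``context``
    is "CG", "CHG", "CHH", None (no cytosine) or "undetermined" (flanking
    sequence missing or ambiguous at a chromosome edge / N run).
    """

    motif_position: int
    genomic_coord: int
    cytosine_strand: str | None
    context: str | None


@dataclass(frozen=True)
class MotifSite:
    """One motif occurrence within (at most) one gene body."""

    gene_id: str | None
    region: GenomicInterval
    strand: str
    matched_seq: str
    position_annotations: tuple[CytosinePositionAnnotation, ...] = ()

    def annotation(self, motif_position: int) -> CytosinePositionAnnotation:
        return self.position_annotations[motif_position - 1]

    @property
    def site_id(self) -> str:
        return f"{self.region.chrom}:{self.region.start}-{self.region.end}({self.strand})"


def cytosine_context(genome: GenomeSequence, chrom: str, pos: int, strand: str) -> str:
    """Bisulfite context of the cytosine at (chrom, pos, strand).

    Read 5'->3' on the cytosine's strand: CG if the next base is G; CHG if the
    next base is H (A/C/T) and the one after is G; CHH if both following bases
    are H; "undetermined" when the required flanking bases run off the
    chromosome or contain N.
    """
    if genome.base(chrom, pos, strand) != "C":
        raise ValueError(f"base at {chrom}:{pos}({strand}) is not C on that strand")
    step = 1 if strand == "+" else -1
    length = genome.length(chrom)

    def base_at(offset: int) -> str | None:
        p = pos + step * offset
        if not 1 <= p <= length:
            return None
        return genome.base(chrom, p, strand)

    n1 = base_at(1)
    if n1 is None or n1 == "N":
        return "undetermined"
    if n1 == "G":
        return "CG"
    n2 = base_at(2)
    if n2 is None or n2 == "N":
        return "undetermined"
    return "CHG" if n2 == "G" else "CHH"


def scan_motif(
    genome: GenomeSequence,
    genes: Sequence[GeneModel] | None,
    motif: str = REF6_MOTIF,
) -> list[MotifSite]:
    """All motif occurrences (both strands) lying entirely within gene bodies.

    With ``genes=None`` whole chromosomes are scanned instead (gene_id None).
    Minus-strand matches are reported with plus-strand coordinates of the
    covered interval; ``matched_seq`` is always in motif orientation.
    Overlapping occurrences are all reported; a site inside two overlapping
    genes yields one record per gene.
    """
    motif = _check_iupac(motif)
    fwd = re.compile(f"(?=({iupac_to_regex(motif)}))")
    rev = re.compile(f"(?=({iupac_to_regex(iupac_reverse_complement(motif))}))")
    k = len(motif)

    regions: list[tuple[str | None, str, int, int]]
    if genes is None:
        regions = [(None, c, 1, genome.length(c)) for c in genome.chrom_names]
    else:
        regions = [(g.gene_id, g.body.chrom, g.body.start, g.body.end) for g in genes]

    sites: list[MotifSite] = []
    seen: set[tuple[str | None, str, int, str]] = set()
    for gene_id, chrom, start, end in regions:
        seq = genome[chrom][start - 1 : end]
        for m in fwd.finditer(seq):
            gstart = start + m.start()
            key = (gene_id, chrom, gstart, "+")
            if key in seen:
                continue
            seen.add(key)
            sites.append(
                MotifSite(
                    gene_id,
                    GenomicInterval(chrom, gstart, gstart + k - 1, "+"),
                    "+",
                    m.group(1),
                )
            )
        for m in rev.finditer(seq):
            gstart = start + m.start()
            key = (gene_id, chrom, gstart, "-")
            if key in seen:
                continue
            seen.add(key)
            sites.append(
                MotifSite(
                    gene_id,
                    GenomicInterval(chrom, gstart, gstart + k - 1, "-"),
                    "-",
                    reverse_complement(m.group(1)),
                )
            )
    sites.sort(key=lambda s: (s.region.chrom, s.region.start, s.strand, s.gene_id or ""))
    return sites


def annotate_site_positions(site: MotifSite, genome: GenomeSequence) -> MotifSite:
    """Fill per-position cytosine annotations of a scanned site.

    In motif orientation, a C at position i is a cytosine on the site's own
    strand; a G is a cytosine on the opposite strand at the same genomic
    coordinate; any other base carries no cytosine.
    """
    k = site.region.length
    annos: list[CytosinePositionAnnotation] = []
    for i in range(1, k + 1):
        if site.strand == "+":
            coord = site.region.start + (i - 1)
        else:
            coord = site.region.end - (i - 1)
        base = site.matched_seq[i - 1]
        if base == "C":
            cstrand = site.strand
        elif base == "G":
            cstrand = "-" if site.strand == "+" else "+"
        else:
            annos.append(CytosinePositionAnnotation(i, coord, None, None))
            continue
        ctx = cytosine_context(genome, site.region.chrom, coord, cstrand)
        annos.append(CytosinePositionAnnotation(i, coord, cstrand, ctx))
    return MotifSite(
        site.gene_id, site.region, site.strand, site.matched_seq, tuple(annos)
    )


def chg_capable_positions(motif: str = REF6_MOTIF) -> set[int]:
    """Motif positions at which some realization + flanking places a cytosine
    (either strand) in CHG context.

    For CTCTGYTY these are positions 3, 5 and 8: position 3 (C-T-G on the
    sense strand), position 5 (the G is a cytosine on the antisense strand
    read C-A-G) and position 8 (a terminal Y=C whose context depends on the
    two downstream flanking bases).
    """
    motif = _check_iupac(motif)
    k = len(motif)
    capable: set[int] = set()
    for realization in itertools.product(*(IUPAC[c] for c in motif)):
        for i in range(k):  # 0-based position
            base = realization[i]
            if base == "C":
                # sense-strand cytosine: next two bases 5'->3' downstream
                n1 = {realization[i + 1]} if i + 1 < k else set("ACGT")
                n2 = {realization[i + 2]} if i + 2 < k else set("ACGT")
                if n1 & set("ACT") and "G" in n2:
                    capable.add(i + 1)
            elif base == "G":
                # antisense cytosine: next two bases on "-" are the
                # complements of the two bases immediately upstream
                p1 = {realization[i - 1]} if i - 1 >= 0 else set("ACGT")
                p2 = {realization[i - 2]} if i - 2 >= 0 else set("ACGT")
                if p1 & set("TGA") and "C" in p2:
                    capable.add(i + 1)
    return capable


def sites_to_frame(sites: Iterable[MotifSite]) -> pd.DataFrame:
    """One row per (site, motif position) annotation."""
    rows = []
    for s in sites:
        for a in s.position_annotations:
            rows.append(
                {
                    "gene_id": s.gene_id,
                    "chrom": s.region.chrom,
                    "site_start": s.region.start,
                    "site_end": s.region.end,
                    "site_strand": s.strand,
                    "matched_seq": s.matched_seq,
                    "motif_position": a.motif_position,
                    "genomic_coord": a.genomic_coord,
                    "cytosine_strand": a.cytosine_strand,
                    "context": a.context,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "site_start", "site_end", "site_strand",
            "matched_seq", "motif_position", "genomic_coord",
            "cytosine_strand", "context",
        ],
    )


def write_sites_bed(sites: Sequence[MotifSite], path) -> None:
    """Export sites as BED6, name = gene_id:start (motif orientation strand)."""
    from .genome_io import write_bed

    names = [f"{s.gene_id or 'intergenic'}:{s.region.start}" for s in sites]
    write_bed([s.region for s in sites], path, names=names)
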