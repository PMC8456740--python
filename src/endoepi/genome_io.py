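"""Genome sequence, annotation and interval I/O.

All coordinates inside the package are 1-based inclusive, matching GFF3 and
per-cytosine methylation reports.  BED (0-based half-open) is converted at the
read/write boundary and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MARKS = ("H3K27me3", "H3K9me2")
ALLELES = ("maternal", "paternal", "unphased")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (uppercase)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval.

    ``strand`` is "+", "-" or "." (unstranded).  Zero- or negative-length
    intervals are invalid.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class GeneModel:
    """A gene: its full annotated body plus the translation start used for
    promoter extraction."""

    gene_id: str
    body: GenomicInterval
    translation_start: int

    def __post_init__(self) -> None:
        if not self.body.contains(self.translation_start):
            raise ValueError(
                f"gene {self.gene_id}: translation_start {self.translation_start} "
                f"outside body {self.body.start}-{self.body.end}"
            )

    @property
    def strand(self) -> str:
        return self.body.strand


@dataclass(frozen=True)
class ChromatinDomain:
    """An interval covered by a repressive histone mark on a given allele."""

    region: GenomicInterval
    mark: str
    allele: str = "maternal"

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        if self.allele not in ALLELES:
            raise ValueError(f"unknown allele {self.allele!r}; expected one of {ALLELES}")


class GenomeSequence:
    """Uppercase DNA sequences keyed by chromosome name, 1-based lookup."""

    def __init__(self, sequences: dict[str, str]):
        for name, seq in sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, b in enumerate(seq) if b in bad)
                raise ValueError(
                    f"chromosome {name}: invalid base {seq[pos]!r} at position {pos + 1}"
                )
        self._seqs = dict(sequences)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base(self, chrom: str, pos: int, strand: str = "+") -> str:
        """Base at 1-based ``pos``; complemented when strand is "-"."""
        seq = self._seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"{chrom}:{pos} out of range 1..{len(seq)}")
        b = seq[pos - 1]
        return b.translate(COMPLEMENT) if strand == "-" else b

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval, reverse-complemented for "-" strand."""
        seq = self._seqs[interval.chrom]
        if interval.end > len(seq):
            raise IndexError(
                f"{interval.chrom}:{interval.start}-{interval.end} beyond length {len(seq)}"
            )
        sub = seq[interval.start - 1 : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (sequences uppercased).

    Duplicate headers and empty files are errors; any letter outside
    A/C/G/T/N is rejected with its position.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA header: {record.id}")
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3.

    The gene body is the full annotated gene interval.  The translation start
    is the strand-appropriate end of the first CDS when CDS features are
    present, otherwise the 5' end of the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise ValueError(f"gene feature at {feat.seqid}:{feat.start} has no ID")
        gene_id = feat.attributes["ID"][0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene ID {gene_id}")
        seen.add(gene_id)
        if feat.end < feat.start:
            raise ValueError(f"gene {gene_id}: end < start")
        body = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        cds = list(db.children(feat, featuretype="CDS"))
        if cds:
            if feat.strand == "-":
                ts = max(c.end for c in cds)
            else:
                ts = min(c.start for c in cds)
        else:
            ts = feat.end if feat.strand == "-" else feat.start
        genes.append(GeneModel(gene_id, body, ts))
    return genes


def write_gff_genes(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            b = g.body
            fh.write(
                f"{b.chrom}\tendoepi\tgene\t{b.start}\t{b.end}\t.\t{b.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_bed, end_bed = fields[0], int(fields[1]), int(fields[2])
            if start_bed < 0:
                raise ValueError(f"{path}:{lineno}: negative BED coordinate")
            if end_bed <= start_bed:
                raise ValueError(f"{path}:{lineno}: zero- or negative-length BED interval")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start_bed + 1, end_bed, strand))
    return out


def read_bed_domains(
    path: str | os.PathLike, mark: str, allele: str = "maternal"
) -> list[ChromatinDomain]:
    """Read a chromatin-mark BED file as domains of one mark on one allele."""
    return [ChromatinDomain(iv, mark, allele) for iv in read_bed_intervals(path)]


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | os.PathLike,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED6 (name/score columns filled as needed)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{strand}\n")


def promoter(
    gene: GeneModel, length: int = 1000, chrom_length: int | None = None
) -> GenomicInterval | None:
    """Up to ``length`` bp immediately 5' of the translation start.

    Truncated at the chromosome edge; returns None when no upstream base
    exists at all.
    """
    ts = gene.translation_start
    if gene.strand == "-":
        start = ts + 1
        end = ts + length
        if chrom_length is not None:
            end = min(end, chrom_length)
        if start > end:
            return None
        return GenomicInterval(gene.body.chrom, start, end, "-")
    start = max(1, ts - length)
    end = ts - 1
    if start > end:
        return None
    return GenomicInterval(gene.body.chrom, start, end, "+")


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabular view of gene models (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.body.chrom for g in genes],
            "start": [g.body.start for g in genes],
            "end": [g.body.end for g in genes],
            "strand": [g.strand for g in genes],
            "translation_start": [g.translation_start for g in genes],
        }
    )
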