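"""Per-cytosine bisulfite methylation: call rules and aggregation.

A methylome is a pandas DataFrame with one row per cytosine per replicate
(columns: chrom, pos, strand, context, count_methylated, count_total,
sample_id, replicate, allele).  Two call rules are supported:

* two-replicate rule: a site is methylated when every replicate has at least
  ``min_cov`` (default 5) reads and every replicate carries at least one
  methylated read; undetermined when any replicate is below coverage.
* pooled rule: replicate counts are summed first; methylated when the pool
  has at least ``min_cov`` reads and at least one methylated read.

Aggregation maps calls to REF6-binding-site CHG-methylation status (any
methylated CHG cytosine within the 8-bp site makes the site methylated),
per-motif-position counts, region-level read-weighted methylation (with the
>0.04 presence cut for gene-body CHG methylation), and 2-kb flank profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval
from .motifs import MotifSite

CONTEXTS = ("CG", "CHG", "CHH")

METHYLOME_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "count_methylated", "count_total",
    "sample_id", "replicate", "allele",
]

CHGM_PRESENCE_CUT = 0.04


@dataclass(frozen=True)
class CytosineRecord:
    """Bisulfite counts for one cytosine in one replicate."""

    chrom: str
    pos: int
    strand: str
    context: str
    count_methylated: int
    count_total: int
    sample_id: str = "sample"
    replicate: int = 1
    allele: str = "unphased"

    def __post_init__(self) -> None:
        if self.count_methylated > self.count_total:
            raise ValueError(
                f"{self.chrom}:{self.pos}: methylated reads exceed total reads"
            )
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class MethylationCall:
    """Three-state call with the per-replicate counts that support it."""

    status: str  # methylated | unmethylated | undetermined
    supporting: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class MethylationLevel:
    """Read-weighted methylation of one region in one context.

    ``level`` is sum(methylated) / sum(total) over covered cytosines, NaN when
    no cytosine of the context has coverage (undefined, never silently 0).
    """

    region: GenomicInterval
    context: str
    level: float
    covered_cytosines: int

    @property
    def defined(self) -> bool:
        return self.covered_cytosines > 0

    def classify(self, cut: float = CHGM_PRESENCE_CUT) -> str:
        """Presence call for gene-body CHG methylation: > cut is "present"."""
        if not self.defined:
            return "undefined"
        return "present" if self.level > cut else "absent"


def _counts(records) -> tuple[int, int]:
    """Sum (methylated, total) over records given as tuples or CytosineRecord."""
    if isinstance(records, (tuple, list)) and len(records) == 2 and all(
        isinstance(v, (int, np.integer)) for v in records
    ):
        records = [records]
    m = t = 0
    pos_seen = set()
    for r in records:
        if isinstance(r, CytosineRecord):
            pos_seen.add((r.chrom, r.pos, r.strand))
            m += r.count_methylated
            t += r.count_total
        else:
            rm, rt = r
            m += int(rm)
            t += int(rt)
    if len(pos_seen) > 1:
        raise ValueError(f"records refer to different positions: {sorted(pos_seen)}")
    if m > t:
        raise ValueError("methylated reads exceed total reads")
    return m, t


def call_site_two_replicates(records_rep1, records_rep2, min_cov: int = 5) -> MethylationCall:
    """Two-replicate call for one cytosine (see module docstring)."""
    m1, t1 = _counts(records_rep1)
    m2, t2 = _counts(records_rep2)
    supporting = ((m1, t1), (m2, t2))
    if t1 < min_cov or t2 < min_cov:
        return MethylationCall("undetermined", supporting)
    if m1 >= 1 and m2 >= 1:
        return MethylationCall("methylated", supporting)
    return MethylationCall("unmethylated", supporting)


def call_site_pooled(records_all_reps, min_cov: int = 5) -> MethylationCall:
    """Pooled-replicate call for one cytosine (see module docstring)."""
    m, t = _counts(records_all_reps)
    supporting = ((m, t),)
    if t < min_cov:
        return MethylationCall("undetermined", supporting)
    if m >= 1:
        return MethylationCall("methylated", supporting)
    return MethylationCall("unmethylated", supporting)


def _filter_allele(methylome: pd.DataFrame, allele: str | None) -> pd.DataFrame:
    if allele is None:
        return methylome
    return methylome[methylome["allele"] == allele]


def call_positions(
    methylome: pd.DataFrame,
    positions: pd.DataFrame,
    rule: str = "two_replicates",
    min_cov: int = 5,
    allele: str | None = None,
) -> pd.DataFrame:
    """Vectorised calls for a table of cytosine positions.

    ``positions`` needs columns chrom/pos/strand; the result carries those
    plus ``status``.  Positions absent from the methylome are undetermined.
    """
    if rule not in ("two_replicates", "pooled"):
        raise ValueError(f"unknown rule {rule!r}")
    sub = _filter_allele(methylome, allele)
    pos = positions[["chrom", "pos", "strand"]].drop_duplicates().reset_index(drop=True)
    pos["_key"] = np.arange(len(pos))
    merged = pos.merge(sub, on=["chrom", "pos", "strand"], how="left")
    merged["count_methylated"] = merged["count_methylated"].fillna(0)
    merged["count_total"] = merged["count_total"].fillna(0)

    if rule == "pooled":
        agg = merged.groupby("_key")[["count_methylated", "count_total"]].sum()
        status = np.where(
            agg["count_total"] < min_cov,
            "undetermined",
            np.where(agg["count_methylated"] >= 1, "methylated", "unmethylated"),
        )
    else:
        replicates = sorted(sub["replicate"].dropna().unique())
        n_reps = max(len(replicates), 1)
        per_rep = merged.groupby(["_key", "replicate"])[
            ["count_methylated", "count_total"]
        ].sum()
        ok_cov = (per_rep["count_total"] >= min_cov).groupby(level="_key").sum()
        ok_meth = (
            ((per_rep["count_total"] >= min_cov) & (per_rep["count_methylated"] >= 1))
            .groupby(level="_key")
            .sum()
        )
        ok_cov = ok_cov.reindex(pos["_key"], fill_value=0)
        ok_meth = ok_meth.reindex(pos["_key"], fill_value=0)
        status = np.where(
            ok_cov < n_reps,
            "undetermined",
            np.where(ok_meth == n_reps, "methylated", "unmethylated"),
        )
        agg = None
    out = pos.drop(columns="_key").copy()
    out["status"] = status
    return out


def refbs_chgm_status(
    site: MotifSite,
    methylome: pd.DataFrame,
    rule: str = "two_replicates",
    min_cov: int = 5,
    allele: str | None = None,
) -> str:
    """CHG-methylation status of one annotated REF6-binding site.

    Methylated if any CHG-context cytosine in the site is called methylated;
    unmethylated if at least one CHG cytosine has a determinate call and all
    determinate calls are unmethylated; undetermined otherwise.  Undetermined
    per-cytosine calls are treated as absent evidence, never as methylation.
    """
    table = sites_chgm_status([site], methylome, rule=rule, min_cov=min_cov, allele=allele)
    return str(table["status"].iloc[0])


def _site_chg_positions(sites: Sequence[MotifSite]) -> pd.DataFrame:
    rows = []
    for idx, s in enumerate(sites):
        if not s.position_annotations:
            raise ValueError(f"site {s.site_id} has no position annotations")
        for a in s.position_annotations:
            if a.context == "CHG":
                rows.append(
                    (idx, s.gene_id, s.site_id, a.motif_position,
                     s.region.chrom, a.genomic_coord, a.cytosine_strand)
                )
    return pd.DataFrame(
        rows,
        columns=["site_index", "gene_id", "site_id", "motif_position",
                 "chrom", "pos", "strand"],
    )


def sites_chgm_status(
    sites: Sequence[MotifSite],
    methylome: pd.DataFrame,
    rule: str = "two_replicates",
    min_cov: int = 5,
    allele: str | None = None,
) -> pd.DataFrame:
    """Per-site CHG-methylation status for many annotated sites at once."""
    base = pd.DataFrame(
        {
            "site_index": np.arange(len(sites)),
            "gene_id": [s.gene_id for s in sites],
            "site_id": [s.site_id for s in sites],
        }
    )
    chg = _site_chg_positions(sites)
    if chg.empty:
        base["status"] = "undetermined"
        return base
    calls = call_positions(methylome, chg, rule=rule, min_cov=min_cov, allele=allele)
    chg = chg.merge(calls, on=["chrom", "pos", "strand"], how="left")
    per_site = chg.groupby("site_index")["status"].agg(
        lambda s: "methylated"
        if (s == "methylated").any()
        else ("unmethylated" if (s == "unmethylated").any() else "undetermined")
    )
    base["status"] = base["site_index"].map(per_site).fillna("undetermined")
    return base


def position_chgm_table(
    sites: Sequence[MotifSite],
    methylome: pd.DataFrame,
    rule: str = "two_replicates",
    min_cov: int = 5,
    allele: str | None = None,
    motif_length: int = 8,
) -> pd.DataFrame:
    """Per-motif-position CHG-methylation counts across sites.

    numerator = sites whose CHG cytosine at that position is called
    methylated; denominator = sites with a determinate call there.  Positions
    without CHG capability report a zero denominator.
    """
    out = pd.DataFrame(
        {
            "motif_position": np.arange(1, motif_length + 1),
            "n_methylated": 0,
            "n_determinate": 0,
        }
    ).set_index("motif_position")
    if sites:
        chg = _site_chg_positions(sites)
        if not chg.empty:
            calls = call_positions(methylome, chg, rule=rule, min_cov=min_cov, allele=allele)
            chg = chg.merge(calls, on=["chrom", "pos", "strand"], how="left")
            grp = chg.groupby("motif_position")["status"]
            meth = grp.apply(lambda s: int((s == "methylated").sum()))
            det = grp.apply(lambda s: int((s != "undetermined").sum()))
            out.loc[meth.index, "n_methylated"] = meth
            out.loc[det.index, "n_determinate"] = det
    out = out.reset_index()
    with np.errstate(invalid="ignore"):
        out["fraction_methylated"] = np.where(
            out["n_determinate"] > 0, out["n_methylated"] / out["n_determinate"], np.nan
        )
    return out


def region_methylation_level(
    region: GenomicInterval,
    methylome: pd.DataFrame,
    context: str,
    allele: str | None = None,
) -> MethylationLevel:
    """Read-weighted methylation level of a region (replicates pooled)."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sub = _filter_allele(methylome, allele)
    sub = sub[
        (sub["chrom"] == region.chrom)
        & (sub["context"] == context)
        & (sub["pos"] >= region.start)
        & (sub["pos"] <= region.end)
    ]
    total = int(sub["count_total"].sum())
    meth = int(sub["count_methylated"].sum())
    covered = int(
        sub.loc[sub["count_total"] > 0, ["pos", "strand"]].drop_duplicates().shape[0]
    )
    level = meth / total if total > 0 else float("nan")
    return MethylationLevel(region, context, level, covered)


def gene_body_levels(
    genes: Sequence[GeneModel],
    methylome: pd.DataFrame,
    context: str = "CHG",
    allele: str | None = None,
    cut: float = CHGM_PRESENCE_CUT,
) -> pd.DataFrame:
    """Gene-body methylation level and presence call for every gene."""
    sub = _filter_allele(methylome, allele)
    sub = sub[sub["context"] == context]
    rows = []
    for chrom, chrom_df in sub.groupby("chrom"):
        chrom_df = chrom_df.sort_values("pos")
        pos = chrom_df["pos"].to_numpy()
        m = chrom_df["count_methylated"].to_numpy()
        t = chrom_df["count_total"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(m)])
        ct = np.concatenate([[0], np.cumsum(t)])
        for g in genes:
            if g.body.chrom != chrom:
                continue
            lo = np.searchsorted(pos, g.body.start, side="left")
            hi = np.searchsorted(pos, g.body.end, side="right")
            tm, tt = int(cm[hi] - cm[lo]), int(ct[hi] - ct[lo])
            level = tm / tt if tt > 0 else np.nan
            rows.append((g.gene_id, level, tt))
    covered_chroms = {c for c, _ in sub.groupby("chrom")}
    for g in genes:
        if g.body.chrom not in covered_chroms:
            rows.append((g.gene_id, np.nan, 0))
    out = pd.DataFrame(rows, columns=["gene_id", "level", "total_reads"])
    out["presence"] = np.where(
        out["total_reads"] == 0, "undefined",
        np.where(out["level"] > cut, "present", "absent"),
    )
    return out


def flank_profile(
    gene: GeneModel,
    methylome: pd.DataFrame,
    context: str,
    allele: str | None = None,
    flank: int = 2000,
    bins: int = 20,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Binned methylation along upstream flank / gene body / downstream flank.

    Flanks are fixed ``flank`` bp in genomic distance; the gene body is
    rescaled to ``bins`` bins.  Bins are ordered 5'->3' relative to the gene,
    so the first upstream bin is the farthest from the gene.  Flanks
    truncated at chromosome edges contribute empty (NaN) bins.
    """
    sub = _filter_allele(methylome, allele)
    sub = sub[(sub["context"] == context) & (sub["chrom"] == gene.body.chrom)]
    sub = sub.sort_values("pos")
    pos = sub["pos"].to_numpy()
    m = sub["count_methylated"].to_numpy()
    t = sub["count_total"].to_numpy()

    def bin_levels(start: int, end: int, n_bins: int) -> list[tuple[float, int]]:
        # genomic [start, end] split into n_bins left-to-right bins
        edges = np.linspace(start, end + 1, n_bins + 1)
        out = []
        for i in range(n_bins):
            lo = np.searchsorted(pos, edges[i], side="left")
            hi = np.searchsorted(pos, edges[i + 1], side="left")
            tm, tt = int(m[lo:hi].sum()), int(t[lo:hi].sum())
            out.append((tm / tt if tt else np.nan, tt))
        return out

    body = gene.body
    length = chrom_length
    up_start, up_end = body.start - flank, body.start - 1
    dn_start, dn_end = body.end + 1, body.end + flank
    up_start = max(1, up_start)
    if length is not None:
        dn_end = min(length, dn_end)

    segments: list[tuple[str, list[tuple[float, int]]]] = []
    up = bin_levels(up_start, up_end, bins) if up_start <= up_end else [(np.nan, 0)] * bins
    dn = bin_levels(dn_start, dn_end, bins) if dn_start <= dn_end else [(np.nan, 0)] * bins
    bd = bin_levels(body.start, body.end, bins)
    if gene.strand == "-":
        up, dn = dn[::-1], up[::-1]
        bd = bd[::-1]
    segments = [("upstream", up), ("body", bd), ("downstream", dn)]

    rows = []
    for seg, vals in segments:
        for i, (level, total) in enumerate(vals, 1):
            rows.append((gene.gene_id, seg, i, level, total))
    return pd.DataFrame(
        rows, columns=["gene_id", "segment", "bin", "level", "total_reads"]
    )


def read_cx_report(path) -> pd.DataFrame:
    """Read a CX-report-style TSV into a methylome frame.

    Required columns: chrom, pos, strand, count_methylated, count_unmethylated,
    context.  Optional: sample_id, replicate, allele (defaulted when absent).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(f"{path}: invalid context values {df.loc[bad, 'context'].unique()}")
    out = df.copy()
    out["count_total"] = out["count_methylated"] + out["count_unmethylated"]
    if "sample_id" not in out:
        out["sample_id"] = "sample"
    if "replicate" not in out:
        out["replicate"] = 1
    if "allele" not in out:
        out["allele"] = "unphased"
    return out[METHYLOME_COLUMNS]


def write_cx_report(methylome: pd.DataFrame, path) -> None:
    out = methylome.copy()
    out["count_unmethylated"] = out["count_total"] - out["count_methylated"]
    cols = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated",
            "context", "sample_id", "replicate", "allele"]
    out[cols].to_csv(path, sep="\t", index=False)
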