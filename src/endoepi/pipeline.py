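"""End-to-end analyses combining the stage modules.

Three orchestrated analyses mirror the study designs the package exists for:

* CHG methylation of REF6-binding sites across chromatin strata
  (:func:`run_site_methylation_analysis`): per-stratum percentage of
  methylated sites, per-motif-position methylation, and activation during
  germination stratified by site methylation.
* Parent-of-origin bias (:func:`run_allelic_bias_analysis`): maternal
  expression ratios per (stratum x site methylation x condition) against the
  all-genes background.
* DE overlay (:func:`run_de_overlay`): enrichment of each (stratum x site
  methylation) category among up- and downregulated genes.

Every run returns a plain dict of DataFrames plus the fully resolved
configuration, and is deterministic given its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .allelic import add_ratios, group_bias_test, min_coverage_filter
from .chromatin import STATES, state_table
from .enrichment import fisher_exact_2x2, pairwise_fisher_bh
from .genome_io import ChromatinDomain, GeneModel, GenomeSequence
from .methylome import position_chgm_table, sites_chgm_status
from .motifs import MotifSite, annotate_site_positions, scan_motif


@dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds, with the standard defaults baked in."""

    min_cov: int = 5
    call_rule: str = "two_replicates"
    chgm_cut: float = 0.04
    log2fc_cut: float = 1.0
    alpha: float = 0.05
    promoter_length: int = 1000
    flank: int = 2000
    min_allelic_reads: int = 10
    de_window: tuple[float, float] = (1.0, 38.0)
    seed: int = 0

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def annotated_sites(
    genome: GenomeSequence, genes: Sequence[GeneModel]
) -> list[MotifSite]:
    """Scan gene bodies for REF6-binding sites and annotate every position."""
    return [annotate_site_positions(s, genome) for s in scan_motif(genome, genes)]


def gene_site_status(
    sites: Sequence[MotifSite],
    methylome: pd.DataFrame,
    config: RunConfig = RunConfig(),
    allele: str | None = None,
) -> pd.DataFrame:
    """Per-gene CHG-methylation status of REF6-binding sites.

    A gene is "methylated" when any of its sites is, "unmethylated" when all
    determinate sites are unmethylated, "undetermined" when it has sites but
    none yields a determinate call.  Genes without sites are absent; callers
    label them "no_refbs".
    """
    per_site = sites_chgm_status(
        sites, methylome, rule=config.call_rule, min_cov=config.min_cov, allele=allele
    )
    per_site = per_site[per_site["gene_id"].notna()]
    agg = per_site.groupby("gene_id")["status"].agg(
        lambda s: "methylated"
        if (s == "methylated").any()
        else ("unmethylated" if (s == "unmethylated").any() else "undetermined")
    )
    return agg.rename("status").reset_index()


def run_site_methylation_analysis(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    domains: Sequence[ChromatinDomain],
    methylome: pd.DataFrame,
    de_table: pd.DataFrame | None = None,
    config: RunConfig = RunConfig(),
    allele: str | None = None,
) -> dict:
    """Site-methylation-by-stratum analysis (three linked panels).

    Returns a dict with per-stratum site methylation percentages and their
    pairwise Fisher/BH comparisons (under both the determinate-only
    denominator and the alternative undetermined-as-unmethylated convention),
    per-motif-position methylation per stratum, and — when a DE table is
    supplied — the percentage of upregulated genes per (stratum x gene site
    status) with pairwise Fisher/BH.
    """
    states = state_table(genes, domains)
    sites = annotated_sites(genome, genes)
    per_site = sites_chgm_status(
        sites, methylome, rule=config.call_rule, min_cov=config.min_cov, allele=allele
    )
    state_of = states.set_index("gene_id")["state"]
    per_site = per_site.assign(state=per_site["gene_id"].map(state_of))

    # panel A: % of REF6-binding sites with CHG methylation, per stratum
    marked_states = [s for s in STATES if s != "unmarked"]
    rows = []
    for st in STATES:
        sub = per_site[per_site["state"] == st]
        n_meth = int((sub["status"] == "methylated").sum())
        n_det = int((sub["status"] != "undetermined").sum())
        n_all = int(len(sub))
        rows.append(
            {
                "state": st,
                "n_sites": n_all,
                "n_determinate": n_det,
                "n_methylated": n_meth,
                "pct_methylated_determinate": 100 * n_meth / n_det if n_det else np.nan,
                "pct_methylated_all": 100 * n_meth / n_all if n_all else np.nan,
            }
        )
    site_pct = pd.DataFrame(rows)
    idx = site_pct.set_index("state")
    pairwise_det = pairwise_fisher_bh(
        idx.loc[marked_states, "n_methylated"].tolist(),
        idx.loc[marked_states, "n_determinate"].tolist(),
        marked_states,
    )
    pairwise_all = pairwise_fisher_bh(
        idx.loc[marked_states, "n_methylated"].tolist(),
        idx.loc[marked_states, "n_sites"].tolist(),
        marked_states,
    )

    # panel B: per-motif-position methylation per stratum
    pos_frames = []
    for st in marked_states:
        st_sites = [
            s for s, gs in zip(sites, per_site["state"]) if gs == st
        ]
        tab = position_chgm_table(
            st_sites, methylome, rule=config.call_rule, min_cov=config.min_cov, allele=allele
        )
        tab.insert(0, "state", st)
        pos_frames.append(tab)
    position_table = pd.concat(pos_frames, ignore_index=True)

    report: dict = {
        "config": config.asdict(),
        "states": states,
        "site_status": per_site,
        "site_pct": site_pct,
        "site_pct_pairwise": pairwise_det,
        "site_pct_pairwise_undetermined_as_unmethylated": pairwise_all,
        "position_table": position_table,
    }

    # panel C: activation during germination by gene-level site status
    if de_table is not None:
        gstat = gene_site_status(sites, methylome, config, allele=allele)
        gstat = gstat.assign(state=gstat["gene_id"].map(state_of))
        de = de_table.set_index("gene_id")
        categories = []
        for st in ("K27_K9", "K27_only"):
            for status in ("methylated", "unmethylated"):
                members = gstat.loc[
                    (gstat["state"] == st) & (gstat["status"] == status), "gene_id"
                ]
                members = [g for g in members if g in de.index]
                n_up = int((de.loc[members, "class"] == "up").sum())
                categories.append(
                    {
                        "category": f"{st}:{status}",
                        "n_genes": len(members),
                        "n_up": n_up,
                        "pct_up": 100 * n_up / len(members) if members else np.nan,
                    }
                )
        up_pct = pd.DataFrame(categories)
        nonzero = up_pct[up_pct["n_genes"] > 0]
        report["upregulation_by_status"] = up_pct
        report["upregulation_pairwise"] = (
            pairwise_fisher_bh(
                nonzero["n_up"].tolist(),
                nonzero["n_genes"].tolist(),
                nonzero["category"].tolist(),
            )
            if len(nonzero) >= 2
            else pd.DataFrame()
        )
        report["gene_site_status"] = gstat
    return report


def run_allelic_bias_analysis(
    allelic_counts: pd.DataFrame,
    states: pd.DataFrame,
    gene_status: pd.DataFrame,
    config: RunConfig = RunConfig(),
    focus_states: tuple[str, ...] = ("K27_K9", "K27_only"),
) -> dict:
    """Maternal-ratio comparison of gene categories against all genes.

    For each condition present in ``allelic_counts``, genes passing the
    minimum-read filter define the background; each (stratum x site
    methylation) category is tested against it with a two-sided Wilcoxon
    rank-sum test and BH correction across the categories of that condition.
    """
    state_of = states.set_index("gene_id")["state"]
    status_of = gene_status.set_index("gene_id")["status"] if len(gene_status) else pd.Series(dtype=object)
    results = {}
    for cond, sub in allelic_counts.groupby("condition"):
        sub = min_coverage_filter(sub, config.min_allelic_reads)
        sub = add_ratios(sub)
        sub = sub.assign(
            state=sub["gene_id"].map(state_of),
            status=sub["gene_id"].map(status_of).fillna("no_refbs"),
        )
        background = sub["ratio"].to_numpy()
        groups: dict[str, np.ndarray] = {}
        for st in focus_states:
            for status in ("methylated", "unmethylated"):
                mask = (sub["state"] == st) & (sub["status"] == status)
                groups[f"{st}:{status}"] = sub.loc[mask, "ratio"].to_numpy()
        table = group_bias_test(groups, background)
        table.insert(0, "condition", cond)
        results[str(cond)] = table
    summary = pd.concat(results.values(), ignore_index=True)
    return {"config": config.asdict(), "per_condition": results, "summary": summary}


def run_de_overlay(
    de_table: pd.DataFrame,
    states: pd.DataFrame,
    gene_status: pd.DataFrame,
    config: RunConfig = RunConfig(),
    focus_states: tuple[str, ...] = ("K27_K9", "K27_only"),
) -> dict:
    """Enrichment of (stratum x site methylation) categories among up- and
    downregulated genes, each direction BH-corrected across categories.

    Also emits a volcano-style table (gene, log2fc, p, category).  Empty DE
    tables give empty results with a warning flag; empty categories are
    excluded with a note.
    """
    report: dict = {"config": config.asdict()}
    if de_table is None or len(de_table) == 0:
        report["warning"] = "empty DE table"
        report["enrichment"] = pd.DataFrame()
        report["volcano"] = pd.DataFrame()
        return report
    state_of = states.set_index("gene_id")["state"]
    status_of = gene_status.set_index("gene_id")["status"] if len(gene_status) else pd.Series(dtype=object)
    de = de_table.copy()
    de["state"] = de["gene_id"].map(state_of)
    de["status"] = de["gene_id"].map(status_of).fillna("no_refbs")
    de["category"] = de["state"].astype(str) + ":" + de["status"].astype(str)

    n_all = len(de)
    rows = []
    excluded = []
    for direction in ("up", "down"):
        n_dir = int((de["class"] == direction).sum())
        for st in focus_states:
            for status in ("methylated", "unmethylated"):
                cat = f"{st}:{status}"
                members = (de["state"] == st) & (de["status"] == status)
                n_cat = int(members.sum())
                if n_cat == 0:
                    excluded.append((direction, cat))
                    continue
                a = int((members & (de["class"] == direction)).sum())
                b = n_cat - a
                c = n_dir - a
                d = n_all - n_cat - c
                odds, p = fisher_exact_2x2(a, b, c, d)
                rows.append(
                    {
                        "direction": direction,
                        "category": cat,
                        "n_category": n_cat,
                        "n_in_direction": a,
                        "pct_in_direction": 100 * a / n_cat,
                        "odds_ratio": odds,
                        "p": p,
                    }
                )
    enr = pd.DataFrame(
        rows,
        columns=["direction", "category", "n_category", "n_in_direction",
                 "pct_in_direction", "odds_ratio", "p"],
    )
    enr["q"] = np.nan
    for direction in ("up", "down"):
        mask = enr["direction"] == direction
        if mask.any():
            enr.loc[mask, "q"] = bh_adjust(enr.loc[mask, "p"].to_numpy())
    report["enrichment"] = enr
    report["excluded_categories"] = excluded
    report["volcano"] = de[["gene_id", "log2fc", "p", "class", "category"]]
    return report


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(report: dict, outdir, input_paths: dict | None = None) -> None:
    """Write a run report: each DataFrame as TSV plus a JSON manifest with
    the resolved configuration and input checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": report.get("config", {}), "tables": []}
    if input_paths:
        manifest["input_checksums"] = {
            name: _file_checksum(p) for name, p in input_paths.items()
        }
    for key, value in report.items():
        if isinstance(value, pd.DataFrame):
            path = outdir / f"{key}.tsv"
            value.to_csv(path, sep="\t", index=False)
            manifest["tables"].append(path.name)
        elif isinstance(value, dict) and all(
            isinstance(v, pd.DataFrame) for v in value.values()
        ) and key != "config":
            for sub, frame in value.items():
                path = outdir / f"{key}_{sub}.tsv"
                frame.to_csv(path, sep="\t", index=False)
                manifest["tables"].append(path.name)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
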