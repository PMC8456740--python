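"""Synthetic datasets with planted ground truth.

Generates, from a single seed, every input shape the pipeline consumes: a
small genome with genes and planted REF6-binding sites (CTCTGYTY), maternal
H3K27me3/H3K9me2 domain intervals, replicate bisulfite methylomes whose CHG
methylation at motif positions depends on the gene's chromatin stratum,
allele-resolved read counts around the triploid-endosperm 2:1 neutral
expectation, and a germination time course in which H3K27me3-only genes
activate late.

The planted structure mirrors the biology the analysis is built to detect:
dual H3K27me3/H3K9me2 genes carry frequent CHG methylation at motif position
five (the position that blocks REF6 binding) and are paternally biased;
H3K27me3-only genes have unmethylated sites, activate late in germination
and are maternally biased in dormant seeds; background genes sit at the 2/3
neutral maternal fraction.

Coverage is Poisson and methylated reads binomial given coverage; planted
sites never overlap each other, and accidental motif occurrences created by
the random background are detected by re-scanning and registered rather
than suppressed, so the scanner is exercised honestly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin import STATES
from .expression import ExpressionMatrix
from .genome_io import (
    ChromatinDomain,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    genes_to_frame,
    reverse_complement,
    write_bed,
    write_fasta,
    write_gff_genes,
)
from .methylome import METHYLOME_COLUMNS, write_cx_report
from .motifs import REF6_MOTIF, annotate_site_positions, scan_motif

CONDITIONS = ("dormant", "non_dormant")

# per-stratum planted parameters (probabilities; log2 units for activation)
STATE_DEFAULTS = {
    #                pos3   pos5   pos8  body_chg  mat_dorm  mat_nondorm  act
    "K27_only": (0.05, 0.05, 0.05, 0.01, 0.85, 2 / 3, 3.0),
    "K9_only": (0.25, 0.50, 0.15, 0.30, 2 / 3, 2 / 3, 0.0),
    "K27_K9": (0.30, 0.70, 0.20, 0.30, 0.20, 0.20, 0.0),
    "unmarked": (0.05, 0.05, 0.05, 0.01, 2 / 3, 2 / 3, 0.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Sizes and rates of the synthetic study.

    Group sizes (300/300/300/600) give stable Fisher and Wilcoxon behaviour
    at desk scale; gene/intergenic lengths keep the genome near one megabase.
    """

    n_k27_only: int = 300
    n_k9_only: int = 300
    n_k27_k9: int = 300
    n_unmarked: int = 600
    gene_length: int = 500
    intergenic_length: int = 200
    n_refbs_per_gene: int = 2
    chrom_name: str = "chr1"
    domain_margin: int = 50
    background_levels: dict = field(
        default_factory=lambda: {"CG": 0.25, "CHG": 0.01, "CHH": 0.02}
    )

    @property
    def n_genes(self) -> int:
        return self.n_k27_only + self.n_k9_only + self.n_k27_k9 + self.n_unmarked

    def state_counts(self) -> dict[str, int]:
        return {
            "K27_only": self.n_k27_only,
            "K9_only": self.n_k9_only,
            "K27_K9": self.n_k27_k9,
            "unmarked": self.n_unmarked,
        }


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth plus the generating configuration."""

    genes: pd.DataFrame  # gene_id, state, per-position CHG probs, fractions...
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "genes": self.genes.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["genes"]), SimulationConfig(**payload["config"]))


def make_truth(config: SimulationConfig, seed: int) -> SyntheticTruth:
    """Assign strata and planted parameters to genes (stratum order shuffled
    along the chromosome so position and stratum are unconfounded)."""
    rng = np.random.default_rng(seed)
    states: list[str] = []
    for state, n in config.state_counts().items():
        states.extend([state] * n)
    states = list(rng.permutation(states))
    rows = []
    for i, state in enumerate(states):
        p3, p5, p8, body, md, mn, act = STATE_DEFAULTS[state]
        rows.append(
            {
                "gene_id": f"G{i + 1:05d}",
                "state": state,
                "n_planted_refbs": config.n_refbs_per_gene,
                "p_chgm_pos3": p3,
                "p_chgm_pos5": p5,
                "p_chgm_pos8": p8,
                "body_chg_level": body,
                "maternal_fraction_dormant": md,
                "maternal_fraction_non_dormant": mn,
                "activation_log2fc": act,
            }
        )
    columns = [
        "gene_id", "state", "n_planted_refbs", "p_chgm_pos3", "p_chgm_pos5",
        "p_chgm_pos8", "body_chg_level", "maternal_fraction_dormant",
        "maternal_fraction_non_dormant", "activation_log2fc",
    ]
    return SyntheticTruth(pd.DataFrame(rows, columns=columns), config)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(
    config: SimulationConfig | None = None,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[GenomeSequence, list[GeneModel], SyntheticTruth, pd.DataFrame, list[ChromatinDomain]]:
    """Random genome with genes, planted REF6-binding sites and mark domains.

    Returns (genome, genes, truth, site_registry, domains).  The registry
    lists every motif occurrence in the final sequence (planted or
    accidental, genic or intergenic), found by re-scanning, with the gene it
    falls in (if any) and a ``planted`` flag.
    """
    config = config or SimulationConfig()
    if config.gene_length < 8:
        raise ValueError("gene_length must be at least the motif length (8)")
    if truth is None:
        truth = make_truth(config, seed)
    rng = np.random.default_rng(seed + 1)

    n = config.n_genes
    unit = config.gene_length + config.intergenic_length
    total_len = config.intergenic_length + n * unit
    seq = rng.choice(_BASES, size=total_len)

    genes: list[GeneModel] = []
    planted: set[tuple[int, str]] = set()  # (1-based start, strand)
    motif = REF6_MOTIF
    k = len(motif)
    for i, gene_id in enumerate(truth.genes["gene_id"]):
        start = config.intergenic_length + i * unit + 1
        end = start + config.gene_length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        ts = start if strand == "+" else end
        genes.append(GeneModel(gene_id, GenomicInterval(config.chrom_name, start, end, strand), ts))
        # plant non-overlapping motif copies, one per equal-width slot
        n_sites = config.n_refbs_per_gene
        if n_sites == 0:
            continue
        slot = config.gene_length // n_sites
        if slot < k + 4:
            raise ValueError("gene_length too small for the requested site count")
        for s in range(n_sites):
            off = int(rng.integers(2, slot - k - 1))
            site_start = start + s * slot + off  # 1-based
            realization = "".join(
                ("C" if rng.random() < 0.5 else "T") if b == "Y" else b for b in motif
            )
            site_strand = "+" if rng.random() < 0.5 else "-"
            ins = realization if site_strand == "+" else reverse_complement(realization)
            seq[site_start - 1 : site_start - 1 + k] = np.frombuffer(
                ins.encode(), dtype=np.uint8
            )
            planted.add((site_start, site_strand))

    genome = GenomeSequence({config.chrom_name: seq.tobytes().decode()})

    # registry: everything actually present, genic or not
    all_sites = scan_motif(genome, None, motif)
    starts = np.array([g.body.start for g in genes])
    ends = np.array([g.body.end for g in genes])
    reg_rows = []
    for s in all_sites:
        gi = int(np.searchsorted(starts, s.region.start, side="right")) - 1
        gene_id = None
        if gi >= 0 and s.region.start >= starts[gi] and s.region.end <= ends[gi]:
            gene_id = genes[gi].gene_id
        reg_rows.append(
            {
                "chrom": s.region.chrom,
                "start": s.region.start,
                "end": s.region.end,
                "strand": s.strand,
                "matched_seq": s.matched_seq,
                "gene_id": gene_id,
                "planted": (s.region.start, s.strand) in planted,
            }
        )
    registry = pd.DataFrame(
        reg_rows,
        columns=["chrom", "start", "end", "strand", "matched_seq", "gene_id", "planted"],
    )

    domains: list[ChromatinDomain] = []
    margin = config.domain_margin
    chrom_len = genome.length(config.chrom_name)
    for g, state in zip(genes, truth.genes["state"]):
        region = GenomicInterval(
            g.body.chrom, max(1, g.body.start - margin), min(chrom_len, g.body.end + margin)
        )
        if state in ("K27_only", "K27_K9"):
            domains.append(ChromatinDomain(region, "H3K27me3", "maternal"))
        if state in ("K9_only", "K27_K9"):
            domains.append(ChromatinDomain(region, "H3K9me2", "maternal"))
    return genome, genes, truth, registry, domains


_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def _cytosine_table(seq_bytes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All cytosine positions (1-based), strands and context codes of one
    chromosome; edge cytosines with incomplete context are omitted."""
    C, G, A, T = 67, 71, 65, 84
    codes = seq_bytes
    n = codes.size
    pos_list, strand_list, ctx_list = [], [], []

    # plus strand: C at i, next bases i+1, i+2
    idx = np.flatnonzero(codes == C)
    idx = idx[idx + 1 < n]
    n1 = codes[idx + 1]
    is_cg = n1 == G
    h1 = (n1 == A) | (n1 == C) | (n1 == T)
    idx2 = idx[idx + 2 < n]
    # contexts resolvable with one base (CG) vs two (CHG/CHH)
    cg_pos = idx[is_cg]
    rest = idx[h1 & (idx + 2 < n)]
    n2 = codes[rest + 2]
    chg = rest[n2 == G]
    chh = rest[(n2 == A) | (n2 == C) | (n2 == T)]
    for arr, ctx in ((cg_pos, 0), (chg, 1), (chh, 2)):
        pos_list.append(arr + 1)
        strand_list.append(np.full(arr.size, 0, dtype=np.uint8))
        ctx_list.append(np.full(arr.size, ctx, dtype=np.uint8))

    # minus strand: cytosine where forward base is G; neighbours at i-1, i-2
    idx = np.flatnonzero(codes == G)
    idx = idx[idx - 1 >= 0]
    b1 = codes[idx - 1]
    is_cg = b1 == C  # comp(C) = G
    h1 = (b1 == T) | (b1 == G) | (b1 == A)  # complement in {A,C,T}
    cg_pos = idx[is_cg]
    rest = idx[h1 & (idx - 2 >= 0)]
    b2 = codes[rest - 2]
    chg = rest[b2 == C]  # comp(C) = G
    chh = rest[(b2 == T) | (b2 == G) | (b2 == A)]
    for arr, ctx in ((cg_pos, 0), (chg, 1), (chh, 2)):
        pos_list.append(arr + 1)
        strand_list.append(np.full(arr.size, 1, dtype=np.uint8))
        ctx_list.append(np.full(arr.size, ctx, dtype=np.uint8))

    pos = np.concatenate(pos_list)
    order = np.argsort(pos, kind="stable")
    return pos[order], np.concatenate(strand_list)[order], np.concatenate(ctx_list)[order]


def simulate_methylome(
    truth: SyntheticTruth,
    genome: GenomeSequence,
    genes: list[GeneModel],
    registry: pd.DataFrame,
    depth_mean: float = 20.0,
    n_replicates: int = 2,
    seed: int = 0,
    sample_id: str = "endosperm",
    allele: str = "unphased",
    meth_read_rate: float = 1.0,
    error_read_rate: float = 0.0,
) -> pd.DataFrame:
    """Replicate bisulfite methylomes over every cytosine of the genome.

    Coverage is Poisson(depth_mean) per cytosine per replicate.  At CHG
    cytosines of registered REF6-binding sites the stratum's per-position
    probability is the chance that the cytosine IS methylated (an epiallele
    drawn once per cytosine, shared by the replicates); methylated cytosines
    then yield methylated reads at ``meth_read_rate`` and unmethylated ones
    at ``error_read_rate`` (defaults 1 and 0: a clean, digital epiallele).
    All other cytosines draw methylated reads binomially at the gene-body or
    background level of their context, which makes region-level analyses
    read-weighted-correct without a per-site state.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed + 2)
    ctx_names = np.array(["CG", "CHG", "CHH"])
    truth_by_gene = truth.genes.set_index("gene_id")

    frames = []
    for chrom in genome.chrom_names:
        codes = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)
        pos, strand_code, ctx_code = _cytosine_table(codes)
        p = np.empty(pos.size, dtype=float)
        for ci, name in enumerate(ctx_names):
            p[ctx_code == ci] = truth.config.background_levels[name]

        # genic CHG cytosines take the gene's body level
        chrom_genes = [g for g in genes if g.body.chrom == chrom]
        if chrom_genes:
            starts = np.array([g.body.start for g in chrom_genes])
            ends = np.array([g.body.end for g in chrom_genes])
            body = np.array(
                [truth_by_gene.loc[g.gene_id, "body_chg_level"] for g in chrom_genes]
            )
            gi = np.searchsorted(starts, pos, side="right") - 1
            gi_ok = (gi >= 0) & (pos <= ends[np.clip(gi, 0, len(ends) - 1)])
            sel = gi_ok & (ctx_code == 1)
            p[sel] = body[gi[sel]]

        # registered motif sites: per-position stratum probabilities
        overrides: dict[tuple[int, int], float] = {}
        reg = registry[(registry["chrom"] == chrom) & registry["gene_id"].notna()]
        from .motifs import MotifSite  # local import to avoid cycle at module load

        for row in reg.itertuples():
            tg = truth_by_gene.loc[row.gene_id]
            site = MotifSite(
                row.gene_id,
                GenomicInterval(chrom, row.start, row.end, row.strand),
                row.strand,
                row.matched_seq,
            )
            site = annotate_site_positions(site, genome)
            for a in site.position_annotations:
                if a.context != "CHG":
                    continue
                key = f"p_chgm_pos{a.motif_position}"
                if key in tg.index:
                    sc = 0 if a.cytosine_strand == "+" else 1
                    overrides[(a.genomic_coord, sc)] = float(tg[key])
        site_mask = np.zeros(pos.size, dtype=bool)
        if overrides:
            keys = pos.astype(np.int64) * 2 + strand_code
            omap = {int(c) * 2 + s: v for (c, s), v in overrides.items()}
            okeys = np.array(sorted(omap))
            ovals = np.array([omap[kk] for kk in okeys])
            loc = np.searchsorted(okeys, keys)
            loc_ok = (loc < okeys.size) & (okeys[np.clip(loc, 0, okeys.size - 1)] == keys)
            p[loc_ok] = ovals[loc[loc_ok]]
            site_mask = loc_ok

        # epiallele state at site cytosines: drawn once, shared by replicates
        read_p = p.copy()
        if site_mask.any():
            state = rng.random(site_mask.sum()) < p[site_mask]
            read_p[site_mask] = np.where(state, meth_read_rate, error_read_rate)

        strand_names = np.where(strand_code == 0, "+", "-")
        for rep in range(1, n_replicates + 1):
            cov = rng.poisson(depth_mean, size=pos.size)
            meth = rng.binomial(cov, read_p)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": pd.Categorical([chrom] * pos.size),
                        "pos": pos.astype(np.int64),
                        "strand": pd.Categorical(strand_names),
                        "context": pd.Categorical(ctx_names[ctx_code]),
                        "count_methylated": meth,
                        "count_total": cov,
                        "sample_id": pd.Categorical([sample_id] * pos.size),
                        "replicate": rep,
                        "allele": pd.Categorical([allele] * pos.size),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[METHYLOME_COLUMNS]


def simulate_allelic_counts(
    truth: SyntheticTruth,
    depth_mean: float = 50.0,
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Allele-resolved read counts per gene and condition.

    Total reads ~ Poisson(depth_mean); maternal reads ~ Binomial(total, f)
    with f the planted maternal fraction of the gene in that condition.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed + 3)
    frames = []
    for cond in conditions:
        col = f"maternal_fraction_{cond}"
        if col not in truth.genes.columns:
            raise ValueError(f"truth lacks column {col}")
        f = truth.genes[col].to_numpy(dtype=float)
        total = rng.poisson(depth_mean, size=f.size)
        maternal = rng.binomial(total, f)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": truth.genes["gene_id"],
                    "condition": cond,
                    "maternal_reads": maternal,
                    "paternal_reads": total - maternal,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_timecourse(
    truth: SyntheticTruth,
    timepoints: tuple[float, ...] = (1, 7, 13, 19, 25, 31, 38),
    n_replicates: int = 3,
    seed: int = 0,
    late_from: float = 25.0,
    baseline_log2_mean: float = 5.0,
    baseline_log2_sd: float = 1.5,
    noise_log2_sd: float = 0.15,
    genotype: str = "wt",
) -> ExpressionMatrix:
    """Germination time course (hours of imbibition) in RPKM.

    Every gene has a log-normal baseline; genes with a planted activation
    effect (H3K27me3-only by default) multiply by 2**activation_log2fc at
    time points at or after ``late_from`` hours.  Replicates add log-normal
    noise.
    """
    if len(timepoints) < 2:
        raise ValueError("need at least two timepoints")
    rng = np.random.default_rng(seed + 4)
    n_genes = len(truth.genes)
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    act = truth.genes["activation_log2fc"].to_numpy(dtype=float)

    columns = {}
    meta = []
    for tp in timepoints:
        shift = act if tp >= late_from else 0.0
        for rep in range(1, n_replicates + 1):
            name = f"{genotype}_t{tp:g}_r{rep}"
            noise = rng.normal(0.0, noise_log2_sd, size=n_genes)
            columns[name] = np.exp2(base + shift + noise)
            meta.append({"sample": name, "timepoint": tp, "genotype": genotype, "replicate": rep})
    values = pd.DataFrame(columns, index=truth.genes["gene_id"].to_numpy())
    values.index.name = "gene_id"
    samples = pd.DataFrame(meta).set_index("sample")
    return ExpressionMatrix(values, samples)


def simulate_de_table(
    truth: SyntheticTruth,
    gene_site_status: pd.DataFrame,
    target_state: str = "K27_only",
    target_status: str = "unmethylated",
    p_down_target: float = 0.6,
    p_down_other: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixture DE table planting downregulation in one gene category.

    Genes in (``target_state``, ``target_status``) are downregulated with
    probability ``p_down_target``, all others with ``p_down_other``.  This
    fabricates the externally produced DE tables the overlay analysis
    consumes; it is not a DE method.
    """
    rng = np.random.default_rng(seed + 5)
    status = gene_site_status.set_index("gene_id")["status"] if len(gene_site_status) else pd.Series(dtype=object)
    rows = []
    for row in truth.genes.itertuples():
        st = status.get(row.gene_id, "no_refbs")
        p_down = (
            p_down_target
            if (row.state == target_state and st == target_status)
            else p_down_other
        )
        if rng.random() < p_down:
            log2fc, p = float(rng.normal(-2.5, 0.4)), float(rng.uniform(1e-6, 0.01))
            log2fc = min(log2fc, -1.0)
        else:
            log2fc, p = float(rng.normal(0.0, 0.25)), float(rng.uniform(0.2, 1.0))
            log2fc = float(np.clip(log2fc, -0.9, 0.9))
        rows.append({"gene_id": row.gene_id, "log2fc": log2fc, "p": p, "expressed": True})
    from .expression import classify_de_table

    return classify_de_table(pd.DataFrame(rows))


def generate_dataset(outdir, config: SimulationConfig | None = None, seed: int = 0) -> dict:
    """Write a complete synthetic dataset (all file formats) to ``outdir``.

    Returns the paths written, keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig()
    genome, genes, truth, registry, domains = simulate_genome(config, seed)
    methylome = simulate_methylome(truth, genome, genes, registry, seed=seed)
    allelic = simulate_allelic_counts(truth, seed=seed)
    timecourse = simulate_timecourse(truth, seed=seed)

    paths = {
        "fasta": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "k27_bed": outdir / "H3K27me3_maternal.bed",
        "k9_bed": outdir / "H3K9me2_maternal.bed",
        "methylome": outdir / "methylome.cx.tsv",
        "allelic": outdir / "allelic_counts.tsv",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "registry": outdir / "site_registry.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome, paths["fasta"])
    write_gff_genes(genes, paths["gff"])
    for mark, key in (("H3K27me3", "k27_bed"), ("H3K9me2", "k9_bed")):
        write_bed([d.region for d in domains if d.mark == mark], paths[key])
    write_cx_report(methylome, paths["methylome"])
    allelic.to_csv(paths["allelic"], sep="\t", index=False)
    timecourse.write(paths["expression"], paths["samples"])
    registry.to_csv(paths["registry"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
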