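# endoepi

Analysis toolkit for the interplay of repressive epigenetic marks at
REF6-binding sites in *Arabidopsis thaliana* endosperm: how combinations of
maternal H3K27me3, H3K9me2 and CHG DNA methylation decide which genes are
reactivated during seed germination, and which show parent-of-origin
expression bias.

## The biology and the statistics

The H3K27me3 demethylase REF6 binds the 8-bp motif CTCTG**Y**T**Y**
(Y = C or T) through its zinc fingers, and CHG methylation (mCHG, H = A/C/T)
within the motif repels it. Genes in the endosperm fall into strata by their
maternal repressive marks — H3K27me3 only, H3K9me2 only, both
(H3K27me3/H3K9me2), or neither. The package links these strata to the CHG
methylation status of REF6-binding sites (REF6-BS) in gene bodies, to
activation during germination, and to allelic expression in the triploid
endosperm, where 2 maternal : 1 paternal genome dosage makes the neutral
maternal read fraction m/(m+p) = 2/3.

Core operations, in the field's standard conventions:

* **IUPAC motif scanning** of gene bodies on both strands, with per-position
  cytosine context annotation (CG / CHG / CHH, read 5′→3′ on the cytosine's
  strand). Of CTCTGYTY's eight positions, exactly three — 3, 5 and 8 — can
  carry a cytosine in CHG context (position 5 as the antisense cytosine under
  the G, read C-A-G).
* **Bisulfite methylation calls**: a cytosine is methylated when every
  replicate has ≥ 5 reads and ≥ 1 methylated read (two-replicate rule), or
  when the pooled replicates do (pooled rule); below coverage the call is
  *undetermined*, never silently unmethylated. Site status aggregates by
  "any methylated CHG cytosine"; gene-body mCHG uses the read-weighted level
  with presence defined as level > 0.04.
* **Expression**: RPKM normalisation, mean-scaled relative time-course
  profiles with two-sided Wilcoxon rank-sum tests against the 1-hour
  reference, and change classes (up: log₂FC ≥ 1 and p < 0.05; down:
  log₂FC ≤ −1 and p < 0.05; non-expressed; stable).
* **Enrichment**: two-sided Fisher exact tests (probability-mass criterion,
  exact integer hypergeometric enumeration), pairwise Fisher families and
  Wilcoxon group-vs-background tests with Benjamini–Hochberg correction, and
  promoter hexamer overrepresentation on 1-kb upstream-of-ATG sequences
  (presence/absence per promoter, either strand).
* **Synthetic data**: a generator that emits every input shape (FASTA, GFF3,
  BED domains, CX-style methylomes, allelic count and expression TSVs) with
  planted ground truth, so the whole pipeline is testable at desk scale.

## Worked example

`examples/03_site_methylation_by_stratum.py` simulates 500 genes
(100/100/100 marked, 200 unmarked; planted position-5 mCHG probability 0.7
in dual-marked vs 0.05 in H3K27me3-only genes; depth 20, two replicates)
and runs the stratum analysis:

```
% of REF6-binding sites with CHG methylation, per stratum:
   state  n_determinate  n_methylated  pct_methylated_determinate
K27_only            206            23                   11.165049
 K9_only            207           119                   57.487923
  K27_K9            204           164                   80.392157
unmarked            416            39                    9.375000

Pairwise Fisher tests (BH-corrected):
  group1  group2            p            q
K27_only K9_only 2.947344e-24 4.421016e-24
K27_only  K27_K9 6.885750e-49 2.065725e-48
 K9_only  K27_K9 5.033288e-07 5.033288e-07
```

Sites in dual-marked genes are methylated far more often than in
H3K27me3-only genes (80% vs 11%, q ≈ 2×10⁻⁴⁸), and within the dual-marked
stratum position five carries the maximum per-position methylated fraction
(0.676 at 204 determinate sites, recovering the planted 0.7). The other
examples walk through the call rules, allelic bias (planted maternal
fractions 0.2 / 0.85 against the 2/3 background) and hexamer enrichment.

A thin CLI wraps the same pipeline for file inputs:

```sh
endoepi simulate --outdir data --seed 1
endoepi site-methylation --fasta data/genome.fa --gff data/genes.gff3 \
    --k27-bed data/H3K27me3_maternal.bed --k9-bed data/H3K9me2_maternal.bed \
    --cx data/methylome.cx.tsv --outdir results/site-methylation
```

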