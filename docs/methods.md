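# Methods

## Coordinates and file formats

All internal coordinates are 1-based inclusive, matching GFF3 and
per-cytosine methylation reports; BED's 0-based half-open convention is
converted at the read/write boundary only (`start_internal = start_bed + 1`,
`end_internal = end_bed`). The gene body is the full annotated gene
interval, introns and UTRs included — marks and binding sites are assigned
to gene bodies without transcript-model structure. The translation start is
the strand-appropriate end of the first CDS when CDS features are present,
else the 5′ gene end; promoters are the up-to-1-kb window immediately 5′ of
it, truncated (never rejected) at chromosome edges, because the small
synthetic genomes hit edges often.

## Motif scanning and cytosine context

The scanner expands an IUPAC motif (default CTCTGYTY) into a character-class
regex with overlap-permitting lookahead and runs it over each gene body and,
for minus-strand hits, over the reverse-complement pattern with coordinate
mapping. Motif positions are always numbered in motif orientation
(position 1 = the first C), for minus-strand sites too, so per-position
statistics aggregate across strands. Overlapping occurrences are all kept,
deduplicated per (gene, interval, strand); a site spanning two overlapping
genes yields one record per gene, since no collapsing rule is defined for
this analysis. An N inside the 8-bp window prevents a match; an N (or a
chromosome edge) in the flank needed for context makes the context
"undetermined".

Context is read 5′→3′ on the cytosine's strand: CG if the next base is G,
CHG if the next base is H (A/C/T) and the one after is G, CHH otherwise. A
motif-orientation C is a cytosine on the site's own strand; a G is the
antisense cytosine at the same coordinate. `chg_capable_positions`
enumerates every concrete motif realization with free flanking bases on
either strand; for CTCTGYTY this yields positions {3, 5, 8}. (Note the
antisense route: any G two bases after a C is CHG-capable on the minus
strand — e.g. in CAG both position 1 and position 3 qualify.)

## Methylation calls and aggregation

Calls are three-state. Two-replicate rule: undetermined if any replicate
has < 5 reads; methylated if every replicate has ≥ 5 reads and ≥ 1
methylated read; otherwise unmethylated. Pooled rule: the same thresholds
applied to summed counts, used for parental-allele methylomes where
replicates are pooled upstream. "Undetermined" is absent evidence — it
never counts as methylated, and enrichment denominators use determinate
sites only. Because the appropriate denominator for percent-methylated
summaries is a genuine convention choice, the stratum report also carries
the alternative all-sites denominator (undetermined treated as
unmethylated) side by side.

Site-level status is "any methylated CHG cytosine within the 8-bp site";
the per-position table resolves the same calls by motif position. Gene-body
levels are read-weighted (Σ methylated / Σ total over the region's
cytosines of the context), with presence defined as level > 0.04 and 0/0
flagged undefined rather than zero. Flank profiles use fixed 2-kb genomic
flanks and a body rescaled to a fixed bin count, ordered 5′→3′ relative to
the gene. Allele filtering is by the explicit allele column of the records;
no read-level phasing is attempted.

## Chromatin strata

A mark is present on a gene when the gene body's overlap fraction with the
mark's merged (maternal-allele, by default) domains exceeds
`min_overlap_fraction`; the default 0.0 means any overlap of ≥ 1 bp. The
threshold is configurable because the stratum definitions are inherited
from domain calls made upstream, and any fixed fraction would be false
precision. The four strata (K27_only, K9_only, K27_K9, unmarked) partition
the gene universe by construction.

## Expression and allelic bias

Relative time-course profiles divide each gene's replicate-mean RPKM by its
mean across time points (all-zero genes flagged undefined); "relative
expression" has no canonical definition, and mean-scaling was chosen as the
scale-free option and recorded in output metadata. Group shifts are tested
per time point against the 1-hour reference with a two-sided Wilcoxon
rank-sum test — exact null distribution when both samples have ≤ 10
observations without ties, normal approximation with tie correction
otherwise. Change classes: non-expressed (below an RPKM floor of 1 in every
sample, configurable — the category is named without a threshold upstream,
so one had to be chosen); up (log₂FC ≥ 1, p < 0.05); down (log₂FC ≤ −1,
p < 0.05); stable (expressed, neither). Taking "stable" as "expressed but
neither up nor down" diverges deliberately from a literal reading that
would gate stability on p < 0.05, so that the four classes partition all
genes. The default comparison window is 1 vs 38 hours of imbibition. The
bundled two-group DE helper (log₂ fold change of mean RPKM with
pseudo-count 1, Welch t on log₂(RPKM+1)) exists only to fabricate DE tables
for synthetic runs; real DE tables are consumed as input.

Maternal ratios are maternal/(maternal+paternal) reads, undefined at zero
total, filtered at ≥ 10 allele-resolved reads by default (the upstream
filter is not restated, so a conservative default is exposed as a
parameter). Bias is tested per condition against the empirical all-genes
background — not against the theoretical 2/3 — with two-sided Wilcoxon
rank-sum and BH across the compared categories; direction is the sign of
the group-vs-background median difference. A consequence worth knowing:
strongly biased categories shift the background, so a neutral category can
test weakly significant against "all genes" while sitting exactly at 2/3.

## Contingency statistics

The two-sided Fisher exact p sums, over the hypergeometric support at the
observed margins, the probabilities of all tables no more probable than the
observed one. Weights are exact integers (binomial coefficients), so tie
comparison is exact and the returned p is correctly rounded; scipy's
implementation serves as an independent cross-check in the tests. BH
adjustment is the statsmodels step-up implementation behind a validating
wrapper, tested against the direct formula. Each family-level call (one
pairwise panel, one k-mer scan, one direction of the DE overlay, one
condition of the bias analysis) is its own multiple-testing family.

K-mer overrepresentation counts presence per promoter (multiple occurrences
count once) on either strand, Fisher-tests each k-mer seen in ≥ 3 target
promoters, and BH-corrects across tested k-mers. Presence/absence rather
than occurrence counts avoids promoter-length confounding; k is capped at 8
to bound the table.

## Synthetic data: what it emulates and what it does not

The generator plants, per gene: a chromatin stratum (default sizes
300/300/300/600 for stable test behaviour), two non-overlapping REF6-BS
copies with random Y realizations and strands, per-position CHG methylation
probabilities (defaults: position 5 = 0.7, 3 = 0.3, 8 = 0.2 in dual-marked
genes; 0.5/0.25/0.15 in K9-only; 0.05 in H3K27me3-only and unmarked — the
dual-marked-vs-single contrast concentrated on position five), gene-body
CHG levels (0.30 marked-by-K9 strata, 0.01 otherwise, straddling the 0.04
cut), maternal fractions (0.2 for dual-marked genes, 0.85 for
H3K27me3-only genes in the dormant condition, 2/3 elsewhere), and a +3 log₂
late-activation effect for H3K27me3-only genes from 25 h of imbibition.
Genes are 500 bp with 200-bp intergenic spacers (~1 Mb genome at default
scale) — small enough for seconds-scale runs, large enough for stable
statistics.

Coverage is Poisson per cytosine per replicate (depth 20 for methylomes, 50
for allelic counts) and methylated reads are binomial given coverage. At
REF6-BS CHG cytosines the planted probability is the chance the cytosine
*is* methylated: an epiallele state drawn once per cytosine and shared by
replicates, with methylated cytosines yielding methylated reads at rate 1
and unmethylated at rate 0 by default (knobs exist for read-level noise).
This digital-epiallele choice is what makes the planted per-position
fractions directly recoverable through the one-methylated-read call rule;
a flat per-read rate would saturate the rule at any realistic depth.
Elsewhere the planted value is a per-read level, which is what
read-weighted region statistics estimate. Accidental motif occurrences
created by the random background are detected by re-scanning and added to
the site registry (inheriting their gene's stratum parameters when genic)
rather than suppressed.

Passing tests on these data show that the statistical machinery recovers
planted structure at realistic depths and group sizes. They do not show
robustness to what the generator omits: beta-binomial overdispersion,
mapping and conversion artefacts, correlated methylation along reads,
transcript isoforms, SNP-driven allelic mis-assignment, or real
genome composition.

## Numerical and degenerate-input conventions

Undefined levels and ratios are NaN and flagged, never zero. Degenerate
Fisher tables (an empty margin) return p = 1 with an undefined odds ratio.
Groups below minimum size (3) are flagged and excluded from their BH
family. Identical group-vs-background comparisons short-circuit to p = 1
with no direction. All generators and analyses are deterministic given
(configuration, seed); derived seeds are small fixed offsets of the user
seed so the stages draw independent streams.
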