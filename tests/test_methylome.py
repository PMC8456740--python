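import itertools

import numpy as np
import pandas as pd
import pytest

from endoepi.genome_io import GenomeSequence, GenomicInterval, GeneModel
from endoepi.methylome import (
    call_site_pooled,
    call_site_two_replicates,
    flank_profile,
    position_chgm_table,
    refbs_chgm_status,
    region_methylation_level,
)
from endoepi.motifs import annotate_site_positions, scan_motif

# count tuples are (count_methylated, count_total)


def _methylome_frame(rows):
    """rows: (chrom,pos,strand,context,meth,total,replicate)"""
    return pd.DataFrame(
        [
            {
                "chrom": r[0], "pos": r[1], "strand": r[2], "context": r[3],
                "count_methylated": r[4], "count_total": r[5],
                "sample_id": "s", "replicate": r[6], "allele": "unphased",
            }
            for r in rows
        ],
        columns=["chrom", "pos", "strand", "context", "count_methylated",
                 "count_total", "sample_id", "replicate", "allele"],
    )


class TestCallRules:
    @pytest.mark.parametrize(
        "rep1,rep2,expected",
        [
            ((1, 5), (1, 7), "methylated"),
            ((4, 4), (10, 20), "undetermined"),  # rep1 below 5-read coverage
            ((0, 10), (0, 12), "unmethylated"),
            ((5, 10), (0, 12), "unmethylated"),  # needs a methylated read in EACH rep
        ],
    )
    def test_two_replicate_rule(self, rep1, rep2, expected):
        assert call_site_two_replicates(rep1, rep2).status == expected

    @pytest.mark.parametrize(
        "records,expected",
        [
            ([(1, 3), (0, 2)], "methylated"),
            ([(1, 2), (1, 1)], "undetermined"),  # pooled coverage 3 < 5
            ([(0, 4), (0, 4)], "unmethylated"),
        ],
    )
    def test_pooled_rule(self, records, expected):
        assert call_site_pooled(records).status == expected

    def test_records_for_different_positions_rejected(self):
        from endoepi.methylome import CytosineRecord

        r1 = CytosineRecord("c", 10, "+", "CHG", 1, 5)
        r2 = CytosineRecord("c", 11, "+", "CHG", 1, 5)
        with pytest.raises(ValueError, match="different positions"):
            call_site_pooled([r1, r2])

    def test_exhaustive_agreement_with_rule_transcription(self):
        """Every coverage/methylated combination up to 10 reads per replicate
        matches a direct transcription of the quoted rules."""
        for t1, t2 in itertools.product(range(11), repeat=2):
            for m1 in range(t1 + 1):
                for m2 in range(t2 + 1):
                    got = call_site_two_replicates((m1, t1), (m2, t2)).status
                    if t1 < 5 or t2 < 5:
                        assert got == "undetermined"
                    elif m1 >= 1 and m2 >= 1:
                        assert got == "methylated"
                    else:
                        assert got == "unmethylated"
                    got = call_site_pooled([(m1, t1), (m2, t2)]).status
                    if t1 + t2 < 5:
                        assert got == "undetermined"
                    elif m1 + m2 >= 1:
                        assert got == "methylated"
                    else:
                        assert got == "unmethylated"

    def test_monotonicity_of_calls(self):
        rng = np.random.default_rng(2)
        order = {"unmethylated": 0, "methylated": 1}
        for _ in range(200):
            t1, t2 = rng.integers(5, 15, size=2)
            m1, m2 = rng.integers(0, t1 + 1), rng.integers(0, t2 + 1)
            base = call_site_two_replicates((m1, t1), (m2, t2)).status
            plus_unmeth = call_site_two_replicates((m1, t1 + 3), (m2, t2)).status
            plus_meth = call_site_two_replicates((m1 + 1, t1 + 1), (m2, t2)).status
            if base == "unmethylated":
                assert plus_unmeth != "methylated"
            if base == "methylated":
                assert plus_meth != "unmethylated"

    def test_pooled_agrees_when_both_replicates_individually_qualify(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t1, t2 = rng.integers(5, 20, size=2)
            m1 = rng.integers(1, t1 + 1)
            m2 = rng.integers(1, t2 + 1)
            assert (
                call_site_two_replicates((m1, t1), (m2, t2)).status
                == call_site_pooled([(m1, t1), (m2, t2)]).status
                == "methylated"
            )


def _annotated_site(genome_str="CTCTGTTTAA"):
    genome = GenomeSequence({"c": genome_str})
    gene = GeneModel("g", GenomicInterval("c", 1, len(genome_str), "+"), 1)
    (site,) = scan_motif(genome, [gene])
    return annotate_site_positions(site, genome)


class TestSiteStatus:
    # the CTCTGTTT site has CHG cytosines at position 3 (+ strand, coord 3)
    # and position 5 (- strand, coord 5)

    def test_any_methylated_chg_cytosine_makes_site_methylated(self):
        site = _annotated_site()
        meth = _methylome_frame(
            [("c", 3, "+", "CHG", 1, 8, 1), ("c", 3, "+", "CHG", 2, 9, 2),
             ("c", 5, "-", "CHG", 0, 8, 1), ("c", 5, "-", "CHG", 0, 9, 2)]
        )
        assert refbs_chgm_status(site, meth) == "methylated"

    def test_all_determinate_unmethylated_makes_site_unmethylated(self):
        site = _annotated_site()
        meth = _methylome_frame(
            [("c", 3, "+", "CHG", 0, 8, 1), ("c", 3, "+", "CHG", 0, 9, 2),
             ("c", 5, "-", "CHG", 0, 8, 1), ("c", 5, "-", "CHG", 0, 9, 2)]
        )
        assert refbs_chgm_status(site, meth) == "unmethylated"

    def test_all_chg_cytosines_below_coverage_gives_undetermined(self):
        site = _annotated_site()
        meth = _methylome_frame(
            [("c", 3, "+", "CHG", 1, 3, 1), ("c", 3, "+", "CHG", 1, 2, 2)]
        )
        assert refbs_chgm_status(site, meth) == "undetermined"

    def test_undetermined_is_absent_evidence_not_methylation(self):
        site = _annotated_site()
        # position 3 low coverage, position 5 well-covered and unmethylated
        meth = _methylome_frame(
            [("c", 3, "+", "CHG", 1, 2, 1), ("c", 3, "+", "CHG", 1, 2, 2),
             ("c", 5, "-", "CHG", 0, 10, 1), ("c", 5, "-", "CHG", 0, 10, 2)]
        )
        assert refbs_chgm_status(site, meth) == "unmethylated"


class TestPositionTable:
    def test_counts_and_chg_capable_denominators(self):
        # ten identical forward sites on one chromosome, spaced apart
        seq = ("CTCTGTTT" + "A" * 12) * 10
        genome = GenomeSequence({"c": seq})
        gene = GeneModel("g", GenomicInterval("c", 1, len(seq), "+"), 1)
        sites = [annotate_site_positions(s, genome) for s in scan_motif(genome, [gene])]
        sites = [s for s in sites if s.strand == "+"]
        assert len(sites) == 10
        rows = []
        for i, s in enumerate(sites):
            meth3 = 1 if i < 4 else 0  # 4 of 10 methylated at position 3
            c3 = s.annotation(3).genomic_coord
            c5 = s.annotation(5).genomic_coord
            for rep in (1, 2):
                rows.append(("c", c3, "+", "CHG", meth3, 10, rep))
                rows.append(("c", c5, "-", "CHG", 0, 10, rep))
        table = position_chgm_table(sites, _methylome_frame(rows))
        t = table.set_index("motif_position")
        assert t.loc[3, "n_methylated"] == 4 and t.loc[3, "n_determinate"] == 10
        assert t.loc[5, "n_methylated"] == 0 and t.loc[5, "n_determinate"] == 10
        # positions without CHG capability in these sites report zero denominators
        for p in (1, 2, 4, 6, 7):
            assert t.loc[p, "n_determinate"] == 0

    def test_empty_site_set_gives_all_zeros(self):
        table = position_chgm_table([], _methylome_frame([]))
        assert (table["n_determinate"] == 0).all() and (table["n_methylated"] == 0).all()


class TestRegionLevel:
    def region(self):
        return GenomicInterval("c", 1, 100)

    def test_read_weighted_level_above_cut_is_present(self):
        meth = _methylome_frame(
            [("c", 10, "+", "CHG", 1, 10, 1), ("c", 20, "+", "CHG", 0, 10, 1)]
        )
        level = region_methylation_level(self.region(), meth, "CHG")
        assert level.level == pytest.approx(0.05)
        assert level.classify() == "present"

    def test_boundary_level_is_absent(self):
        meth = _methylome_frame([("c", 10, "+", "CHG", 1, 25, 1)])
        level = region_methylation_level(self.region(), meth, "CHG")
        assert level.level == pytest.approx(0.04)
        assert level.classify() == "absent"

    def test_no_reads_is_undefined_not_zero(self):
        level = region_methylation_level(self.region(), _methylome_frame([]), "CHG")
        assert not level.defined
        assert np.isnan(level.level)
        assert level.classify() == "undefined"

    def test_concatenation_is_read_weighted_combination(self):
        rng = np.random.default_rng(8)
        rows = []
        for pos in range(1, 61):
            t = int(rng.integers(1, 30))
            m = int(rng.integers(0, t + 1))
            rows.append(("c", pos, "+", "CHG", m, t, 1))
        meth = _methylome_frame(rows)
        left = region_methylation_level(GenomicInterval("c", 1, 30), meth, "CHG")
        right = region_methylation_level(GenomicInterval("c", 31, 60), meth, "CHG")
        both = region_methylation_level(GenomicInterval("c", 1, 60), meth, "CHG")
        lw = sum(r[5] for r in rows if r[1] <= 30)
        rw = sum(r[5] for r in rows if r[1] > 30)
        assert both.level == pytest.approx((left.level * lw + right.level * rw) / (lw + rw))


class TestFlankProfile:
    def _gene(self, strand="+"):
        return GeneModel("g", GenomicInterval("c", 3001, 4000, strand),
                         3001 if strand == "+" else 4000)

    def test_uniform_methylation_gives_uniform_bins(self):
        rows = [("c", pos, "+", "CHG", 1, 10, 1) for pos in range(1, 7001, 10)]
        prof = flank_profile(self._gene(), _methylome_frame(rows), "CHG")
        filled = prof.dropna(subset=["level"])
        assert np.allclose(filled["level"], 0.1)

    def test_methylation_only_downstream(self):
        rows = [("c", pos, "+", "CHG", 1 if pos > 4000 else 0, 10, 1)
                for pos in range(1, 7001, 10)]
        prof = flank_profile(self._gene(), _methylome_frame(rows), "CHG")
        up = prof[prof.segment == "upstream"]["level"].dropna()
        dn = prof[prof.segment == "downstream"]["level"].dropna()
        assert (up == 0).all() and (dn > 0).all()

    def test_minus_strand_gene_takes_upstream_from_higher_coordinates(self):
        # methylation only at coordinates above the gene end
        rows = [("c", pos, "+", "CHG", 1 if pos > 4000 else 0, 10, 1)
                for pos in range(1, 7001, 10)]
        prof = flank_profile(self._gene("-"), _methylome_frame(rows), "CHG")
        up = prof[prof.segment == "upstream"]["level"].dropna()
        assert (up > 0).all()
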