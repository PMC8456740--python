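import numpy as np
import pandas as pd
import pytest

from endoepi.expression import relative_profile, timepoint_shift_test
from endoepi.genome_io import read_bed_domains, read_fasta, read_gff_genes
from endoepi.methylome import read_cx_report
from endoepi.motifs import scan_motif
from endoepi.simulate import (
    SimulationConfig,
    SyntheticTruth,
    generate_dataset,
    make_truth,
    simulate_allelic_counts,
    simulate_genome,
    simulate_methylome,
    simulate_timecourse,
)


class TestGenome:
    def test_registry_equals_scanner_output(self, small_dataset):
        genome, genes, registry = (
            small_dataset["genome"], small_dataset["genes"], small_dataset["registry"]
        )
        scanned = scan_motif(genome, None)
        got = {(s.region.start, s.strand) for s in scanned}
        assert got == set(zip(registry["start"], registry["strand"]))
        # every planted site is present, two per gene
        planted = registry[registry["planted"]]
        assert len(planted) == 2 * len(genes)
        assert planted["gene_id"].notna().all()

    def test_seed_determinism_and_divergence(self):
        cfg = SimulationConfig(n_k27_only=5, n_k9_only=5, n_k27_k9=5, n_unmarked=5)
        g1, *_ = simulate_genome(cfg, seed=7)
        g2, *_ = simulate_genome(cfg, seed=7)
        g3, *_ = simulate_genome(cfg, seed=8)
        assert g1["chr1"] == g2["chr1"]
        assert g1["chr1"] != g3["chr1"]

    def test_no_genes_gives_intergenic_only_genome(self):
        cfg = SimulationConfig(n_k27_only=0, n_k9_only=0, n_k27_k9=0, n_unmarked=0)
        genome, genes, truth, registry, domains = simulate_genome(cfg, seed=1)
        assert genes == [] and domains == []
        assert genome.length("chr1") == cfg.intergenic_length

    def test_too_short_genes_rejected(self):
        with pytest.raises(ValueError, match="at least the motif"):
            simulate_genome(SimulationConfig(gene_length=6), seed=0)

    def test_domains_match_truth_states(self, small_dataset):
        truth, domains, genes = (
            small_dataset["truth"], small_dataset["domains"], small_dataset["genes"]
        )
        from endoepi.chromatin import state_table

        table = state_table(genes, domains).set_index("gene_id")["state"]
        planted = truth.genes.set_index("gene_id")["state"]
        assert (table.loc[planted.index] == planted).all()


class TestMethylome:
    def test_replicates_differ_but_structure_is_shared(self, small_dataset):
        meth = small_dataset["methylome"]
        assert set(meth["replicate"].unique()) == {1, 2}
        r1 = meth[meth["replicate"] == 1]
        r2 = meth[meth["replicate"] == 2]
        assert len(r1) == len(r2)
        assert not np.array_equal(
            r1["count_total"].to_numpy(), r2["count_total"].to_numpy()
        )

    def test_degenerate_probabilities(self):
        cfg = SimulationConfig(n_k27_only=4, n_k9_only=0, n_k27_k9=4, n_unmarked=0)
        genome, genes, truth, registry, _ = simulate_genome(cfg, seed=3)
        for col, val in (("p_chgm_pos3", 1.0), ("p_chgm_pos5", 1.0), ("p_chgm_pos8", 1.0)):
            truth.genes[col] = val
        meth = simulate_methylome(truth, genome, genes, registry, depth_mean=30, seed=3)
        from endoepi.methylome import sites_chgm_status
        from endoepi.pipeline import annotated_sites

        sites = annotated_sites(genome, genes)
        status = sites_chgm_status(sites, meth)
        determinate = status[status["status"] != "undetermined"]
        assert (determinate["status"] == "methylated").all()

        truth.genes[["p_chgm_pos3", "p_chgm_pos5", "p_chgm_pos8"]] = 0.0
        truth.genes["body_chg_level"] = 0.0
        cfgz = SimulationConfig(**{**cfg.__dict__, "background_levels": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0}})
        truth.config = cfgz
        meth = simulate_methylome(truth, genome, genes, registry, depth_mean=30, seed=3)
        assert (meth["count_methylated"] == 0).all()

    def test_planted_position5_fraction_recovered(self, small_dataset):
        from endoepi.methylome import position_chgm_table
        from endoepi.pipeline import annotated_sites

        truth = small_dataset["truth"]
        genes_by_state = truth.genes.set_index("gene_id")["state"]
        sites = annotated_sites(small_dataset["genome"], small_dataset["genes"])
        k27k9_sites = [s for s in sites if genes_by_state.get(s.gene_id) == "K27_K9"]
        table = position_chgm_table(k27k9_sites, small_dataset["methylome"])
        frac5 = table.set_index("motif_position").loc[5, "fraction_methylated"]
        # planted 0.7 at ~120 sites: allow ~3 binomial standard errors
        assert frac5 == pytest.approx(0.7, abs=0.13)

    def test_methylome_determinism(self, small_dataset):
        again = simulate_methylome(
            small_dataset["truth"], small_dataset["genome"],
            small_dataset["genes"], small_dataset["registry"], seed=1,
        )
        pd.testing.assert_frame_equal(again, small_dataset["methylome"])


class TestAllelicCounts:
    def test_full_maternal_fraction_zeroes_paternal(self):
        truth = make_truth(SimulationConfig(n_k27_only=0, n_k9_only=0, n_k27_k9=0, n_unmarked=50), seed=1)
        truth.genes["maternal_fraction_dormant"] = 1.0
        counts = simulate_allelic_counts(truth, conditions=("dormant",), seed=1)
        assert (counts["paternal_reads"] == 0).all()

    def test_neutral_median_concentrates_at_two_thirds(self):
        truth = make_truth(SimulationConfig(n_k27_only=0, n_k9_only=0, n_k27_k9=0, n_unmarked=1000), seed=2)
        counts = simulate_allelic_counts(truth, depth_mean=50, conditions=("dormant",), seed=2)
        ratio = counts["maternal_reads"] / (counts["maternal_reads"] + counts["paternal_reads"])
        assert np.median(ratio) == pytest.approx(2 / 3, abs=0.03)

    def test_determinism(self):
        truth = make_truth(SimulationConfig(n_unmarked=20), seed=3)
        c1 = simulate_allelic_counts(truth, seed=3)
        c2 = simulate_allelic_counts(truth, seed=3)
        pd.testing.assert_frame_equal(c1, c2)


class TestTimecourse:
    def test_k27_only_genes_activate_late(self):
        truth = make_truth(
            SimulationConfig(n_k27_only=200, n_k9_only=50, n_k27_k9=50, n_unmarked=50), seed=4
        )
        matrix = simulate_timecourse(truth, seed=4)
        means = matrix.timepoint_means()
        profiles, _ = relative_profile(means)
        states = truth.genes.set_index("gene_id")["state"]
        k27 = profiles.loc[states[states == "K27_only"].index]
        flat = profiles.loc[states[states == "K27_K9"].index]
        k27_result = timepoint_shift_test(k27, 1.0).set_index("timepoint")
        flat_result = timepoint_shift_test(flat, 1.0).set_index("timepoint")
        assert k27_result.loc[38.0, "p"] < 0.01
        assert k27_result.loc[13.0, "p"] > 0.01
        assert flat_result.loc[38.0, "p"] > 0.01

    def test_null_activation_shows_no_shift(self):
        truth = make_truth(SimulationConfig(n_k27_only=100, n_k9_only=0, n_k27_k9=0, n_unmarked=0), seed=5)
        truth.genes["activation_log2fc"] = 0.0
        matrix = simulate_timecourse(truth, seed=5)
        profiles, _ = relative_profile(matrix.timepoint_means())
        result = timepoint_shift_test(profiles, 1.0)
        assert (result["p"].dropna() > 0.01).all()

    def test_determinism(self):
        truth = make_truth(SimulationConfig(n_unmarked=10), seed=6)
        m1 = simulate_timecourse(truth, seed=6)
        m2 = simulate_timecourse(truth, seed=6)
        pd.testing.assert_frame_equal(m1.values, m2.values)


class TestRoundTrip:
    def test_generated_files_are_valid_inputs_to_every_reader(self, tmp_path):
        cfg = SimulationConfig(n_k27_only=6, n_k9_only=6, n_k27_k9=6, n_unmarked=12)
        paths = generate_dataset(tmp_path, cfg, seed=9)
        genome = read_fasta(paths["fasta"])
        genes = read_gff_genes(paths["gff"])
        assert len(genes) == 30
        k27 = read_bed_domains(paths["k27_bed"], "H3K27me3")
        k9 = read_bed_domains(paths["k9_bed"], "H3K9me2")
        assert len(k27) == 12 and len(k9) == 12
        meth = read_cx_report(paths["methylome"])
        assert (meth["count_methylated"] <= meth["count_total"]).all()
        truth = SyntheticTruth.from_json(paths["truth"])
        assert truth.genes["gene_id"].tolist() == [g.gene_id for g in genes]
        # genome round-trips byte-identically through FASTA
        genome2, *_ = simulate_genome(cfg, seed=9)
        assert genome["chr1"] == genome2["chr1"]
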