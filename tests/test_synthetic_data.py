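"""Generator guarantees: determinism, planted truth, error-model rates."""

from __future__ import annotations

import numpy as np
import pytest

from brcaudit.callability import (
    AUTOMATIC,
    REVIEW,
    UNCALLABLE,
    audit_catalogue,
)
from brcaudit.catalogue import merge_catalogues, read_catalogue_vcf, GERMLINE_DB
from brcaudit.pathogenicity import assign_origin, classify_cohort, cohort_summary
from brcaudit.reference_panel import (
    covered_regions,
    find_homopolymers,
    load_reference,
    read_exon_table,
    read_panel_bed,
)
from brcaudit.synthetic_data import (
    SimConfig,
    generate_catalogues,
    generate_genome,
    generate_reference,
    simulate_cohort,
    simulate_pileups,
)
from conftest import small_config


class TestGenerateGenome:
    def test_same_seed_reproduces_identical_output(self):
        ref1, runs1 = generate_reference(small_config(seed=3))
        ref2, runs2 = generate_reference(small_config(seed=3))
        assert ref1 == ref2 and runs1 == runs2
        ref3, _ = generate_reference(small_config(seed=4))
        assert ref3 != ref1

    def test_planted_runs_recovered_exactly_by_scanner(self):
        config = small_config(seed=5)
        genome = generate_genome(config)
        seq = genome.reference[config.chrom]
        scanned = find_homopolymers(seq, min(config.hp_run_lengths), config.chrom)
        assert [
            (r.interval.start, r.interval.end, r.base) for r in scanned
        ] == [(r.interval.start, r.interval.end, r.base) for r in genome.runs]

    def test_no_planted_runs_means_no_long_runs_at_all(self):
        config = small_config(seed=6, hp_run_lengths=(), frac_review=0.0,
                              frac_hp_indel=0.0)
        genome = generate_genome(config)
        assert genome.runs == ()
        assert find_homopolymers(genome.reference[config.chrom], 4) == []

    def test_exon_model_matches_requested_sizes(self):
        config = small_config(seed=1)
        genome = generate_genome(config)
        by_gene = {t.gene: t for t in genome.transcripts}
        for gene, sizes in config.exon_sizes_by_gene.items():
            assert [e.length for e in by_gene[gene].exons] == list(sizes)

    def test_gaps_are_uncovered_and_the_rest_of_exons_covered(self):
        config = small_config(seed=2)
        genome = generate_genome(config)
        covered = covered_regions(genome.panel)

        def is_covered(pos):
            return any(iv.start <= pos < iv.end for iv in covered)

        for gap in genome.gap_intervals:
            assert not any(is_covered(p) for p in range(gap.start, gap.end))
        gap_positions = {
            p for g in genome.gap_intervals for p in range(g.start, g.end)
        }
        for t in genome.transcripts:
            for e in t.exons:
                for p in range(e.start, e.end):
                    if p not in gap_positions:
                        assert is_covered(p)


class TestGenerateCatalogues:
    def test_catalogue_sizes_and_overlap(self, small_sim):
        config = small_sim["config"]
        assert len(small_sim["cat_a"]) == config.n_catalogue_a
        assert len(small_sim["cat_b"]) == config.n_catalogue_b
        merged = small_sim["catalogue"]
        expected = config.n_catalogue_a + config.n_catalogue_b - config.n_overlap
        assert len(merged) == expected

    def test_full_overlap_merge_equals_either_catalogue(self):
        config = small_config(
            seed=9, n_catalogue_a=10, n_catalogue_b=10, n_overlap=10
        )
        genome = generate_genome(config)
        cat_a, cat_b, _ = generate_catalogues(config, genome)
        merged = merge_catalogues(cat_a, cat_b)
        assert {v.key for v in merged} == {v.key for v in cat_a} == {
            v.key for v in cat_b
        }

    def test_disjoint_catalogues_merge_additively(self):
        config = small_config(seed=9, n_catalogue_a=5, n_catalogue_b=5, n_overlap=0)
        genome = generate_genome(config)
        cat_a, cat_b, _ = generate_catalogues(config, genome)
        assert len(merge_catalogues(cat_a, cat_b)) == 10

    def test_planted_composition_counts(self, small_sim):
        config = small_sim["config"]
        truths = small_sim["truths"]
        n = len(truths)
        tiers = [t.planted_tier for t in truths]
        assert tiers.count(REVIEW) == round(config.frac_review * n)
        hp = sum(
            1 for t in truths
            if t.planted_tier == UNCALLABLE and t.planted_reason == "homopolymer_indel"
        )
        gap = sum(
            1 for t in truths
            if t.planted_tier == UNCALLABLE and t.planted_reason == "not_covered"
        )
        assert hp == round(config.frac_hp_indel * n)
        assert gap == round(config.frac_gap * n)

    def test_variants_validate_against_reference(self, small_sim):
        seq = small_sim["genome"].reference[small_sim["config"].chrom]
        for v in small_sim["catalogue"]:
            assert seq[v.start : v.start + len(v.ref)] == v.ref


class TestSimulatePileups:
    def test_uncovered_loci_have_zero_depth(self, small_sim):
        truths = {t.key: t for t in small_sim["truths"]}
        for v in small_sim["catalogue"]:
            if truths[v.key].planted_reason == "not_covered":
                for sample in small_sim["pileups"]:
                    assert sample[(v.chrom, v.start)].depth == 0

    def test_depth_fluctuates_poisson_around_mean(self, small_sim):
        config = small_sim["config"]
        depths = [
            col.depth
            for sample in small_sim["pileups"]
            for col in sample.values()
            if col.depth > 0
        ]
        mean = np.mean(depths)
        # Poisson(500): the mean over ~100 loci lies well within 3 sigma
        sem = np.sqrt(config.depth_mean / len(depths))
        assert abs(mean - config.depth_mean) < 5 * sem + 5

    def test_present_variant_vaf_tracks_binomial_expectation(self):
        config = small_config(seed=13, variant_present_prob=1.0, strand_bias_fraction=0.0)
        genome = generate_genome(config)
        cat_a, cat_b, truths = generate_catalogues(config, genome)
        merged = merge_catalogues(cat_a, cat_b)
        pileups = simulate_pileups(config, genome, merged, truths, n_samples=3)
        truth_by_key = {t.key: t for t in truths}
        vafs = []
        for sample in pileups:
            for v in merged:
                if truth_by_key[v.key].planted_tier != AUTOMATIC or v.var_type != "SNV":
                    continue
                col = sample[(v.chrom, v.start)]
                fwd, rev = col.counts(v.alt)
                if fwd + rev:
                    vafs.append((fwd + rev) / col.depth)
        mean_vaf = np.mean(vafs)
        se = np.sqrt(0.25 / (len(vafs) * config.depth_mean))
        assert abs(mean_vaf - config.present_vaf) < 4 * se + 0.01

    def test_homopolymer_noise_rate_scales_with_run_length(self):
        config = small_config(
            seed=21,
            hp_run_lengths=(8,) * 4,
            hp_indel_rate_base=0.01,
            hp_indel_rate_cap=0.2,
            variant_present_prob=0.0,
            frac_hp_indel=0.08,
            frac_review=0.0,
            frac_gap=0.0,
        )
        genome = generate_genome(config)
        cat_a, cat_b, truths = generate_catalogues(config, genome)
        merged = merge_catalogues(cat_a, cat_b)
        pileups = simulate_pileups(config, genome, merged, truths, n_samples=5)
        # expected spurious indel fraction at an 8-bp run: 0.01 * 8 = 0.08
        fractions = []
        run_positions = {
            r.interval.start - 1: r.base for r in genome.runs
        }
        for sample in pileups:
            for (chrom, pos), col in sample.items():
                if pos in run_positions and col.depth:
                    fwd, rev = col.counts("-" + run_positions[pos])
                    fractions.append((fwd + rev) / col.depth)
        assert fractions, "no run-adjacent pileups simulated"
        assert np.mean(fractions) == pytest.approx(0.08, abs=0.02)

    def test_reproducible_for_fixed_seed(self, small_sim):
        config = small_sim["config"]
        again = simulate_pileups(
            config,
            small_sim["genome"],
            small_sim["catalogue"],
            small_sim["truths"],
        )
        first = small_sim["pileups"]
        assert len(again) == len(first)
        for s1, s2 in zip(first, again):
            assert s1.keys() == s2.keys()
            for key in s1:
                assert dict(s1[key].allele_counts) == dict(s2[key].allele_counts)


class TestSimulateCohort:
    def test_planted_origins_and_vaf_formulas(self):
        config = small_config(seed=19)
        observed, truths = simulate_cohort(config)
        assert len(observed) == config.n_mutated
        truth_by_key = {t.key: t for t in truths}
        for v in observed:
            t = truth_by_key[(v.sample_id, v.gene, v.hgvs_c)]
            t_true, n_true = t.planted_vafs
            if t.planted_origin == "somatic":
                assert t_true == pytest.approx(config.purity / 2)
                assert n_true == 0.0
            else:
                assert n_true == 0.5
                assert t_true in (0.5, pytest.approx(0.5 + config.purity / 2))
            # sampled VAFs stay close to the planted means at depth 500
            assert abs(v.tumour_vaf - t_true) < 0.12
            assert abs(v.normal_vaf - n_true) < 0.12

    def test_origin_recovery_with_default_thresholds(self):
        config = small_config(seed=19)
        observed, truths = simulate_cohort(config)
        truth_by_key = {t.key: t for t in truths}
        for v in observed:
            origin, _ = assign_origin(v)
            assert origin == truth_by_key[(v.sample_id, v.gene, v.hgvs_c)].planted_origin

    def test_gene_split_and_somatic_counts(self):
        config = small_config(seed=23)
        observed, truths = simulate_cohort(config)
        genes = list(config.exon_sizes_by_gene)
        per_gene = {g: sum(1 for v in observed if v.gene == g) for g in genes}
        assert per_gene == dict(zip(genes, config.mutated_gene_split))
        n_somatic = sum(1 for t in truths if t.planted_origin == "somatic")
        assert n_somatic == config.n_somatic

    def test_cohort_summary_recovers_planted_fraction(self):
        config = small_config(seed=29)
        observed, _ = simulate_cohort(config)
        calls = classify_cohort(observed, [])
        summary = cohort_summary(calls, config.n_samples)
        assert summary["n_mutated_samples"] == config.n_mutated


class TestEndToEndRecovery:
    def test_context_driven_tiers_recovered_exactly(self, small_sim):
        results = audit_catalogue(
            small_sim["catalogue"],
            small_sim["pileups"],
            small_sim["genome"].panel,
            small_sim["genome"].reference,
        )
        truth_by_key = {t.key: t for t in small_sim["truths"]}
        for r in results:
            planted = truth_by_key[r.variant.key]
            if planted.planted_tier == UNCALLABLE:
                assert r.tier == UNCALLABLE
                assert planted.planted_reason in r.reasons
            elif planted.planted_reason == "near_homopolymer":
                assert r.tier == REVIEW


class TestFileEmission:
    def test_written_files_round_trip(self, tmp_path):
        from brcaudit.synthetic_data import write_simulation

        config = small_config(seed=37)
        paths = write_simulation(config, tmp_path)
        reference = load_reference(paths["reference"])
        genome = generate_genome(config)
        assert reference == genome.reference
        panel = read_panel_bed(paths["panel"])
        assert panel.inserts == genome.panel.inserts
        transcripts = read_exon_table(paths["exons"])
        assert {t.gene for t in transcripts} == set(config.exon_sizes_by_gene)
        cat = read_catalogue_vcf(paths["catalogue_a"], GERMLINE_DB, reference)
        assert len(cat) == config.n_catalogue_a
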