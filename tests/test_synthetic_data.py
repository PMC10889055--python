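"""Generator ground truth: determinism, planted motifs, LD targets, cohorts."""

import json

import numpy as np
import pytest

from caism.annotator import count_occurrences
from caism.ld_analysis import r_squared
from caism.sequence_windows import Variant, revcomp
from caism.synthetic_data import (
    CohortSpec, PlantedFeature, PlantedSite, ScenarioSpec, answer_key,
    default_scenario, make_cohort, make_genome, make_haplotypes,
    simulate_pair_cohort, write_scenario,
)


class TestGenome:
    def test_seed_determinism(self, scenario, genome):
        again = make_genome(default_scenario(seed=7))
        assert again.extract("chr1", 0, scenario.contig_length) == \
            genome.extract("chr1", 0, scenario.contig_length)

    def test_planted_motifs_in_place(self, scenario, genome):
        """Each planted motif is present verbatim except at variant-overlap
        positions where the reference carries the major allele."""
        vs = {v.id: v for v in scenario.variants}
        for feat in scenario.features:
            for site in feat.sites:
                v = vs[site.variant_id]
                start = v.pos - 1 - site.motif_offset
                got = genome.extract(v.chrom, start, start + len(site.motif))
                expect = list(site.motif)
                expect[site.motif_offset] = v.major
                assert got == "".join(expect)

    def test_motif_counts_are_exactly_the_planted_ones(self, scenario, genome):
        """Sanitization: outside planted sites the genome contains no match —
        and no near-match reachable by one substitution — of any motif."""
        seq = genome.extract("chr1", 0, scenario.contig_length)
        planted_complete = {}
        for feat in scenario.features:
            for site in feat.sites:
                if site.present_allele == "major":
                    planted_complete[site.motif] = \
                        planted_complete.get(site.motif, 0) + 1
        for feat in scenario.features:
            for motif in feat.motifs:
                n = count_occurrences(seq, motif) + count_occurrences(
                    seq, revcomp(motif))
                assert n == planted_complete.get(motif, 0), motif

    def test_edge_margin_violation(self):
        spec = default_scenario(1)
        bad = ScenarioSpec(
            seed=1, contig_length=3000,
            variants=(Variant("v", "chr1", 100, "A", "C"),),
            features=(PlantedFeature(
                "F", "single", ("ATCGATTACG",),
                (PlantedSite("v", "ATCGATTACG", "major", motif_offset=0),)),),
            cohort=spec.cohort)
        with pytest.raises(ValueError, match="edge"):
            make_genome(bad)

    def test_contradictory_motif_allele_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            make_genome(ScenarioSpec(
                seed=1,
                variants=(Variant("v", "chr1", 10_000, "G", "C"),),
                features=(PlantedFeature(
                    "F", "single", ("ATCGATTACG",),
                    # motif has A at offset 4 but the declared allele is G
                    (PlantedSite("v", "ATCGATTACG", "major", motif_offset=4),)),),
            ))


class TestHaplotypes:
    def test_target_r2_one_identical_columns(self):
        spec = ScenarioSpec(
            seed=3,
            variants=(Variant("a", "chr1", 10_000, "A", "C", maf=0.3),
                      Variant("b", "chr1", 11_000, "G", "T", maf=0.3)),
            ld_pairs=(("a", "b", 1.0),))
        hap = make_haplotypes(spec)
        np.testing.assert_array_equal(hap.column("a"), hap.column("b"))
        assert r_squared(hap, "a", "b") == pytest.approx(1.0, abs=1e-12)

    def test_target_r2_zero_independent(self):
        spec = ScenarioSpec(
            seed=4, n_haplotypes=10_000,
            variants=(Variant("a", "chr1", 10_000, "A", "C", maf=0.3),
                      Variant("b", "chr1", 11_000, "G", "T", maf=0.3)),
            ld_pairs=(("a", "b", 0.0),))
        assert r_squared(make_haplotypes(spec), "a", "b") < 0.01

    @pytest.mark.parametrize("target", [0.5, 0.9, 0.98])
    def test_realized_r2_within_tolerance(self, target):
        spec = ScenarioSpec(
            seed=5, n_haplotypes=2000,
            variants=(Variant("a", "chr1", 10_000, "A", "C", maf=0.3),
                      Variant("b", "chr1", 11_000, "G", "T", maf=0.3)),
            ld_pairs=(("a", "b", target),))
        assert r_squared(make_haplotypes(spec), "a", "b") == \
            pytest.approx(target, abs=0.05)

    def test_variant_in_two_pairs_rejected(self):
        spec = ScenarioSpec(
            seed=6,
            variants=(Variant("a", "chr1", 10_000, "A", "C"),
                      Variant("b", "chr1", 11_000, "G", "T"),
                      Variant("c", "chr1", 12_000, "A", "T")),
            ld_pairs=(("a", "b", 0.9), ("b", "c", 0.9)))
        with pytest.raises(ValueError, match="multiple LD pairs"):
            make_haplotypes(spec)


class TestCohort:
    def test_neutral_model_matches_baseline(self):
        gt = simulate_pair_cohort(20_000, 0.3, 0.3, 0.35, seed=12)
        rate = gt.phenotype.mean()
        assert rate == pytest.approx(0.35, abs=3 * np.sqrt(0.35 * 0.65 / 20_000))

    def test_determinism(self):
        a = simulate_pair_cohort(500, 0.2, 0.4, 0.3, or_interaction=1.5, seed=2)
        b = simulate_pair_cohort(500, 0.2, 0.4, 0.3, or_interaction=1.5, seed=2)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_pair_cohort(100, 0.0, 0.3, 0.35)
        with pytest.raises(ValueError):
            simulate_pair_cohort(100, 0.3, 0.3, 1.0)
        with pytest.raises(ValueError):
            simulate_pair_cohort(100, 0.3, 0.3, 0.35, or_interaction=0.0)

    def test_scenario_cohort_covers_all_variants(self, scenario):
        gt = make_cohort(scenario)
        assert gt.variant_ids == [v.id for v in scenario.variants]
        assert gt.dosage.shape == (scenario.cohort.n_samples,
                                   len(scenario.variants))


class TestScenarioOutput:
    def test_answer_key_names_every_variant(self, scenario, key):
        ids = {v.id for v in scenario.variants}
        covered = set(key["expected_log_odds_change"]) | set(key["null_variants"])
        assert covered == ids

    def test_written_scenario_is_self_consistent(self, scenario_dir):
        from caism.annotator import SyntheticAnnotator
        from caism.epistasis import GenotypeTable
        from caism.ld_analysis import HaplotypeMatrix
        from caism.sequence_windows import load_reference, load_variants

        genome = load_reference(scenario_dir["fasta"])
        variants = load_variants(scenario_dir["variants"])
        assert len(variants) == 7
        annot = SyntheticAnnotator.load(scenario_dir["annotator"])
        assert len(annot.feature_names) == 8
        hap = HaplotypeMatrix.load(scenario_dir["haplotypes"])
        assert hap.n_haplotypes == 2000
        gt = GenotypeTable.load(scenario_dir["dosages"],
                                scenario_dir["phenotypes"])
        assert len(gt.sample_ids) == 2000
        key = json.loads(scenario_dir["answer_key"].read_text())
        assert set(key["expected_log_odds_change"]) <= {v.id for v in variants}
        # genome window matches FASTA round trip
        v = variants[0]
        assert genome.base(v.chrom, v.pos) == v.major

    def test_phased_vcf_round_trip(self, scenario_dir, scenario, haplotypes):
        from caism.ld_analysis import HaplotypeMatrix

        hap = HaplotypeMatrix.from_vcf(scenario_dir["phased_vcf"],
                                       variants=list(scenario.variants))
        for v in scenario.variants:
            np.testing.assert_array_equal(hap.column(v.id),
                                          haplotypes.column(v.id))
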