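"""Effect statistics: closed forms, background null, empirical e-values."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from caism.annotator import FeatureSpec, SyntheticAnnotator
from caism.context_enum import enumerate_contexts
from caism.effect_stats import (
    BackgroundNull, build_background, e_statistic, empirical_e_value,
    log_odds_change, records_to_frame, reversed_pass_discrepancy,
    score_variant, uniform_snv_sampler,
)
from caism.synthetic_data import candidate_exclusion_zones


class TestClosedForms:
    def test_hand_computed_values(self):
        assert log_odds_change(0.3, 0.3) == 0.0
        assert log_odds_change(0.9, 0.5) == pytest.approx(math.log(9.0), abs=1e-12)
        assert e_statistic(0.9, 0.5) == pytest.approx(math.log(9.0) * 0.4, abs=1e-12)

    def test_antisymmetry_and_symmetry(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p, q = rng.uniform(1e-6, 1 - 1e-6, size=2)
            assert log_odds_change(p, q) == pytest.approx(-log_odds_change(q, p))
            assert e_statistic(p, q) == pytest.approx(e_statistic(q, p))
            assert e_statistic(p, q) >= 0.0

    def test_sign_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p, q = rng.uniform(0.01, 0.99, size=2)
            assert np.sign(log_odds_change(p, q)) == np.sign(p - q)

    def test_rejects_degenerate_probabilities(self):
        for bad in [(0.0, 0.5), (0.5, 1.0), (1.0, 0.0)]:
            with pytest.raises(ValueError):
                log_odds_change(*bad)


class TestBackgroundNull:
    def test_same_seed_identical(self, genome, annot, scenario):
        zones = candidate_exclusion_zones(scenario)
        nulls = [
            build_background(
                genome, uniform_snv_sampler(genome, seed=99, L=2000, exclude=zones),
                annot, n=20, seed=99, L=2000)
            for _ in range(2)
        ]
        for f in nulls[0].features:
            np.testing.assert_array_equal(nulls[0].values[f], nulls[1].values[f])

    def test_n_one_vector_lengths(self, genome, annot):
        null = build_background(
            genome, uniform_snv_sampler(genome, seed=5, L=2000), annot,
            n=1, seed=5, L=2000)
        assert all(len(v) == 1 for v in null.values.values())

    def test_unplanted_background_all_zero(self, genome, annot, scenario):
        """No background variant can touch a motif: the sanitized genome has
        no position within one substitution of any motif outside the planted
        (and excluded) candidate regions."""
        zones = candidate_exclusion_zones(scenario)
        null = build_background(
            genome, uniform_snv_sampler(genome, seed=31, L=2000, exclude=zones),
            annot, n=300, seed=31, L=2000)
        for f, v in null.values.items():
            assert np.all(v == 0.0), f

    def test_save_load_round_trip(self, genome, annot, tmp_path):
        null = build_background(
            genome, uniform_snv_sampler(genome, seed=8, L=2000), annot,
            n=10, seed=8, L=2000)
        p = tmp_path / "null.tsv"
        null.save(p)
        loaded = BackgroundNull.load(p)
        assert loaded.n_background == 10
        assert loaded.metadata["seed"] == 8
        for f in null.features:
            np.testing.assert_allclose(loaded.values[f], null.values[f])


class TestEmpiricalEValue:
    def _null(self, values):
        v = np.sort(np.asarray(values, dtype=float))
        return BackgroundNull({"F": v}, len(v), {})

    def test_extreme_rank_add_one(self):
        null = self._null(np.linspace(0.0, 1.0, 999))
        assert empirical_e_value(2.0, null, "F") == pytest.approx(1 / 1000)

    def test_zero_statistic_maximal(self):
        null = self._null([0.0, 0.1, 0.2])
        assert empirical_e_value(0.0, null, "F") == 1.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(2)
        null = self._null(rng.exponential(size=500))
        stats = np.sort(rng.exponential(size=100))
        evals = [empirical_e_value(s, null, "F") for s in stats]
        assert all(a >= b for a, b in zip(evals, evals[1:]))

    def test_unknown_feature(self):
        with pytest.raises(KeyError):
            empirical_e_value(1.0, self._null([0.0]), "nope")

    def test_null_draws_uniform(self, genome):
        """E-values of null-drawn statistics against an independent null are
        uniform: KS test and the 5% rejection-rate check."""
        annot = SyntheticAnnotator(
            [FeatureSpec("dense_null", "dense", dense_seed=404)], L=2000)
        null = build_background(
            genome, uniform_snv_sampler(genome, seed=51, L=2000), annot,
            n=999, seed=51, L=2000)
        draws = build_background(
            genome, uniform_snv_sampler(genome, seed=52, L=2000), annot,
            n=1000, seed=52, L=2000)
        evals = np.array([empirical_e_value(e, null, "dense_null")
                          for e in draws.values["dense_null"]])
        assert kstest(evals, "uniform").pvalue > 0.01
        assert (evals <= 0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestScoreVariant:
    def test_planted_effects_match_closed_form(self, genome, annot, scenario,
                                               variants_by_id, key):
        for vid, feats in key["expected_log_odds_change"].items():
            center = variants_by_id[vid]
            ctxs = enumerate_contexts(center, [], "minor")
            recs = score_variant(genome, center, [], annot, None, ctxs)
            got = {r.feature: r.log_odds_change for r in recs}
            for feat, expected in feats.items():
                assert got[feat] == pytest.approx(expected, abs=1e-9)
            # all unplanted features untouched
            for feat, loc in got.items():
                if feat not in feats:
                    assert loc == pytest.approx(0.0, abs=1e-9)

    def test_null_variant_all_zero_and_maximal_e_value(
            self, genome, annot, scenario, variants_by_id):
        from caism.effect_stats import build_background
        null = build_background(
            genome,
            uniform_snv_sampler(genome, seed=13, L=2000,
                                exclude=candidate_exclusion_zones(scenario)),
            annot, n=50, seed=13, L=2000)
        center = variants_by_id["rs_null_1"]
        recs = score_variant(genome, center, [], annot, null,
                             enumerate_contexts(center, [], "minor"))
        assert all(r.e_stat == 0.0 for r in recs)
        assert all(r.e_value == 1.0 for r in recs)

    def test_cooperative_margin_closed_form(self, genome, annot,
                                            variants_by_id, key):
        info = key["context_dependent"]["rs_coop_center"]
        center = variants_by_id["rs_coop_center"]
        nbr = variants_by_id[info["neighbor"]]
        ctxs = enumerate_contexts(center, [nbr], "minor")
        recs = [r for r in score_variant(genome, center, [nbr], annot, None, ctxs)
                if r.feature == info["feature"]]
        by_ctx = {r.context_label.split(";")[1]: r.log_odds_change for r in recs}
        assert by_ctx[f"{nbr.id}=major"] == pytest.approx(
            info["loc_neighbor_major"], abs=1e-9)
        assert by_ctx[f"{nbr.id}=minor"] == pytest.approx(
            info["loc_neighbor_minor"], abs=1e-9)

    def test_non_negativity_all_records(self, genome, annot, scenario,
                                        variants_by_id):
        center = variants_by_id["rs_coop_center"]
        nbr = variants_by_id["rs_coop_neighbor"]
        recs = score_variant(genome, center, [nbr], annot, None,
                             enumerate_contexts(center, [nbr], "minor"))
        assert all(r.e_stat >= 0.0 for r in recs)

    def test_zero_neighbors_reduces_to_no_context(self, genome, annot,
                                                  variants_by_id):
        """With-context scoring restricted to the all-major context is
        bit-identical to the no-context analysis."""
        center = variants_by_id["rs_coop_center"]
        nbr = variants_by_id["rs_coop_neighbor"]
        no_ctx = score_variant(genome, center, [], annot, None,
                               enumerate_contexts(center, [], "minor"))
        with_ctx = score_variant(genome, center, [nbr], annot, None,
                                 enumerate_contexts(center, [nbr], "minor"))
        all_major = [r for r in with_ctx
                     if r.context_label == f"center=minor;{nbr.id}=major"]
        assert len(all_major) == len(no_ctx)
        for a, b in zip(no_ctx, all_major):
            assert (a.p_ref, a.p_alt, a.log_odds_change, a.e_stat) == \
                   (b.p_ref, b.p_alt, b.log_odds_change, b.e_stat)

    def test_records_frame_columns(self, genome, annot, variants_by_id):
        center = variants_by_id["rs_lof"]
        df = records_to_frame(score_variant(
            genome, center, [], annot, None,
            enumerate_contexts(center, [], "minor")))
        assert {"variant_id", "feature", "log_odds_change", "e_stat",
                "e_value", "direction"} <= set(df.columns)
        lof = df[df.feature == "DNase_glioblastoma"].iloc[0]
        assert lof.direction == "loss"


def test_reversed_pass_zero_for_symmetric_annotator(genome, annot,
                                                    variants_by_id):
    center = variants_by_id["rs_lof"]
    d = reversed_pass_discrepancy(
        genome, center, [], annot, enumerate_contexts(center, [], "minor"))
    assert d == 0.0
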