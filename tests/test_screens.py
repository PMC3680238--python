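"""Knockout / overexpression / combined screens and ranking."""

import numpy as np
import pytest

import fluxscreen as fs
from fluxscreen.screens import Perturbation, ScreenResult, rank_targets


class TestPerturbation:
    def test_kind_field_consistency_enforced(self):
        with pytest.raises(ValueError):
            Perturbation("knockout")  # no genes
        with pytest.raises(ValueError):
            Perturbation("knockout", knockout_genes={"g"}, amplified_reaction="R",
                         amplification_factor=2.0)
        with pytest.raises(ValueError):
            Perturbation("overexpression", amplified_reaction="R",
                         amplification_factor=0.0)
        ok = Perturbation("combined", knockout_genes={"g"},
                          amplified_reaction="R", amplification_factor=2.0)
        assert ok.spec_string() == "ko:g|oe:Rx2"

    def test_spec_string_sorts_genes(self):
        p = Perturbation("knockout", knockout_genes={"b", "a"})
        assert p.spec_string() == "ko:a,b"


class TestComputeFph:
    def test_identity_is_exactly_one(self, core_model, core_cond, core_ref):
        fb, fp, fph = fs.compute_fph(core_ref, core_ref, "BIO", "EX_fk")
        assert (fb, fp, fph) == (1.0, 1.0, 1.0)

    def test_exact_arithmetic(self):
        wild = fs.FluxState(fluxes={"BIO": 2.0, "EX_fk": 0.5}, status="optimal")
        mut = fs.FluxState(fluxes={"BIO": 1.0, "EX_fk": 1.0}, status="optimal")
        fb, fp, fph = fs.compute_fph(wild, mut, "BIO", "EX_fk")
        assert (fb, fp, fph) == (0.5, 2.0, 1.0)

    def test_zero_wild_product_rejected(self):
        wild = fs.FluxState(fluxes={"BIO": 2.0, "EX_fk": 0.0}, status="optimal")
        with pytest.raises(ValueError, match="product"):
            fs.compute_fph(wild, wild, "BIO", "EX_fk")

    def test_fph_is_product_of_factors(self, core_model, core_cond, core_ref, core_opts):
        results = fs.knockout_screen(core_model, core_cond, core_ref,
                                     genes=["gdh", "ppc"], options=core_opts)
        for r in results:
            if r.status == "optimal":
                assert r.f_ph == pytest.approx(r.f_biomass * r.f_product, abs=1e-9)


class TestKnockoutScreen:
    def test_gene_absent_from_gprs_behaves_as_wild_type(self, core_model, core_cond,
                                                        core_ref, core_opts):
        with pytest.warns(UserWarning):
            results = fs.knockout_screen(core_model, core_cond, core_ref,
                                         genes=["ghost"], options=core_opts)
        (r,) = results
        assert r.status == "optimal"
        assert r.f_ph == pytest.approx(1.0, abs=1e-6)

    def test_gene_order_invariance(self, core_model, core_cond, core_ref, core_opts):
        a = fs.knockout_screen(core_model, core_cond, core_ref,
                               genes=["ppc", "gdh"], options=core_opts)
        b = fs.knockout_screen(core_model, core_cond, core_ref,
                               genes=["gdh", "ppc"], options=core_opts)
        assert [r.perturbation.spec_string() for r in a] == \
               [r.perturbation.spec_string() for r in b]
        for ra, rb in zip(a, b):
            assert ra.growth == pytest.approx(rb.growth, abs=1e-9)

    def test_planted_drain_ranks_first(self, core_model, core_cond, core_ref, core_opts):
        truth = fs.planted_truth()
        results = fs.knockout_screen(core_model, core_cond, core_ref, options=core_opts)
        top = [r for r in results if r.rank == 1][0]
        assert top.perturbation.knockout_genes == {truth.knockout_gene}
        assert top.product_flux > core_ref.value("EX_fk")

    def test_growth_filter_excludes_slow_mutants_from_ranking(
            self, core_model, core_cond, core_ref, core_opts):
        results = fs.knockout_screen(core_model, core_cond, core_ref, options=core_opts)
        for r in results:
            if r.status == "optimal" and not r.passes_growth_filter:
                assert r.rank is None

    def test_pairwise_screen_enumerates_unordered_pairs(self, core_model, core_cond,
                                                        core_ref, core_opts):
        results = fs.knockout_screen(core_model, core_cond, core_ref,
                                     genes=["gdh", "ppc", "pnt"], pairs=True,
                                     options=core_opts)
        specs = {r.perturbation.spec_string() for r in results}
        assert specs == {"ko:gdh,ppc", "ko:gdh,pnt", "ko:pnt,ppc"}

    def test_resolving_recorded_perturbation_reproduces_result(
            self, core_model, core_cond, core_ref, core_opts):
        """Every optimal record can be reproduced from scratch to 1e-6."""
        results = fs.knockout_screen(core_model, core_cond, core_ref,
                                     genes=["gdh", "ppc", "tcaA"], options=core_opts)
        for r in results:
            if r.status != "optimal":
                continue
            cs = core_cond.without("EX_fk").merge(
                fs.knockout_bounds(core_model, r.perturbation.knockout_genes))
            again = fs.solve_moma(core_model, cs, core_ref)
            assert again.value("BIO") == pytest.approx(r.growth, abs=1e-6)
            assert again.value("EX_fk") == pytest.approx(r.product_flux, abs=1e-6)


class TestOverexpressionScreen:
    def test_k1_pins_at_reference_all_fph_one(self, core_model, core_cond,
                                              core_ref, core_opts):
        opts = fs.ScreenOptions(k=1.0, growth_min=core_opts.growth_min)
        results = fs.overexpression_screen(core_model, core_cond, core_ref, options=opts)
        assert results
        for r in results:
            assert r.status == "optimal"
            assert r.f_ph == pytest.approx(1.0, abs=1e-6)

    def test_zero_flux_candidates_skipped(self, core_model, core_cond,
                                          core_ref, core_opts):
        results = fs.overexpression_screen(core_model, core_cond, core_ref,
                                           options=core_opts)
        screened = {r.perturbation.amplified_reaction for r in results}
        assert "PNT" not in screened  # idle valve: nothing to amplify

    def test_supra_optimal_biomass_pin_is_lethal(self, core_model, core_cond,
                                                 core_ref, core_opts):
        results = fs.overexpression_screen(core_model, core_cond, core_ref,
                                           candidates=["BIO"], options=core_opts)
        (r,) = results
        assert r.status == "lethal"
        assert r.rank is None

    def test_pin_clipped_to_bounds_reported_bound_limited(self, core_model, core_cond,
                                                          core_ref, core_opts):
        # GDH runs at its capacity in the reference: 2x exceeds its bounds
        results = fs.overexpression_screen(core_model, core_cond, core_ref,
                                           candidates=["GDH"], options=core_opts)
        (r,) = results
        assert r.bound_limited
        assert r.f_ph == pytest.approx(1.0, abs=1e-6)  # clipped back to reference

    def test_planted_supply_step_ranks_first(self, core_model, core_cond,
                                             core_ref, core_opts):
        truth = fs.planted_truth()
        results = fs.overexpression_screen(core_model, core_cond, core_ref,
                                           options=core_opts)
        top = [r for r in results if r.rank == 1][0]
        assert top.perturbation.amplified_reaction == truth.overexpression_reaction


class TestCombinedScreen:
    def test_empty_knockout_with_k1_gives_fph_one(self, core_model, core_cond,
                                                  core_ref, core_opts):
        opts = fs.ScreenOptions(k=1.0, growth_min=core_opts.growth_min)
        results = fs.combined_screen(core_model, core_cond, core_ref,
                                     knockout_sets=[()], oe_candidates=["PSUP"],
                                     options=opts)
        (r,) = results
        assert r.f_ph == pytest.approx(1.0, abs=1e-6)

    def test_pinned_reaction_disabled_by_knockout_skipped(self, core_model, core_cond,
                                                          core_ref, core_opts):
        results = fs.combined_screen(core_model, core_cond, core_ref,
                                     knockout_sets=[("dahp",)], oe_candidates=["PSUP"],
                                     options=core_opts)
        assert results == []

    def test_synergy_of_planted_pair_exceeds_singles(self, core_model, core_cond,
                                                     core_ref, core_opts):
        """The fixture couples drain and supply through the NADPH pool:
        knocking the drain AND amplifying the supply beats either alone
        on f_PH (super-additivity by construction)."""
        truth = fs.planted_truth()
        combo = fs.combined_screen(core_model, core_cond, core_ref,
                                   knockout_sets=[(truth.knockout_gene,)],
                                   oe_candidates=[truth.overexpression_reaction],
                                   options=core_opts)
        (both,) = combo
        ko = fs.knockout_screen(core_model, core_cond, core_ref,
                                genes=[truth.knockout_gene], options=core_opts)[0]
        oe = fs.overexpression_screen(core_model, core_cond, core_ref,
                                      candidates=[truth.overexpression_reaction],
                                      options=core_opts)[0]
        assert both.f_ph >= max(ko.f_ph, oe.f_ph)
        assert both.product_flux >= max(ko.product_flux, oe.product_flux)


def _result(spec, fph, growth, status="optimal"):
    return ScreenResult(
        perturbation=Perturbation("overexpression", amplified_reaction=spec,
                                  amplification_factor=2.0),
        status=status, growth=growth, product_flux=0.0,
        f_biomass=1.0, f_product=fph, f_ph=fph,
        passes_growth_filter=True,
    )


class TestRankTargets:
    def test_stable_order_for_equal_scores(self):
        results = [_result(s, 1.0, 1.0) for s in ["R1", "R2", "R3"]]
        # equal score, growth and distinct spec: lexicographic spec decides,
        # which here coincides with input order
        ranked = rank_targets(results, by="f_ph", growth_min=None)
        assert [r.perturbation.amplified_reaction for r in ranked] == ["R1", "R2", "R3"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_lethal_entries_last_and_unranked(self):
        results = [_result("R1", 2.0, 1.0), _result("R2", 0.0, 0.0, status="lethal")]
        ranked = rank_targets(results, by="f_ph", growth_min=None)
        assert ranked[-1].status == "lethal"
        assert ranked[-1].rank is None

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(11)
        results = [_result(f"R{i}", float(rng.integers(0, 5)), float(rng.integers(0, 3)))
                   for i in range(30)]
        ranked = rank_targets(results, by="f_ph", growth_min=None)
        expected = sorted(
            results,
            key=lambda r: (-r.f_ph, -r.growth, r.perturbation.spec_string()),
        )
        assert [r.perturbation.spec_string() for r in ranked] == \
               [r.perturbation.spec_string() for r in expected]

    def test_growth_filter_boundary_inclusive(self):
        results = [_result("R1", 1.0, 0.04), _result("R2", 2.0, 0.039)]
        ranked = rank_targets(results, by="f_ph", growth_min=0.04)
        assert ranked[0].perturbation.amplified_reaction == "R1"
        assert ranked[0].rank == 1 and ranked[1].rank is None

    def test_unknown_sort_key_rejected(self):
        with pytest.raises(ValueError):
            rank_targets([], by="growth")


class TestGeneLevelScores:
    def test_gene_score_is_max_over_its_reactions(self, core_model, core_cond,
                                                  core_ref, core_opts):
        results = fs.overexpression_screen(core_model, core_cond, core_ref,
                                           options=core_opts)
        best = fs.gene_level_scores(core_model, results)
        assert best["dahp"].perturbation.amplified_reaction == "PSUP"
        for gene, res in best.items():
            for r in results:
                rid = r.perturbation.amplified_reaction
                if r.status == "optimal" and gene in core_model.reactions[rid].genes:
                    assert res.f_ph >= r.f_ph - 1e-12
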