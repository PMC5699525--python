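"""The up-regulated pathway analysis pipeline, stage by stage."""

import math

import pytest

import upfinder as uf
from upfinder.model_io import report_lines
from upfinder.synthetic import ToySpec
from upfinder.upa import CandidateRecord, UPAOptions, rank_candidates

INF = math.inf


# ---------------------------------------------------------------------------
# Demand augmentation & biomass selection
# ---------------------------------------------------------------------------


def test_ensure_demand_reuses_existing_drain(branch):
    model, demand_id = uf.ensure_demand(branch, "p_c")
    assert demand_id == "DM_p"
    assert model is branch  # unchanged, not copied
    again, demand_again = uf.ensure_demand(model, "p_c")
    assert demand_again == "DM_p" and again is model


def test_ensure_demand_appends_drain_with_standard_bounds(lin3):
    model, demand_id = uf.ensure_demand(lin3, "m2")
    assert demand_id == "DM_m2"
    rec = model.reaction("DM_m2")
    assert (rec.lower_bound, rec.upper_bound) == (0.0, 1000.0)
    assert rec.stoichiometry == {"m2": -1.0}
    assert not lin3.has_reaction("DM_m2")  # original untouched
    model2, _ = uf.ensure_demand(model, "m2")
    assert model2 is model  # second call reuses the new drain


def test_ensure_demand_unknown_metabolite(branch):
    with pytest.raises(KeyError):
        uf.ensure_demand(branch, "ghost_c")


def test_select_biomass_auto_unique_and_explicit(branch):
    assert uf.select_biomass(branch) == "BIO"
    assert uf.select_biomass(branch, "RB") == "RB"
    with pytest.raises(KeyError):
        uf.select_biomass(branch, "NOPE")


def test_select_biomass_requires_flag_for_multiple_objectives(branch):
    branch.cobra_model.reactions.get_by_id("RB").objective_coefficient = 1.0
    branch._rebuild_records()
    with pytest.raises(uf.UPAError, match="several objective reactions"):
        uf.select_biomass(branch)
    assert uf.select_biomass(branch, "BIO") == "BIO"


# ---------------------------------------------------------------------------
# Wild-type and maximum-yield states
# ---------------------------------------------------------------------------


def test_wild_type_fluxes_close_the_demand(branch):
    wt = uf.wild_type_fluxes(branch, "BIO", demand_id="DM_p")
    assert wt.flux("DM_p") == pytest.approx(0.0)
    assert wt.flux("RB") == pytest.approx(8.0)
    assert wt.flux("RP") == pytest.approx(2.0)
    assert wt.objective_value == pytest.approx(10.0)


def test_wild_type_fluxes_scale_with_uptake_override(branch):
    opts = UPAOptions(bound_overrides={})
    branch.apply_bounds({"EX_glc": (-5.0, 1000.0)})
    wt = uf.wild_type_fluxes(branch, "BIO", opts, demand_id="DM_p")
    assert wt.objective_value == pytest.approx(5.0)
    assert wt.flux("RB") == pytest.approx(4.0)


def test_wild_type_zero_uptake_idles_the_network(branch):
    branch.apply_bounds({"EX_glc": (0.0, 0.0)})
    wt = uf.wild_type_fluxes(branch, "BIO", demand_id="DM_p")
    assert all(abs(v) < 1e-9 for v in wt.fluxes.values())


def test_optimum_fluxes_branch(branch):
    opt = uf.optimum_fluxes(branch, "DM_p")
    assert opt.objective_value == pytest.approx(10.0)
    assert opt.flux("RP") == pytest.approx(10.0)
    assert opt.flux("BIO") == pytest.approx(0.0)


def test_optimum_fluxes_linear_interior_target(lin3):
    model, demand_id = uf.ensure_demand(lin3, "m2")
    opt = uf.optimum_fluxes(model, demand_id)
    assert opt.objective_value == pytest.approx(10.0)
    assert opt.flux("R2") == pytest.approx(0.0)


def test_unproducible_target_returns_empty_result_with_warning(branch, caplog):
    cm = branch.cobra_model
    import cobra

    cm.add_metabolites([cobra.Metabolite("orphan_c", compartment="c")])
    branch._rebuild_records()
    with caplog.at_level("WARNING", logger="upfinder.upa"):
        result = uf.run_upa(branch, "orphan_c")
    assert result.candidates == []
    assert result.theoretical_max_yield == pytest.approx(0.0, abs=1e-9)
    assert any("not producible" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------------------
# Detection and re-verification
# ---------------------------------------------------------------------------


def test_detect_upregulated_branch_finds_only_the_product_branch(branch):
    wt = uf.wild_type_fluxes(branch, "BIO", demand_id="DM_p")
    opt = uf.optimum_fluxes(branch, "DM_p")
    assert uf.detect_upregulated(wt, opt, branch) == ["RP"]


def test_detect_upregulated_linear_chain_has_no_candidates(lin3):
    model, demand_id = uf.ensure_demand(lin3, "m2")
    wt = uf.wild_type_fluxes(model, "BIO", demand_id=demand_id)
    opt = uf.optimum_fluxes(model, demand_id)
    assert uf.detect_upregulated(wt, opt, model) == []


def test_detect_upregulated_newly_activated_reaction_gets_inf_ratio():
    # biomass consuming only B leaves RP silent in the wild type
    model = uf.make_branch_model(ToySpec(biomass_stoichiometry={"b_c": 1.0}))
    result = uf.run_upa(model, "p_c")
    assert [c.reaction_id for c in result.candidates] == ["RP"]
    cand = result.candidates[0]
    assert math.isinf(cand.ratio)
    assert cand.flux_wt == pytest.approx(0.0, abs=1e-9)
    assert cand.yield_value == pytest.approx(10.0)


def test_verify_yield_branch_candidate(branch):
    model, demand_id = uf.ensure_demand(branch, "p_c")
    y = uf.verify_yield(model, "RP", 10.0, "BIO", demand_id)
    assert y == pytest.approx(10.0)


def test_verify_yield_degradation_consumes_forced_flux(degradation):
    model, demand_id = uf.ensure_demand(degradation, "p_c")
    assert uf.verify_yield(model, "RP", 10.0, "BIO", demand_id) == pytest.approx(0.0)


def test_verify_yield_infeasible_clamp_maps_to_zero(branch):
    # RB clamped at 10 demands more carbon than the uptake limit allows
    model, demand_id = uf.ensure_demand(branch, "p_c")
    assert uf.verify_yield(model, "RB", 10.0, "BIO", demand_id) == 0.0


def test_genes_for_flattens_and_sorts(branch):
    assert uf.genes_for(branch, "RP") == ["gRP1", "gRP2", "gRP3"]
    assert uf.genes_for(branch, "T1") == ["gT1"]
    assert uf.genes_for(branch, "BIO") == []
    with pytest.raises(KeyError):
        uf.genes_for(branch, "NOPE")


# ---------------------------------------------------------------------------
# Ranking and module grouping
# ---------------------------------------------------------------------------


def _cand(rid, ratio, y):
    return CandidateRecord(
        reaction_id=rid, reaction_name=rid, genes=[], formula="",
        flux_wt=1.0, flux_opt=ratio if not math.isinf(ratio) else 5.0,
        ratio=ratio, yield_value=y,
    )


@pytest.mark.parametrize(
    "records, expected_order",
    [
        ([_cand("A", 5, 1), _cand("B", INF, 1), _cand("C", 2, 1)], ["B", "A", "C"]),
        ([_cand("A", 5, 3), _cand("B", 5, 10)], ["B", "A"]),  # yield tie-break
        ([_cand("A", 5, 1), _cand("B", 5, 1)], ["A", "B"]),  # id tie-break
        ([_cand("A", 5, 0.0), _cand("B", 2, 1)], ["B"]),  # zero yield dropped
        ([_cand("A", 1.0, 5)], []),  # ratio not above 1 dropped
    ],
)
def test_rank_candidates_sorting_and_filtering(records, expected_order):
    result = rank_candidates(records, UPAOptions())
    assert [c.reaction_id for c in result.candidates] == expected_order
    assert [c.rank for c in result.candidates] == list(
        range(1, len(expected_order) + 1)
    )


@pytest.mark.parametrize(
    "ratios, expected_modules",
    [
        ([10.0, 9.8, 4.0], [1, 1, 2]),
        ([7.0], [1]),
        ([INF, INF, 10.0, 9.8, 4.0], [1, 1, 2, 2, 3]),
        ([10.0, 10.0, 10.0], [1, 1, 1]),
    ],
)
def test_group_modules_splits_on_relative_ratio_gaps(ratios, expected_modules):
    records = [_cand(f"R{i}", r, 1.0) for i, r in enumerate(ratios)]
    result = uf.group_modules(rank_candidates(records, UPAOptions()))
    assert [c.module for c in result.candidates] == expected_modules


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def test_run_upa_branch_full_pipeline(branch):
    result = uf.run_upa(branch, "p[c]")
    assert result.demand_id == "DM_p"
    assert result.biomass_id == "BIO"
    assert result.theoretical_max_yield == pytest.approx(10.0)
    assert len(result.candidates) == 1
    cand = result.candidates[0]
    assert cand.reaction_id == "RP"
    assert cand.flux_wt == pytest.approx(2.0)
    assert cand.flux_opt == pytest.approx(10.0)
    assert cand.ratio == pytest.approx(5.0)
    assert cand.yield_value == pytest.approx(10.0)
    assert (cand.rank, cand.module) == (1, 1)
    assert cand.genes == ["gRP1", "gRP2", "gRP3"]


def test_run_upa_is_idempotent(branch):
    first = report_lines(uf.run_upa(branch, "p[c]"))
    second = report_lines(uf.run_upa(branch, "p[c]"))
    assert first == second


def test_run_upa_linear_and_degradation_are_empty(lin3, degradation):
    assert uf.run_upa(lin3, "m2").candidates == []
    assert uf.run_upa(degradation, "p_c").candidates == []


def test_run_upa_scaling_invariance(branch):
    base = uf.run_upa(branch, "p_c")
    k = 0.5
    scaled_opts = UPAOptions(
        bound_overrides={
            rec.id: (rec.lower_bound * k, rec.upper_bound * k)
            for rec in branch.reactions
        }
    )
    scaled = uf.run_upa(branch, "p_c", scaled_opts)
    assert [c.reaction_id for c in scaled.candidates] == [
        c.reaction_id for c in base.candidates
    ]
    for a, b in zip(scaled.candidates, base.candidates):
        assert a.ratio == pytest.approx(b.ratio, rel=1e-6)
        assert a.module == b.module
        assert a.yield_value == pytest.approx(b.yield_value * k, rel=1e-6)


def test_run_upa_yields_bounded_by_theoretical_max(branch):
    result = uf.run_upa(branch, "p_c")
    for cand in result.candidates:
        assert cand.yield_value <= result.theoretical_max_yield + 1e-6


def test_run_upa_pfba_mode_matches_on_nondegenerate_toy(branch):
    plain = uf.run_upa(branch, "p_c")
    pfba = uf.run_upa(branch, "p_c", UPAOptions(use_pfba=True))
    assert report_lines(plain) == report_lines(pfba)


def test_options_validation():
    with pytest.raises(ValueError):
        UPAOptions(eps_flux=0.0)
    with pytest.raises(ValueError):
        UPAOptions(yield_mode="bogus")
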