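"""Model structures, I/O round trips, pathway edits, medium, mass balance."""

import json

import pytest

from gabaflux import (
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelEdit,
    Reaction,
    add_butyrolactam_pathway,
    add_gaba_pathway,
    apply_edits,
    check_mass_balance,
    load_model,
    maximize,
    save_model,
    set_medium,
)
from gabaflux.metnet import (
    ConfigurationError,
    EditError,
    ModelError,
    ParseError,
    format_formula,
    parse_formula,
)
from gabaflux.synthetic import CoreModelParams, build_core_model


def three_reaction_fixture() -> dict:
    return {
        "id": "tiny",
        "metabolites": [
            {"id": "a_c", "compartment": "c"},
            {"id": "b_c", "compartment": "c"},
            {"id": "a_e", "compartment": "e"},
        ],
        "reactions": [
            {"id": "EX_a", "stoichiometry": {"a_e": -1},
             "lower_bound": -10, "upper_bound": 0},
            {"id": "T_a", "stoichiometry": {"a_e": -1, "a_c": 1}, "lower_bound": 0},
            {"id": "R1", "stoichiometry": {"a_c": -1, "b_c": 1}, "lower_bound": 0},
        ],
        "objective": {"R1": 1.0},
    }


class TestJsonIO:
    def test_three_reaction_fixture_loads(self, tmp_path):
        path = tmp_path / "tiny.json"
        path.write_text(json.dumps(three_reaction_fixture()))
        model = load_model(path)
        assert len(model.reactions) == 3
        assert len(model.metabolites) == 3

    @pytest.mark.parametrize("fmt", ["json", "sbml"])
    def test_round_trip_identity(self, core_model, tmp_path, fmt):
        suffix = "json" if fmt == "json" else "xml"
        path = tmp_path / f"core.{suffix}"
        save_model(core_model, path, format=fmt)
        reloaded = load_model(path, format=fmt)
        assert reloaded == core_model
        # save-load-save is stable too
        path2 = tmp_path / f"core2.{suffix}"
        save_model(reloaded, path2, format=fmt)
        assert load_model(path2, format=fmt) == core_model

    def test_unknown_metabolite_is_named_in_error(self, tmp_path):
        data = three_reaction_fixture()
        data["reactions"][2]["stoichiometry"] = {"a_c": -1, "foo": 1}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ParseError, match="foo"):
            load_model(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        data = three_reaction_fixture()
        data["reactions"].append(dict(data["reactions"][0]))
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ParseError, match="duplicate"):
            load_model(path)

    def test_malformed_bound_rejected(self, tmp_path):
        data = three_reaction_fixture()
        data["reactions"][0]["lower_bound"] = "minus ten"
        path = tmp_path / "badbound.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ParseError, match="bound"):
            load_model(path)

    def test_model_without_objective_round_trips(self, tmp_path):
        data = three_reaction_fixture()
        data["objective"] = {}
        path = tmp_path / "noobj.json"
        path.write_text(json.dumps(data))
        model = load_model(path)
        out = tmp_path / "noobj2.json"
        save_model(model, out)
        assert load_model(out) == model
        assert model.objective == {}

    def test_bounds_default_to_1000(self, tmp_path):
        data = three_reaction_fixture()
        del data["reactions"][2]["lower_bound"]
        path = tmp_path / "nodefault.json"
        path.write_text(json.dumps(data))
        model = load_model(path)
        assert model.reactions["R1"].lower_bound == -1000
        assert model.reactions["R1"].upper_bound == 1000


class TestFormula:
    @pytest.mark.parametrize(
        "text,counts",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("H2O", {"H": 2, "O": 1}),
            ("C21H36N7O16P3S", {"C": 21, "H": 36, "N": 7, "O": 16, "P": 3, "S": 1}),
        ],
    )
    def test_parse_format_round_trip(self, text, counts):
        assert parse_formula(text) == counts
        assert parse_formula(format_formula(counts)) == counts

    def test_negative_formula_count_rejected(self):
        with pytest.raises(ModelError):
            Metabolite("x", formula={"C": -1})


class TestGabaPathway:
    def test_gad_stoichiometry_is_decarboxylation(self, core_no_shunt):
        base = build_core_model(CoreModelParams(include_gad=False,
                                                include_gaba_shunt=False))
        edited = add_gaba_pathway(base)
        gad = edited.reactions["GAD"]
        assert gad.stoichiometry == {"glu_c": -1.0, "4aba_c": 1.0, "co2_c": 1.0}
        assert gad.reversible  # written with a double arrow
        assert edited.reactions_by_role("GABA_EXPORT")

    def test_adds_exactly_three_reactions_to_bare_model(self):
        model = MetabolicModel(
            "bare",
            [Metabolite("glu_c", formula=parse_formula("C5H9NO4")),
             Metabolite("co2_c", formula=parse_formula("CO2"))],
            [],
        )
        edited = add_gaba_pathway(model)
        assert len(edited.reactions) == len(model.reactions) + 3

    def test_applying_twice_errors(self, core_model):
        with pytest.raises(ConfigurationError, match="GAD"):
            add_gaba_pathway(core_model)

    def test_missing_species_is_configuration_error(self):
        model = MetabolicModel("empty", [], [])
        with pytest.raises(ConfigurationError, match="glutamate"):
            add_gaba_pathway(model)

    def test_no_new_elemental_imbalance(self):
        base = build_core_model(CoreModelParams(include_gad=False,
                                                include_gaba_shunt=False))
        edited = add_gaba_pathway(base)
        assert check_mass_balance(edited).imbalanced == {}


class TestButyrolactamPathway:
    def test_coa_moiety_conserved(self, core_model):
        edited = add_butyrolactam_pathway(core_model)
        act = edited.reactions["ACT"]
        # acetyl-CoA in, free CoA out: net CoA-moiety balance zero
        assert act.stoichiometry["accoa_c"] == -1.0
        assert act.stoichiometry["coa_c"] == 1.0
        assert check_mass_balance(edited).imbalanced == {}

    def test_butyrolactam_exportable_after_edit(self, core_model):
        edited = add_butyrolactam_pathway(core_model)
        state = maximize(edited, "EX_blm_c")
        assert state.optimal and state.objective_value > 0.1

    def test_missing_acetyl_coa_is_configuration_error(self):
        model = MetabolicModel(
            "noacc", [Metabolite("4aba_c", formula=parse_formula("C4H9NO2"))], []
        )
        with pytest.raises(ConfigurationError, match="accoa"):
            add_butyrolactam_pathway(model)


class TestEdits:
    def test_delete_fixes_bounds_to_zero(self, core_model):
        edited = apply_edits(
            core_model, [ModelEdit("delete_reaction", "role:SUCOAS", "dsucCD")]
        )
        rxn = edited.reaction_by_role("SUCOAS")
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
        assert rxn.id in edited.reactions  # retained for reporting

    def test_empty_edit_list_is_identity(self, core_model):
        assert apply_edits(core_model, []) == core_model

    def test_scale_bounds_inverse_pair_restores(self, core_model):
        before = core_model.reactions["PDH"]
        edited = apply_edits(
            core_model,
            [ModelEdit("scale_bounds", ("PDH", 2.0)),
             ModelEdit("scale_bounds", ("PDH", 0.5))],
        )
        after = edited.reactions["PDH"]
        assert (after.lower_bound, after.upper_bound) == (
            before.lower_bound, before.upper_bound
        )

    def test_edits_do_not_mutate_source(self, core_model):
        snapshot = core_model.to_dict()
        apply_edits(core_model, [ModelEdit("delete_reaction", "role:GAD", "dgad")])
        assert core_model.to_dict() == snapshot

    def test_missing_reaction_error_names_edit_label(self, core_model):
        with pytest.raises(EditError, match="my-edit"):
            apply_edits(core_model, [ModelEdit("delete_reaction", "NOPE", "my-edit")])

    def test_delete_equivalent_to_zero_bounds_for_fba(self, core_model):
        deleted = apply_edits(
            core_model, [ModelEdit("delete_reaction", "role:ACEA", "daceA")]
        )
        pruned = core_model.copy()
        del pruned.reactions["ICL"]
        a = maximize(deleted, "BIOMASS").objective_value
        b = maximize(pruned, "BIOMASS").objective_value
        assert a == pytest.approx(b, abs=1e-9)


class TestMedium:
    def test_fixed_uptake_becomes_equality(self, core_model):
        medium = MediumSpec(fixed_uptakes={"EX_glc_e": 4.67},
                            free_exchanges=["EX_o2_c"])
        out = set_medium(core_model, medium)
        glc = out.reactions["EX_glc_e"]
        assert (glc.lower_bound, glc.upper_bound) == (-4.67, -4.67)

    def test_free_exchange_opens_both_directions(self, core_model):
        out = set_medium(core_model, MediumSpec(free_exchanges=["EX_o2_c"]))
        o2 = out.reactions["EX_o2_c"]
        assert (o2.lower_bound, o2.upper_bound) == (-1000.0, 1000.0)

    def test_zero_uptake_gives_zero_growth(self):
        # no carbon, no flux; maintenance ATP must be off or the model is
        # (correctly) infeasible rather than resting at zero
        model = build_core_model(CoreModelParams(atp_maintenance=0.0))
        free = [r.id for r in model.exchanges() if r.id != "EX_glc_e"]
        out = set_medium(
            model, MediumSpec(fixed_uptakes={"EX_glc_e": 0.0},
                              free_exchanges=free)
        )
        state = maximize(out, "BIOMASS")
        assert state.optimal
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unlisted_exchange_closed_to_uptake(self, core_model):
        out = set_medium(core_model, MediumSpec(fixed_uptakes={"EX_glc_e": 4.67}))
        assert out.reactions["EX_o2_c"].lower_bound == 0.0

    def test_unknown_exchange_rejected(self, core_model):
        with pytest.raises(ModelError, match="EX_nope"):
            set_medium(core_model, MediumSpec(fixed_uptakes={"EX_nope": 1.0}))

    def test_negative_rate_rejected(self):
        with pytest.raises(ModelError):
            MediumSpec(fixed_uptakes={"EX_glc_e": -1.0})


class TestMassBalance:
    def test_core_model_is_balanced(self, core_model):
        report = check_mass_balance(core_model)
        assert report.imbalanced == {}
        assert "BIOMASS" in report.skipped  # biomass pseudo-metabolite

    def test_corrupted_coefficient_detected(self, core_model):
        broken = core_model.copy()
        broken.reactions["CS"].stoichiometry["cit_c"] += 1.0
        report = check_mass_balance(broken)
        assert "CS" in report.imbalanced
        assert report.imbalanced["CS"].get("C")

    def test_model_without_formulas_all_skipped(self, m1):
        report = check_mass_balance(m1)
        assert report.imbalanced == {}
        assert "R_AB" in report.skipped
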