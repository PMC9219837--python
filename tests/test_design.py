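"""Design analytics: multiplier scan, delta map, node split, robustness
surface, strain series."""

import numpy as np
import pytest

from gabaflux import (
    ProductionConstraint,
    acn_scan,
    delta_map,
    double_robustness,
    export_share,
    maximize,
    node_split,
    packaged_strain_series,
    pfba,
    production_fba,
    strain_series,
    theoretical_max_yield,
)
from gabaflux.design import ScanError, ScanSpec
from gabaflux.fba import FBAError
from gabaflux.synthetic import oracle_solve


def constrained_scan_instance(model, k, v0, floor):
    """Rebuild one scan cell as a standalone model for the oracle."""
    acn = model.reaction_by_role("ACN").id
    biomass = model.reaction_by_role("BIOMASS").id
    cell = model.copy()
    cell.reactions[acn].lower_bound = cell.reactions[acn].upper_bound = k * v0
    cell.reactions[biomass].lower_bound = floor
    return cell


class TestAcnScan:
    def test_spec_validates_multipliers(self):
        with pytest.raises(ScanError):
            ScanSpec(product_rxn="EX_gaba", multipliers=(1.0, 0.5))
        with pytest.raises(ScanError):
            ScanSpec(product_rxn="EX_gaba", multipliers=(-1.0, 2.0))

    def test_unit_multiplier_column_consistent_with_state(self, shunt_leak):
        result = acn_scan(shunt_leak, ScanSpec(product_rxn="EX_gaba"))
        state = result.states[1.0]
        wt = result.reference_state
        uptake = abs(state.fluxes["EX_s"])
        for rxn_id in state.fluxes:
            expected = (state.fluxes[rxn_id] - wt.fluxes[rxn_id]) / uptake
            assert result.delta_matrix.loc[rxn_id, 1.0] == pytest.approx(
                expected, abs=1e-9
            )

    def test_product_trace_matches_oracle_per_cell(self, shunt_leak):
        result = acn_scan(shunt_leak, ScanSpec(product_rxn="EX_gaba"))
        floor = 0.2 * result.reference_state.objective_value
        for k, value in result.product_trace.items():
            cell = constrained_scan_instance(shunt_leak, k, result.reference_flux,
                                             floor)
            cell.objective = {"EX_gaba": 1.0}
            oracle = oracle_solve(cell)
            assert value == pytest.approx(oracle.objective_value, abs=1e-6), k

    def test_forced_high_flux_recruits_gaba_shunt(self, shunt_leak):
        result = acn_scan(shunt_leak, ScanSpec(product_rxn="EX_gaba"))
        shunt_lo = result.states[1.0].fluxes["GABA_TA"]
        shunt_hi = result.states[3.0].fluxes["GABA_TA"]
        assert shunt_hi >= shunt_lo - 1e-9
        assert shunt_hi > shunt_lo + 0.1  # strict recruitment on this fixture

    def test_trace_bounded_by_theoretical_max(self, core_model):
        result = acn_scan(core_model, ScanSpec(product_rxn="EX_4aba_e"))
        cap = theoretical_max_yield(core_model, "EX_4aba_e", "EX_glc_e") * 4.67
        for value in result.product_trace.values():
            if value is not None:
                assert value <= cap + 1e-6

    def test_best_multiplier_ties_break_to_smallest(self, core_model):
        result = acn_scan(core_model, ScanSpec(product_rxn="EX_4aba_e"))
        feasible = {k: v for k, v in result.product_trace.items() if v is not None}
        best_value = max(feasible.values())
        expected = min(k for k, v in feasible.items()
                       if v >= best_value - 1e-12)
        assert result.best_multiplier == expected

    def test_zero_reference_flux_is_scan_error(self, akg_node):
        # akg_node's WT solution leaves the GAD-branch lump unused; a model
        # whose ACN-role reaction idles at WT has no multiplier reference
        silent = akg_node.copy()
        silent.reactions["RED"].role = None
        silent.reactions["GADL"].role = "ACN"
        with pytest.raises(ScanError, match="zero"):
            acn_scan(silent, ScanSpec(product_rxn="EX_gaba"))


class TestDeltaMap:
    def test_self_comparison_all_unchanged(self, core_model):
        wt = pfba(core_model, "BIOMASS")
        dm = delta_map(wt, wt, "EX_glc_e")
        assert (dm.table["direction"] == "unchanged").all()
        assert (dm.table["delta_normalized"].abs() < 1e-12).all()

    def test_sign_flip_classified_reversed(self, core_model):
        wt = pfba(core_model, "BIOMASS")
        alt = pfba(core_model, "BIOMASS")
        alt.fluxes["SUCOAS"] = -2.0
        wt.fluxes["SUCOAS"] = 2.0
        dm = delta_map(wt, alt, "EX_glc_e")
        assert dm.direction("SUCOAS") == "reversed"

    def test_producer_redirects_tca_entry_up(self, core_model):
        """Citrate synthase carries more flux in the producer than in the WT."""
        wt = pfba(core_model, "BIOMASS")
        prod = production_fba(core_model, ProductionConstraint("EX_4aba_e", 0.2))
        dm = delta_map(wt, prod, "EX_glc_e")
        assert dm.direction("CS") == "up"
        # EMP rises while the oxidative PPP falls in the producer
        assert dm.direction("PGI") == "up"
        assert dm.direction("PPP_OX") == "down"

    def test_mismatched_universes_rejected(self, core_model, m1):
        wt = pfba(core_model, "BIOMASS")
        other = maximize(m1)
        with pytest.raises(FBAError):
            delta_map(wt, other, "EX_glc_e")


class TestNodeSplit:
    def test_fractions_sum_to_one(self, core_model):
        prod = production_fba(core_model, ProductionConstraint("EX_4aba_e", 0.2))
        for met in ("akg_c", "pyr_c", "accoa_c", "nadph_c"):
            split = node_split(prod, core_model, met)
            assert sum(split.values()) == pytest.approx(1.0, abs=1e-6)

    def test_akg_node_producer_fractions_match_oracle(self, akg_node):
        floored = akg_node.copy()
        floored.reactions["BIOMASS"].lower_bound = 2.0  # 0.2 x mu* = 2
        floored.objective = {"EX_gaba": 1.0}
        oracle = oracle_solve(floored)
        state = production_fba(akg_node, ProductionConstraint("EX_gaba", 0.2))
        split = node_split(state, akg_node, "akg")
        expected = {
            "GADL": oracle.fluxes["GADL"],
            "RED": oracle.fluxes["RED"],
            "BIOMASS": 0.5 * oracle.fluxes["BIOMASS"],
        }
        total = sum(expected.values())
        for rxn_id, value in expected.items():
            assert split[rxn_id] == pytest.approx(value / total, abs=1e-6)
        assert split["GADL"] == pytest.approx(0.8, abs=1e-6)

    def test_single_consumer_gets_fraction_one(self, m1):
        state = maximize(m1)
        assert node_split(state, m1, "B") == {"BIOMASS": pytest.approx(1.0)}

    def test_zero_consumption_is_error(self, core_model):
        wt = pfba(core_model, "BIOMASS")
        with pytest.raises(FBAError):
            node_split(wt, core_model, "ssa_c")

    def test_export_share_at_most_node_total(self, core_model):
        prod = production_fba(core_model, ProductionConstraint("EX_4aba_e", 0.2))
        share = export_share(prod, core_model, "akg_c", "EX_4aba_e")
        assert 0.0 <= share <= 1.0 + 1e-9


class TestDoubleRobustness:
    def test_zero_corner_equals_theoretical_max(self, akg_node):
        surface = double_robustness(akg_node, "role:AKGDH", "EX_gaba", grid=6)
        corner = surface.objective_matrix[0, 0]
        cap = theoretical_max_yield(akg_node, "EX_gaba", "EX_akg") * 10.0
        assert corner == pytest.approx(cap, abs=1e-6)

    def test_full_growth_cell_matches_oracle(self, akg_node):
        mu_star = maximize(akg_node, "BIOMASS").objective_value
        surface = double_robustness(
            akg_node, "role:AKGDH", "EX_gaba",
            growth_values=[mu_star], flux_values=[0.5 * mu_star],
        )
        cell = akg_node.copy()
        cell.reactions["BIOMASS"].lower_bound = mu_star
        cell.reactions["BIOMASS"].upper_bound = mu_star
        cell.reactions["RED"].lower_bound = 0.5 * mu_star
        cell.reactions["RED"].upper_bound = 0.5 * mu_star
        cell.objective = {"EX_gaba": 1.0}
        oracle = oracle_solve(cell)
        assert surface.objective_matrix[0, 0] == pytest.approx(
            oracle.objective_value, abs=1e-6
        )
        assert surface.objective_matrix[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_global_max_at_zero_zero_corner(self, akg_node):
        surface = double_robustness(akg_node, "role:AKGDH", "EX_gaba", grid=6)
        assert surface.max_cell == (0.0, 0.0)

    def test_infeasible_cells_masked_not_fatal(self, akg_node):
        surface = double_robustness(
            akg_node, "role:AKGDH", "EX_gaba",
            growth_values=[10.0], flux_values=[100.0],
        )
        assert not surface.feasible_mask[0, 0]
        assert np.isnan(surface.objective_matrix[0, 0])

    def test_monotone_in_growth_at_fixed_flux(self, core_model):
        mu_star = maximize(core_model, "BIOMASS").objective_value
        surface = double_robustness(
            core_model, "role:SUCOAS", "EX_4aba_e",
            growth_values=np.linspace(0, mu_star, 6),
            flux_values=[0.0],
        )
        values = surface.objective_matrix[surface.feasible_mask[:, 0], 0]
        assert np.all(np.diff(values) <= 1e-6)


class TestStrainSeries:
    def test_packaged_series_runs_and_labels_unique(self, core_model):
        series = packaged_strain_series()
        table = strain_series(core_model, series,
                              ProductionConstraint("role:GABA_EXPORT", 0.2))
        assert list(table["label"]) == [
            "GABA-1", "GABA-2", "GABA-3", "GABA-4", "GABA-5", "GABA-6",
            "BLM-1", "BLM-2", "BLM-3",
        ]
        assert (table["status"] == "optimal").all()

    def test_sucCD_deletion_retains_growth(self, core_model):
        series = [s for s in packaged_strain_series() if s["label"] == "GABA-4"]
        table = strain_series(core_model, series,
                              ProductionConstraint("role:GABA_EXPORT", 0.2))
        assert table.loc[0, "growth_max"] > 0.01

    def test_gad_deletion_zeroes_product(self, core_model):
        series = [{"label": "dGAD", "edits": [
            {"op": "delete", "role": "GAD", "label": "dgad"}]}]
        table = strain_series(core_model, series,
                              ProductionConstraint("role:GABA_EXPORT", 0.2))
        assert table.loc[0, "product_flux"] == pytest.approx(0.0, abs=1e-6)

    def test_bad_strain_recorded_not_fatal(self, core_model):
        series = [
            {"label": "broken", "edits": [
                {"op": "delete", "reaction": "NOPE", "label": "dnope"}]},
            {"label": "fine", "edits": []},
        ]
        table = strain_series(core_model, series,
                              ProductionConstraint("role:GABA_EXPORT", 0.2))
        assert table.loc[0, "status"].startswith("error")
        assert table.loc[1, "status"] == "optimal"

    def test_determinism_across_runs_and_backends(self, core_model):
        series = packaged_strain_series()[:4]
        constraint = ProductionConstraint("role:GABA_EXPORT", 0.2)
        t1 = strain_series(core_model, series, constraint)
        t2 = strain_series(core_model, series, constraint)
        t3 = strain_series(core_model, series, constraint, backend="glpk")
        assert t1.equals(t2)
        assert np.allclose(t1["growth_max"], t3["growth_max"], atol=1e-6)
        assert np.allclose(t1["product_flux"], t3["product_flux"], atol=1e-6)
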