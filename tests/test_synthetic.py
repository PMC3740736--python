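from dataclasses import replace

import pytest

from myoflux.fba import solve_fba
from myoflux.model import validate_model
from myoflux.proteins import load_reference_compositions
from myoflux.synthetic import (
    ToySpec,
    bottleneck_amino_acid,
    closed_form_optimum,
    make_assembly_model,
    make_muscle_like_model,
    random_assembly_spec,
    reference_muscle_spec,
    synthetic_composition_table,
    toy_condition,
)
from myoflux.supplementation import supplement, sweep


def spec_from(counts, concs, **kw):
    return ToySpec(composition=counts, concentrations=concs, **kw)


class TestClosedForm:
    def test_two_amino_acids_unit_counts(self):
        spec = spec_from({"alanine": 1, "glycine": 1}, {"alanine": 3.0, "glycine": 5.0})
        assert closed_form_optimum(spec) == 3.0
        assert solve_fba(make_assembly_model(spec)).objective_value == pytest.approx(3.0)

    def test_three_amino_acids_mixed_counts(self):
        spec = spec_from(
            {"alanine": 2, "glycine": 1, "serine": 4},
            {"alanine": 4.0, "glycine": 9.0, "serine": 8.0},
        )
        assert closed_form_optimum(spec) == 2.0  # min(2, 9, 2); tie between ala and ser
        assert solve_fba(make_assembly_model(spec)).objective_value == pytest.approx(2.0)

    def test_supplementing_bottleneck_moves_to_next_minimum(self):
        spec = spec_from(
            {"alanine": 2, "glycine": 1, "serine": 4},
            {"alanine": 4.0, "glycine": 3.0, "serine": 12.0},
        )
        # ratios: ala 2, gly 3, ser 3 -> bottleneck alanine
        assert bottleneck_amino_acid(spec) == "alanine"
        model = make_assembly_model(spec)
        relaxed = supplement(model, {"alanine"})
        assert solve_fba(relaxed).objective_value == pytest.approx(3.0)

    def test_refuses_non_assembly_specs(self):
        spec = replace(random_assembly_spec(0, 3), energy_pathway=True)
        with pytest.raises(ValueError, match="assembly"):
            closed_form_optimum(spec)

    @pytest.mark.parametrize("seed", range(0, 60, 2))
    def test_lp_matches_closed_form_on_seeded_specs(self, seed):
        spec = random_assembly_spec(seed, 3 + seed % 8)
        sol = solve_fba(make_assembly_model(spec))
        assert sol.objective_value == pytest.approx(closed_form_optimum(spec), abs=1e-6)


class TestSpecValidation:
    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="same amino acids"):
            ToySpec(composition={"alanine": 1, "glycine": 1}, concentrations={"alanine": 1.0})

    def test_all_zero_composition_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ToySpec(
                composition={"alanine": 0, "glycine": 0},
                concentrations={"alanine": 1.0, "glycine": 1.0},
            )

    def test_determinism_given_seed(self):
        a, b = random_assembly_spec(99, 6), random_assembly_spec(99, 6)
        assert a == b
        ma, mb = make_assembly_model(a), make_assembly_model(b)
        assert ma.reaction_ids() == mb.reaction_ids()
        assert [r.upper_bound for r in ma.reactions] == [r.upper_bound for r in mb.reactions]


class TestMuscleLikeModels:
    def base_spec(self, **kw):
        defaults = dict(
            composition={"methionine": 2, "leucine": 1, "glycine": 3},
            concentrations={"methionine": 0.05, "leucine": 0.4, "glycine": 0.6},
            essential_set=frozenset({"methionine", "leucine"}),
            energy_pathway=True,
            energy_cost_per_bond=4.0,
            n_chains=1,
        )
        defaults.update(kw)
        return ToySpec(**defaults)

    def test_generous_energy_recovers_assembly_optimum(self):
        spec = self.base_spec(glucose_conc=100.0)
        assembly = replace(spec, energy_pathway=False, energy_cost_per_bond=0.0)
        sol = solve_fba(make_muscle_like_model(spec))
        assert sol.objective_value == pytest.approx(closed_form_optimum(assembly), abs=1e-8)

    def test_scarce_energy_depresses_optimum(self):
        spec = self.base_spec(
            glucose_conc=1e-4, palmitate_conc=0.0, tetradecanoate_conc=0.0
        )
        assembly = replace(spec, energy_pathway=False, energy_cost_per_bond=0.0)
        sol = solve_fba(make_muscle_like_model(spec))
        assert sol.objective_value < closed_form_optimum(assembly) - 1e-9

    def test_fuel_amino_acid_supplementation_raises_optimum(self):
        """Supplementing a catabolizable surplus amino acid helps even though
        it is not the composition bottleneck (fuel effect in miniature)."""
        spec = self.base_spec(
            glucose_conc=0.0,
            palmitate_conc=0.0,
            tetradecanoate_conc=0.0,
            catabolizable={"leucine": 0.5},
        )
        model = make_muscle_like_model(spec)
        base = solve_fba(model).objective_value
        boosted = solve_fba(supplement(model, {"leucine"})).objective_value
        assert bottleneck_amino_acid(replace(spec, energy_pathway=False,
                                             energy_cost_per_bond=0.0)) != "leucine"
        assert boosted > base + 1e-9

    def test_energy_demand_without_source_rejected(self):
        spec = self.base_spec(glucose_conc=0.0, palmitate_conc=0.0, tetradecanoate_conc=0.0)
        with pytest.raises(ValueError, match="no energy source"):
            make_muscle_like_model(spec)

    def test_interconversion_relaxes_nonessential_bottleneck(self):
        spec = self.base_spec(
            composition={"methionine": 1, "glutamate": 1, "glycine": 4},
            concentrations={"methionine": 5.0, "glutamate": 5.0, "glycine": 0.1},
            essential_set=frozenset({"methionine"}),
            glucose_conc=100.0,
        )
        without = solve_fba(make_muscle_like_model(spec)).objective_value
        with_conv = solve_fba(
            make_muscle_like_model(replace(spec, allow_interconversion=True))
        ).objective_value
        assert with_conv > without + 1e-9  # glutamate converts into scarce glycine


class TestGeneratedModelHygiene:
    @pytest.mark.parametrize("seed", range(5))
    def test_assembly_models_validate_clean(self, seed):
        assert validate_model(make_assembly_model(random_assembly_spec(seed, 4))) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_muscle_like_models_validate_clean(self, seed):
        spec = replace(
            random_assembly_spec(seed, 5),
            energy_pathway=True,
            energy_cost_per_bond=4.0,
            allow_interconversion=True,
            catabolizable={"leucine": 20.0},
        )
        assert validate_model(make_muscle_like_model(spec)) == []

    def test_planted_bottleneck_recovered_by_sweep(self):
        spec = random_assembly_spec(31, 5)
        outcome = sweep(make_assembly_model(spec), toy_condition(spec), k_max=1)
        improvers = [next(iter(r.subset)) for r in outcome.results if r.improved]
        assert improvers == [bottleneck_amino_acid(spec)]


class TestReferenceMuscleModel:
    def test_reference_spec_uses_plasma_profile_and_complex_demand(self):
        spec = reference_muscle_spec()
        comps = load_reference_compositions()
        assert spec.concentrations["methionine"] == 0.025
        assert spec.glucose_conc == 5
        assert spec.n_chains == 33
        total = sum(spec.composition.values())
        per_chain = {
            "actin": 7, "myosin_heavy_chain_2a": 7, "myosin_light_chain_kinase": 7,
            "myosin_light_chain_phosphorylatable": 7, "tropomyosin_2": 2,
            "troponin_c_2": 1, "troponin_i_2": 1, "troponin_t_2": 1,
        }
        assert total == sum(comps[p].length * m for p, m in per_chain.items())

    def test_reference_model_feasible_with_positive_optimum(self):
        model = make_muscle_like_model(reference_muscle_spec())
        assert validate_model(model) == []
        sol = solve_fba(model)
        assert sol.status == "optimal" and sol.objective_value > 0

    def test_bundled_table_matches_generator(self):
        assert load_reference_compositions() == synthetic_composition_table()
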