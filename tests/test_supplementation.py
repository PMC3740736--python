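import itertools
from dataclasses import replace

import pytest

from myoflux.conditions import Condition, fasting_condition, post_absorptive_condition
from myoflux.fba import solve_fba
from myoflux.supplementation import (
    ConditionMappingError,
    apply_condition,
    best_per_size,
    supplement,
    sweep,
)
from myoflux.synthetic import (
    ToySpec,
    bottleneck_amino_acid,
    make_assembly_model,
    make_muscle_like_model,
    random_assembly_spec,
    toy_condition,
)


class TestConditionProfiles:
    def test_fasting_profile_values(self):
        cond = fasting_condition()
        assert cond.uptake_bounds["glucose"] == 5
        assert cond.uptake_bounds["methionine"] == 0.025
        assert cond.uptake_bounds["leucine"] == 0.123
        assert cond.uptake_bounds["glutamine"] == 0.586

    def test_post_absorptive_profile_values(self):
        cond = post_absorptive_condition()
        assert cond.uptake_bounds["glucose"] == 7
        assert cond.uptake_bounds["leucine"] == 0.271
        assert cond.uptake_bounds["methionine"] == 0.030
        assert cond.uptake_bounds["palmitate"] == 0.125

    def test_profiles_cover_canonical_metabolites(self):
        for cond in (fasting_condition(), post_absorptive_condition()):
            cond.require_canonical()  # raises on any gap
            assert len(cond.uptake_bounds) == 23

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            Condition("bad", {"glucose": -1.0})


class TestApplyCondition:
    def test_sets_listed_uptake_bounds(self):
        spec = random_assembly_spec(0, 4)
        model = make_assembly_model(spec)
        aa = spec.amino_acids[0]
        cond = Condition("custom", {aa: 0.5})
        bounded = apply_condition(model, cond)
        assert bounded.reaction(f"EX_{aa}").upper_bound == 0.5
        # unlisted exchanges untouched
        other = spec.amino_acids[1]
        assert bounded.reaction(f"EX_{other}").upper_bound == spec.concentrations[other]

    def test_empty_condition_is_noop(self):
        model = make_assembly_model(random_assembly_spec(0, 4))
        bounded = apply_condition(model, Condition("empty", {}))
        assert [(r.lower_bound, r.upper_bound) for r in bounded.reactions] == [
            (r.lower_bound, r.upper_bound) for r in model.reactions
        ]

    def test_missing_exchange_names_metabolite(self):
        model = make_assembly_model(random_assembly_spec(0, 4))
        with pytest.raises(ConditionMappingError, match="tryptophan"):
            apply_condition(model, Condition("bad", {"tryptophan": 1.0}))


class TestSupplement:
    def test_empty_subset_keeps_objective(self):
        spec = random_assembly_spec(2, 4)
        model = make_assembly_model(spec)
        assert solve_fba(supplement(model, set())).objective_value == pytest.approx(
            solve_fba(model).objective_value
        )

    def test_original_model_unmodified(self):
        spec = random_assembly_spec(2, 4)
        model = make_assembly_model(spec)
        aa = bottleneck_amino_acid(spec)
        supplement(model, {aa})
        assert model.reaction(f"EX_{aa}").upper_bound == spec.concentrations[aa]

    def test_cap_equal_to_bound_is_idempotent(self):
        spec = random_assembly_spec(2, 4)
        model = make_assembly_model(spec)
        aa = spec.amino_acids[0]
        same = supplement(model, {aa}, cap=spec.concentrations[aa])
        assert solve_fba(same).objective_value == pytest.approx(
            solve_fba(model).objective_value
        )

    def test_union_equals_sequential_application(self):
        spec = random_assembly_spec(4, 5)
        model = make_assembly_model(spec)
        a, b = spec.amino_acids[0], spec.amino_acids[1]
        both = supplement(model, {a, b})
        seq = supplement(supplement(model, {a}), {b})
        assert solve_fba(both).objective_value == pytest.approx(
            solve_fba(seq).objective_value
        )
        assert [(r.id, r.upper_bound) for r in both.reactions] == [
            (r.id, r.upper_bound) for r in seq.reactions
        ]

    def test_non_amino_acid_rejected(self):
        model = make_assembly_model(random_assembly_spec(0, 4))
        with pytest.raises(ValueError, match="non-amino-acid"):
            supplement(model, {"glucose"})


class TestSweep:
    def test_enumerates_all_subsets_and_matches_per_subset_oracle(self):
        spec = random_assembly_spec(5, 3)
        model = make_assembly_model(spec)
        cond = toy_condition(spec)
        outcome = sweep(model, cond, k_max=3)
        assert len(outcome.results) == 7  # C(3,1)+C(3,2)+C(3,3)
        bounded = apply_condition(model, cond)
        for res in outcome.results:
            oracle = solve_fba(supplement(bounded, set(res.subset))).objective_value
            assert res.objective_value == pytest.approx(oracle, abs=1e-8)
            assert res.improved == (
                res.objective_value > outcome.control_objective + 1e-9
            )

    def test_control_never_exceeds_supplemented_objective(self):
        spec = random_assembly_spec(6, 4)
        outcome = sweep(make_assembly_model(spec), toy_condition(spec), k_max=2)
        for res in outcome.results:
            assert res.objective_value >= outcome.control_objective - 1e-9

    def test_full_subset_dominates_smaller_ones(self):
        spec = random_assembly_spec(7, 4)
        outcome = sweep(make_assembly_model(spec), toy_condition(spec), k_max=4)
        full = max(len(r.subset) for r in outcome.results)
        best_full = max(
            r.objective_value for r in outcome.results if len(r.subset) == full
        )
        assert all(r.objective_value <= best_full + 1e-9 for r in outcome.results)

    def test_infeasible_control_aborts_with_diagnosis(self):
        spec = random_assembly_spec(0, 4)
        model = make_assembly_model(spec)
        model.reaction(model.objective_id).lower_bound = 1e6  # impossible demand
        model.reaction(model.objective_id).upper_bound = 1e7
        with pytest.raises(RuntimeError, match="infeasible"):
            sweep(model, toy_condition(spec), k_max=1)


class TestBestPerSize:
    def test_monotone_in_size_and_oracle_argmax(self):
        spec = random_assembly_spec(8, 4)
        outcome = sweep(make_assembly_model(spec), toy_condition(spec), k_max=3)
        table = best_per_size(outcome)
        objs = table["objective"].tolist()
        assert objs == sorted(objs)  # non-decreasing in k
        for _, row in table.iterrows():
            peers = [r for r in outcome.results if len(r.subset) == row["size"]]
            assert row["objective"] == pytest.approx(
                max(r.objective_value for r in peers)
            )

    def test_bottleneck_in_every_best_subset(self):
        spec = random_assembly_spec(9, 4)
        bn = bottleneck_amino_acid(spec)
        outcome = sweep(make_assembly_model(spec), toy_condition(spec), k_max=3)
        for _, row in best_per_size(outcome).iterrows():
            if row["improved"]:
                assert bn in row["subset"]

    def test_symmetric_amino_acids_flagged_as_tie(self):
        # alanine and glycine are joint bottlenecks: no single supplement
        # improves, all three subsets tie at the control objective
        spec = ToySpec(
            composition={"alanine": 1, "glycine": 1, "serine": 1},
            concentrations={"alanine": 1.0, "glycine": 1.0, "serine": 10.0},
        )
        outcome = sweep(make_assembly_model(spec), toy_condition(spec), k_max=1)
        row = best_per_size(outcome).iloc[0]
        assert row["tie"] and not row["improved"]
        assert row["subset"] == ("alanine",)  # lexicographic winner among ties

    def test_empty_results_rejected(self):
        from myoflux.fba import FluxSolution
        from myoflux.supplementation import SweepOutcome

        with pytest.raises(ValueError, match="empty"):
            best_per_size(SweepOutcome("x", FluxSolution("optimal", 1.0), []))


class TestPruning:
    def test_prune_matches_exhaustive_when_improvement_exists(self):
        spec = random_assembly_spec(10, 4)
        model = make_assembly_model(spec)
        cond = toy_condition(spec)
        plain = best_per_size(sweep(model, cond, k_max=3, prune=False))
        pruned = best_per_size(sweep(model, cond, k_max=3, prune=True))
        assert plain["subset"].tolist() == pruned["subset"].tolist()
        assert plain["objective"].tolist() == pytest.approx(pruned["objective"].tolist())

    def test_prune_matches_exhaustive_when_nothing_improves(self):
        # energy so scarce that no amino-acid relaxation can help
        spec = replace(
            random_assembly_spec(11, 4),
            energy_pathway=True,
            energy_cost_per_bond=4.0,
            glucose_conc=1e-6,
            palmitate_conc=0.0,
            tetradecanoate_conc=0.0,
        )
        model = make_muscle_like_model(spec)
        cond = toy_condition(spec)
        plain = sweep(model, cond, k_max=2, prune=False)
        pruned = sweep(model, cond, k_max=2, prune=True)
        assert not any(r.improved for r in plain.results)
        assert not any(r.improved for r in pruned.results)
        pb = best_per_size(plain)["objective"]
        qb = best_per_size(pruned)["objective"]
        assert pb.tolist() == pytest.approx(qb.tolist(), abs=1e-8)
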