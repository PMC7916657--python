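"""Rule synthesis, genotype priming, synchronous dynamics, BoolNet dialect."""

import itertools

import pytest

from hallmarknet import (
    BooleanModel,
    CausalGraph,
    Edge,
    Genotype,
    Node,
    default_initial_state,
    find_attractors,
    prime_with_genotype,
    read_boolnet,
    synchronous_step,
    synthesize_rules,
    write_boolnet,
)
from hallmarknet.rules import format_expr, parse_expr

from conftest import attractors_by_table_walk, random_graph, truth_table_oracle


def graph_of(edges):
    return CausalGraph(edges=[Edge(*e) for e in edges])


class TestSynthesizeRules:
    def test_same_sign_inputs_join_with_or(self):
        g = graph_of([("a", "v", +1), ("b", "v", +1)])
        m = synthesize_rules(g)
        assert format_expr(m.rules["v"]) == "a | b"

    def test_inhibitor_wins_mixed_sign(self):
        g = graph_of([("a", "v", +1), ("i", "v", -1)])
        m = synthesize_rules(g, policy="inhibitor_wins")
        assert format_expr(m.rules["v"]) == "a & !i"
        assert m.rules["v"].evaluate({"a": 1, "i": 1, "v": 0}) == 0

    def test_activator_wins_mixed_sign(self):
        g = graph_of([("a", "v", +1), ("i", "v", -1)])
        m = synthesize_rules(g, policy="activator_wins")
        assert m.rules["v"].evaluate({"a": 1, "i": 1, "v": 0}) == 1
        assert m.rules["v"].evaluate({"a": 0, "i": 1, "v": 1}) == 0
        assert m.rules["v"].evaluate({"a": 0, "i": 0, "v": 1}) == 0

    def test_regulator_free_node_holds_value(self):
        g = graph_of([("a", "v", +1)])
        m = synthesize_rules(g)
        assert format_expr(m.rules["a"]) == "a"

    def test_inhibitor_only_node_active_unless_inhibited(self):
        g = graph_of([("i", "v", -1)])
        m = synthesize_rules(g)
        assert m.rules["v"].evaluate({"i": 0, "v": 0}) == 1
        assert m.rules["v"].evaluate({"i": 1, "v": 0}) == 0

    def test_both_sign_pair_inhibitor_wins_forces_off(self):
        g = graph_of([("a", "v", +1), ("a", "v", -1)])
        m = synthesize_rules(g, policy="inhibitor_wins")
        assert m.rules["v"].evaluate({"a": 1, "v": 0}) == 0
        assert m.rules["v"].evaluate({"a": 0, "v": 1}) == 0

    def test_overrides_replace_verbatim(self):
        g = graph_of([("a", "v", +1), ("b", "v", +1)])
        m = synthesize_rules(g, overrides={"v": "a & b"})
        assert format_expr(m.rules["v"]) == "a & b"

    def test_override_unknown_variable_rejected(self):
        g = graph_of([("a", "v", +1)])
        with pytest.raises(ValueError, match="unknown"):
            synthesize_rules(g, overrides={"v": parse_expr("a & ghost")})

    def test_override_unknown_target_rejected(self):
        g = graph_of([("a", "v", +1)])
        with pytest.raises(ValueError, match="ghost"):
            synthesize_rules(g, overrides={"ghost": "a"})

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("policy", ["inhibitor_wins", "activator_wins"])
    def test_activator_monotonicity(self, seed, policy):
        """Turning an activator on never turns the target off."""
        import numpy as np

        g = random_graph(seed, n_nodes=6, density=0.5)
        m = synthesize_rules(g, policy=policy)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            state = {n: int(rng.integers(0, 2)) for n in m.nodes}
            for v in m.nodes:
                acts = sorted(g.activators(v))
                if not acts:
                    continue
                a = acts[int(rng.integers(0, len(acts)))]
                if a in g.inhibitors(v):
                    continue  # both-sign regulators are not monotone inputs
                low = dict(state, **{a: 0})
                high = dict(state, **{a: 1})
                assert m.rules[v].evaluate(high) >= m.rules[v].evaluate(low)


class TestGenotype:
    def test_label_is_sorted_and_wt(self):
        assert Genotype().label == "WT"
        g = Genotype((("NPM1", "LOF"), ("FLT3", "GOF")))
        assert g.label == "FLT3:GOF+NPM1:LOF"

    def test_parse_round_trip(self):
        g = Genotype.parse("FLT3:GOF,NPM1:LOF")
        assert g.lesions == (("FLT3", "GOF"), ("NPM1", "LOF"))
        assert Genotype.parse("wt") == Genotype()

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            Genotype((("FLT3", "GOF"), ("FLT3", "LOF")))

    def test_bad_lesion_rejected(self):
        with pytest.raises(ValueError):
            Genotype((("FLT3", "AMP"),))


class TestPriming:
    def test_empty_genotype_is_identity(self, aml_model):
        assert prime_with_genotype(aml_model, Genotype()) == aml_model

    def test_lof_clamps_to_zero_everywhere(self, aml_model):
        primed = prime_with_genotype(aml_model, Genotype.parse("NPM1:LOF"))
        result = find_attractors(
            primed, mode="trajectory",
            init=default_initial_state(primed, overrides={"DNMT3A": 1}),
        )
        for i in range(len(result.attractors)):
            for state in result.states(i):
                assert state["NPM1"] == 0

    def test_gof_clamps_to_one_everywhere(self, aml_model):
        primed = prime_with_genotype(aml_model, Genotype.parse("FLT3:GOF"))
        result = find_attractors(
            primed, mode="trajectory",
            init=default_initial_state(primed),
        )
        for i in range(len(result.attractors)):
            for state in result.states(i):
                assert state["FLT3"] == 1

    def test_unknown_gene_error_names_it(self, aml_model):
        with pytest.raises(KeyError, match="GHOST"):
            prime_with_genotype(aml_model, Genotype.parse("GHOST:LOF"))

    def test_priming_is_idempotent(self, aml_model):
        g = Genotype.parse("FLT3:GOF,NPM1:LOF")
        once = prime_with_genotype(aml_model, g)
        twice = prime_with_genotype(once, g)
        assert once == twice

    def test_input_model_unmodified(self, aml_model):
        before = dict(aml_model.clamps)
        prime_with_genotype(aml_model, Genotype.parse("FLT3:GOF"))
        assert aml_model.clamps == before


class TestSynchronousStep:
    def test_mutual_activation_fixed_points(self):
        m = synthesize_rules(graph_of([("a", "b", +1), ("b", "a", +1)]))
        assert synchronous_step(m, {"a": 1, "b": 1}) == {"a": 1, "b": 1}
        assert synchronous_step(m, {"a": 0, "b": 0}) == {"a": 0, "b": 0}

    def test_negative_feedback_transition_table(self):
        # a -> b, b -| a: successors worked out by hand over all 4 states
        m = synthesize_rules(graph_of([("a", "b", +1), ("b", "a", -1)]))
        expected = {
            (0, 0): (1, 0),
            (1, 0): (1, 1),
            (1, 1): (0, 1),
            (0, 1): (0, 0),
        }
        for (a, b), (a2, b2) in expected.items():
            assert synchronous_step(m, {"a": a, "b": b}) == {"a": a2, "b": b2}

    def test_incomplete_state_rejected(self):
        m = synthesize_rules(graph_of([("a", "b", +1)]))
        with pytest.raises(ValueError, match="missing"):
            synchronous_step(m, {"a": 1})

    def test_clamped_node_returns_clamp(self):
        m = BooleanModel({"a": parse_expr("a"), "b": parse_expr("a")},
                         clamps={"b": 1})
        assert synchronous_step(m, {"a": 0, "b": 0})["b"] == 1


class TestFindAttractors:
    def test_all_clamped_single_fixed_point(self):
        m = BooleanModel({"a": parse_expr("a"), "b": parse_expr("b")},
                         clamps={"a": 1, "b": 0})
        res = find_attractors(m, mode="exhaustive")
        assert res.attractors == [((1, 0),)]
        assert res.basin_counts == {0: 1}

    def test_mutual_activation_two_fixed_points(self):
        m = synthesize_rules(graph_of([("a", "b", +1), ("b", "a", +1)]))
        res = find_attractors(m, mode="exhaustive")
        fps = {tuple(sorted(fp.items())) for fp in res.fixed_points}
        assert fps == {(("a", 0), ("b", 0)), (("a", 1), ("b", 1))}
        assert sum(res.basin_counts.values()) == 4

    def test_negative_feedback_four_cycle(self):
        m = synthesize_rules(graph_of([("a", "b", +1), ("b", "a", -1)]))
        res = find_attractors(m, mode="exhaustive")
        assert len(res.attractors) == 1
        assert len(res.attractors[0]) == 4
        act = res.activation(0)
        assert act == {"a": 0.5, "b": 0.5}

    def test_exhaustive_bound_error_suggests_trajectory(self):
        rules = {f"n{i}": parse_expr(f"n{i}") for i in range(30)}
        m = BooleanModel(rules)
        with pytest.raises(ValueError, match="trajectory"):
            find_attractors(m, mode="exhaustive", exhaustive_bound=25)

    def test_trajectory_requires_init_or_seed(self):
        m = synthesize_rules(graph_of([("a", "b", +1)]))
        with pytest.raises(ValueError):
            find_attractors(m, mode="trajectory")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_truth_table_oracle(self, seed):
        g = random_graph(seed, n_nodes=6, density=0.4, n_phenotypes=1)
        m = synthesize_rules(g)
        res = find_attractors(m, mode="exhaustive")
        table = truth_table_oracle(m)
        assert set(map(tuple, res.attractors)) == attractors_by_table_walk(table)
        assert sum(res.basin_counts.values()) == len(table)

    @pytest.mark.parametrize("seed", range(10))
    def test_trajectory_lands_in_exhaustive_attractor(self, seed):
        g = random_graph(seed, n_nodes=7, density=0.4, n_phenotypes=1)
        m = synthesize_rules(g)
        exhaustive = {tuple(a) for a in
                      find_attractors(m, mode="exhaustive").attractors}
        for bits in itertools.product((0, 1), repeat=len(m.nodes)):
            init = dict(zip(m.nodes, bits))
            res = find_attractors(m, mode="trajectory", init=init)
            assert tuple(res.attractors[0]) in exhaustive

    def test_fixed_points_are_fixed(self, aml_model):
        primed = prime_with_genotype(aml_model, Genotype.parse("FLT3:GOF"))
        res = find_attractors(primed, mode="trajectory",
                              init=default_initial_state(primed))
        for fp in res.fixed_points:
            assert synchronous_step(primed, fp) == fp


class TestBoolnetDialect:
    def test_round_trip_identity_on_fixture(self, aml_model, tmp_path):
        path = write_boolnet(aml_model, tmp_path / "model.bnet")
        assert read_boolnet(path) == aml_model

    def test_round_trip_preserves_clamps_and_policy(self, aml_model, tmp_path):
        primed = prime_with_genotype(aml_model, Genotype.parse("FLT3:GOF,NPM1:LOF"))
        path = write_boolnet(primed, tmp_path / "primed.bnet")
        again = read_boolnet(path)
        assert again == primed
        assert again.clamps == {"FLT3": 1, "NPM1": 0}
        assert again.policy == "inhibitor_wins"

    def test_header_and_syntax(self, aml_model, tmp_path):
        text = write_boolnet(aml_model, tmp_path / "m.bnet").read_text()
        lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
        assert lines[0] == "targets, factors"
        assert len(lines) == 1 + len(aml_model.nodes)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.bnet"
        path.write_text("a, b\n")
        with pytest.raises(ValueError, match="header"):
            read_boolnet(path)
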