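"""Search engines: UCT mechanics, cycle prevention, oracle equivalence."""

import json
import math

import pytest

import retroplan as rp
from retroplan.chem import canonicalize
from retroplan.scoring import negative_log_prior_cost
from retroplan.search import (
    SearchConfig,
    breadth_first_search,
    mcts_search,
    prevent_cycle,
    retrostar_search,
    uct_select,
)
from retroplan.search.mcts import MctsNode, MctsState, _Item

import oracles
from conftest import make_config


def _node(q, visits, parent=None):
    state = MctsState([_Item(canonicalize("CCO"), True, 0, frozenset(), 0)], ())
    node = MctsNode(state, parent, None)
    node.visits = visits
    node.total_reward = q * visits
    return node


class TestUctSelect:
    def test_hand_computed_example(self):
        parent = _node(0, 10)
        child_a, child_b = _node(0.8, 5, parent), _node(0.5, 1, parent)
        parent.children = [child_a, child_b]
        # UCT_A = 0.8 + 1.4*sqrt(ln10/5) ~ 1.750; UCT_B = 0.5 + 1.4*sqrt(ln10) ~ 2.624
        assert uct_select(parent, 1.4) is child_b
        assert 0.8 + 1.4 * math.sqrt(math.log(10) / 5) == pytest.approx(1.7505, abs=1e-3)

    def test_zero_exploration_is_pure_exploitation(self):
        parent = _node(0, 10)
        parent.children = [_node(0.9, 3, parent), _node(0.3, 3, parent)]
        assert uct_select(parent, 0.0) is parent.children[0]

    def test_ties_broken_by_creation_order(self):
        parent = _node(0, 10)
        parent.children = [_node(0.5, 2, parent), _node(0.5, 2, parent)]
        assert uct_select(parent, 1.4) is parent.children[0]

    def test_childless_node_is_contract_error(self):
        with pytest.raises(ValueError):
            uct_select(_node(0, 1), 1.4)


class TestCyclePrevention:
    def _reaction(self, product, reactants):
        template = rp.RetroTemplate(
            "[C:1](=[O:2])[NH1:3][C:4]>>[C:1](=[O:2])[OH1].[NH2:3][C:4]", "amide", 1
        )
        return rp.RetroReaction(
            canonicalize(product), tuple(canonicalize(r) for r in reactants), template, 0.5
        )

    def test_reactant_regenerating_ancestor_rejected(self):
        reaction = self._reaction("CC(=O)NC", ["CC(=O)O", "CN"])
        ancestors = frozenset({canonicalize("CN").inchi_key})
        assert not prevent_cycle(reaction, ancestors)

    def test_disjoint_reactants_kept(self):
        reaction = self._reaction("CC(=O)NC", ["CC(=O)O", "CN"])
        assert prevent_cycle(reaction, frozenset({canonicalize("CCCCCC").inchi_key}))

    def test_product_always_banned(self):
        reaction = self._reaction("CC(=O)NC", ["CC(=O)O", "CN"])
        assert prevent_cycle(reaction, frozenset())
        # the constructor itself refuses product-in-reactants
        with pytest.raises(ValueError):
            self._reaction("CC(=O)NC", ["CC(=O)NC", "CN"])


class TestMcts:
    def test_solves_planted_targets(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        for target in universe.targets[:4]:
            result = mcts_search(target.molecule, make_config(), expansion, [], stock)
            assert result.solved
            assert any(rp.compute_metrics(t).solved for t in result.routes)

    def test_target_in_stock_is_trivially_solved(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        block = universe.building_blocks[0]
        result = mcts_search(block, make_config(), expansion, [], stock)
        assert result.solved and result.iterations_used == 0
        assert rp.compute_metrics(result.routes.routes[0]).n_steps == 0

    def test_unsolvable_target_respects_iteration_limit(self, universe_setup):
        universe, templates, _, expansion = universe_setup
        empty_stock = rp.Stock.from_smiles(["[He]"])
        config = make_config(iteration_limit=1)
        result = mcts_search(
            universe.targets[0].molecule, config, expansion, [], empty_stock
        )
        assert not result.solved and result.iterations_used == 1

    def test_root_visits_equal_iterations(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        for target in universe.targets[:3]:
            result = mcts_search(
                target.molecule, make_config(iteration_limit=137), expansion, [], stock
            )
            assert result.diagnostics["root_visits"] == result.iterations_used

    def test_deterministic_rerun(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        target = universe.targets[0].molecule
        first = mcts_search(target, make_config(), expansion, [], stock)
        second = mcts_search(target, make_config(), expansion, [], stock)
        assert json.dumps(first.to_record(), sort_keys=True) == json.dumps(
            second.to_record(), sort_keys=True
        )

    def test_caching_does_not_change_results(self, universe_setup):
        universe, templates, stock, _ = universe_setup
        target = universe.targets[1].molecule
        records = []
        for cache_enabled in (True, False):
            expansion = rp.TemplateExpansion(
                templates,
                rp.frequency_prior(templates),
                top_k=1000,
                cutoff_cumulative=1.0,
                cache_enabled=cache_enabled,
            )
            result = mcts_search(target, make_config(), expansion, [], stock)
            records.append(json.dumps(result.to_record(), sort_keys=True))
        assert records[0] == records[1]

    def test_return_first_stops_early(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        target = universe.targets[0].molecule
        full = mcts_search(target, make_config(), expansion, [], stock)
        quick = mcts_search(
            target, make_config(return_first=True), expansion, [], stock
        )
        assert quick.solved
        assert quick.iterations_used <= full.iterations_used


class TestBreadthFirst:
    def test_max_transforms_zero_boundary(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        config = make_config(algorithm="breadth_first", max_transforms=0)
        unsolved = breadth_first_search(
            universe.targets[0].molecule, config, expansion, [], stock
        )
        assert not unsolved.solved
        solved = breadth_first_search(
            universe.building_blocks[0], config, expansion, [], stock
        )
        assert solved.solved

    def test_deepening_never_loses_routes(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        target = universe.targets[0].molecule
        seen = set()
        for depth in (1, 2, 3):
            config = make_config(algorithm="breadth_first", max_transforms=depth)
            result = breadth_first_search(target, config, expansion, [], stock)
            now = {
                oracles.route_tree_signature(t)
                for t in result.route_records
                if rp.compute_metrics(t).solved
            }
            assert seen <= now
            seen = now

    def test_matches_independent_enumerator(self, universe_setup):
        universe, templates, stock, expansion = universe_setup
        compiled = oracles.compile_templates(templates)
        stock_keys = {m.inchi_key for m in universe.building_blocks}
        for target in universe.targets[:4]:
            config = make_config(algorithm="breadth_first", max_transforms=3)
            result = breadth_first_search(target.molecule, config, expansion, [], stock)
            ours = {
                oracles.route_tree_signature(t)
                for t in result.route_records
                if rp.compute_metrics(t).solved
            }
            reference = {
                sig
                for sig, _ in oracles.enumerate_routes(
                    target.molecule.smiles, compiled, stock_keys, 3
                )
            }
            assert ours == reference


class TestRetroStar:
    def test_target_in_stock_costs_zero(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        config = make_config(algorithm="retrostar")
        result = retrostar_search(universe.building_blocks[0], config, expansion, [], stock)
        assert result.solved and result.diagnostics["best_route_cost"] == 0.0

    def test_best_cost_matches_enumerator_minimum(self, universe_setup):
        universe, templates, stock, expansion = universe_setup
        compiled = oracles.compile_templates(templates)
        stock_keys = {m.inchi_key for m in universe.building_blocks}
        for target in universe.targets[:4]:
            config = make_config(algorithm="retrostar", iteration_limit=3000, max_transforms=3)
            result = retrostar_search(target.molecule, config, expansion, [], stock)
            assert result.diagnostics["proven"]
            reference = oracles.enumerate_routes(
                target.molecule.smiles, compiled, stock_keys, 3
            )
            assert result.diagnostics["best_route_cost"] == pytest.approx(
                min(cost for _, cost in reference)
            )

    def test_prefers_high_prior_disconnection(self):
        # route via prior 0.8 (cost ~0.22) beats the prior-0.2 alternative
        t_cheap = rp.RetroTemplate("[CX4:1][O:2][CX4:3]>>[CX4:1]Br.[OH1:2][CX4:3]", "ether", 80)
        t_rare = rp.RetroTemplate(
            "[CX4:1][O:2][CX4:3]([CX4])>>[CX4:1]I.[OH1:2][C:3]", "iodo", 20
        )
        templates = [t_cheap, t_rare]
        for i, t in enumerate(templates):
            t.index = i
        expansion = rp.TemplateExpansion(
            templates, rp.frequency_prior(templates), top_k=10, cutoff_cumulative=1.0
        )
        stock = rp.Stock.from_smiles(["CCBr", "CCO", "CC(C)O", "CC(C)Br"])
        config = make_config(algorithm="retrostar", max_transforms=2)
        result = retrostar_search("CCOC(C)C", config, expansion, [], stock)
        assert result.solved
        best = result.routes.routes[0]
        labels = [r.metadata["template_label"] for r in best.reaction_nodes()]
        assert "iodo" not in labels


class TestRouteValidity:
    def test_all_algorithms_emit_replayable_routes(self, universe_setup):
        universe, _, stock, expansion = universe_setup
        target = universe.targets[2]
        for algo, fn in (
            ("mcts", mcts_search),
            ("breadth_first", breadth_first_search),
            ("retrostar", retrostar_search),
        ):
            config = make_config(algorithm=algo)
            result = fn(target.molecule, config, expansion, [], stock)
            solved_routes = [t for t in result.routes if rp.compute_metrics(t).solved]
            assert solved_routes, algo
            for tree in solved_routes:
                assert rp.replay_route(tree, universe), algo
                _assert_no_repeated_key_on_path(tree)


def _assert_no_repeated_key_on_path(tree):
    def walk(node, seen):
        key = canonicalize(node.smiles).inchi_key
        assert key not in seen
        for reaction in node.children:
            for child in reaction.children:
                walk(child, seen | {key})

    walk(tree.root, frozenset())
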