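"""Reaction-tree serialization, metrics, edit distance and clustering."""

import itertools
import json
import random

import pytest

import retroplan as rp
from retroplan.routes import (
    MoleculeNode,
    ReactionNode,
    ReactionTree,
    RouteCollection,
    RouteFormatError,
    cluster_routes,
    compute_metrics,
    tree_edit_distance,
)

import oracles


def mol(smiles, in_stock=False, children=()):
    return MoleculeNode(smiles, in_stock, children=list(children))


def rxn(label, children):
    return ReactionNode(metadata={"template_label": label}, children=list(children))


@pytest.fixture()
def convergent_route():
    """Final coupling of two fragments, each made in one step (3 steps total)."""
    frag_a = mol("CC(=O)NCCO", children=[rxn("amide", [mol("CC(=O)O", True), mol("NCCO", True)])])
    frag_b = mol("OCC(=O)OCC", children=[rxn("ester", [mol("OCC(=O)O", True), mol("CCO", True)])])
    top = rxn("ester2", [frag_a, frag_b])
    return ReactionTree(mol("CC(=O)NCCOC(=O)COCC", children=[top]))


@pytest.fixture()
def linear_route():
    leaf3 = mol("CCC", True)
    lvl2 = mol("CCCO", children=[rxn("c", [leaf3, mol("CO", True)])])
    lvl1 = mol("CCCOC", children=[rxn("b", [lvl2, mol("C", True)])])
    return ReactionTree(mol("CCCOCC", children=[rxn("a", [lvl1, mol("CC", True)])]))


class TestMetrics:
    def test_zero_step_route(self):
        metrics = compute_metrics(ReactionTree(mol("CCO", True)))
        assert (metrics.n_steps, metrics.longest_linear_sequence) == (0, 0)
        assert metrics.n_starting_materials == 1
        assert metrics.solved and not metrics.convergent

    def test_linear_three_step_route(self, linear_route):
        metrics = compute_metrics(linear_route)
        assert metrics.n_steps == 3
        assert metrics.longest_linear_sequence == 3
        assert not metrics.convergent
        assert metrics.n_starting_materials == 4

    def test_convergent_route(self, convergent_route):
        metrics = compute_metrics(convergent_route)
        assert metrics.n_steps == 3
        assert metrics.longest_linear_sequence == 2
        assert metrics.n_starting_materials == 4
        assert metrics.convergent

    def test_lls_equals_steps_iff_linear(self, linear_route, convergent_route):
        linear = compute_metrics(linear_route)
        convergent = compute_metrics(convergent_route)
        assert linear.longest_linear_sequence == linear.n_steps
        assert convergent.longest_linear_sequence < convergent.n_steps


class TestJson:
    def test_round_trip_preserves_everything(self, convergent_route):
        text = convergent_route.to_json()
        rebuilt = ReactionTree.from_json(text)
        assert rebuilt == convergent_route
        assert rebuilt.to_json() == text  # byte-stable

    def test_serialization_is_order_invariant(self):
        a = ReactionTree(mol("CCOC", children=[rxn("x", [mol("CCO", True), mol("CO", True)])]))
        b = ReactionTree(mol("CCOC", children=[rxn("x", [mol("CO", True), mol("CCO", True)])]))
        assert a.to_json() == b.to_json()

    def test_missing_smiles_reports_path(self):
        with pytest.raises(RouteFormatError, match=r"\$\.smiles"):
            ReactionTree.from_dict({"type": "mol", "in_stock": True})

    def test_bad_nested_node_reports_path(self):
        data = {
            "type": "mol",
            "smiles": "CCO",
            "children": [{"type": "reaction", "children": [{"type": "oops"}]}],
        }
        with pytest.raises(RouteFormatError, match=r"children\[0\]\.children\[0\]"):
            ReactionTree.from_dict(data)

    def test_unknown_keys_preserved(self):
        data = {"type": "mol", "smiles": "CCO", "in_stock": True, "custom": 42}
        tree = ReactionTree.from_dict(data)
        assert tree.to_dict()["custom"] == 42


class TestTreeEditDistance:
    def test_identical_routes_distance_zero(self, convergent_route):
        assert tree_edit_distance(convergent_route, convergent_route) == 0.0

    def test_single_leaf_substitution_costs_one_minus_tanimoto(self):
        def route(leaf):
            return ReactionTree(
                mol("CC(=O)NC", children=[rxn("amide", [mol("CC(=O)O", True), mol(leaf, True)])])
            )

        a, b = route("CN"), route("CCCCCN")
        # optimal edit script: substitute the changed leaf and the reaction
        # node above it (substitutions cost < 1 each, so they always beat a
        # delete+insert pair); everything else maps identically at cost 0
        fp_a = rp.canonicalize("CN").fingerprint()
        fp_b = rp.canonicalize("CCCCCN").fingerprint()
        leaf_cost = 1.0 - rp.tanimoto(fp_a, fp_b)
        from rdkit.Chem import AllChem

        def diff_fp(reactant):
            rxn_obj = AllChem.ReactionFromSmarts(
                f"CC(=O)O.{reactant}>>CC(=O)NC", useSmiles=True
            )
            return AllChem.CreateDifferenceFingerprintForReaction(rxn_obj)

        rxn_cost = 1.0 - rp.tanimoto(diff_fp("CN"), diff_fp("CCCCCN"))
        assert tree_edit_distance(a, b) == pytest.approx(leaf_cost + rxn_cost)

    def test_metric_properties_on_universe_routes(self, universe_setup):
        universe, *_ = universe_setup
        routes = [t.route for t in universe.targets]
        rng = random.Random(0)
        for a, b in itertools.combinations(routes[:5], 2):
            dab = tree_edit_distance(a, b)
            assert dab >= 0
            assert dab == pytest.approx(tree_edit_distance(b, a))
        for _ in range(10):
            a, b, c = rng.sample(routes, 3)
            assert tree_edit_distance(a, c) <= (
                tree_edit_distance(a, b) + tree_edit_distance(b, c) + 1e-9
            )


class TestClustering:
    def _distinct_routes(self, universe_setup, n):
        universe, *_ = universe_setup
        return [universe.targets[i].route for i in range(n)]

    def test_duplicate_pairs_recovered(self, universe_setup):
        base = self._distinct_routes(universe_setup, 3)
        collection = RouteCollection(routes=[base[0], base[0], base[1], base[1], base[2], base[2]])
        labels, k = cluster_routes(collection, max_k=5)
        assert k == 3
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[4] == labels[5]
        assert labels[0] == 0 and labels[2] == 1 and labels[4] == 2  # first-appearance order

    def test_silhouette_agrees_with_oracle(self, universe_setup):
        base = self._distinct_routes(universe_setup, 3)
        collection = RouteCollection(routes=[r for r in base for _ in range(2)])
        matrix = collection.compute_distance_matrix()
        labels, k = cluster_routes(collection, max_k=5)
        ours = oracles.silhouette(matrix.tolist(), labels)
        # oracle: the chosen k beats every other candidate clustering
        from sklearn.cluster import AgglomerativeClustering

        for other_k in range(2, 5):
            other = AgglomerativeClustering(
                n_clusters=other_k, metric="precomputed", linkage="average"
            ).fit_predict(matrix)
            assert ours >= oracles.silhouette(matrix.tolist(), list(other)) - 1e-9

    def test_identical_routes_degenerate_to_one_cluster(self, universe_setup):
        route = self._distinct_routes(universe_setup, 1)[0]
        collection = RouteCollection(routes=[route] * 4)
        labels, k = cluster_routes(collection)
        assert k == 1 and labels == [0, 0, 0, 0]

    def test_two_distinct_routes(self, universe_setup):
        collection = RouteCollection(routes=self._distinct_routes(universe_setup, 2))
        labels, k = cluster_routes(collection)
        assert k == 2 and labels == [0, 1]

    def test_single_route(self):
        labels, k = cluster_routes(RouteCollection(routes=[]))
        assert k == 0 and labels == []


class TestAggregate:
    def test_percent_solved_and_unique_templates(self, universe_setup):
        universe, templates, stock, expansion = universe_setup
        from conftest import make_config

        results = [
            rp.mcts_search(t.molecule, make_config(iteration_limit=100), expansion, [], stock)
            for t in universe.targets[:4]
        ]
        stats = rp.aggregate_statistics(results)
        assert 0 <= stats["percent_solved"] <= 100
        # unique templates equals a brute-force union over route metadata
        labels = set()
        for result in results:
            for tree in result.routes:
                for node in tree.reaction_nodes():
                    if "template_label" in node.metadata:
                        labels.add(str(node.metadata["template_label"]))
        assert stats["n_unique_templates"] == len(labels)
        assert len(stats["used_template_examples"]) == len(labels)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rp.aggregate_statistics([])
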