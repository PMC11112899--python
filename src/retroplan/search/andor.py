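"""AND/OR-tree search: breadth-first enumeration and Retro* best-first search.

OR nodes are molecules (solved by any one reaction); AND nodes are reactions
(requiring every reactant solved).  Nodes are path-specific — the same
molecule reached along different routes appears as separate OR nodes — which
makes the per-path cycle guard exact.

Breadth-first search expands every unsolved molecule level by level down to
``max_transforms`` and then enumerates all solved routes, so on universes
small enough to exhaust it serves as the reference enumeration.

Retro* is implemented in its zero-heuristic variant: reaction cost is
``-ln(max(prior, 1e-10))``, unexpanded and purchasable molecules carry value
0, and each iteration expands an unexpanded molecule inside the current
minimum-cost partial route.  Because the zero heuristic is admissible, the
first time the minimum-cost partial route is fully proven (all leaves in
stock) it is the globally optimal route.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

from ..chem import Molecule
from ..policies import ExpansionStrategy, FilterStrategy
from ..routes import MoleculeNode, ReactionNode, ReactionTree, extract_routes
from ..scoring import Scorer, StateScoreScorer
from ..stock import Stock
from .base import Diagnostics, Proposer, SearchConfig, SearchResult, Timer

_COST_FLOOR = 1e-10
_INF = math.inf


class OrNode:
    """A molecule to solve, on a specific path from the target."""

    __slots__ = ("mol", "in_stock", "depth", "ancestors", "children", "expanded", "value", "parent")

    def __init__(self, mol: Molecule, in_stock: bool, depth: int, ancestors: frozenset, parent):
        self.mol = mol
        self.in_stock = in_stock
        self.depth = depth
        self.ancestors = ancestors
        self.children: list[AndNode] = []
        self.expanded = False
        self.parent: Optional[AndNode] = parent
        # optimistic cost-to-solve bound (Retro*-0): 0 until proven otherwise
        self.value = 0.0 if in_stock else 0.0

    @property
    def terminal(self) -> bool:
        return self.in_stock or (self.expanded and not self.children)


class AndNode:
    """A reaction and its reactant subgoals."""

    __slots__ = ("reaction", "cost", "children", "parent")

    def __init__(self, reaction, cost: float, parent: OrNode):
        self.reaction = reaction
        self.cost = cost
        self.children: list[OrNode] = []
        self.parent = parent

    @property
    def value(self) -> float:
        return self.cost + sum(c.value for c in self.children)


def reaction_cost(prior: float) -> float:
    return -math.log(max(prior, _COST_FLOOR))


class _AndOrSearch:
    def __init__(
        self,
        config: SearchConfig,
        expansion: ExpansionStrategy,
        filters: Sequence[FilterStrategy],
        stock: Stock,
        scorer: Optional[Scorer] = None,
    ):
        self.config = config
        self.stock = stock
        self.diagnostics = Diagnostics()
        self.proposer = Proposer(expansion, filters, self.diagnostics)
        self.scorer = scorer or StateScoreScorer(max_transforms=config.max_transforms)

    def _expand_or(self, node: OrNode) -> None:
        node.expanded = True
        if node.depth >= self.config.max_transforms:
            return
        ancestors = node.ancestors | {node.mol.inchi_key}
        for reaction in self.proposer.reactions(node.mol, node.ancestors):
            and_node = AndNode(reaction, reaction_cost(reaction.prior), node)
            for mol in reaction.reactants:
                and_node.children.append(
                    OrNode(mol, mol in self.stock, node.depth + 1, ancestors, and_node)
                )
            node.children.append(and_node)
        if not node.children:
            self.diagnostics.dead_ends += 1

    # -- route enumeration ------------------------------------------------

    def _routes_for(self, node: OrNode, budget: list[int]) -> list[MoleculeNode]:
        """All solved sub-routes rooted at an OR node (stock terminates)."""
        if node.in_stock:
            return [MoleculeNode(node.mol.smiles, True)]
        options: list[MoleculeNode] = []
        for and_node in node.children:
            child_sets = []
            feasible = True
            for child in and_node.children:
                sub = self._routes_for(child, budget)
                if not sub:
                    feasible = False
                    break
                child_sets.append(sub)
            if not feasible:
                continue
            for combo in itertools.product(*child_sets):
                if budget[0] <= 0:
                    return options
                budget[0] -= 1
                rxn = ReactionNode(metadata=dict(and_node.reaction.metadata))
                rxn.metadata.setdefault(
                    "reaction_smiles", and_node.reaction.reaction_smiles
                )
                rxn.children = [_copy_subroute(c) for c in combo]
                options.append(
                    MoleculeNode(node.mol.smiles, False, children=[rxn])
                )
        return options

    def enumerate_routes(self, root: OrNode) -> list[ReactionTree]:
        budget = [self.config.route_limit]
        return [ReactionTree(m) for m in self._routes_for(root, budget)]

    def _finish(self, target: Molecule, root: OrNode, iterations: int, timer: Timer) -> SearchResult:
        records = self.enumerate_routes(root)
        solved = bool(records) or root.in_stock
        if root.in_stock and not records:
            records = [ReactionTree(MoleculeNode(target.smiles, True))]
        if not solved and root.children:
            # a partial record so unsolved searches still expose a best state
            records = records or [ReactionTree(MoleculeNode(target.smiles, False))]
        result = SearchResult(
            target=target,
            solved=solved,
            routes=None,
            iterations_used=iterations,
            wall_time=timer.elapsed(),
            diagnostics=self.diagnostics.as_dict(),
            route_records=records,
        )
        result.routes = extract_routes(result, top_n=self.config.top_routes, scorer=self.scorer)
        return result


def _copy_subroute(node: MoleculeNode) -> MoleculeNode:
    clone = MoleculeNode(node.smiles, node.in_stock)
    for rxn in node.children:
        rxn_clone = ReactionNode(metadata=dict(rxn.metadata))
        rxn_clone.children = [_copy_subroute(m) for m in rxn.children]
        clone.children.append(rxn_clone)
    return clone


class BreadthFirstSearch(_AndOrSearch):
    def search(self, target: Molecule) -> SearchResult:
        timer = Timer(self.config.time_limit)
        root = OrNode(target, target in self.stock, 0, frozenset(), None)
        frontier = [root] if not root.in_stock else []
        expansions = 0
        for _depth in range(self.config.max_transforms):
            if not frontier or timer.expired():
                break
            next_frontier: list[OrNode] = []
            for node in frontier:
                self._expand_or(node)
                expansions += 1
                for and_node in node.children:
                    next_frontier.extend(
                        c for c in and_node.children if not c.in_stock
                    )
            frontier = next_frontier
        return self._finish(target, root, expansions, timer)


class RetroStarSearch(_AndOrSearch):
    def _best_partial(self, root: OrNode) -> tuple[float, list[OrNode]]:
        """Follow argmin AND choices from the root; collect the unexpanded,
        unpurchasable molecules of the current minimum-cost partial route."""
        open_mols: list[OrNode] = []

        def walk(node: OrNode) -> None:
            if node.in_stock:
                return
            if not node.expanded:
                open_mols.append(node)
                return
            best, best_value = None, _INF
            for and_node in node.children:
                value = and_node.value
                if value < best_value - 1e-12:
                    best, best_value = and_node, value
            if best is None:
                return  # dead end; value is inf upstream
            for child in best.children:
                walk(child)

        walk(root)
        return root.value, open_mols

    @staticmethod
    def _update_values(node: OrNode) -> None:
        """Recompute cost bounds bottom-up from a newly expanded node."""
        current: Optional[OrNode] = node
        while current is not None:
            if current.in_stock:
                value = 0.0
            elif not current.expanded:
                value = 0.0
            elif not current.children:
                value = _INF
            else:
                value = min(a.value for a in current.children)
            current.value = value
            current = current.parent.parent if current.parent is not None else None

    def search(self, target: Molecule) -> SearchResult:
        timer = Timer(self.config.time_limit)
        root = OrNode(target, target in self.stock, 0, frozenset(), None)
        iterations = 0
        proven = root.in_stock
        while not proven and iterations < self.config.iteration_limit and not timer.expired():
            if root.value == _INF:
                break  # unsolvable within the depth bound
            _, open_mols = self._best_partial(root)
            if not open_mols:
                proven = True  # min-cost partial route is complete: optimal
                break
            # expand the shallowest open molecule (deterministic tie-break)
            open_mols.sort(key=lambda n: (n.depth, n.mol.inchi_key))
            node = open_mols[0]
            iterations += 1
            self._expand_or(node)
            self._update_values(node)
        result = self._finish(target, root, iterations, timer)
        best_cost = root.value if proven and not root.in_stock else (0.0 if root.in_stock else _INF)
        result.diagnostics["proven"] = proven
        result.diagnostics["best_route_cost"] = best_cost
        return result


def breadth_first_search(
    target,
    config: SearchConfig,
    expansion: ExpansionStrategy,
    filters: Sequence[FilterStrategy] = (),
    stock: Stock = None,
    scorer: Optional[Scorer] = None,
) -> SearchResult:
    from ..chem import canonicalize

    mol = target if isinstance(target, Molecule) else canonicalize(target)
    return BreadthFirstSearch(config, expansion, filters, stock, scorer).search(mol)


def retrostar_search(
    target,
    config: SearchConfig,
    expansion: ExpansionStrategy,
    filters: Sequence[FilterStrategy] = (),
    stock: Stock = None,
    scorer: Optional[Scorer] = None,
) -> SearchResult:
    from ..chem import canonicalize

    mol = target if isinstance(target, Molecule) else canonicalize(target)
    return RetroStarSearch(config, expansion, filters, stock, scorer).search(mol)
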