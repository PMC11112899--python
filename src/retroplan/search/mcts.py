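"""Monte Carlo tree search on the super-node state representation.

Each search node holds the full multiset of molecules still to be made (plus
those already purchasable) — the "super node".  One iteration performs the
classic select / expand / rollout / backpropagate cycle:

* selection follows UCT (``Q + c * sqrt(ln N_parent / n_child)``) while the
  node has no untried proposals;
* expansion pops the highest-prior untried proposal, instantiates the
  template (which may queue several concrete disconnections at that prior),
  applies the cycle guard and filters, and adds a single child;
* the rollout greedily applies the highest-prior admissible reaction to the
  first expandable molecule until the state is solved, depth-frozen or
  action-less (rollout states are not added to the tree);
* the reward is the terminal state's score, backpropagated to the root.

Molecules carry a per-molecule transform count; at ``max_transforms`` they
freeze (stay in the state but are no longer expandable).  Every solved state
encountered — in the tree or at a rollout terminus — is recorded as a route.
"""

from __future__ import annotations

import itertools
import math
from typing import NamedTuple, Optional, Sequence

from ..chem import Molecule, RetroReaction
from ..policies import ExpansionStrategy, FilterStrategy, TemplateAction
from ..routes import MoleculeNode, ReactionTree, extract_routes
from ..scoring import Scorer, StateScoreScorer
from ..stock import Stock
from .base import (
    Diagnostics,
    Proposer,
    SearchConfig,
    SearchResult,
    Step,
    Timer,
    build_route,
)

_ROLLOUT_CAP = 1000


class _Item(NamedTuple):
    """One molecule instance in a state, with its retro depth and ancestry."""

    mol: Molecule
    in_stock: bool
    n_transforms: int
    ancestors: frozenset
    token: int

    @property
    def smiles(self) -> str:
        return self.mol.smiles


class MctsState:
    """A multiset of molecules with stock flags and transform counts."""

    __slots__ = ("items", "steps")

    def __init__(self, items: Sequence[_Item], steps: tuple[Step, ...]):
        self.items: tuple[_Item, ...] = tuple(
            sorted(items, key=lambda it: (it.mol.inchi_key, it.token))
        )
        self.steps = steps

    @property
    def solved(self) -> bool:
        return all(it.in_stock for it in self.items)

    @property
    def n_transforms(self) -> int:
        return max((it.n_transforms for it in self.items), default=0)

    def expandable(self, max_transforms: int) -> list[_Item]:
        return [
            it
            for it in self.items
            if not it.in_stock and it.n_transforms < max_transforms
        ]


class MctsNode:
    __slots__ = (
        "state",
        "parent",
        "action_taken",
        "children",
        "untried",
        "visits",
        "total_reward",
        "dead_end",
        "_expanded",
    )

    def __init__(self, state: MctsState, parent: Optional["MctsNode"], action: Optional[RetroReaction]):
        self.state = state
        self.parent = parent
        self.action_taken = action
        self.children: list[MctsNode] = []
        self.untried: Optional[list] = None  # built lazily on first visit
        self.visits = 0
        self.total_reward = 0.0
        self.dead_end = False
        self._expanded = False

    @property
    def steps(self) -> tuple[Step, ...]:
        return self.state.steps

    @property
    def q(self) -> float:
        return self.total_reward / self.visits if self.visits else 0.0


def uct_select(node: MctsNode, c: float) -> MctsNode:
    """Child maximizing ``Q + c * sqrt(ln N / n)``; ties go to the child
    created first."""
    if not node.children:
        raise ValueError("uct_select on a childless node")
    log_n = math.log(max(node.visits, 1))
    best, best_value = None, -math.inf
    for child in node.children:
        value = child.q + c * math.sqrt(log_n / max(child.visits, 1))
        if value > best_value + 1e-12:
            best, best_value = child, value
    return best


class _Pending(NamedTuple):
    """An untried entry: either a lazy action or a concrete reaction."""

    prior: float
    template_index: int
    mol_key: str
    order: int
    item: _Item
    action: Optional[TemplateAction]  # None when concrete
    reaction: Optional[RetroReaction]

    @property
    def sort_key(self):
        return (-self.prior, self.template_index, self.mol_key, self.order)


class MctsSearch:
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
        self._tokens = itertools.count(1)
        self._order = itertools.count()
        self._records: list[ReactionTree] = []
        self._recorded: set[str] = set()
        self._found_solution = False

    # -- state bookkeeping ---------------------------------------------

    def _reward(self, state: MctsState) -> float:
        from ..scoring import state_score

        items = state.items
        frac = sum(1 for it in items if it.in_stock) / len(items) if items else 1.0
        return state_score(frac, state.n_transforms, max_transforms=self.config.max_transforms)

    def _record(self, state: MctsState, target: Molecule, target_in_stock: bool) -> None:
        tree = build_route(target, target_in_stock, state.steps)
        key = tree.to_json()
        if key not in self._recorded:
            self._recorded.add(key)
            self._records.append(tree)
        if state.solved:
            self._found_solution = True

    def _apply(self, state: MctsState, item: _Item, reaction: RetroReaction) -> MctsState:
        ancestors = item.ancestors | {item.mol.inchi_key}
        children = []
        new_items = [it for it in state.items if it.token != item.token]
        for mol in reaction.reactants:
            token = next(self._tokens)
            in_stock = mol in self.stock
            children.append((token, mol, in_stock))
            new_items.append(
                _Item(mol, in_stock, item.n_transforms + 1, ancestors, token)
            )
        step = Step(item.token, reaction, tuple(children))
        return MctsState(new_items, state.steps + (step,))

    # -- proposal queue --------------------------------------------------

    def _build_untried(self, node: MctsNode) -> None:
        """Pooled, ranked proposals for every expandable molecule (sibling
        expansion: one batched strategy call per state)."""
        items = node.state.expandable(self.config.max_transforms)
        node.untried = []
        if not items:
            return
        batches = self.proposer.actions([it.mol for it in items])
        for item, actions in zip(items, batches):
            for action in actions:
                node.untried.append(
                    _Pending(
                        action.prior,
                        action.template.index,
                        item.mol.inchi_key,
                        next(self._order),
                        item,
                        action,
                        None,
                    )
                )
        node.untried.sort(key=lambda p: p.sort_key)

    def expand(self, node: MctsNode, target: Molecule, target_in_stock: bool) -> Optional[MctsNode]:
        """Pop proposals until one concrete reaction survives the guards; add
        and return the resulting child, or None when the node dead-ends."""
        while node.untried:
            pending = node.untried.pop(0)
            if pending.reaction is None:
                reactions = pending.action.instantiate()
                self.diagnostics.invalid_outcomes += pending.action.diagnostics.get(
                    "invalid", 0
                )
                # queue each distinct disconnection at the action's prior
                concrete = [
                    _Pending(
                        pending.prior,
                        pending.template_index,
                        pending.mol_key,
                        pending.order,
                        pending.item,
                        None,
                        reaction,
                    )
                    for reaction in reactions
                ]
                node.untried[:0] = concrete
                continue
            reaction = pending.reaction
            if not self.proposer.accept(reaction, pending.item.ancestors):
                continue
            child_state = self._apply(node.state, pending.item, reaction)
            child = MctsNode(child_state, node, reaction)
            node.children.append(child)
            self._record(child_state, target, target_in_stock)
            return child
        return None

    # -- rollout ----------------------------------------------------------

    def rollout(self, state: MctsState) -> MctsState:
        """Greedy descent: highest-prior admissible reaction for the first
        expandable molecule, until solved, frozen or action-less."""
        for _ in range(_ROLLOUT_CAP):
            if state.solved:
                return state
            expandable = state.expandable(self.config.max_transforms)
            if not expandable:
                return state
            progressed = False
            for item in expandable:
                reaction = self._first_admissible(item)
                if reaction is not None:
                    state = self._apply(state, item, reaction)
                    progressed = True
                    break
            if not progressed:
                return state
        return state

    def _first_admissible(self, item: _Item) -> Optional[RetroReaction]:
        for action in self.proposer.actions([item.mol])[0]:
            reactions = action.instantiate()
            self.diagnostics.invalid_outcomes += action.diagnostics.get("invalid", 0)
            for reaction in reactions:
                if self.proposer.accept(reaction, item.ancestors):
                    return reaction
        return None

    # -- main loop ---------------------------------------------------------

    def search(self, target: Molecule) -> SearchResult:
        config = self.config
        timer = Timer(config.time_limit)
        target_in_stock = target in self.stock
        root_item = _Item(target, target_in_stock, 0, frozenset(), 0)
        root = MctsNode(MctsState([root_item], ()), None, None)

        if target_in_stock:
            self._record(root.state, target, True)
            return self._finish(target, root, iterations=0, timer=timer)

        iterations = 0
        while iterations < config.iteration_limit and not timer.expired():
            iterations += 1
            node = root
            # selection
            while True:
                if node.untried is None:
                    self._build_untried(node)
                if node.state.solved or node.dead_end or node.untried or not node.children:
                    break
                node = uct_select(node, config.exploration_c)

            if node.state.solved or node.dead_end or (not node.untried and not node.children):
                if not node.untried and not node.children and not node.state.solved:
                    node.dead_end = True
                    self.diagnostics.dead_ends += 1
                reward = 0.0 if node.dead_end else self._reward(node.state)
                self._backpropagate(node, reward)
            else:
                child = self.expand(node, target, target_in_stock)
                if child is None:
                    if not node.children:
                        node.dead_end = True
                        self.diagnostics.dead_ends += 1
                        self._backpropagate(node, 0.0)
                    else:
                        self._backpropagate(node, self._reward(node.state))
                else:
                    if child.state.solved:
                        terminal = child.state
                    else:
                        terminal = self.rollout(child.state)
                        if terminal.solved:
                            self._record(terminal, target, target_in_stock)
                    self._backpropagate(child, self._reward(terminal))
            if config.return_first and self._found_solution:
                break

        return self._finish(target, root, iterations, timer)

    def _backpropagate(self, node: MctsNode, reward: float) -> None:
        while node is not None:
            node.visits += 1
            node.total_reward += reward
            node = node.parent

    def _finish(self, target: Molecule, root: MctsNode, iterations: int, timer: Timer) -> SearchResult:
        self.diagnostics.extra["root_visits"] = root.visits
        result = SearchResult(
            target=target,
            solved=self._found_solution or (target in self.stock),
            routes=None,  # filled below
            iterations_used=iterations,
            wall_time=timer.elapsed(),
            diagnostics=self.diagnostics.as_dict(),
            route_records=list(self._records),
        )
        result.routes = extract_routes(result, top_n=self.config.top_routes, scorer=self.scorer)
        return result


def mcts_search(
    target,
    config: SearchConfig,
    expansion: ExpansionStrategy,
    filters: Sequence[FilterStrategy] = (),
    stock: Stock = None,
    scorer: Optional[Scorer] = None,
) -> SearchResult:
    """Run an MCTS search for a target molecule (SMILES or Molecule)."""
    from ..chem import canonicalize

    mol = target if isinstance(target, Molecule) else canonicalize(target)
    return MctsSearch(config, expansion, filters, stock, scorer).search(mol)
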