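"""Shared search infrastructure: configuration, results, action proposal.

All engines share the same expansion pipeline: a batched call to the
expansion strategy yields lazy ranked proposals; instantiating a proposal
applies the template; each concrete reaction then passes the cycle guard
(no reactant may regenerate the product or any ancestor on its path) and the
configured filter strategies.  Rejections are tallied in diagnostics
counters rather than raised.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ..chem import Molecule, RetroReaction
from ..policies import ExpansionStrategy, FilterStrategy, TemplateAction
from ..routes import MoleculeNode, ReactionNode, ReactionTree, RouteCollection
from ..stock import Stock


@dataclass
class SearchConfig:
    """Knobs shared by every search algorithm.

    ``max_transforms`` caps the number of retro steps any molecule may lie
    from the target; the time limit is checked between iterations only, so a
    run bounded by ``iteration_limit`` is deterministic.
    """

    algorithm: str = "mcts"
    iteration_limit: int = 100
    time_limit: float = 120.0
    max_transforms: int = 6
    exploration_c: float = 1.4
    return_first: bool = False
    seed: int = 0
    top_routes: int = 20
    route_limit: int = 5000  # cap on exhaustive route enumeration (AND/OR)

    def __post_init__(self):
        if self.iteration_limit < 1 and self.time_limit <= 0:
            raise ValueError("at least one of iteration_limit/time_limit must be active")
        if self.max_transforms < 0:
            raise ValueError("max_transforms must be >= 0")
        if self.exploration_c < 0:
            raise ValueError("exploration_c must be >= 0")
        if self.algorithm not in ("mcts", "retrostar", "breadth_first"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class Diagnostics:
    filtered_reactions: int = 0
    cycles_prevented: int = 0
    invalid_outcomes: int = 0
    dead_ends: int = 0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        data = {
            "filtered_reactions": self.filtered_reactions,
            "cycles_prevented": self.cycles_prevented,
            "invalid_outcomes": self.invalid_outcomes,
            "dead_ends": self.dead_ends,
        }
        data.update(self.extra)
        return data


@dataclass
class SearchResult:
    target: Molecule
    solved: bool
    routes: RouteCollection
    iterations_used: int
    wall_time: Optional[float]
    diagnostics: dict
    route_records: list[ReactionTree] = field(default_factory=list)

    def to_record(self, top_n: Optional[int] = None, include_time: bool = False) -> dict:
        routes = self.routes.routes[:top_n] if top_n else self.routes.routes
        record = {
            "target": self.target.smiles,
            "solved": self.solved,
            "iterations": self.iterations_used,
            "n_routes": len(self.routes),
            "diagnostics": self.diagnostics,
            "routes": [t.to_dict() for t in routes],
        }
        if include_time:
            record["wall_time"] = self.wall_time
        return record


def prevent_cycle(reaction: RetroReaction, ancestors: frozenset[str]) -> bool:
    """Keep (True) unless a reactant regenerates the product or an ancestor."""
    banned = ancestors | {reaction.product.inchi_key}
    return not any(r.inchi_key in banned for r in reaction.reactants)


class Proposer:
    """Instantiates, cycle-guards and filters ranked proposals for one molecule."""

    def __init__(
        self,
        expansion: ExpansionStrategy,
        filters: Sequence[FilterStrategy],
        diagnostics: Diagnostics,
    ):
        self.expansion = expansion
        self.filters = list(filters)
        self.diagnostics = diagnostics

    def actions(self, mols: Sequence[Molecule]) -> list[list[TemplateAction]]:
        return self.expansion.get_actions(mols)

    def accept(self, reaction: RetroReaction, ancestors: frozenset[str]) -> bool:
        if not prevent_cycle(reaction, ancestors):
            self.diagnostics.cycles_prevented += 1
            return False
        for flt in self.filters:
            keep, _reason = flt(reaction)
            if not keep:
                self.diagnostics.filtered_reactions += 1
                return False
        return True

    def reactions(
        self, mol: Molecule, ancestors: frozenset[str]
    ) -> list[RetroReaction]:
        """All admissible concrete reactions for one molecule, ranked."""
        out: list[RetroReaction] = []
        for action in self.actions([mol])[0]:
            reactions = action.instantiate()
            self.diagnostics.invalid_outcomes += action.diagnostics.get("invalid", 0)
            for reaction in reactions:
                if self.accept(reaction, ancestors):
                    out.append(reaction)
        return out


@dataclass(frozen=True)
class Step:
    """One recorded retro step on the path from the target."""

    parent_token: int
    reaction: RetroReaction
    children: tuple[tuple[int, Molecule, bool], ...]  # (token, molecule, in_stock)


def build_route(target: Molecule, target_in_stock: bool, steps: Sequence[Step]) -> ReactionTree:
    """Reconstruct the reaction tree from a chain of recorded steps."""
    nodes: dict[int, MoleculeNode] = {0: MoleculeNode(target.smiles, target_in_stock)}
    for step in steps:
        parent = nodes[step.parent_token]
        rxn = ReactionNode(metadata=dict(step.reaction.metadata))
        rxn.metadata.setdefault("reaction_smiles", step.reaction.reaction_smiles)
        for token, mol, in_stock in step.children:
            child = MoleculeNode(mol.smiles, in_stock)
            nodes[token] = child
            rxn.children.append(child)
        parent.children.append(rxn)
    return ReactionTree(nodes[0])


class Timer:
    def __init__(self, limit: Optional[float]):
        self.start = time.monotonic()
        self.limit = limit

    def expired(self) -> bool:
        return self.limit is not None and self.limit > 0 and self.elapsed() >= self.limit

    def elapsed(self) -> float:
        return time.monotonic() - self.start
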