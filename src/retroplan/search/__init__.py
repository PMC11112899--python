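"""Tree-search engines for retrosynthesis planning."""

from .andor import (
    AndNode,
    BreadthFirstSearch,
    OrNode,
    RetroStarSearch,
    breadth_first_search,
    reaction_cost,
    retrostar_search,
)
from .base import (
    Diagnostics,
    Proposer,
    SearchConfig,
    SearchResult,
    Step,
    build_route,
    prevent_cycle,
)
from .mcts import MctsNode, MctsSearch, MctsState, mcts_search, uct_select

ALGORITHMS = {
    "mcts": mcts_search,
    "breadth_first": breadth_first_search,
    "retrostar": retrostar_search,
}


def run_search(target, config: SearchConfig, expansion, filters=(), stock=None, scorer=None):
    """Dispatch to the engine named by ``config.algorithm``."""
    return ALGORITHMS[config.algorithm](target, config, expansion, filters, stock, scorer)


__all__ = [
    "ALGORITHMS",
    "AndNode",
    "BreadthFirstSearch",
    "Diagnostics",
    "MctsNode",
    "MctsSearch",
    "MctsState",
    "OrNode",
    "Proposer",
    "RetroStarSearch",
    "SearchConfig",
    "SearchResult",
    "Step",
    "breadth_first_search",
    "build_route",
    "mcts_search",
    "prevent_cycle",
    "reaction_cost",
    "retrostar_search",
    "run_search",
    "uct_select",
]
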