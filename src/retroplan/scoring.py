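"""Scoring of search states and finished routes.

The default node/route score is a bounded linear combination of the fraction
of starting material in stock and a depth penalty::

    score = w_stock * frac_in_stock + w_len * (1 - min(n, L_max) / L_max)

with defaults ``w_stock = 0.95``, ``w_len = 0.05`` and ``L_max`` the search's
maximum transform count.  It is exactly 1 for a solved zero-step state and 0
for an unsolved state at maximum depth.  Alternative scorers cover the stock
fraction alone, reaction and precursor counts, average template occurrence,
and the additive reaction/starting-material cost of Badowski-style route
costing (flat cost per reaction plus a flat penalty per unavailable leaf,
optionally replaced by stock prices).

Scorers accept either a :class:`~retroplan.routes.ReactionTree` or an MCTS
node/state; for routes the depth term uses the longest linear sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .routes import ReactionTree, compute_metrics
from .stock import Stock


def state_score(
    frac_in_stock: float,
    n_transforms: int,
    w_stock: float = 0.95,
    w_len: float = 0.05,
    max_transforms: int = 6,
) -> float:
    """Closed-form node score in [0, 1]; see module docstring."""
    if not 0.0 <= frac_in_stock <= 1.0:
        raise ValueError(f"frac_in_stock outside [0,1]: {frac_in_stock}")
    if n_transforms < 0:
        raise ValueError("n_transforms must be non-negative")
    if max_transforms < 1:
        raise ValueError("max_transforms must be >= 1")
    if abs(w_stock + w_len - 1.0) > 1e-9 or w_stock < 0 or w_len < 0:
        raise ValueError("weights must be non-negative and sum to 1")
    depth_term = 1.0 - min(n_transforms, max_transforms) / max_transforms
    return w_stock * frac_in_stock + w_len * depth_term


@dataclass(frozen=True)
class CostParameters:
    """Flat costs for Badowski-style route costing."""

    reaction_cost: float = 1.0
    unavailable_molecule_cost: float = 10.0

    def __post_init__(self):
        if not (self.reaction_cost > 0 and self.unavailable_molecule_cost > 0):
            raise ValueError("cost parameters must be positive")


def _view(item) -> tuple[float, int, list, list]:
    """(frac_in_stock, depth, leaves, reaction metadata) for a route or node."""
    if isinstance(item, ReactionTree):
        leaves = list(item.leaves())
        metrics = compute_metrics(item)
        frac = (
            sum(1 for l in leaves if l.in_stock) / len(leaves) if leaves else 1.0
        )
        reactions = [r.metadata for r in item.reaction_nodes()]
        return frac, metrics.longest_linear_sequence, leaves, reactions
    state = getattr(item, "state", item)  # MctsNode or MctsState
    items = state.items
    frac = sum(1 for it in items if it.in_stock) / len(items) if items else 1.0
    steps = getattr(item, "steps", getattr(state, "steps", ()))
    reactions = [step.reaction.metadata for step in steps]
    leaves = list(items)
    return frac, state.n_transforms, leaves, reactions


class Scorer:
    """Base scorer: named, deterministic, with an explicit ordering."""

    name = "scorer"
    ordering = "maximize"

    def __call__(self, item) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


class StateScoreScorer(Scorer):
    """The default squashed stock-fraction/depth score (maximize, in [0,1])."""

    name = "state score"

    def __init__(self, w_stock: float = 0.95, w_len: float = 0.05, max_transforms: int = 6):
        self.w_stock = w_stock
        self.w_len = w_len
        self.max_transforms = max(1, max_transforms)  # depth-0 searches still score

    def __call__(self, item) -> float:
        frac, depth, _, _ = _view(item)
        return state_score(frac, depth, self.w_stock, self.w_len, self.max_transforms)


class FractionInStockScorer(Scorer):
    name = "fraction in stock"

    def __call__(self, item) -> float:
        return _view(item)[0]


class NumberOfReactionsScorer(Scorer):
    name = "number of reactions"
    ordering = "minimize"

    def __call__(self, item) -> float:
        return float(len(_view(item)[3]))


class NumberOfPrecursorsScorer(Scorer):
    """Count of precursor molecules; duplicate leaves count per occurrence."""

    name = "number of precursors"
    ordering = "minimize"

    def __call__(self, item) -> float:
        return float(len(_view(item)[2]))


class AverageTemplateOccurrenceScorer(Scorer):
    """Mean template example count over a route's reactions (0 if no reactions)."""

    name = "average template occurrence"

    ordering = "maximize"

    def __call__(self, item) -> float:
        reactions = _view(item)[3]
        counts = [float(meta.get("n_examples", 0)) for meta in reactions]
        return sum(counts) / len(counts) if counts else 0.0


class BadowskiCostScorer(Scorer):
    """Additive route cost: one ``reaction_cost`` per reaction plus, for each
    leaf, 0 if purchasable else ``unavailable_molecule_cost`` (or the stock
    price when ``use_prices`` and a price is known)."""

    name = "badowski cost"
    ordering = "minimize"

    def __init__(
        self,
        params: CostParameters = CostParameters(),
        stock: Optional[Stock] = None,
        use_prices: bool = False,
    ):
        self.params = params
        self.stock = stock
        self.use_prices = use_prices

    def _leaf_cost(self, leaf) -> float:
        in_stock = bool(getattr(leaf, "in_stock", False))
        if in_stock:
            if self.use_prices and self.stock is not None:
                from .chem import canonicalize

                mol = getattr(leaf, "mol", None) or canonicalize(leaf.smiles)
                price = self.stock.price(mol)
                return float(price) if price is not None else 0.0
            return 0.0
        return self.params.unavailable_molecule_cost

    def __call__(self, item) -> float:
        _, _, leaves, reactions = _view(item)
        return self.params.reaction_cost * len(reactions) + sum(
            self._leaf_cost(leaf) for leaf in leaves
        )


def fraction_in_stock(item) -> float:
    return FractionInStockScorer()(item)


def number_of_reactions(item) -> int:
    return int(NumberOfReactionsScorer()(item))


def number_of_precursors(item) -> int:
    return int(NumberOfPrecursorsScorer()(item))


def average_template_occurrence(item) -> float:
    return AverageTemplateOccurrenceScorer()(item)


def badowski_cost(
    item,
    params: CostParameters = CostParameters(),
    stock: Optional[Stock] = None,
    use_prices: bool = False,
) -> float:
    return BadowskiCostScorer(params, stock, use_prices)(item)


def negative_log_prior_cost(tree: ReactionTree, floor: float = 1e-10) -> float:
    """Route cost as the sum over reactions of ``-ln(max(prior, floor))``;
    the quantity minimized by the best-first AND/OR search."""
    import math

    return sum(
        -math.log(max(float(rxn.metadata.get("prior", floor)), floor))
        for rxn in tree.reaction_nodes()
    )


SCORERS = {
    "state_score": StateScoreScorer,
    "fraction_in_stock": FractionInStockScorer,
    "number_of_reactions": NumberOfReactionsScorer,
    "number_of_precursors": NumberOfPrecursorsScorer,
    "average_template_occurrence": AverageTemplateOccurrenceScorer,
    "badowski_cost": BadowskiCostScorer,
}


def make_scorer(name: str, **params) -> Scorer:
    if name not in SCORERS:
        raise ValueError(f"unknown scorer {name!r}; known: {sorted(SCORERS)}")
    return SCORERS[name](**params)
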