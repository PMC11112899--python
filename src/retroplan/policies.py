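"""Expansion and filter strategies.

An *expansion strategy* proposes ranked retro reactions for a molecule; a
*filter strategy* is a pure predicate vetoing proposed reactions.  Template
prioritisation is delegated to a pluggable :class:`PriorModel` so that any
ranking source (frequency statistics, reaction-database lookup, an external
learned model) can drive the same template-application machinery.

Template application is deferred: :meth:`ExpansionStrategy.get_actions`
returns lazy :class:`TemplateAction` objects, and the concrete
:class:`~retroplan.chem.RetroReaction` instances only materialise when an
action is instantiated by the search.  Proposals are memoised per
(strategy id, InChI key) so sibling expansions and repeated visits cost one
prior-model evaluation per molecule.
"""

from __future__ import annotations

import abc
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .chem import Molecule, RetroReaction, RetroTemplate, apply_retro_template

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid strategy configuration."""


class PriorModel(abc.ABC):
    """Maps a batch of molecules to per-molecule probability vectors over a
    template library.  Each vector is non-negative; molecule-specific models
    may return an all-zero vector meaning "no proposals"."""

    id: str = "prior"

    def __init__(self):
        self.n_evaluations = 0  # batch calls actually computed

    @abc.abstractmethod
    def predict(self, mols: Sequence[Molecule]) -> list[np.ndarray]:
        ...


class FrequencyPrior(PriorModel):
    """Molecule-independent prior proportional to each template's example count.

    Stands in for a trained template-ranking model: templates derived from
    many literature examples are proposed first.  If every count is zero the
    prior falls back to uniform with a logged warning.
    """

    id = "frequency"

    def __init__(self, templates: Sequence[RetroTemplate]):
        super().__init__()
        if not templates:
            raise ConfigError("frequency prior requires at least one template")
        counts = np.array([t.n_examples for t in templates], dtype=float)
        total = counts.sum()
        if total <= 0:
            logger.warning(
                "all template example counts are zero; using a uniform prior"
            )
            self._probs = np.full(len(templates), 1.0 / len(templates))
        else:
            self._probs = counts / total

    def predict(self, mols: Sequence[Molecule]) -> list[np.ndarray]:
        self.n_evaluations += 1
        return [self._probs.copy() for _ in mols]


class LookupPrior(PriorModel):
    """Exact-match lookup from InChI key to a template probability vector.

    Emulates augmenting predictions with a reaction-database lookup: known
    molecules get their recorded disconnections, unknown molecules get the
    all-zero vector (no proposals).
    """

    id = "lookup"

    def __init__(self, table: Mapping[str, Sequence[float]], n_templates: int):
        super().__init__()
        self.n_templates = n_templates
        self._table: dict[str, np.ndarray] = {}
        for key, vec in table.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (n_templates,):
                raise ConfigError(
                    f"lookup vector for {key} has length {arr.size}, "
                    f"expected {n_templates}"
                )
            if arr.min() < 0:
                raise ConfigError(f"lookup vector for {key} has negative entries")
            self._table[key] = arr

    def predict(self, mols: Sequence[Molecule]) -> list[np.ndarray]:
        self.n_evaluations += 1
        zero = np.zeros(self.n_templates)
        return [self._table.get(m.inchi_key, zero) for m in mols]


def frequency_prior(templates: Sequence[RetroTemplate]) -> FrequencyPrior:
    return FrequencyPrior(templates)


def lookup_prior(table: Mapping[str, Sequence[float]], n_templates: int) -> LookupPrior:
    return LookupPrior(table, n_templates)


class TemplateAction:
    """A lazy proposal: (molecule, template, prior).

    ``instantiate()`` performs the template application once and caches the
    resulting concrete retro reactions (one per distinct reactant tuple).
    """

    __slots__ = ("molecule", "template", "prior", "policy_id", "_reactions", "diagnostics")

    def __init__(self, molecule: Molecule, template: RetroTemplate, prior: float, policy_id: str):
        self.molecule = molecule
        self.template = template
        self.prior = float(prior)
        self.policy_id = policy_id
        self._reactions: Optional[list[RetroReaction]] = None
        self.diagnostics: dict[str, int] = {}

    def instantiate(self) -> list[RetroReaction]:
        if self._reactions is None:
            tuples, self.diagnostics = apply_retro_template(self.template, self.molecule)
            meta = {
                "template_label": self.template.label,
                "template_index": self.template.index,
                "n_examples": self.template.n_examples,
                "policy": self.policy_id,
                "prior": self.prior,
            }
            self._reactions = [
                RetroReaction(self.molecule, tup, self.template, self.prior, dict(meta))
                for tup in tuples
            ]
        return self._reactions

    def __repr__(self) -> str:
        return (
            f"TemplateAction({self.molecule.smiles!r}, {self.template.label!r}, "
            f"prior={self.prior:.3g})"
        )


class ExpansionStrategy(abc.ABC):
    """Deterministic proposer of ranked retro reactions for molecules."""

    id: str = "expansion"

    @abc.abstractmethod
    def get_actions(self, mols: Sequence[Molecule]) -> list[list[TemplateAction]]:
        """Per-molecule ranked proposals, priors non-increasing."""

    def reset_cache(self) -> None:  # pragma: no cover - trivial default
        pass


class TemplateExpansion(ExpansionStrategy):
    """Template-based expansion: rank the library by a prior model, keep the
    ``top_k`` best and truncate at a cumulative-probability cutoff.

    The cumulative rule is inclusive — the proposal whose inclusion first
    reaches ``cutoff_cumulative`` is kept — so at least one proposal survives
    whenever any template has positive prior.
    """

    def __init__(
        self,
        templates: Sequence[RetroTemplate],
        prior_model: PriorModel,
        top_k: int = 50,
        cutoff_cumulative: float = 0.995,
        id: str = "template",
        cache_enabled: bool = True,
    ):
        if top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if not 0.0 < cutoff_cumulative <= 1.0:
            raise ConfigError("cutoff_cumulative must be in (0, 1]")
        self.templates = list(templates)
        self.prior_model = prior_model
        self.top_k = top_k
        self.cutoff_cumulative = cutoff_cumulative
        self.id = id
        self.cache_enabled = cache_enabled
        self._cache: dict[str, list[TemplateAction]] = {}

    def reset_cache(self) -> None:
        self._cache.clear()

    def _select(self, probs: np.ndarray, mol: Molecule) -> list[TemplateAction]:
        # sort by prior descending, ties by template index ascending
        order = np.argsort(-probs, kind="stable")
        actions: list[TemplateAction] = []
        cumulative = 0.0
        for idx in order[: self.top_k]:
            p = float(probs[idx])
            if p <= 0.0:
                break
            actions.append(TemplateAction(mol, self.templates[idx], p, self.id))
            cumulative += p
            if cumulative >= self.cutoff_cumulative:
                break
        return actions

    def get_actions(self, mols: Sequence[Molecule]) -> list[list[TemplateAction]]:
        if not mols:
            raise ValueError("get_actions requires a non-empty batch")
        if self.cache_enabled:
            pending, seen = [], set()
            for mol in mols:
                if mol.inchi_key not in self._cache and mol.inchi_key not in seen:
                    pending.append(mol)
                    seen.add(mol.inchi_key)
            if pending:
                for mol, probs in zip(pending, self.prior_model.predict(pending)):
                    self._cache[mol.inchi_key] = self._select(probs, mol)
            return [self._cache[mol.inchi_key] for mol in mols]
        vectors = self.prior_model.predict(list(mols))
        return [self._select(p, mol) for mol, p in zip(mols, vectors)]


class CombinedExpansion(ExpansionStrategy):
    """Combine several expansion strategies.

    mode ``"all"``: union of every strategy's proposals re-sorted by prior
    descending (priors are *not* rescaled across strategies; each proposal
    records its originating strategy id).  mode ``"first"``: per molecule,
    the proposals of the first strategy returning a non-empty list; later
    strategies are only queried for molecules the earlier ones left empty.
    """

    def __init__(self, strategies: Sequence[ExpansionStrategy], mode: str = "all"):
        if not strategies:
            raise ConfigError("combine_expansions requires at least one strategy")
        if mode not in ("all", "first"):
            raise ConfigError(f"unknown combination mode: {mode!r}")
        self.strategies = list(strategies)
        self.mode = mode
        self.id = f"combined-{mode}"

    def reset_cache(self) -> None:
        for strategy in self.strategies:
            strategy.reset_cache()

    def get_actions(self, mols: Sequence[Molecule]) -> list[list[TemplateAction]]:
        if self.mode == "all":
            merged: list[list[TemplateAction]] = [[] for _ in mols]
            for strategy in self.strategies:
                for out, proposals in zip(merged, strategy.get_actions(mols)):
                    out.extend(proposals)
            for out in merged:
                out.sort(key=lambda a: -a.prior)  # stable: strategy order breaks ties
            return merged
        # mode "first": lazy per-molecule fallback
        results: list[Optional[list[TemplateAction]]] = [None] * len(mols)
        remaining = list(range(len(mols)))
        for strategy in self.strategies:
            if not remaining:
                break
            batch = [mols[i] for i in remaining]
            proposals = strategy.get_actions(batch)
            still = []
            for i, props in zip(remaining, proposals):
                if props:
                    results[i] = props
                else:
                    still.append(i)
            remaining = still
        return [r if r is not None else [] for r in results]


def combine_expansions(
    strategies: Sequence[ExpansionStrategy], mode: str = "all"
) -> CombinedExpansion:
    return CombinedExpansion(strategies, mode)


class FilterStrategy(abc.ABC):
    """Pure predicate on a retro reaction: ``(keep, reason)``."""

    id: str = "filter"

    @abc.abstractmethod
    def __call__(self, reaction: RetroReaction) -> tuple[bool, Optional[str]]:
        ...


class ReactantCountFilter(FilterStrategy):
    """Reject reactions whose reactant count differs from the template's
    declared reactant-pattern count (e.g. an intramolecular match of a
    bimolecular template, or a pattern emitting extra fragments)."""

    id = "reactant-count"

    def __call__(self, reaction: RetroReaction) -> tuple[bool, Optional[str]]:
        expected = reaction.template.n_reactant_patterns
        if len(reaction.reactants) != expected:
            return False, "reactant-count"
        return True, None


class FeasibilityFilter(FilterStrategy):
    """Score-based feasibility veto: reject when ``score_fn(reaction) < cutoff``.

    The score is recorded in the reaction metadata for later inspection.
    """

    id = "feasibility"

    def __init__(self, score_fn: Callable[[RetroReaction], float], cutoff: float = 0.05):
        if not 0.0 <= cutoff <= 1.0:
            raise ConfigError("feasibility cutoff must be in [0, 1]")
        self.score_fn = score_fn
        self.cutoff = cutoff

    def __call__(self, reaction: RetroReaction) -> tuple[bool, Optional[str]]:
        score = float(self.score_fn(reaction))
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"feasibility score outside [0,1]: {score}")
        if isinstance(reaction.metadata, dict):
            reaction.metadata["feasibility"] = score
        if score < self.cutoff:
            return False, "feasibility"
        return True, None


def reactant_count_filter() -> ReactantCountFilter:
    return ReactantCountFilter()


def feasibility_filter(
    score_fn: Callable[[RetroReaction], float], cutoff: float = 0.05
) -> FeasibilityFilter:
    return FeasibilityFilter(score_fn, cutoff)
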