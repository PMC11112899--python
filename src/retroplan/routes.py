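"""Reaction trees: the unit of route analysis.

A route is a bipartite tree alternating molecule and reaction nodes, rooted
at the target molecule; leaves are (ideally purchasable) starting materials.
The JSON serialization uses nested objects with ``"type": "mol" | "reaction"``
and ``"children"`` arrays, root-first, compatible with the layout commonly
used by open-source retrosynthesis planners.

This module also provides route metrics (steps, longest linear sequence,
starting-material count, convergence), a chemistry-aware tree edit distance,
and agglomerative clustering of route collections.
"""

from __future__ import annotations

import functools
import json
import statistics
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from rdkit.Chem import AllChem
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from . import ted
from .chem import Molecule, canonicalize, tanimoto


class RouteFormatError(ValueError):
    """Raised with a JSON path when deserialization hits a schema violation."""


@dataclass
class ReactionNode:
    metadata: dict = field(default_factory=dict)
    children: list["MoleculeNode"] = field(default_factory=list)
    extra: dict = field(default_factory=dict)  # unknown JSON keys, preserved


@dataclass
class MoleculeNode:
    smiles: str
    in_stock: bool = False
    children: list[ReactionNode] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


class ReactionTree:
    """A single synthetic route."""

    def __init__(self, root: MoleculeNode):
        self.root = root
        self._json: Optional[str] = None

    # -- traversal ---------------------------------------------------------

    def molecule_nodes(self) -> Iterator[MoleculeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for rxn in node.children:
                stack.extend(rxn.children)

    def reaction_nodes(self) -> Iterator[ReactionNode]:
        for mol in self.molecule_nodes():
            yield from mol.children

    def leaves(self) -> Iterator[MoleculeNode]:
        for mol in self.molecule_nodes():
            if not mol.children:
                yield mol

    @property
    def solved(self) -> bool:
        return all(leaf.in_stock for leaf in self.leaves())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return _mol_to_dict(self.root)

    def to_json(self, indent: Optional[int] = None) -> str:
        if indent is None:
            if self._json is None:
                self._json = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
            return self._json
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionTree":
        return cls(_mol_from_dict(data, "$"))

    @classmethod
    def from_json(cls, text: str) -> "ReactionTree":
        return cls.from_dict(json.loads(text))

    def signature(self):
        """Structure-only identity (smiles + template labels), ignoring
        priors, policy ids and other run-dependent metadata."""
        return _signature(self.root)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReactionTree) and self.to_json() == other.to_json()

    def __hash__(self) -> int:
        return hash(self.to_json())

    def __repr__(self) -> str:
        m = compute_metrics(self)
        return f"ReactionTree({self.root.smiles!r}, steps={m.n_steps}, solved={m.solved})"


def _mol_to_dict(node: MoleculeNode) -> dict:
    data = dict(node.extra)
    data.update(
        {
            "type": "mol",
            "smiles": node.smiles,
            "in_stock": bool(node.in_stock),
            "children": sorted(
                (_rxn_to_dict(r) for r in node.children),
                key=lambda d: json.dumps(d, sort_keys=True),
            ),
        }
    )
    if not node.children:
        data.pop("children")
    return data


def _rxn_to_dict(node: ReactionNode) -> dict:
    data = dict(node.extra)
    data.update(
        {
            "type": "reaction",
            "metadata": node.metadata,
            "children": sorted(
                (_mol_to_dict(m) for m in node.children),
                key=lambda d: json.dumps(d, sort_keys=True),
            ),
        }
    )
    return data


def _mol_from_dict(data: dict, path: str) -> MoleculeNode:
    if not isinstance(data, dict):
        raise RouteFormatError(f"{path}: expected an object")
    if data.get("type") != "mol":
        raise RouteFormatError(f"{path}.type: expected 'mol', got {data.get('type')!r}")
    if "smiles" not in data:
        raise RouteFormatError(f"{path}.smiles: missing")
    known = {"type", "smiles", "in_stock", "children"}
    node = MoleculeNode(
        smiles=data["smiles"],
        in_stock=bool(data.get("in_stock", False)),
        extra={k: v for k, v in data.items() if k not in known},
    )
    for i, child in enumerate(data.get("children", [])):
        node.children.append(_rxn_from_dict(child, f"{path}.children[{i}]"))
    return node


def _rxn_from_dict(data: dict, path: str) -> ReactionNode:
    if not isinstance(data, dict) or data.get("type") != "reaction":
        raise RouteFormatError(f"{path}.type: expected 'reaction'")
    known = {"type", "metadata", "children"}
    node = ReactionNode(
        metadata=dict(data.get("metadata", {})),
        extra={k: v for k, v in data.items() if k not in known},
    )
    children = data.get("children", [])
    if not children:
        raise RouteFormatError(f"{path}.children: reaction node requires children")
    for i, child in enumerate(children):
        node.children.append(_mol_from_dict(child, f"{path}.children[{i}]"))
    return node


def _signature(node: MoleculeNode):
    return (
        node.smiles,
        tuple(
            sorted(
                (
                    str(r.metadata.get("template_label", "")),
                    tuple(sorted(_signature(m) for m in r.children)),
                )
                for r in node.children
            )
        ),
    )


# -- metrics ---------------------------------------------------------------


@dataclass(frozen=True)
class RouteMetrics:
    n_steps: int
    longest_linear_sequence: int
    n_starting_materials: int
    solved: bool
    convergent: bool


def compute_metrics(tree: ReactionTree) -> RouteMetrics:
    """Route metrics: step count, longest linear sequence (max reactions on
    any root-to-leaf path), starting-material count, solved flag and a
    structural convergence flag (some reaction joins >= 2 branches that each
    contain further reactions)."""

    n_steps = 0
    n_leaves = 0
    solved = True
    convergent = False

    def depth(mol: MoleculeNode) -> int:
        nonlocal n_steps, n_leaves, solved, convergent
        if not mol.children:
            n_leaves += 1
            solved = solved and mol.in_stock
            return 0
        best = 0
        for rxn in mol.children:
            n_steps += 1
            child_depths = [depth(m) for m in rxn.children]
            if sum(1 for d in child_depths if d > 0) >= 2:
                convergent = True
            best = max(best, 1 + max(child_depths))
        return best

    lls = depth(tree.root)
    return RouteMetrics(n_steps, lls, n_leaves, solved, convergent)


# -- tree edit distance ----------------------------------------------------


@functools.lru_cache(maxsize=50_000)
def _difference_fingerprint(reaction_smiles: str):
    rxn = AllChem.ReactionFromSmarts(reaction_smiles, useSmiles=True)
    return AllChem.CreateDifferenceFingerprintForReaction(rxn)


class _TedNode:
    __slots__ = ("kind", "payload", "children")

    def __init__(self, kind: str, payload, children):
        self.kind = kind
        self.payload = payload
        self.children = children


def _ted_tree(node: MoleculeNode, fp_radius: int, fp_bits: int) -> _TedNode:
    kids = []
    for rxn in node.children:
        rxn_smiles = (
            ".".join(m.smiles for m in rxn.children) + ">>" + node.smiles
        )
        rxn_children = [_ted_tree(m, fp_radius, fp_bits) for m in rxn.children]
        # canonical deterministic child order: by subtree serialization
        rxn_children.sort(key=_ted_key)
        kids.append(_TedNode("reaction", rxn_smiles, rxn_children))
    kids.sort(key=_ted_key)
    mol = canonicalize(node.smiles)
    return _TedNode("mol", mol.fingerprint(fp_radius, fp_bits), kids)


def _ted_key(node: _TedNode) -> str:
    if node.kind == "reaction":
        own = f"r:{node.payload}"
    else:
        own = f"m:{node.payload.GetNumOnBits()}:{node.payload.ToBase64()}"
    return own + "|" + "|".join(_ted_key(c) for c in node.children)


def tree_edit_distance(
    a: ReactionTree,
    b: ReactionTree,
    fp_radius: int = 2,
    fp_bits: int = 2048,
) -> float:
    """Chemistry-aware ordered tree edit distance between two routes.

    Unit insertion/deletion cost per node.  Substitution costs:
    ``1 - Tanimoto`` of Morgan fingerprints for molecule pairs, ``1 -
    Tanimoto`` of reaction difference fingerprints for reaction pairs, and 1
    for mixed-kind pairs.  Children are placed in a canonical deterministic
    order before the (ordered-tree) comparison, making the result invariant
    to child enumeration order.
    """

    def substitute(x: _TedNode, y: _TedNode) -> float:
        if x.kind != y.kind:
            return 1.0
        if x.kind == "mol":
            return 1.0 - tanimoto(x.payload, y.payload)
        return 1.0 - tanimoto(
            _difference_fingerprint(x.payload), _difference_fingerprint(y.payload)
        )

    return ted.tree_edit_distance(
        _ted_tree(a.root, fp_radius, fp_bits),
        _ted_tree(b.root, fp_radius, fp_bits),
        children=lambda n: n.children,
        substitute_cost=substitute,
    )


# -- collections & clustering ---------------------------------------------


@dataclass
class RouteCollection:
    routes: list[ReactionTree] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    distance_matrix: Optional[np.ndarray] = None
    cluster_labels: Optional[list[int]] = None

    def __post_init__(self):
        if self.scores and len(self.scores) != len(self.routes):
            raise ValueError("scores and routes must be parallel sequences")

    def __len__(self) -> int:
        return len(self.routes)

    def __iter__(self) -> Iterator[ReactionTree]:
        return iter(self.routes)

    def compute_distance_matrix(self, **ted_kwargs) -> np.ndarray:
        n = len(self.routes)
        matrix = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = tree_edit_distance(self.routes[i], self.routes[j], **ted_kwargs)
                matrix[i, j] = matrix[j, i] = d
        self.distance_matrix = matrix
        return matrix


def cluster_routes(
    collection: RouteCollection, max_k: int = 8
) -> tuple[list[int], int]:
    """Agglomerative (average-linkage) clustering of a route collection.

    The number of clusters is chosen in ``[2, min(max_k, n - 1)]`` by maximum
    silhouette on the precomputed tree-edit-distance matrix.  Labels are
    contiguous integers numbered in order of first route appearance.  Fewer
    than two routes, or an all-(near-)zero distance matrix, degenerate to a
    single cluster.
    """
    n = len(collection)
    if n < 2:
        labels = [0] * n
        collection.cluster_labels = labels
        return labels, 1 if n else 0
    if collection.distance_matrix is None:
        collection.compute_distance_matrix()
    matrix = collection.distance_matrix
    if float(matrix.max()) <= 1e-9:
        labels = [0] * n
        collection.cluster_labels = labels
        return labels, 1
    if n == 2:
        labels = [0, 1]
        collection.cluster_labels = labels
        return labels, 2

    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(2, min(max_k, n - 1) + 1):
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        )
        labels = model.fit_predict(matrix)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(matrix, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels
    if best_labels is None:  # no valid split found
        labels = [0] * n
        collection.cluster_labels = labels
        return labels, 1
    relabel: dict[int, int] = {}
    labels = []
    for raw in best_labels:
        if raw not in relabel:
            relabel[raw] = len(relabel)
        labels.append(relabel[raw])
    collection.cluster_labels = labels
    return labels, best_k


# -- extraction & aggregation ----------------------------------------------


def extract_routes(result, top_n: int = 20, scorer=None) -> RouteCollection:
    """Build the ranked route collection from a finished search.

    Routes are de-duplicated by serialized form, ranked by the scorer
    (default: the squashed stock-fraction/depth state score), with solved
    routes ahead of unsolved at equal score, ties broken by step count then
    first-found order, and truncated to ``top_n``.
    """
    from .scoring import StateScoreScorer  # local import to avoid a cycle

    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scorer = scorer or StateScoreScorer()
    seen: set[str] = set()
    entries = []
    for order, tree in enumerate(result.route_records):
        key = tree.to_json()
        if key in seen:
            continue
        seen.add(key)
        metrics = compute_metrics(tree)
        score = scorer(tree)
        rank_score = score if scorer.ordering == "maximize" else -score
        entries.append((-rank_score, 0 if metrics.solved else 1, metrics.n_steps, order, tree, score))
    entries.sort(key=lambda e: e[:4])
    entries = entries[:top_n]
    return RouteCollection(
        routes=[e[4] for e in entries], scores=[e[5] for e in entries]
    )


def aggregate_statistics(results: Sequence) -> dict:
    """Aggregate a batch of search results into summary statistics.

    Covers percent solved, median search time, mean routes for unsolved and
    solved targets, mean solved routes, mean starting materials / steps /
    longest linear sequence over the best solved route per target, and a
    template-usage summary over all extracted routes (count of distinct
    template labels and the example-count distribution of used templates).
    """
    if not results:
        raise ValueError("aggregate_statistics requires at least one result")

    def _mean(values):
        return float(statistics.fmean(values)) if values else None

    solved_flags = [bool(r.solved) for r in results]
    times = [r.wall_time for r in results if r.wall_time is not None]
    routes_unsolved = [len(r.routes) for r in results if not r.solved]
    routes_solved = [len(r.routes) for r in results if r.solved]
    n_solved_routes = [
        sum(1 for t in r.routes if compute_metrics(t).solved) for r in results if r.solved
    ]

    best_metrics = []
    for r in results:
        if not r.solved:
            continue
        for tree in r.routes:
            metrics = compute_metrics(tree)
            if metrics.solved:
                best_metrics.append(metrics)
                break

    used_templates: dict[str, int] = {}
    for r in results:
        for tree in r.routes:
            for rxn in tree.reaction_nodes():
                label = rxn.metadata.get("template_label")
                if label is not None:
                    used_templates[str(label)] = int(rxn.metadata.get("n_examples", 0))

    return {
        "n_targets": len(results),
        "percent_solved": 100.0 * sum(solved_flags) / len(results),
        "median_search_time": float(statistics.median(times)) if times else None,
        "mean_routes_unsolved_targets": _mean(routes_unsolved),
        "mean_routes_solved_targets": _mean(routes_solved),
        "mean_solved_routes": _mean(n_solved_routes),
        "mean_starting_materials": _mean([m.n_starting_materials for m in best_metrics]),
        "mean_steps": _mean([m.n_steps for m in best_metrics]),
        "mean_longest_linear_sequence": _mean(
            [m.longest_linear_sequence for m in best_metrics]
        ),
        "n_unique_templates": len(used_templates),
        "used_template_examples": sorted(used_templates.values()),
    }
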