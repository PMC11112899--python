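"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the package's own search/dedup/apply
code paths: raw RDKit calls, plain recursion, hand-coded statistics.
"""

from __future__ import annotations

import itertools
import math

from rdkit import Chem
from rdkit.Chem import AllChem


def canon(smiles: str) -> str:
    return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


def ikey(smiles: str) -> str:
    return Chem.MolToInchiKey(Chem.MolFromSmiles(smiles))


def compile_templates(templates):
    """[(label, rdkit reaction, prior)] with frequency priors over n_examples."""
    total = sum(t.n_examples for t in templates)
    out = []
    for t in templates:
        rxn = AllChem.ReactionFromSmarts(t.smarts)
        prior = t.n_examples / total if total else 1.0 / len(templates)
        out.append((t.label, rxn, prior))
    return out


def disconnections(smiles: str, compiled):
    """All distinct retro disconnections of a molecule: (label, prior,
    sorted reactant smiles tuple), deduplicated per template by the
    reactant-key multiset; product-regenerating outcomes dropped."""
    mol = Chem.MolFromSmiles(smiles)
    product_key = ikey(smiles)
    results = []
    for label, rxn, prior in compiled:
        seen = set()
        for outcome in rxn.RunReactants((mol,)):
            try:
                frags = []
                for m in outcome:
                    Chem.SanitizeMol(m)
                    frags.extend(Chem.MolToSmiles(m).split("."))
                frags = sorted(canon(f) for f in frags)
            except Exception:
                continue
            keys = tuple(sorted(ikey(f) for f in frags))
            if product_key in keys or keys in seen:
                continue
            seen.add(keys)
            results.append((label, prior, tuple(frags)))
    return results


def enumerate_routes(smiles: str, compiled, stock_keys: set, max_depth: int, _ancestors=frozenset()):
    """All solved routes as (signature, cost) pairs.

    A route terminates at any molecule whose InChI key is in stock; no
    reactant may repeat a key on the path from the target.  Signatures are
    nested tuples: ("leaf", smiles) or ("mol", smiles, label, sorted child
    signatures); cost is the summed -ln(prior).
    """
    smiles = canon(smiles)
    key = ikey(smiles)
    if key in stock_keys:
        return [(("leaf", smiles), 0.0)]
    if max_depth == 0:
        return []
    ancestors = _ancestors | {key}
    routes = []
    for label, prior, reactants in disconnections(smiles, compiled):
        if any(ikey(r) in ancestors for r in reactants):
            continue
        child_sets = [
            enumerate_routes(r, compiled, stock_keys, max_depth - 1, ancestors)
            for r in reactants
        ]
        if any(not cs for cs in child_sets):
            continue
        step_cost = -math.log(max(prior, 1e-10))
        for combo in itertools.product(*child_sets):
            signature = ("mol", smiles, label, tuple(sorted(sig for sig, _ in combo)))
            routes.append((signature, step_cost + sum(c for _, c in combo)))
    return routes


def route_tree_signature(tree) -> tuple:
    """Convert a package ReactionTree into the oracle signature form."""

    def walk(node):
        if not node.children:
            return ("leaf", canon(node.smiles))
        rxn = node.children[0]  # solved routes have one reaction per molecule
        label = str(rxn.metadata.get("template_label", ""))
        return (
            "mol",
            canon(node.smiles),
            label,
            tuple(sorted(walk(m) for m in rxn.children)),
        )

    return walk(tree.root)


def silhouette(matrix, labels) -> float:
    """Hand-coded mean silhouette from a precomputed distance matrix."""
    n = len(labels)
    values = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            values.append(0.0)
            continue
        a = sum(matrix[i][j] for j in own) / len(own)
        b = math.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, sum(matrix[i][j] for j in members) / len(members))
        values.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return sum(values) / n
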