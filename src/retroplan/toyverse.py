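"""Synthetic reaction universes with planted ground-truth routes.

Targets are composed *forward* from a catalogue of simple building blocks
(primary amines, carboxylic acids, alcohols, alkyl/aryl bromides, boronic
acids, plus bifunctional linkers) using four classic bond-forming reactions
— amide formation, ester formation, Williamson ether synthesis and a biaryl
(Suzuki-type) coupling — each paired with the exactly inverse retro template.
Because every target is built by forward application of real RDKit chemistry,
each comes with a planted reaction tree whose leaves are building blocks, and
the matching retro-template library is guaranteed to be able to rediscover
it.  Everything is reproducible from the seed, including the emitted files.

The generator also produces adversarial template libraries: decoy
disconnections that yield halogenated fragments no template can consume and
no stock contains (guaranteed dead ends), and a template whose declared
reactant-pattern count disagrees with what it produces, to exercise the
reactant-count filter.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Molecule, RetroTemplate, canonicalize
from .routes import MoleculeNode, ReactionNode, ReactionTree
from .stock import Stock

# catalogue of purchasable building blocks, grouped by dominant functionality
CATALOGUE: dict[str, list[str]] = {
    "amine": ["CCN", "CCCN", "CC(C)N", "NCc1ccccc1", "NCCc1ccccc1", "NC1CCCCC1"],
    "acid": ["CC(=O)O", "CCC(=O)O", "CC(C)C(=O)O", "OC(=O)c1ccccc1", "OC(=O)Cc1ccccc1"],
    "alcohol": ["CCO", "CCCO", "OCC(C)C", "OCc1ccccc1", "OCCc1ccccc1"],
    "alkyl_bromide": ["CCBr", "CCCBr", "BrCc1ccccc1", "BrCCc1ccccc1"],
    "aryl_bromide": ["Brc1ccccc1", "Cc1ccc(Br)cc1", "COc1ccc(Br)cc1"],
    "boronic_acid": ["OB(O)c1ccccc1", "OB(O)c1ccc(C)cc1"],
    # bifunctional linkers keep products reactive, enabling multi-step targets
    "linker": [
        "NCCO",
        "NCCCO",
        "OCCO",
        "NCCN",
        "NCC(=O)O",
        "NCCC(=O)O",
        "OCC(=O)O",
        "OCCC(=O)O",
        "OCc1ccc(Br)cc1",
        "NCc1ccc(Br)cc1",
    ],
}

# (label, forward SMARTS, retro SMARTS); the pairs are exact inverses
REACTION_FAMILIES: list[tuple[str, str, str]] = [
    (
        "amide formation",
        "[C:1](=[O:2])[OH1].[NH2:3][C:4]>>[C:1](=[O:2])[NH1:3][C:4]",
        "[C:1](=[O:2])[NH1:3][C:4]>>[C:1](=[O:2])[OH1].[NH2:3][C:4]",
    ),
    (
        "ester formation",
        "[C:1](=[O:2])[OH1].[OH1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]",
        "[C:1](=[O:2])[O:3][CX4:4]>>[C:1](=[O:2])[OH1].[OH1:3][C:4]",
    ),
    (
        "ether formation",
        "[CX4:1][Br].[OH1:2][CX4:3]>>[CX4:1][O:2][CX4:3]",
        "[CX4:1][O:2][CX4:3]>>[CX4:1]Br.[OH1:2][CX4:3]",
    ),
    (
        "biaryl coupling",
        "[c:1][Br].[c:2][B]([OH1])[OH1]>>[c:1]-[c:2]",
        "[c:1]-!@[c:2]>>[c:1]Br.[c:2]B(O)O",
    ),
]

_DECOY_PATTERNS = [
    ("[CX4:1][CX4:2]>>[CX4:1]I.[CX4:2]I", "decoy C-C iodination"),
    ("[C:1][N:2]>>[C:1]I.[N:2]", "decoy C-N iodination"),
    ("[C:1][O:2]>>[C:1]I.[O:2]", "decoy C-O iodination"),
    ("[c:1][CX4:2]>>[c:1]I.[CX4:2]I", "decoy benzylic iodination"),
]

# declares one reactant pattern but emits two fragments
_COUNT_DECOY = ("[CX4:1][O:2][CX4:3]>>([CX4:1][OH1:2].[CX4:3]O)", "decoy wrong count")


class UniverseError(RuntimeError):
    """Raised when no feasible composition exists after bounded retries."""


@dataclass(frozen=True)
class ForwardReaction:
    label: str
    forward_smarts: str
    retro_smarts: str
    n_examples: int


@dataclass(frozen=True)
class PlantedTarget:
    molecule: Molecule
    route: ReactionTree
    depth: int


@dataclass
class ToyUniverse:
    building_blocks: list[Molecule]
    reactions: list[ForwardReaction]
    targets: list[PlantedTarget]
    seed: int

    def template_library(self) -> list[RetroTemplate]:
        return [
            RetroTemplate(r.retro_smarts, r.label, r.n_examples, index=i)
            for i, r in enumerate(self.reactions)
        ]

    def stock(self) -> Stock:
        return Stock.from_smiles(
            [m.smiles for m in self.building_blocks], name="building-blocks"
        )

    def write(self, directory) -> dict[str, Path]:
        """Emit the files the main pipeline consumes: template CSV, stock
        SMILES list, targets SMILES list, and the planted routes as JSON.
        Byte-for-byte reproducible for a fixed universe."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "templates": directory / "templates.csv",
            "stock": directory / "stock.smi",
            "targets": directory / "targets.smi",
            "routes": directory / "planted_routes.json",
        }
        lines = ["template_smarts,label,n_examples"]
        for r in self.reactions:
            lines.append(f"\"{r.retro_smarts}\",{r.label},{r.n_examples}")
        paths["templates"].write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths["stock"].write_text(
            "\n".join(m.smiles for m in self.building_blocks) + "\n", encoding="utf-8"
        )
        paths["targets"].write_text(
            "\n".join(t.molecule.smiles for t in self.targets) + "\n", encoding="utf-8"
        )
        paths["routes"].write_text(
            json.dumps([t.route.to_dict() for t in self.targets], sort_keys=True, indent=1)
            + "\n",
            encoding="utf-8",
        )
        return paths


import functools


@functools.lru_cache(maxsize=256)
def _forward_rxn(forward_smarts: str):
    rxn = AllChem.ReactionFromSmarts(forward_smarts)
    rxn.Initialize()
    return rxn


@functools.lru_cache(maxsize=256)
def _reactant_queries(forward_smarts: str):
    rxn = _forward_rxn(forward_smarts)
    return tuple(rxn.GetReactantTemplate(i) for i in range(rxn.GetNumReactantTemplates()))


def _matches(mol: Molecule, query) -> bool:
    return mol.rdmol.HasSubstructMatch(query)


def _forward_apply(forward_smarts: str, reactants: Sequence[Molecule]) -> list[Molecule]:
    """All sanitizable products of a forward reaction on an ordered reactant
    tuple (used both in generation and in route replay)."""
    rxn = _forward_rxn(forward_smarts)
    if rxn.GetNumReactantTemplates() != len(reactants):
        return []
    products: list[Molecule] = []
    seen: set[str] = set()
    try:
        outcomes = rxn.RunReactants(tuple(m.rdmol for m in reactants))
    except Exception:
        return []
    for outcome in outcomes:
        for raw in outcome:
            try:
                Chem.SanitizeMol(raw)
                mol = canonicalize(Chem.MolToSmiles(raw))
            except Exception:
                continue
            if mol.inchi_key not in seen:
                seen.add(mol.inchi_key)
                products.append(mol)
    return products


def generate_universe(
    n_blocks: int = 12,
    depth: int = 3,
    branching: int = 2,
    seed: int = 0,
    n_targets: int = 10,
    max_attempts: int = 200,
) -> ToyUniverse:
    """Sample a reproducible toy reaction universe.

    ``n_blocks`` building blocks are drawn round-robin across the catalogue
    groups (always including bifunctional linkers so multi-step targets are
    feasible); ``n_targets`` targets are composed by up to ``depth`` levels
    of forward reactions with at most ``branching`` reactive branches per
    step.  Template example counts are sampled uniformly in [1, 1000].
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = random.Random(seed)

    groups = list(CATALOGUE)
    pools = {g: list(CATALOGUE[g]) for g in groups}
    for pool in pools.values():
        rng.shuffle(pool)
    blocks: list[Molecule] = []
    block_keys: set[str] = set()

    def _take(group: str) -> None:
        if pools[group] and len(blocks) < n_blocks:
            mol = canonicalize(pools[group].pop())
            if mol.inchi_key not in block_keys:
                block_keys.add(mol.inchi_key)
                blocks.append(mol)

    # bifunctional linkers get a third of the slots so deep (multi-step)
    # targets stay feasible; the rest is drawn round-robin across groups
    for _ in range(max(1, n_blocks // 3)):
        _take("linker")
    gi = 0
    while len(blocks) < n_blocks and any(pools.values()):
        _take(groups[gi % len(groups)])
        gi += 1
    blocks.sort(key=lambda m: m.smiles)

    reactions = [
        ForwardReaction(label, fwd, retro, rng.randint(1, 1000))
        for label, fwd, retro in REACTION_FAMILIES
    ]

    all_queries = [
        q for family in reactions for q in _reactant_queries(family.forward_smarts)
    ]

    def _reactive(mol: Molecule) -> bool:
        return any(_matches(mol, q) for q in all_queries)

    def _couple(
        left: MoleculeNode, right: MoleculeNode, must_react: bool
    ) -> Optional[MoleculeNode]:
        """Try every reaction family/orientation on a pair of subtrees; when
        ``must_react`` only accept products that keep a usable group."""
        left_mol, right_mol = canonicalize(left.smiles), canonicalize(right.smiles)
        options = []
        for family in reactions:
            qa, qb = _reactant_queries(family.forward_smarts)
            if _matches(left_mol, qa) and _matches(right_mol, qb):
                options.append((family, (left, right), (left_mol, right_mol)))
            if _matches(right_mol, qa) and _matches(left_mol, qb):
                options.append((family, (right, left), (right_mol, left_mol)))
        rng.shuffle(options)
        for family, pair, mols in options:
            products = [
                p
                for p in _forward_apply(family.forward_smarts, mols)
                if p.inchi_key not in block_keys and (not must_react or _reactive(p))
            ]
            if products:
                rxn = ReactionNode(
                    metadata={
                        "template_label": family.label,
                        "n_examples": family.n_examples,
                    },
                    children=[pair[0], pair[1]],
                )
                return MoleculeNode(products[0].smiles, False, children=[rxn])
        return None

    def grow(depth_left: int, must_react: bool = False) -> MoleculeNode:
        """Build a molecule of retro depth exactly ``depth_left`` with its
        planted subtree; one branch goes deep, the other a building block or,
        with branching > 1, occasionally another subtree (convergent routes).
        When ``must_react`` the product must retain a usable functional
        group, so the level above can keep building."""
        if depth_left == 0:
            return MoleculeNode(rng.choice(blocks).smiles, True)
        for _ in range(max_attempts):
            left = grow(depth_left - 1, must_react=depth_left > 1)
            partners: list[MoleculeNode] = []
            if branching > 1 and depth_left > 1 and rng.random() < 0.4:
                try:
                    partners.append(grow(rng.randint(1, depth_left - 1), must_react=True))
                except UniverseError:
                    pass
            shuffled = list(blocks)
            rng.shuffle(shuffled)
            partners.extend(MoleculeNode(b.smiles, True) for b in shuffled)
            for right in partners:
                product = _couple(left, right, must_react)
                if product is not None:
                    return product
        raise UniverseError(
            f"no feasible composition after {max_attempts} attempts "
            f"(depth_left={depth_left})"
        )

    targets: list[PlantedTarget] = []
    target_keys: set[str] = set()
    attempts = 0
    depth_cycle = itertools.cycle(range(depth, 0, -1))  # balanced depth mix
    while len(targets) < n_targets:
        attempts += 1
        if attempts > max_attempts * n_targets:
            raise UniverseError("could not compose enough distinct targets")
        root = None
        for target_depth in range(next(depth_cycle), 0, -1):
            try:
                root = grow(target_depth)
                break
            except UniverseError:
                continue
        if root is None:
            continue
        mol = canonicalize(root.smiles)
        if mol.inchi_key in target_keys or mol.inchi_key in block_keys:
            continue
        target_keys.add(mol.inchi_key)
        targets.append(PlantedTarget(mol, ReactionTree(root), target_depth))

    return ToyUniverse(blocks, reactions, targets, seed)


def adversarial_templates(
    universe: ToyUniverse,
    n_decoys: int = 4,
    seed: int = 0,
    decoy_examples: tuple[int, int] = (1, 10),
    include_count_decoy: bool = True,
) -> list[RetroTemplate]:
    """The universe's true templates plus decoys.

    Decoys disconnect real bonds but produce iodinated fragments that no
    template consumes and no stock contains, so routes through them are
    guaranteed dead ends.  Optionally appends a template whose declared
    reactant count disagrees with its output (reactant-count filter fodder).
    Decoy example counts are sampled in ``decoy_examples``.
    """
    rng = random.Random(seed)
    templates = universe.template_library()
    index = len(templates)
    for i in range(n_decoys):
        smarts, label = _DECOY_PATTERNS[i % len(_DECOY_PATTERNS)]
        templates.append(
            RetroTemplate(
                smarts,
                f"{label} #{i}",
                rng.randint(*decoy_examples),
                index=index,
            )
        )
        index += 1
    if include_count_decoy:
        templates.append(
            RetroTemplate(
                _COUNT_DECOY[0], _COUNT_DECOY[1], rng.randint(*decoy_examples), index=index
            )
        )
    return templates


def replay_route(tree: ReactionTree, universe: ToyUniverse) -> bool:
    """Replay a route forward: bottom-up, apply each reaction's forward
    template to its reactants and require the recorded product's InChI key
    among the outcomes.  Returns True iff every step replays."""
    forward = {r.label: r.forward_smarts for r in universe.reactions}

    def check(node: MoleculeNode) -> bool:
        product = canonicalize(node.smiles)
        for rxn in node.children:
            label = rxn.metadata.get("template_label")
            smarts = forward.get(str(label))
            if smarts is None:
                return False
            reactants = [canonicalize(m.smiles) for m in rxn.children]
            regenerated = False
            # reactant order is not recorded; try both assignments
            import itertools as _it

            for perm in _it.permutations(reactants):
                if any(
                    p.inchi_key == product.inchi_key
                    for p in _forward_apply(smarts, perm)
                ):
                    regenerated = True
                    break
            if not regenerated:
                return False
            if not all(check(m) for m in rxn.children):
                return False
        return True

    return check(tree.root)
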