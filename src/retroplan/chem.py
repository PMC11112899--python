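"""Molecule and reaction primitives.

Molecules are identified by their full 27-character InChI key, which is also
the unit of stock membership.  Retro reactions are produced by applying a
retrosynthetic reaction template (reaction SMARTS written in the retro
direction, ``product >> reactants``) to a product molecule; template
application over-generates, so chemically invalid outcomes are dropped and
counted rather than raised.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator

# Template application routinely produces unsanitizable intermediates; the
# per-outcome noise is handled via diagnostics counters instead of the log.
RDLogger.DisableLog("rdApp.*")


class MoleculeError(ValueError):
    """Raised for SMILES that RDKit cannot parse."""


class TemplateError(ValueError):
    """Raised at load time for malformed template SMARTS."""


@functools.lru_cache(maxsize=16)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


class Molecule:
    """An immutable molecule with canonical SMILES / InChI-key identity.

    Equality and hashing use the full InChI key so that stereoisomers and
    isotopologues remain distinct, matching the exact-structure semantics of
    an InChI-key stock lookup.
    """

    __slots__ = ("smiles", "inchi_key", "_rdmol", "_fps")

    def __init__(self, rdmol: Chem.Mol):
        self.smiles: str = Chem.MolToSmiles(rdmol)
        self.inchi_key: str = Chem.MolToInchiKey(rdmol)
        self._rdmol = rdmol
        self._fps: dict = {}

    @property
    def rdmol(self) -> Chem.Mol:
        return self._rdmol

    def fingerprint(self, radius: int = 2, n_bits: int = 2048):
        """Morgan (circular) bit fingerprint, cached per (radius, n_bits)."""
        if radius < 1 or n_bits < 64:
            raise ValueError("fingerprint requires radius >= 1 and n_bits >= 64")
        key = (radius, n_bits)
        if key not in self._fps:
            self._fps[key] = _morgan_generator(radius, n_bits).GetFingerprint(self._rdmol)
        return self._fps[key]

    def __eq__(self, other) -> bool:
        return isinstance(other, Molecule) and self.inchi_key == other.inchi_key

    def __hash__(self) -> int:
        return hash(self.inchi_key)

    def __repr__(self) -> str:
        return f"Molecule({self.smiles!r})"


@functools.lru_cache(maxsize=200_000)
def _canonicalize_cached(smiles: str) -> Molecule:
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise MoleculeError(f"cannot parse SMILES: {smiles!r}")
    return Molecule(rdmol)


def canonicalize(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Idempotent: re-canonicalizing the canonical SMILES returns an equal
    molecule.  Raises :class:`MoleculeError` on unparseable input.
    """
    return _canonicalize_cached(smiles)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity between two RDKit fingerprints."""
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


class RetroTemplate:
    """A retrosynthetic reaction template (``product >> reactants`` SMARTS).

    ``n_examples`` is the number of literature reactions the template was
    derived from; frequency-based priors use it as support.
    """

    __slots__ = ("smarts", "label", "n_examples", "index", "_rxn")

    def __init__(self, smarts: str, label: str, n_examples: int = 0, index: int = 0):
        if n_examples < 0:
            raise TemplateError(f"template {label!r}: n_examples must be >= 0")
        try:
            rxn = AllChem.ReactionFromSmarts(smarts)
        except Exception as exc:
            raise TemplateError(
                f"template {label!r}: cannot parse SMARTS {smarts!r}: {exc}"
            ) from exc
        if rxn is None:
            raise TemplateError(f"template {label!r}: cannot parse SMARTS {smarts!r}")
        if rxn.GetNumReactantTemplates() != 1:
            raise TemplateError(
                f"template {label!r}: retro SMARTS must have exactly one "
                f"product-side pattern, got {rxn.GetNumReactantTemplates()}"
            )
        rxn.Initialize()
        self.smarts = smarts
        self.label = label
        self.n_examples = int(n_examples)
        self.index = int(index)
        self._rxn = rxn

    @property
    def rxn(self):
        return self._rxn

    @property
    def n_reactant_patterns(self) -> int:
        """Number of reactant patterns the template expects to produce."""
        return self._rxn.GetNumProductTemplates()

    def __repr__(self) -> str:
        return f"RetroTemplate({self.label!r}, index={self.index})"


def load_templates(path) -> list[RetroTemplate]:
    """Load a template library from CSV with header ``template_smarts,label,n_examples``.

    Row order defines the template index.  Malformed SMARTS raise
    :class:`TemplateError` at load time.
    """
    frame = pd.read_csv(path)
    required = {"template_smarts", "label", "n_examples"}
    missing = required - set(frame.columns)
    if missing:
        raise TemplateError(f"template CSV {path} lacks columns: {sorted(missing)}")
    return [
        RetroTemplate(row.template_smarts, str(row.label), int(row.n_examples), index=i)
        for i, row in enumerate(frame.itertuples(index=False))
    ]


@dataclass(frozen=True)
class RetroReaction:
    """One concrete retro step: a product disconnected into a reactant tuple."""

    product: Molecule
    reactants: tuple[Molecule, ...]
    template: RetroTemplate
    prior: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.reactants:
            raise ValueError("RetroReaction requires at least one reactant")
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError(f"prior must be in [0,1], got {self.prior}")
        if any(r.inchi_key == self.product.inchi_key for r in self.reactants):
            raise ValueError("reactant equals product (cycle)")

    @property
    def reaction_smiles(self) -> str:
        """Forward reaction SMILES, ``reactants >> product``."""
        return ".".join(m.smiles for m in self.reactants) + ">>" + self.product.smiles

    def __repr__(self) -> str:
        return f"RetroReaction({self.reaction_smiles!r}, prior={self.prior:.3g})"


def apply_retro_template(
    template: RetroTemplate, product: Molecule
) -> tuple[list[tuple[Molecule, ...]], dict[str, int]]:
    """Apply a retro template to a product molecule.

    Returns one reactant tuple per distinct substructure match, plus a
    diagnostics counter.  Outcomes failing sanitization are dropped and
    counted under ``"invalid"``; tuples regenerating the product under
    ``"self"``; identical reactant multisets under ``"duplicate"``.
    Reactants within each tuple are ordered by canonical SMILES, and the
    tuples themselves are returned in a deterministic lexicographic order.
    """
    diagnostics = {"invalid": 0, "self": 0, "duplicate": 0}
    try:
        outcomes = template.rxn.RunReactants((product.rdmol,))
    except Exception:
        diagnostics["invalid"] += 1
        return [], diagnostics

    results: list[tuple[Molecule, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for outcome in outcomes:
        mols: list[Molecule] = []
        try:
            for raw in outcome:
                Chem.SanitizeMol(raw)
                # a single pattern may emit a multi-fragment outcome
                for frag_smiles in Chem.MolToSmiles(raw).split("."):
                    mols.append(canonicalize(frag_smiles))
        except Exception:
            diagnostics["invalid"] += 1
            continue
        mols.sort(key=lambda m: m.smiles)
        key = tuple(sorted(m.inchi_key for m in mols))
        if product.inchi_key in key:
            diagnostics["self"] += 1
            continue
        if key in seen:
            diagnostics["duplicate"] += 1
            continue
        seen.add(key)
        results.append(tuple(mols))
    results.sort(key=lambda tup: tuple(m.smiles for m in tup))
    return results, diagnostics
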