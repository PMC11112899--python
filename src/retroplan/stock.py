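"""Building-block stocks.

A stock decides whether a molecule is a purchasable starting material.  The
core representation is an in-memory set of InChI keys per named source, with
optional per-key price and amount data and optional stop criteria (maximum
price, minimum amount).  Multiple sources combine as a logical OR with
per-source criteria evaluation; entries lacking price/amount data pass the
corresponding criterion.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .chem import Molecule, MoleculeError, canonicalize

logger = logging.getLogger(__name__)


class StockFormatError(ValueError):
    pass


@dataclass
class StockSource:
    """One named collection of purchasable molecules."""

    name: str
    keys: set[str] = field(default_factory=set)
    price: dict[str, float] = field(default_factory=dict)
    amount: dict[str, float] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self):
        for mapping in (self.price, self.amount):
            unknown = set(mapping) - self.keys
            if unknown:
                raise StockFormatError(
                    f"stock {self.name!r}: priced/amounted keys not in stock: "
                    f"{sorted(unknown)[:3]}"
                )

    def __contains__(self, mol: Molecule) -> bool:
        return mol.inchi_key in self.keys


@dataclass(frozen=True)
class StopCriteria:
    """Optional purchasability constraints on stock entries."""

    max_price: Optional[float] = None
    min_amount: Optional[float] = None

    def __post_init__(self):
        for name, value in (("max_price", self.max_price), ("min_amount", self.min_amount)):
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")

    def admits(self, source: StockSource, key: str) -> bool:
        """Does this source's entry for ``key`` satisfy the criteria?

        Missing price/amount data passes the corresponding criterion.
        """
        if self.max_price is not None:
            price = source.price.get(key)
            if price is not None and price > self.max_price:
                return False
        if self.min_amount is not None:
            amount = source.amount.get(key)
            if amount is not None and amount < self.min_amount:
                return False
        return True


def load_stock(path, name: str) -> StockSource:
    """Load a stock file: plain SMILES lines, or CSV with header
    ``smiles[,price][,amount]``.  Unparseable SMILES are skipped and counted.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    source = StockSource(name=name)
    if lines and "," in lines[0]:
        reader = csv.DictReader(text.splitlines())
        if "smiles" not in (reader.fieldnames or []):
            raise StockFormatError(f"stock CSV {path} lacks a 'smiles' column")
        for row in reader:
            try:
                mol = canonicalize(row["smiles"])
            except MoleculeError:
                source.n_skipped += 1
                continue
            source.keys.add(mol.inchi_key)
            if row.get("price") not in (None, ""):
                source.price[mol.inchi_key] = float(row["price"])
            if row.get("amount") not in (None, ""):
                source.amount[mol.inchi_key] = float(row["amount"])
    else:
        for line in lines:
            try:
                mol = canonicalize(line.split()[0])
            except MoleculeError:
                source.n_skipped += 1
                continue
            source.keys.add(mol.inchi_key)
    if source.n_skipped:
        logger.warning("stock %s: skipped %d unparseable lines", name, source.n_skipped)
    return source


def in_stock(
    mol: Molecule,
    sources: Sequence[StockSource],
    criteria: StopCriteria = StopCriteria(),
) -> bool:
    """True iff some source contains the molecule and that source's entry
    satisfies the stop criteria."""
    return any(
        mol.inchi_key in src.keys and criteria.admits(src, mol.inchi_key)
        for src in sources
    )


class Stock:
    """Convenience wrapper bundling sources and criteria for the search."""

    def __init__(
        self,
        sources: Sequence[StockSource],
        criteria: StopCriteria = StopCriteria(),
    ):
        self.sources = list(sources)
        self.criteria = criteria

    @classmethod
    def from_smiles(cls, smiles: Iterable[str], name: str = "stock") -> "Stock":
        source = StockSource(name=name)
        for smi in smiles:
            source.keys.add(canonicalize(smi).inchi_key)
        return cls([source])

    def __contains__(self, mol: Molecule) -> bool:
        return in_stock(mol, self.sources, self.criteria)

    def source_names(self, mol: Molecule) -> list[str]:
        """Names of every source holding the molecule under the criteria."""
        return [
            src.name
            for src in self.sources
            if mol.inchi_key in src.keys and self.criteria.admits(src, mol.inchi_key)
        ]

    def price(self, mol: Molecule) -> Optional[float]:
        """Minimum price over sources holding the molecule; None if unpriced."""
        prices = [
            src.price[mol.inchi_key]
            for src in self.sources
            if mol.inchi_key in src.price and self.criteria.admits(src, mol.inchi_key)
        ]
        return min(prices) if prices else None


def availability_profile(tree, stock: Stock) -> dict[str, float]:
    """Per-source fraction of a solved route's starting materials.

    A leaf found in several sources counts toward each; denominators are the
    total leaf count.  Raises on unsolved routes.
    """
    from .routes import ReactionTree  # local import to avoid a cycle

    if isinstance(tree, ReactionTree):
        leaves = list(tree.leaves())
    else:
        leaves = list(tree)
    if not leaves:
        raise ValueError("route has no starting materials")
    mols = [canonicalize(leaf.smiles) for leaf in leaves]
    if any(mol not in stock for mol in mols):
        raise ValueError("availability profile requires a solved route")
    counts = {src.name: 0 for src in stock.sources}
    for mol in mols:
        for name in stock.source_names(mol):
            counts[name] += 1
    return {name: counts[name] / len(mols) for name in counts}
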